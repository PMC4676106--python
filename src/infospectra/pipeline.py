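"""The full analysis pipeline: preprocess → spectra → nulls → distances →
dendrograms, with every artifact written as plain text.

One run produces, for each combination of {mincut, maxmer} alignment
variant × {with, without} bias correction × {VH, VMI, HMI} method:
per-species spectrum tables, a √JSD distance matrix with propagated SEs,
a distance "histogram" table (the long-form pair distances feeding the
bar plots) and a WPGMA dendrogram in Newick form — twelve distance
matrices, twelve histograms and twelve dendrograms in total — plus
null-model bands and per-method ANOVA screens. A JSON manifest lists
every file and the parameters/seeds that made it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .clustering import merge_table, to_newick, wpgma
from .divergence import discriminability_screen, distance_matrix
from .fixtures import FixtureSpec, generate
from .io import (
    write_distance_long_tsv,
    write_distance_square_tsv,
    write_mimatrix_tsv,
    write_null_band_tsv,
    write_spectrum_tsv,
)
from .nulls import NullConfig, null_spectrum_band
from .seqset import (
    AlignmentSet,
    TrimPolicy,
    apply_species_cutoff,
    consensus_fill,
    drop_blacklisted,
    drop_gappy_sequences,
    read_species_fasta,
    replace_ambiguities,
    trim_columns,
    trim_columns_pooled,
    write_fasta,
)
from .spectra import SpectrumConfig, hmi_spectrum, vertical_entropy_spectrum, vmi_matrix

__all__ = ["PipelineConfig", "run_pipeline", "preprocess", "plot_reports"]

log = logging.getLogger("infospectra")

VARIANTS = ("mincut", "maxmer")
KINDS = ("VH", "VMI", "HMI")


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults follow the reference analysis
    (species cutoff 7, NOL 1, 10 %/40 %/40 % gap thresholds, mnat unit)."""

    input: str | None = None
    species_from: str = "stem"
    header_regex: str | None = None
    outdir: str = "infospectra_out"
    trim: TrimPolicy = field(default_factory=TrimPolicy)
    per_species_trim: bool = False
    blacklist: tuple[str, ...] = ("synthetic",)
    species_cutoff: int = 7
    nol: int = 1
    unit: str = "mnat"
    null_mode: str = "shuffled"
    null_replicates: int = 20
    jsd_replicates: int = 200
    seed: int = 0
    simulate: FixtureSpec | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a plain-text ``key = value`` config (``#`` comments allowed)."""
        kwargs: dict = {}
        trim_kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in (
                "max_vertical_gaps_mincut",
                "max_vertical_gaps_maxmer",
                "max_horizontal_gaps",
            ):
                trim_kwargs[key] = float(value)
            elif key in ("species_cutoff", "nol", "null_replicates", "jsd_replicates", "seed"):
                kwargs[key] = int(value)
            elif key == "per_species_trim":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key == "blacklist":
                kwargs[key] = tuple(w.strip() for w in value.split(",") if w.strip())
            elif key in ("input", "outdir", "unit", "null_mode", "species_from", "header_regex"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        if trim_kwargs:
            kwargs["trim"] = TrimPolicy(**trim_kwargs)
        return cls(**kwargs)


def _load_sets(cfg: PipelineConfig) -> dict[str, AlignmentSet]:
    if cfg.simulate is not None:
        return generate(cfg.simulate)
    if cfg.input is None:
        raise ValueError("config needs either an input path or a fixture spec")
    path = Path(cfg.input)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    return read_species_fasta(path, species_from=cfg.species_from, header_regex=cfg.header_regex)


def preprocess(
    sets: dict[str, AlignmentSet], cfg: PipelineConfig
) -> dict[str, dict[str, AlignmentSet]]:
    """Blacklist purge → column trim (per variant) → gappy-sequence drop →
    ambiguity replacement → consensus fill → species cutoff.

    Returns ``{variant: {species: gap-free AlignmentSet}}``.
    """
    purged = {sp: drop_blacklisted(a, cfg.blacklist) for sp, a in sets.items()}
    thresholds = {
        "mincut": cfg.trim.max_vertical_gaps_mincut,
        "maxmer": cfg.trim.max_vertical_gaps_maxmer,
    }
    out: dict[str, dict[str, AlignmentSet]] = {}
    for variant in VARIANTS:
        thr = thresholds[variant]
        if cfg.per_species_trim:
            trimmed = {sp: trim_columns(a, thr) for sp, a in purged.items()}
        else:
            trimmed = trim_columns_pooled(purged, thr)
        stage = {}
        for sp, a in trimmed.items():
            a = drop_gappy_sequences(a, cfg.trim.max_horizontal_gaps)
            a = replace_ambiguities(a)
            a = consensus_fill(a)
            stage[sp] = a
        stage = apply_species_cutoff(stage, cfg.species_cutoff)
        if not stage:
            raise ValueError(
                f"no species left after cutoff {cfg.species_cutoff} ({variant})"
            )
        for sp, a in stage.items():
            log.info("%s/%s: n=%d L=%d after preprocessing", variant, sp, a.n, a.L)
        out[variant] = stage
    return out


def _distances_defined(spectra: dict, tag: str) -> bool:
    """JSD needs at least one positive bin per spectrum; a fully conserved
    species has a degenerate (all-zero) spectrum and no distances."""
    import numpy as np

    for sp, s in spectra.items():
        vals = np.asarray(s.values, dtype=float)
        if np.clip(vals, 0, None).sum() <= 0:
            log.warning("%s: %s spectrum degenerate (all zero); distances skipped", sp, tag)
            return False
    return True


def _spectrum_for(kind: str, a: AlignmentSet, scfg: SpectrumConfig):
    if kind == "VH":
        return vertical_entropy_spectrum(a, scfg)
    if kind == "VMI":
        return vmi_matrix(a, scfg)
    return hmi_spectrum(a, scfg)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest (also written
    to ``<outdir>/manifest.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = _load_sets(cfg)
    log.info("loaded %d species: %s", len(sets), ", ".join(sorted(sets)))
    variants = preprocess(sets, cfg)

    manifest: dict = {
        "parameters": {
            **{k: v for k, v in asdict(cfg).items() if k not in ("trim", "simulate")},
            "trim": asdict(cfg.trim),
        },
        "species": {v: sorted(d) for v, d in variants.items()},
        "fasta": [],
        "spectra": [],
        "null_bands": [],
        "anova": {},
        "distance_matrices": [],
        "histograms": [],
        "dendrograms": [],
        "merge_tables": [],
    }

    for variant, species_sets in variants.items():
        for sp, a in species_sets.items():
            p = write_fasta(a, outdir / "fasta" / f"{sp}_{variant}.fasta")
            manifest["fasta"].append(str(p))

    combo_no = 0
    for variant in VARIANTS:
        species_sets = variants[variant]
        for bias in (True, False):
            btag = "bias" if bias else "nobias"
            scfg = SpectrumConfig(nol=cfg.nol, bias_correction=bias, unit=cfg.unit)
            for kind in KINDS:
                tag = f"{kind}_{variant}_{btag}"
                spectra = {
                    sp: _spectrum_for(kind, a, scfg) for sp, a in species_sets.items()
                }
                for sp, s in spectra.items():
                    path = outdir / "spectra" / f"{sp}_{tag}.tsv"
                    if kind == "VMI":
                        write_mimatrix_tsv(s, path, variant=variant, bias_correction=bias)
                    else:
                        write_spectrum_tsv(s, path, variant=variant)
                    manifest["spectra"].append(str(path))

                # null band on the first species (alphabetical), as the
                # representative noise reference for this combination
                rep = sorted(species_sets)[0]
                ncfg = NullConfig(
                    mode=cfg.null_mode,
                    seed=(cfg.seed * 1009 + combo_no * 101) % (2**31 - 1),
                    replicates=cfg.null_replicates,
                )
                band = null_spectrum_band(species_sets[rep], kind, ncfg, scfg)
                bpath = outdir / "nulls" / f"{rep}_{tag}_{cfg.null_mode}.tsv"
                write_null_band_tsv(band, bpath, variant=variant)
                manifest["null_bands"].append(str(bpath))

                try:
                    manifest["anova"][tag] = discriminability_screen(list(spectra.values()))
                except ValueError as exc:
                    manifest["anova"][tag] = f"undefined: {exc}"

                if len(spectra) >= 2 and _distances_defined(spectra, tag):
                    dm = distance_matrix(
                        spectra,
                        replicates=cfg.jsd_replicates,
                        seed=(cfg.seed * 7919 + combo_no) % (2**31 - 1),
                        kind=tag,
                    )
                    dpath = write_distance_square_tsv(
                        dm, outdir / "distances" / f"dist_{tag}.tsv"
                    )
                    manifest["distance_matrices"].append(str(dpath))
                    hpath = write_distance_long_tsv(
                        dm, outdir / "distances" / f"hist_{tag}.tsv", variant=variant
                    )
                    manifest["histograms"].append(str(hpath))

                    tree = wpgma(dm)
                    npath = outdir / "dendrograms" / f"id_{tag}.nwk"
                    npath.parent.mkdir(parents=True, exist_ok=True)
                    npath.write_text(to_newick(tree) + "\n")
                    manifest["dendrograms"].append(str(npath))
                    mpath = outdir / "dendrograms" / f"merges_{tag}.tsv"
                    merge_table(tree).to_csv(
                        mpath, sep="\t", index=False, float_format="%.10g"
                    )
                    manifest["merge_tables"].append(str(mpath))
                combo_no += 1

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info(
        "pipeline done: %d distance matrices, %d histograms, %d dendrograms",
        len(manifest["distance_matrices"]),
        len(manifest["histograms"]),
        len(manifest["dendrograms"]),
    )
    return manifest


# ---------------------------------------------------------------------------
# plotting (best-effort; failures never corrupt data artifacts)


def plot_reports(manifest: dict, outdir: str | Path | None = None) -> list[Path]:
    """Render PNGs for every spectrum, distance histogram and dendrogram in
    the manifest. Each figure is attempted independently."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np
    import pandas as pd
    from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

    from .io import read_distance_square_tsv

    out = Path(outdir) if outdir else Path(manifest["parameters"]["outdir"]) / "plots"
    out.mkdir(parents=True, exist_ok=True)
    images: list[Path] = []

    def attempt(fn, *args):
        try:
            p = fn(*args)
            if p is not None:
                images.append(p)
        except Exception as exc:  # plotting must never break the pipeline
            log.warning("plot failed: %s", exc)

    def plot_spectrum(path_str: str) -> Path | None:
        path = Path(path_str)
        df = pd.read_csv(path, sep="\t", comment="#")
        fig, (ax, axh) = plt.subplots(
            1, 2, figsize=(9, 3), gridspec_kw={"width_ratios": [2.5, 1]}
        )
        if {"i", "j"} <= set(df.columns):  # VMI heat map
            P = int(max(df["i"].max(), df["j"].max()))
            dense = np.full((P, P), np.nan)
            dense[df["i"] - 1, df["j"] - 1] = df["value"]
            dense[df["j"] - 1, df["i"] - 1] = df["value"]
            fig.clf()
            ax = fig.add_subplot(111)
            im = ax.imshow(dense, origin="lower", cmap="viridis")
            fig.colorbar(im, ax=ax)
            ax.set_title(path.stem)
        else:
            v = df["value"].to_numpy()
            ax.errorbar(df["index"], v, yerr=df["se"], lw=0.7, elinewidth=0.4, color="tab:blue")
            ax.axhline(v.mean(), color="black", lw=0.8, label="mean")
            if len(v) > 1:
                ax.axhline(v.mean() + 2 * v.std(ddof=1), color="red", lw=0.8, label="+2 SD")
            ax.set_title(path.stem)
            ax.legend(fontsize=6)
            axh.hist(v, bins=30, orientation="horizontal", color="0.7")
            axh.axhline(v.mean(), color="black", lw=0.8)
            if len(v) > 1:
                axh.axhline(v.mean() + v.std(ddof=1), color="red", lw=0.8)
            axh.axhline(np.median(v), color="gold", lw=0.8)
        fig.tight_layout()
        p = out / f"{path.stem}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        return p

    def plot_histogram(path_str: str) -> Path | None:
        path = Path(path_str)
        df = pd.read_csv(path, sep="\t", comment="#")
        fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(df)), 3))
        labels = df["a"] + "-" + df["b"]
        ax.bar(range(len(df)), df["distance"], yerr=2 * df["se"], color="tab:blue")
        ax.set_xticks(range(len(df)), labels, rotation=90, fontsize=6)
        ax.set_ylabel("sqrt(JSD)")
        ax.set_title(path.stem)
        fig.tight_layout()
        p = out / f"{path.stem}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        return p

    def plot_tree(path_str: str) -> Path | None:
        # rebuild the linkage from the matching distance matrix
        path = Path(path_str)
        tag = path.stem.removeprefix("id_")
        dm_path = path.parent.parent / "distances" / f"dist_{tag}.tsv"
        if not dm_path.exists():
            return None
        from .clustering import wpgma as _wpgma

        dm = read_distance_square_tsv(dm_path)
        tree = _wpgma(dm)
        fig, ax = plt.subplots(figsize=(5, 3))
        _scipy_dendrogram(tree.linkage, labels=dm.labels, ax=ax, leaf_rotation=90)
        ax.set_title(path.stem)
        fig.tight_layout()
        p = out / f"{path.stem}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        return p

    for f in manifest.get("spectra", []):
        attempt(plot_spectrum, f)
    for f in manifest.get("histograms", []):
        attempt(plot_histogram, f)
    for f in manifest.get("dendrograms", []):
        attempt(plot_tree, f)
    return images
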