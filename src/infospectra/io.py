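"""Plain-text artifact writers: spectrum/matrix TSVs with metadata
headers, square and long-form distance matrices, Newick files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .divergence import DistanceMatrix
from .nulls import NullBand
from .spectra import MIMatrix, Spectrum

__all__ = [
    "write_spectrum_tsv",
    "write_mimatrix_tsv",
    "write_null_band_tsv",
    "write_distance_square_tsv",
    "write_distance_long_tsv",
    "read_distance_square_tsv",
]

_FLOAT = "%.10g"


def _write_with_header(df: pd.DataFrame, path: Path, header: dict) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT)
    return path


def write_spectrum_tsv(s: Spectrum, path: str | Path, **extra) -> Path:
    df = pd.DataFrame({"index": s.index, "value": s.values, "se": s.se})
    header = {
        "kind": s.kind,
        "species": s.species,
        "unit": s.unit,
        **{k: v for k, v in s.meta.items()},
        **extra,
    }
    return _write_with_header(df, Path(path), header)


def write_mimatrix_tsv(m: MIMatrix, path: str | Path, **extra) -> Path:
    # 1-based coordinates in reports
    df = pd.DataFrame(
        {"i": m.i + 1, "j": m.j + 1, "value": m.values, "se": m.se}
    )
    header = {
        "kind": "VMI",
        "species": m.species,
        "unit": m.unit,
        "nol": m.nol,
        "max_value": _FLOAT % m.max_value,
        "argmax": "%d x %d" % m.argmax,
        **extra,
    }
    return _write_with_header(df, Path(path), header)


def write_null_band_tsv(b: NullBand, path: str | Path, **extra) -> Path:
    df = pd.DataFrame(
        {"index": b.index, "mean": b.mean, "sd": b.sd, "lo": b.lo, "hi": b.hi}
    )
    header = {
        "kind": b.kind,
        "mode": b.mode,
        "unit": b.unit,
        "replicates": b.replicates,
        **b.meta,
        **extra,
    }
    return _write_with_header(df, Path(path), header)


def write_distance_square_tsv(dm: DistanceMatrix, path: str | Path) -> Path:
    """PHYLIP-like labelled square matrix; the matching ``*.se.tsv`` file
    holds the propagated SEs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dm.to_frame().to_csv(path, sep="\t", float_format=_FLOAT, index_label="species")
    se = pd.DataFrame(dm.se, index=dm.labels, columns=dm.labels)
    se.to_csv(path.with_suffix(".se.tsv"), sep="\t", float_format=_FLOAT, index_label="species")
    return path


def write_distance_long_tsv(dm: DistanceMatrix, path: str | Path, **extra) -> Path:
    long = dm.to_long()
    long["ci_lo"] = long["distance"] - 2 * long["se"]
    long["ci_hi"] = long["distance"] + 2 * long["se"]
    return _write_with_header(long, Path(path), {"kind": dm.kind, **extra})


def read_distance_square_tsv(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    se_path = path.with_suffix(".se.tsv")
    if se_path.exists():
        se = pd.read_csv(se_path, sep="\t", index_col=0).to_numpy()
    else:
        se = np.zeros_like(df.to_numpy())
    return DistanceMatrix(labels=list(df.index), d=df.to_numpy(), se=se)
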