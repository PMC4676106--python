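"""Informational distances between species and their WPGMA dendrogram.

Generates two species from one process plus a structurally different
third species (a periodic motif in its background), computes √JSD
distances between their HMI spectra with empirically propagated SEs, and
clusters them into an informational dendrogram.
"""

from infospectra import (
    FixtureSpec,
    SpectrumConfig,
    discrimination_calls,
    distance_matrix,
    generate,
    hmi_spectrum,
    merge_table,
    to_newick,
    wpgma,
)

cfg = SpectrumConfig(bias_correction=True)

plain = generate(FixtureSpec(n_species=2, n_per_species=12, L=300, seed=1,
                             polymorphic_columns=((23, 0.2), (57, 0.35))))
motif = generate(FixtureSpec(n_species=1, n_per_species=12, L=300, seed=2,
                             periodic_motif=("AACGTGCT", 0.8)))

spectra = {
    "plainA": hmi_spectrum(plain["sp01"], cfg),
    "plainB": hmi_spectrum(plain["sp02"], cfg),
    "motifC": hmi_spectrum(motif["sp01"], cfg),
}

dm = distance_matrix(spectra, replicates=200, seed=3)
print("sqrt(JSD) distance matrix (natural-log JSD):")
print(dm.to_frame().round(4))
print()
print("pairwise calls (CI = d ± 2 SE):")
rep = discrimination_calls(dm)
print(rep.calls[["a", "b", "distance", "se", "discriminated"]].round(4).to_string(index=False))

tree = wpgma(dm)
print()
print("WPGMA merge sequence:")
print(merge_table(tree).round(4).to_string(index=False))
print("newick:", to_newick(tree))
print()
print("The two same-process species sit an order of magnitude closer to")
print("each other than either is to the motif-bearing species, so the")
print("dendrogram joins them first; the motif species attaches last at a")
print("much larger merge height.")
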