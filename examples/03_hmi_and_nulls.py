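"""Horizontal mutual information versus its shuffled null.

A species whose sequences carry a periodic 8-mer motif shows an HMI peak
at the motif period; shuffling the residues (preserving composition)
destroys it. The null band is the mean ± 2 sd over shuffled replicates.
"""

import numpy as np

from infospectra import (
    FixtureSpec,
    NullConfig,
    SpectrumConfig,
    generate,
    hmi_spectrum,
    null_spectrum_band,
)

spec = FixtureSpec(
    n_species=1, n_per_species=10, L=240,
    periodic_motif=("AACGTGCT", 0.9), seed=7,
)
aln = generate(spec)["sp01"]
cfg = SpectrumConfig(bias_correction=True, unit="mnat")

s = hmi_spectrum(aln, cfg)
band = null_spectrum_band(aln, "HMI", NullConfig(mode="shuffled", seed=1, replicates=20), cfg)

peak = int(s.index[np.argmax(s.values)])
print(f"HMI spectrum over lags k = {s.index.min()} .. {s.index.max()}")
print(f"peak at k = {peak} with HMI = {s.values.max():.1f} mnat (ensemble SE {s.se[np.argmax(s.values)]:.1f})")
print(f"real spectrum mean = {s.values.mean():.2f} mnat")
print(f"shuffled null mean = {band.mean.mean():.2f} mnat (sd of bin means {band.mean.std(ddof=1):.2f})")
exceed = (s.values > band.hi).sum()
print(f"bins above the null upper band: {exceed} / {len(s.values)}")
print()
print("The periodic motif repeats every 8 bases, so positions 8 apart are")
print("strongly dependent: HMI peaks at k = 8 (and its multiples). After")
print("shuffling, the bias-corrected HMI collapses to ~0 mnat — the real")
print("spectrum carries signal that composition alone cannot explain.")
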