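# infospectra

Information-theoretic comparison of species sequence sets. Given aligned
DNA sequences grouped by species, `infospectra` computes three
"information spectra" per species, turns them into pairwise
**informational distances** via the Jensen–Shannon divergence, and
clusters species into **informational dendrograms**. It is aimed at
molecular-evolution work on closely related species — asking whether a
locus carries enough statistical signature to tell species apart — and
at exploratory covariation analysis within a locus.

## The quantities

With column (or word) probabilities `p_m`, all logs natural (unit: nat;
`mnat` = 10⁻³ nat; 1 MER = ln 4 nat, the entropy of an equiprobable
A/C/G/T site):

- **Vertical entropy (VH)** — per-column Shannon entropy across a
  species' sequences, `H = −Σ_m p_m ln p_m`: a per-site polymorphism
  profile.
- **Vertical mutual information (VMI)** — for column pairs (i, j),
  `MI(i,j) = H(i) + H(j) − H(i,j) = Σ_{m,n} p_mn ln [p_mn/(p_m p_n)]`:
  inter-site covariation across sequences.
- **Horizontal mutual information (HMI)** — auto-MI of a single
  sequence between positions k apart, averaged over the species
  ensemble, for lags k = 3 … L/2: within-sequence long-range structure.
- Tokens can be words of NOL ≥ 1 letters (alphabet size 4^NOL);
  all defaults use NOL = 1.
- **Bias correction and SEs** — first-order finite-sample corrections
  `H ← H + (M̂−1)/(2N)` and `MI ← MI − (M̂_xy−M̂_x−M̂_y+1)/(2N)` with
  delta-method standard errors (Roulston-style); HMI additionally
  carries the ensemble standard error across sequences.
- **Informational distance** — spectra are normalised to probability
  vectors P, Q over their bins and compared by
  `JSD(P‖Q) = H((P+Q)/2) − ½(H(P)+H(Q))`; `√JSD` is a metric, with SE
  by Monte-Carlo propagation of the per-bin SEs.
- **Informational dendrogram** — WPGMA hierarchical clustering of the
  `√JSD` matrix (a cluster diagram, deliberately not a phylogeny).

Preprocessing follows the standard gap-control recipe: blacklist purge
of undesirable records, column trimming at a maximum per-column gap
fraction (10 % → "mincut", 40 % → "maxmer"), removal of sequences with
more than 40 % gaps, IUPAC ambiguity resolution by column consensus,
and replacement of remaining gaps by the column consensus nucleotide.
Shuffled (composition-preserving) and random null models provide
empirical noise bands for every spectrum.

## Worked example

```python
from infospectra import (AlignmentSet, SequenceRecord, SpectrumConfig,
                         vertical_entropy_spectrum)

cols = ["AAAAAAAA", "AAAAGGGG", "AAAAGGCC", "ACGTACGT"]
rows = ["".join(c[r] for c in cols) for r in range(8)]
aln = AlignmentSet("demo", [SequenceRecord(f"s{i}", f"s{i}", r)
                            for i, r in enumerate(rows)])
s = vertical_entropy_spectrum(aln, SpectrumConfig(unit="nat"))
print(s.values.round(4))
```

prints

```
[0.     0.6931 1.0397 1.3863]
```

— column 1 is conserved (H = 0), column 2 is a 50/50 two-state site
(ln 2 = 0.6931 nat), and column 4 is equiprobable over all four
nucleotides, reaching the DNA maximum 1.3863 nat = 1 MER. The
`examples/` directory has one short narrative script per capability
(entropy spectra, covariation detection, HMI vs. its shuffled null,
distances + dendrograms, and the full pipeline); each prints the numbers
it computes and what they mean.

## Command line

```sh
infospectra simulate --outdir fixture --seed 3        # synthetic species
infospectra all --input fixture --outdir run --seed 1 # full pipeline
```

`all` runs preprocess → spectra → nulls → distances → dendrograms and
writes, for each {mincut, maxmer} × {bias, no-bias} × {VH, VMI, HMI}
combination, the spectrum tables, a √JSD distance matrix with SEs, a
distance histogram table and a Newick dendrogram — twelve of each —
plus null bands and a JSON manifest. The verbs `prepare`, `spectra`,
`nulls`, `distances`, `dendrogram` and `plot` expose the stages
individually; all parameters can also come from a plain-text
`key = value` config file.

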