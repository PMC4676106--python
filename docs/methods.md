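# Methods

## Model and estimators

All spectra are plug-in (maximum-likelihood) information estimates over
the nucleotide alphabet {A, C, G, T}, or over 4^NOL words of NOL
letters, with the convention 0·log 0 = 0 and natural logarithms
throughout. The internal unit is the nat; `mnat` (×1000) and `MER`
(÷ NOL·ln 4, so an equiprobable word distribution scores 1) are pure
presentation conversions applied at the end.

**Vertical entropy (VH).** For each word start position the entropy of
the word distribution across a species' n sequences. One bin per
position; positions are 0-based in function arguments and 1-based in
every report and file.

**Vertical mutual information (VMI).** For every ordered position pair
with non-overlapping word windows (j ≥ i + NOL), the MI of the joint
word-pair distribution across sequences, enumerated row-major (i
ascending, then j). The matrix is stored condensed over that fixed
order; the same order defines the flattening used when a VMI matrix is
normalised for divergence computation. Sample size N = n sequences.

**Horizontal mutual information (HMI).** For a single sequence and lag
k, a cursor slides with step 1 collecting ordered word pairs at
(t, t + k); the pair-count MI is the per-sequence HMI(k). Valid lags are
k = 3 … ⌊L/2⌋ (the lower bound is fixed; lags below 3 are rejected) and
k ≥ NOL so windows never overlap. Sample size N = number of pairs,
L − k − NOL + 1. The species spectrum averages per-sequence values:
the per-bin value is the ensemble mean and the per-bin SE is the
ensemble standard error sd/√n (zero when n = 1). Averaging
per-sequence MI, rather than pooling pair counts across sequences, is
the deliberate choice: the ensemble is the replication unit, which makes
the reported SE meaningful; pooling would give different values at
small N.

**Bias correction.** The optional first-order corrections are
H ← H + (M̂ − 1)/(2N) and MI ← MI − (M̂_xy − M̂_x − M̂_y + 1)/(2N), where
M̂ counts states with nonzero observed probability. They follow from
applying the first-order entropy bias term to each entropy in
MI = H(x) + H(y) − H(xy). Note the MI term can be negative (a
near-bijective joint support is much smaller than the marginal
product), in which case correction moves MI up. Corrected values may
go slightly negative; spectra keep them as estimated, and they are
clamped to zero only when a spectrum is normalised into a probability
vector.

**Standard errors.** Delta-method variances of the plug-in estimators:
Var(H) = (Σ p (ln p)² − H²)/N and
Var(MI) = (Σ p_mn (ln p_mn − ln p_m − ln p_n)² − MI²)/N, evaluated at
the uncorrected point estimates, with N = n for vertical spectra. For
HMI the headline SE is the ensemble standard error (above); the
per-sequence delta-method SE is available through
`mutual_information` but is not what the spectrum reports.

## Preprocessing

Stage order is fixed: blacklist purge → column trimming → gappy-sequence
removal → ambiguity resolution → consensus gap filling → species
cutoff. Trimming deletes columns whose gap fraction strictly exceeds
the threshold — 0.10 for the "mincut" variant, 0.40 for "maxmer" under
the defaults — and is applied to the pooled cross-species alignment by
default (all species share columns; a per-species option exists but
produces species of unequal lengths). Sequences with more than 40 %
gaps are then dropped. IUPAC codes are replaced by the most frequent
column nucleotide among the set the code permits, falling back to the
alphabetically first permitted nucleotide when none occurs; remaining
gaps take the column consensus, ties broken alphabetically
(A < C < G < T). Every downstream spectrum requires this gap-free
{A,C,G,T} output. The default species cutoff keeps species with at
least 7 sequences.

## Null models

The shuffled null permutes each sequence's residues independently
(exactly preserving per-sequence composition); the random null draws
i.i.d. uniform nucleotides of the same shape. Replicate r of a band
uses seed + r; bands report the per-bin replicate mean ± 2 sd. The
default replicate count is 20 (configurable): the empirical bands
stabilise well before that for the statistics involved, and no
analytical null is attempted.

## Distances, SEs, calls

Spectra are normalised (negative bins clamped to 0, then divided by the
sum; an all-zero spectrum is an error) and compared by JSD with natural
logs, so 0 ≤ JSD ≤ ln 2 and √JSD is a metric; base choice only rescales
distances and cannot change clustering topology. HMI spectra of unequal
length are truncated to the shared lag range before comparison; VH and
VMI spectra must already agree in bin structure. Because JSD is
nonlinear, the distance SE is Monte-Carlo propagated: each replicate
(default 200) perturbs every bin with zero-mean Gaussian noise of that
bin's SE, clamps, renormalises and recomputes √JSD; the SE is the sd
over replicates. Bins with value 0 and SE 0 never move. Each species
pair uses its own derived seed, so the matrix is reproducible and
independent of iteration order.

The per-pair discrimination call is "CI excludes zero" with
CI = d ± 2·SE; a stricter matrix-level summary also reports the
fraction of pairs whose CIs overlap no other pair's CI. **Known
limitation:** √JSD between two noisy spectra is a positively biased
statistic — even spectra estimated from the *same* generating process
sit at a small positive distance, and the propagated SE (which tracks
the sampling spread, not the bias) is typically an order of magnitude
smaller than that offset at ~10²-bin resolution. The zero-exclusion
call is therefore liberal; distances should be read comparatively
(same-process pairs land an order of magnitude below
structurally-different pairs), which is what the end-to-end tests
assert.

One-way ANOVA across spectra (each spectrum's bins as one group) is
exposed as a cheap screen that at least one spectrum differs before
distances are computed; it applies no multiple-testing correction, and
none is applied across pairwise calls either.

## Clustering

WPGMA: iteratively merge the closest pair; the new cluster's distance
to an outsider is the plain mean of its members' distances. Merge
height is d/2 (ultrametric convention), so the cophenetic distance
between two leaves is twice the height of their join, and on an
ultrametric input matrix the tree reproduces the input exactly. Ties
break deterministically towards the lowest original label indices.
Newick export writes branch lengths (leaf height 0) and quotes labels
containing separators.

## Synthetic data generator

The generator emulates a conserved locus sampled per species — the
regime where the method is interesting: most columns carry zero
entropy (median VH = 0) and long-range signal is weak. One background
reference is drawn per call and shared by all species (they model
homologous copies of one locus, which is what makes pooled
cross-species trimming coherent and makes species from one call
realisations of the same process); each species' own substream then
realises planted polymorphic columns (minor-allele fractions),
covarying column pairs (with probability c the residue at j is a fixed
Watson–Crick-like bijective image of a uniform draw at i), an optional
periodic motif written into period-aligned blocks with a given
probability (the horizontal signal), and sprinkled gaps and ambiguity
codes. The stock conditions (`conserved_locus_spec`) use 3 species ×
12 sequences × 300 bp, eight polymorphic columns at minor-allele
fractions 0.1–0.4, one fully coupled pair, a 12-mer motif at rate 0.6,
2 % gaps and 0.2 % ambiguity codes. What the fixtures do **not**
emulate: real inter-species divergence, phylogenetic correlation
structure, indel processes, or alignment error — so passing tests show
the estimators and pipeline behave correctly on controlled structure,
not that any particular real locus discriminates species.

## Numerical choices and problem sizes

Zero-probability cells contribute nothing to any sum; variances are
clamped at 0 before the square root; −0.0 entropies are normalised to
0.0. TSV artifacts are written with a fixed `%.10g` float format so
identical runs are byte-identical. All randomness flows through
numpy `default_rng` with explicitly derived sub-seeds.

Test and acceptance runs use deliberately desk-scale problems — e.g.
500 random alignments (n ≤ 6, L ≤ 8) for exact enumeration
equivalence, 100 replicates of a 30 × 40 alignment for planted-pair
recovery, 900-bp sets for the shuffled-HMI null, and the stock
3 × 12 × 300 fixture for the end-to-end pipeline — sizes chosen so the
whole suite exercises every code path in minutes while keeping the
statistical claims (3σ envelopes, ≥ 95 % recovery) meaningful. A run
at 17 species × ~26 sequences × ~860 bp completes in minutes on one
CPU thanks to the vectorised pair counting.
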