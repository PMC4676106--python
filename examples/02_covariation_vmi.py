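"""Finding a covarying column pair with vertical mutual information.

Plants one fully coupled pair of columns (the residue at one position
determines the residue at the other) into an otherwise conserved
synthetic species and shows that the VMI matrix argmax locates it.
"""

from infospectra import FixtureSpec, SpectrumConfig, generate, vmi_matrix

spec = FixtureSpec(
    n_species=1,
    n_per_species=30,
    L=40,
    covarying_pairs=((12, 27, 1.0),),  # 0-based plant; reported 1-based
    seed=42,
)
aln = generate(spec)["sp01"]

m = vmi_matrix(aln, SpectrumConfig(unit="mnat"))
print(f"VMI computed for {len(m)} column pairs of a {aln.n} x {aln.L} alignment")
print(f"max(VMI) = {m.max_value:.1f} mnat at columns {m.argmax[0]} x {m.argmax[1]}")

corr = vmi_matrix(aln, SpectrumConfig(unit="mnat", bias_correction=True))
print(f"with bias correction: {corr.max_value:.1f} mnat at {corr.argmax[0]} x {corr.argmax[1]}")
print()
print("The planted pair sits at columns 13 x 28 (1-based); every other")
print("pair involves at least one conserved column and carries no mutual")
print("information. The first-order correction term (M_xy - M_x - M_y + 1)/(2N)")
print("is negative for a near-bijective pair (the joint support is much")
print("smaller than the product of the marginals), so here the corrected")
print("estimate moves slightly up towards the true ln 4 = 1386 mnat.")
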