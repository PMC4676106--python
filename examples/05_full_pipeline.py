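"""The complete pipeline on a synthetic three-species locus.

Simulates a conserved locus (gaps and ambiguity codes included), then
runs preprocessing (blacklist purge, mincut/maxmer column trimming,
gappy-sequence removal, ambiguity resolution, consensus gap filling,
species cutoff), all three spectra with and without bias correction,
shuffled null bands, √JSD distance matrices with propagated SEs, and
WPGMA dendrograms — 2 variants x 2 bias settings x 3 methods = 12
distance matrices, 12 histograms and 12 dendrograms.
"""

import json
from pathlib import Path

from infospectra import PipelineConfig, conserved_locus_spec, run_pipeline

outdir = Path("scratch_pipeline_demo")
cfg = PipelineConfig(
    outdir=str(outdir),
    simulate=conserved_locus_spec(seed=5),
    seed=11,
    null_replicates=5,
    jsd_replicates=100,
)
manifest = run_pipeline(cfg)

print("artifacts produced:")
for key in ("fasta", "spectra", "null_bands", "distance_matrices",
            "histograms", "dendrograms"):
    print(f"  {key:>18}: {len(manifest[key])}")
print()
print("ANOVA screen p-values per combination:")
print(json.dumps(manifest["anova"], indent=2, default=str))
print()
print("Each of the 12 method/variant/bias combinations yields one distance")
print("matrix, one histogram table and one Newick dendrogram under")
print(f"{outdir}/. Re-running with the same seed reproduces every TSV byte")
print("for byte. Here all species come from one generating process, so the")
print("ANOVA p-values are large — with real species-specific structure they")
print("drop towards zero, licensing the distance comparison.")
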