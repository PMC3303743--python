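"""Predict structure disruption from sequence alone (pSDC, four metrics).

For a WT sequence and a few mutations, computes the predicted Structure
Disruption Coefficient under each metric: MFE binary vectors, partition
function unpaired probabilities, Z-centroid structures, and the medoid of
the most populated k-means cluster.
"""

from sdckit import FoldEngine, psdc_table
from sdckit.synth import make_switchable_sequence, plant_mutations

engine = FoldEngine()
seq, reg1, reg2 = make_switchable_sequence(n=60, seed=1, engine=engine)
muts = plant_mutations(seq, 10, 0.2, seed=7, engine=engine, registers=(reg1, reg2))
mutations = [m for m, c in muts if c == 1] + [m for m, c in muts if c == 0][:2]
table = psdc_table(seq, mutations, engine, sample_size=2000, k=2, seed=0)
print(table.pivot(index="variant_id", columns="metric", values="psdc").round(3).to_string())
print(
    "\npSDC = (1 - Pearson CC of predicted structure vectors) * sqrt(n)."
    "\nStem-breaking doubles score high under every metric; loop"
    "\nsubstitutions stay near zero."
)
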