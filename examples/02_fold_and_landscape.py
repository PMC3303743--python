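"""Fold a switchable RNA and project its conformational landscape.

Computes the MFE structure, exact base-pair probabilities and a Boltzmann
sample for a WT sequence and a stem-breaking mutant, then maps both
ensembles onto the first two principal components and reports how the
mutation repartitions the k-means clusters.
"""

from sdckit import FoldEngine, apply_mutation, pca_project
from sdckit.synth import make_switchable_sequence, plant_mutations

engine = FoldEngine()
seq, reg1, reg2 = make_switchable_sequence(n=60, seed=1, engine=engine)
muts = plant_mutations(seq, 5, 0.2, seed=7, engine=engine, registers=(reg1, reg2))
disruptor = next(m for m, c in muts if c == 1)
mut = apply_mutation(seq, disruptor)

print("WT MFE :", engine.mfe_structure(seq).to_dotbracket())
print("mut MFE:", engine.mfe_structure(mut).to_dotbracket())

ensembles = [
    ("WT", engine.sample_structures(seq, 2000, seed=0)),
    (disruptor.label, engine.sample_structures(mut, 2000, seed=1)),
]
proj = pca_project(ensembles, k=4, seed=0)
print("\ncluster occupancies (rows sum to 1):")
print(proj.occupancies.round(3).to_string())
print(
    "\nEach sampled structure is a point in PC space.  The WT ensemble"
    "\noccupies one pair of clusters; the stem-breaking double mutant moves"
    "\nalmost all of its mass into the clusters of the competing register."
)
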