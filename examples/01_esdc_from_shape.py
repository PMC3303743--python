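"""Quantify mutation-induced structure change from SHAPE profiles (eSDC).

Simulates a small mutate-and-map experiment for a two-hairpin RNA: six WT
replicates plus one profile for a structure-switching mutant and one for a
loop mutant, then runs the normalize -> cap -> eSDC -> p-value pipeline.
"""

import numpy as np

from sdckit import (
    FoldEngine,
    MutantCollection,
    NoiseModel,
    apply_mutation,
    esdc_table,
    prepare_collection,
    simulate_shape,
)
from sdckit.synth import make_switchable_sequence, plant_mutations

engine = FoldEngine()
seq, reg1, reg2 = make_switchable_sequence(n=60, seed=1, engine=engine)
# one verified stem-breaking disruptor and one verified loop neutral
muts = plant_mutations(seq, 5, 0.2, seed=7, engine=engine, registers=(reg1, reg2))
picks = [next(m for m, c in muts if c == 1), next(m for m, c in muts if c == 0)]

profiles = simulate_shape(
    engine.mfe_structure(seq), NoiseModel(sd=0.1), replicates=6, seed=0, variant_id="WT"
)
for mspec in picks:
    mut = apply_mutation(seq, mspec)
    profiles += simulate_shape(
        engine.mfe_structure(mut), NoiseModel(sd=0.1), replicates=1, seed=1,
        variant_id=mspec.label,
    )

collection = prepare_collection(MutantCollection(rna_id="demo", profiles=profiles))
table = esdc_table(collection, n=seq.n, seed=0)
print(table.round(3).to_string(index=False))
print(
    "\neSDC = (1 - Pearson CC) * sqrt(n): the stem-breaking double mutant sits"
    "\nfar above the replicate-noise null (small p-value), the loop mutant"
    "\ndoes not."
)
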