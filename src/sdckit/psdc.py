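"""Predicted Structure Disruption Coefficients (pSDC).

The pSDC mirrors the experimental eSDC but replaces SHAPE profiles with
per-nucleotide structure vectors from a prediction engine::

    pSDC = (1 - r_pred) * sqrt(n)

where ``r_pred`` is the Pearson correlation between the WT and mutant vectors.
Four metrics produce those vectors:

``mfe``              unpaired indicator of the MFE structure;
``bpp``              unpaired probability from the (exact or sampled)
                     partition matrix;
``z_centroid``       unpaired indicator of the >50% pair-probability
                     structure;
``cluster_centroid`` unpaired indicator of the medoid of the most populated
                     k-means cluster of a sampled ensemble.

A constant vector (e.g. a fully unpaired MFE) leaves the correlation
undefined; by convention pSDC is then 0 if both vectors are constant and
equal, else the maximal 2*sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import (
    cluster_centroid_structure,
    ensemble_partition_matrix,
    pairing_vector,
    structure_binary_vector,
    z_centroid,
)
from .esdc import pearson_cc
from .fold import (
    FoldEngine,
    MutationSpec,
    RnaSequence,
    StructureEnsemble,
    apply_mutation,
    parse_mutation,
)

__all__ = [
    "PsdcResult",
    "METRICS",
    "psdc_from_vectors",
    "psdc_mfe",
    "psdc_bpp",
    "psdc_z_centroid",
    "psdc_cluster_centroid",
    "psdc_table",
]

METRICS = ("mfe", "bpp", "z_centroid", "cluster_centroid")


@dataclass
class PsdcResult:
    variant_id: str
    metric: str
    psdc: float
    pred_cc: float
    n: int
    engine: str = "builtin"
    sample_size: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        assert abs(self.psdc - (1.0 - self.pred_cc) * math.sqrt(self.n)) < 1e-9


def psdc_from_vectors(
    wt_vec: np.ndarray,
    mut_vec: np.ndarray,
    n: int,
    variant_id: str = "",
    metric: str = "custom",
    **meta,
) -> PsdcResult:
    """(1 - Pearson CC) * sqrt(n) on two structure vectors, with the
    degenerate-vector fallback described in the module docstring."""
    wt_vec = np.asarray(wt_vec, dtype=float)
    mut_vec = np.asarray(mut_vec, dtype=float)
    if wt_vec.shape != mut_vec.shape:
        raise ValueError("structure vectors must have equal length")
    wt_const = np.ptp(wt_vec) == 0
    mut_const = np.ptp(mut_vec) == 0
    if wt_const or mut_const:
        if wt_const and mut_const and np.allclose(wt_vec, mut_vec):
            cc = 1.0
        else:
            cc = -1.0
    else:
        cc = pearson_cc(wt_vec, mut_vec)
    return PsdcResult(
        variant_id=variant_id,
        metric=metric,
        psdc=(1.0 - cc) * math.sqrt(n),
        pred_cc=cc,
        n=n,
        **meta,
    )


def psdc_mfe(
    wt_seq: RnaSequence, mut_seq: RnaSequence, engine: FoldEngine, variant_id: str = ""
) -> PsdcResult:
    """pSDC between the unpaired-indicator vectors of the two MFE structures."""
    wt_v = structure_binary_vector(engine.mfe_structure(wt_seq))
    mut_v = structure_binary_vector(engine.mfe_structure(mut_seq))
    return psdc_from_vectors(wt_v, mut_v, wt_seq.n, variant_id, "mfe")


def psdc_bpp(
    wt_seq: RnaSequence | None = None,
    mut_seq: RnaSequence | None = None,
    engine: FoldEngine | None = None,
    wt_ensemble: StructureEnsemble | None = None,
    mut_ensemble: StructureEnsemble | None = None,
    variant_id: str = "",
) -> PsdcResult:
    """pSDC between unpaired-probability vectors of the two partition matrices.

    Matrices are exact (engine DP) when sequences + engine are given, or
    sampled (ensemble averages) when pre-computed ensembles are given.
    """
    if wt_ensemble is not None and mut_ensemble is not None:
        wt_P = ensemble_partition_matrix(wt_ensemble)
        mut_P = ensemble_partition_matrix(mut_ensemble)
        n = wt_ensemble.sequence.n
        eng_label = wt_ensemble.engine
    elif wt_seq is not None and mut_seq is not None and engine is not None:
        wt_P = engine.pair_probabilities(wt_seq)
        mut_P = engine.pair_probabilities(mut_seq)
        n = wt_seq.n
        eng_label = "builtin"
    else:
        raise ValueError("provide either sequences + engine or two ensembles")
    res = psdc_from_vectors(pairing_vector(wt_P), pairing_vector(mut_P), n, variant_id, "bpp")
    res.engine = eng_label
    return res


def psdc_z_centroid(
    wt_ensemble: StructureEnsemble, mut_ensemble: StructureEnsemble, variant_id: str = ""
) -> PsdcResult:
    """pSDC between the binary vectors of the two Z-centroid structures."""
    wt_s = z_centroid(ensemble_partition_matrix(wt_ensemble))
    mut_s = z_centroid(ensemble_partition_matrix(mut_ensemble))
    res = psdc_from_vectors(
        structure_binary_vector(wt_s),
        structure_binary_vector(mut_s),
        wt_ensemble.sequence.n,
        variant_id,
        "z_centroid",
    )
    res.engine = wt_ensemble.engine
    return res


def psdc_cluster_centroid(
    wt_ensemble: StructureEnsemble,
    mut_ensemble: StructureEnsemble,
    k: int = 4,
    seed: int = 0,
    variant_id: str = "",
) -> PsdcResult:
    """pSDC between binary vectors of the two most-populated-cluster medoids."""
    wt_s = cluster_centroid_structure(wt_ensemble, k=k, seed=seed)
    mut_s = cluster_centroid_structure(mut_ensemble, k=k, seed=seed)
    res = psdc_from_vectors(
        structure_binary_vector(wt_s),
        structure_binary_vector(mut_s),
        wt_ensemble.sequence.n,
        variant_id,
        "cluster_centroid",
    )
    res.engine = wt_ensemble.engine
    res.seed = seed
    return res


def psdc_table(
    wt_seq: RnaSequence,
    mutation_specs: list[str | MutationSpec],
    engine: FoldEngine,
    metrics: tuple[str, ...] = METRICS,
    sample_size: int = 1000,
    k: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per (mutation, metric), deterministic given the seed.

    The WT ensemble is sampled once and reused across all mutants so that
    sampling noise does not inflate pSDC differences between mutants.
    """
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}; choose from {METRICS}")
    needs_ensembles = bool({"z_centroid", "cluster_centroid"} & set(metrics))
    wt_ens = (
        engine.sample_structures(wt_seq, sample_size, seed) if needs_ensembles else None
    )
    rows: list[PsdcResult] = []
    for idx, spec in enumerate(mutation_specs):
        mspec = parse_mutation(spec) if isinstance(spec, str) else spec
        mut_seq = apply_mutation(wt_seq, mspec)
        mut_ens = (
            engine.sample_structures(mut_seq, sample_size, seed + 1 + idx)
            if needs_ensembles
            else None
        )
        for metric in metrics:
            if metric == "mfe":
                res = psdc_mfe(wt_seq, mut_seq, engine, mspec.label)
            elif metric == "bpp":
                res = psdc_bpp(wt_seq, mut_seq, engine, variant_id=mspec.label)
            elif metric == "z_centroid":
                res = psdc_z_centroid(wt_ens, mut_ens, mspec.label)
            else:
                res = psdc_cluster_centroid(wt_ens, mut_ens, k=k, seed=seed, variant_id=mspec.label)
            res.sample_size = sample_size if needs_ensembles else None
            rows.append(res)
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in rows],
            "metric": [r.metric for r in rows],
            "pred_cc": [r.pred_cc for r in rows],
            "psdc": [r.psdc for r in rows],
            "n": [r.n for r in rows],
            "engine": [r.engine for r in rows],
        }
    )
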