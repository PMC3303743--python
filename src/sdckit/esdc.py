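"""Experimental Structure Disruption Coefficient (eSDC) and its empirical null.

The eSDC of a mutant measures how much a mutation disrupts an RNA's structure
as seen by SHAPE probing::

    eSDC = (1 - r) * sqrt(n)

where ``r`` is the Pearson correlation between the capped WT and mutant SHAPE
profiles and ``n`` is the length of the RNA construct.  Identical profiles give
0; perfectly anti-correlated profiles give 2*sqrt(n).  Significance is assessed
against an empirical "within" null built from all replicate pairs of a single
variant, so the null captures exactly the experiment-to-experiment noise of the
assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .shape import MutantCollection, ReactivityProfile

__all__ = [
    "SDCResult",
    "NullDistribution",
    "pearson_cc",
    "esdc",
    "within_null",
    "empirical_pvalue",
    "bonferroni",
    "esdc_table",
]


def pearson_cc(x: np.ndarray, y: np.ndarray, min_overlap: int = 3) -> float:
    """Pearson correlation over pairwise-complete positions.

    Raises on fewer than ``min_overlap`` complete pairs or on zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share a position frame")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_overlap:
        raise ValueError(f"need >= {min_overlap} pairwise-complete positions, have {ok.sum()}")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero variance")
    if np.array_equal(xs, ys):
        return 1.0  # exact, so eSDC(x, x) is exactly 0
    # product-moment form: bit-for-bit symmetric under argument swap
    dx, dy = xs - xs.mean(), ys - ys.mean()
    r = float(dx @ dy) / math.sqrt(float(dx @ dx) * float(dy @ dy))
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class SDCResult:
    """eSDC of one mutant against WT, with optional significance call."""

    variant_id: str
    esdc: float
    cc: float
    n: int
    n_overlap: int
    p_value: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        assert abs(self.esdc - (1.0 - self.cc) * math.sqrt(self.n)) < 1e-9
        assert -1e-12 <= self.esdc <= 2.0 * math.sqrt(self.n) + 1e-12


def _paired_values(a: ReactivityProfile, b: ReactivityProfile) -> tuple[np.ndarray, np.ndarray]:
    common = np.intersect1d(a.positions, b.positions)
    return a.values_at(common), b.values_at(common)


def esdc(wt: ReactivityProfile, mut: ReactivityProfile, n: int) -> SDCResult:
    """eSDC = (1 - Pearson CC) * sqrt(n) on the shared position frame.

    ``n`` is the declared construct length (not the overlap count, which is
    reported separately as ``n_overlap``).
    """
    for p in (wt, mut):
        if p.state != "capped":
            raise ValueError(f"profile {p.variant_id!r} must be capped, is {p.state!r}")
    x, y = _paired_values(wt, mut)
    ok = ~(np.isnan(x) | np.isnan(y))
    cc = pearson_cc(x, y)
    if n < int(ok.sum()):
        raise ValueError("declared length n smaller than the probed overlap")
    return SDCResult(
        variant_id=mut.variant_id,
        esdc=(1.0 - cc) * math.sqrt(n),
        cc=cc,
        n=n,
        n_overlap=int(ok.sum()),
    )


@dataclass
class NullDistribution:
    """Pairwise 'within' eSDC values from replicates of a single variant."""

    values: np.ndarray
    source_rna: str
    n_replicates: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty null distribution")
        if np.any(self.values < -1e-12):
            raise ValueError("null eSDC values must be >= 0")

    def augmented(self, size: int = 10_000, seed: int = 0) -> "NullDistribution":
        """Bootstrap-resample the pairwise values up to ``size`` draws.

        C(6, 2) = 15 pairwise values cannot express small p-values on their
        own; resampling (with replacement, seeded) gives a smoother null of
        configurable size while leaving the distribution's support unchanged.
        """
        rng = np.random.default_rng(seed)
        vals = rng.choice(self.values, size=size, replace=True)
        return NullDistribution(vals, self.source_rna, self.n_replicates)

    def rescaled(self, n_from: int, n_to: int) -> "NullDistribution":
        """Transfer a null between constructs of different lengths.

        eSDC factors as (1 - CC) * sqrt(n); the noise lives in (1 - CC), so a
        borrowed null is rescaled by sqrt(n_to / n_from).
        """
        return NullDistribution(
            self.values * math.sqrt(n_to / n_from), self.source_rna, self.n_replicates
        )


def within_null(replicates: list[ReactivityProfile], n: int) -> NullDistribution:
    """eSDC over every unordered replicate pair of one variant (C(r,2) values)."""
    if len(replicates) < 3:
        raise ValueError("need >= 3 replicates for a within null")
    states = {p.state for p in replicates}
    if states != {"capped"}:
        raise ValueError(f"replicates must be capped, states={states}")
    vals = []
    for a, b in combinations(replicates, 2):
        x, y = _paired_values(a, b)
        vals.append((1.0 - pearson_cc(x, y)) * math.sqrt(n))
    return NullDistribution(
        np.array(vals), source_rna=replicates[0].rna_id, n_replicates=len(replicates)
    )


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + |null|).

    Never returns 0: the observed value itself counts as one draw from the
    null, which is the conservative convention for Monte-Carlo p-values.
    """
    ge = int(np.sum(null.values >= observed))
    return (1 + ge) / (1 + null.values.size)


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Family-wise significance flags: p_i <= alpha / m (one family per RNA)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(list(p_values), dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    return p <= alpha / m


def esdc_table(
    collection: MutantCollection,
    n: int,
    null: NullDistribution | None = None,
    alpha: float = 0.05,
    wt_replicate: int = 1,
    augment_to: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """eSDC for every non-WT variant of a capped collection.

    If the WT has >= 3 replicates and no null is given, the within null is
    built from them and bootstrap-augmented to ``augment_to`` values.
    Bonferroni flags treat all mutants of the collection as one family.
    """
    wt_id = collection.wt_variant
    wt = collection.get(wt_id, replicate=wt_replicate)
    if null is None:
        reps = collection.replicates_of(wt_id)
        if len(reps) >= 3:
            null = within_null(reps, n).augmented(size=augment_to, seed=seed)
    rows = []
    for variant in collection.variant_ids:
        if variant == wt_id:
            continue
        res = esdc(wt, collection.get(variant), n)
        if null is not None:
            res.p_value = empirical_pvalue(res.esdc, null)
        rows.append(res)
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in rows],
            "cc": [r.cc for r in rows],
            "esdc": [r.esdc for r in rows],
            "n": [r.n for r in rows],
            "n_overlap": [r.n_overlap for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    if null is not None and len(df):
        df["significant"] = bonferroni(df["p_value"].to_numpy(), alpha=alpha)
    else:
        df["significant"] = pd.NA
    return df
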