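"""ROC benchmarking of predictor/metric combinations.

The experimental labels come from a median split of the eSDC values: the top
half of mutants (ranked by eSDC, descending) are taken to disrupt structure,
the bottom half to preserve it.  Predicted scores (pSDC, or any other ranking
statistic) are then swept through their ranks as cutoffs, producing TPR/FPR
points and a trapezoidal AUC.  To keep differently sized mutant sets from
biasing the comparison, the AUC is subsampled: each replicate pools every
mutant of the designated full-pool set with a fixed number drawn (without
replacement) from each other set; the mean and SD over replicates are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledMutantSet",
    "RocResult",
    "label_by_esdc",
    "roc_curve",
    "auc_trapezoid",
    "bootstrap_auc",
    "benchmark_report",
]

DISRUPT, PRESERVE = 1, 0


@dataclass
class LabeledMutantSet:
    """Per-mutant eSDC and per-metric pSDC values for one RNA dataset.

    ``table`` columns: variant_id, esdc, one column per score (e.g. psdc_bpp),
    optionally ``truth`` with planted {1, 0} classes.  ``full_pool`` marks the
    set whose mutants all enter every subsampling replicate (the role the
    largest, best-replicated dataset plays).
    """

    dataset_id: str
    table: pd.DataFrame
    full_pool: bool = False

    def __post_init__(self) -> None:
        for col in ("variant_id", "esdc"):
            if col not in self.table.columns:
                raise ValueError(f"mutant table needs a {col!r} column")


def label_by_esdc(esdc_values, variant_ids=None) -> np.ndarray:
    """Median-split labels: top floor(m/2) by eSDC disrupt, rest preserve.

    Ties are broken by variant_id lexicographic order so the split is
    deterministic.
    """
    esdc_values = np.asarray(esdc_values, dtype=float)
    m = esdc_values.size
    if m < 2:
        raise ValueError("need >= 2 mutants to label")
    if variant_ids is None:
        variant_ids = [str(i) for i in range(m)]
    order = sorted(range(m), key=lambda i: (-esdc_values[i], str(variant_ids[i])))
    labels = np.full(m, PRESERVE, dtype=int)
    for i in order[: m // 2]:
        labels[i] = DISRUPT
    return labels


@dataclass
class RocResult:
    points: list  # (FPR, TPR), sorted by FPR, includes (0,0) and (1,1)
    auc: float
    boot_mean: float | None = None
    boot_sd: float | None = None
    n_boot: int | None = None
    per_set_sample: int | None = None
    boot_values: np.ndarray | None = None


def roc_curve(labels, scores) -> RocResult:
    """ROC by stepping the score cutoff through the sorted score ranks.

    Tied scores cross each cutoff together (one ROC point per distinct
    score).  Requires both classes to be present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size < 2:
        raise ValueError("labels and scores must be equal-length, size >= 2")
    pos = int(np.sum(labels == DISRUPT))
    neg = int(np.sum(labels == PRESERVE))
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    points = [(0.0, 0.0)]
    for cutoff in np.unique(scores)[::-1]:
        called = scores >= cutoff
        tp = int(np.sum(called & (labels == DISRUPT)))
        fp = int(np.sum(called & (labels == PRESERVE)))
        points.append((fp / neg, tp / pos))
    points.append((1.0, 1.0))
    points = sorted(set(points))
    return RocResult(points=points, auc=auc_trapezoid(points))


def auc_trapezoid(points) -> float:
    """Trapezoidal integral of TPR over FPR for FPR-sorted points."""
    pts = sorted(points)
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def bootstrap_auc(
    datasets: list[LabeledMutantSet],
    score: str,
    n_boot: int = 5000,
    per_set: int = 20,
    seed: int = 0,
    label_mode: str = "esdc_split",
) -> RocResult:
    """Mean +/- SD AUC over seeded subsampling replicates.

    Each replicate pools all mutants of every ``full_pool`` set with
    ``per_set`` mutants sampled without replacement from each remaining set.
    ``label_mode``:

    * ``"esdc_split"`` (default) — labels recomputed inside each replicate by
      the median split of that replicate's eSDC values, keeping classes
      balanced as the 50% rule implies;
    * ``"truth"`` — planted ground-truth classes from the ``truth`` column
      (synthetic-study validation).
    """
    if label_mode not in ("esdc_split", "truth"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    if not datasets:
        raise ValueError("no datasets given")
    for ds in datasets:
        if score not in ds.table.columns:
            raise ValueError(f"dataset {ds.dataset_id!r} lacks score column {score!r}")
        if not ds.full_pool and len(ds.table) < per_set:
            raise ValueError(
                f"dataset {ds.dataset_id!r} has {len(ds.table)} mutants, "
                f"fewer than per_set={per_set}"
            )
        if label_mode == "truth" and "truth" not in ds.table.columns:
            raise ValueError(f"dataset {ds.dataset_id!r} lacks a 'truth' column")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        frames = []
        for ds in datasets:
            t = ds.table
            if ds.full_pool:
                frames.append(t)
            else:
                idx = rng.choice(len(t), size=per_set, replace=False)
                frames.append(t.iloc[idx])
        pool = pd.concat(frames, ignore_index=True)
        if label_mode == "truth":
            labels = pool["truth"].to_numpy(dtype=int)
        else:
            labels = label_by_esdc(
                pool["esdc"].to_numpy(), pool["variant_id"].to_numpy()
            )
        aucs[b] = roc_curve(labels, pool[score].to_numpy()).auc
    full = pd.concat([ds.table for ds in datasets], ignore_index=True)
    if label_mode == "truth":
        full_labels = full["truth"].to_numpy(dtype=int)
    else:
        full_labels = label_by_esdc(full["esdc"].to_numpy(), full["variant_id"].to_numpy())
    overall = roc_curve(full_labels, full[score].to_numpy())
    return RocResult(
        points=overall.points,
        auc=overall.auc,
        boot_mean=float(aucs.mean()),
        boot_sd=float(aucs.std(ddof=1)) if n_boot > 1 else 0.0,
        n_boot=n_boot,
        per_set_sample=per_set,
        boot_values=aucs,
    )


def benchmark_report(
    datasets: list[LabeledMutantSet],
    scores: list[str],
    out_dir,
    n_boot: int = 5000,
    per_set: int = 20,
    seed: int = 0,
    label_mode: str = "esdc_split",
) -> pd.DataFrame:
    """AUC summary CSV plus per-score ROC point files and a manifest."""
    import json
    import os

    if not datasets or not scores:
        raise ValueError("need at least one dataset and one score column")
    os.makedirs(out_dir, exist_ok=True)
    roc_dir = os.path.join(out_dir, "roc_points")
    os.makedirs(roc_dir, exist_ok=True)
    rows = []
    for score in scores:
        usable = []
        for ds in datasets:
            t = ds.table
            keep = t[score].notna()
            if not keep.all():
                import warnings

                warnings.warn(
                    f"dropping {(~keep).sum()} mutants without {score} in {ds.dataset_id}"
                )
            usable.append(LabeledMutantSet(ds.dataset_id, t[keep].reset_index(drop=True), ds.full_pool))
        res = bootstrap_auc(
            usable, score, n_boot=n_boot, per_set=per_set, seed=seed, label_mode=label_mode
        )
        pd.DataFrame(res.points, columns=["fpr", "tpr"]).to_csv(
            os.path.join(roc_dir, f"{score}.csv"), index=False
        )
        rows.append(
            {
                "score": score,
                "auc_full": res.auc,
                "auc_boot_mean": res.boot_mean,
                "auc_boot_sd": res.boot_sd,
                "n_boot": n_boot,
                "per_set": per_set,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(out_dir, "auc_summary.csv"), index=False)
    manifest = {
        "seed": seed,
        "n_boot": n_boot,
        "per_set": per_set,
        "label_mode": label_mode,
        "datasets": {ds.dataset_id: len(ds.table) for ds in datasets},
        "scores": scores,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
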