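"""Benchmark a predictor against simulated experiments with known truth.

Builds a small synthetic study (2 RNAs x 12 mutants, 20% planted
disruptors), runs the full eSDC + pSDC(bpp) pipeline, and scores the
predictor with the subsampled ROC procedure, both against the planted truth
and against the experiment-derived median-split labels.
"""

from sdckit import bootstrap_auc
from sdckit.synth import NoiseModel, StudyConfig, build_study, study_to_labeled_sets

cfg = StudyConfig(n_rnas=2, n_mutants=12, noise=NoiseModel(sd=0.1), seed=5)
sets = study_to_labeled_sets(build_study(cfg))

for mode in ("truth", "esdc_split"):
    res = bootstrap_auc(sets, "psdc_bpp", n_boot=200, per_set=8, seed=0, label_mode=mode)
    print(f"pSDC(bpp) AUC vs {mode:10s}: {res.boot_mean:.3f} +/- {res.boot_sd:.3f}")
print(
    "\nAgainst planted truth the predictor is near-perfect (it shares the"
    "\nengine with the generator); against eSDC median-split labels the AUC"
    "\nreflects experimental noise plus the 50% labeling rule."
)
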