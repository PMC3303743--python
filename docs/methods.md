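# Methods

`sdckit` quantifies how much a point mutation disrupts the structure of an
RNA, experimentally from SHAPE chemical probing and computationally from
secondary-structure ensembles, and benchmarks the computational predictors
against the experimental ranking.  This note documents the models,
parameters, numerical choices and limitations.

## The disruption coefficients

SHAPE probing yields one reactivity per nucleotide; flexible (unpaired)
positions react strongly, base-paired ones weakly.  The experimental
Structure Disruption Coefficient of a mutant against the wild type is

    eSDC = (1 − r) · √n

where `r` is the Pearson correlation of the capped WT and mutant profiles
over pairwise-complete positions and `n` is the declared construct length
(not the probed overlap, which is reported separately).  Identical profiles
give 0; perfect anti-correlation gives 2√n.  Before correlating, profiles
are normalized by the standard SHAPE box-plot rule — discard the top
`ceil(0.02 m)` non-missing values as outliers and divide by the mean of the
next `ceil(0.08 m)` (ceilings keep the rule deterministic at small m) — then
negatives are clipped to 0 and values capped at 1, so the statistic compares
the *pattern* of reactive positions rather than peak intensities.  Each
profile is normalized independently; missing values propagate and are
excluded pairwise.

The predicted coefficient pSDC has the same functional form with the SHAPE
profiles replaced by per-nucleotide structure vectors in [0, 1] where 1
means unpaired (so high values align with high reactivity).  Four metrics
supply the vectors:

| metric | vector |
|---|---|
| `mfe` | unpaired indicator of the minimum-free-energy structure |
| `bpp` | unpaired probability, 1 − row sum of the pair-probability matrix |
| `z_centroid` | unpaired indicator of the structure built from all pairs with ensemble probability > ½ |
| `cluster_centroid` | unpaired indicator of the medoid of the most populated k-means cluster of a sampled ensemble |

If a vector is constant the correlation is undefined; pSDC is then 0 when
both vectors are constant and equal and the maximal 2√n otherwise, which
preserves the ordering semantics.  The √n factor never affects rankings
within one RNA (n is constant there); it keeps eSDC and pSDC on one scale.

The Z centroid is always a valid nested structure: two pairs that share a
nucleotide or cross are mutually exclusive events in the ensemble, so their
probabilities cannot both exceed one half.

## Significance of eSDC values

The null distribution of eSDC under pure experimental noise is built from
replicates: every unordered pair of WT replicates yields a "within" eSDC
(C(6,2) = 15 values for a 6-replicate experiment).  The empirical p-value
uses the add-one rule p = (1 + #{null ≥ obs}) / (1 + |null|), so it is never
zero; with a 15-value null, p lives on the grid k/16.  The null can be
bootstrap-resampled to a larger size (seeded) for smoother reporting, and
transferred between constructs of different lengths by rescaling with
√(n_to/n_from), since the noise lives in the (1 − r) factor.  Family-wise
significance uses a Bonferroni correction with the family defined as all
mutants of one RNA dataset.

## The built-in folding engine

External ensemble predictors are supported only through file parsing
(dot-bracket ensembles, sparse `i j p` probability tables).  The built-in
engine exists so that every quantity in the pipeline has an exactly
verifiable reference: the energy model is pairs-only — GC = −3, AU = −2,
GU = −1 (arbitrary units), no stacking or loop terms, minimum hairpin loop 3,
Boltzmann factor exp(−E/kT) with kT = 1 by default.  On the unambiguous
"first position unpaired, or paired to k" decomposition the engine computes:

* the MFE structure by min-plus dynamic programming, with co-optimal ties
  resolved to the lexicographically smallest sorted pair list (the greedy
  traceback that prefers pairing the 5' nucleotide to the smallest partner
  realizes this, because with strictly negative pair energies no co-optimal
  pair list can be a prefix of another);
* exact pair probabilities by inside/outside recursions carried in log space
  (log-sum-exp), which avoids overflow for sequences of hundreds of
  nucleotides without rescaling tricks;
* i.i.d. Boltzmann samples by stochastic traceback with a seeded generator;
  per-interval branch distributions are cached.

Everything is cross-checked against `sdckit.bruteforce`, an independent
exhaustive enumerator feasible up to n ≈ 16: MFE score and tie-break,
partition function (relative error < 1e-9), pair probabilities (absolute
error < 1e-9), and sampling frequencies (chi-square).  The model is *not*
the Turner nearest-neighbour model: absolute energies and ensembles are not
comparable to ViennaRNA/RNAstructure output, and because pair energies are
context-free the model has no stacking cooperativity — single substitutions
perturb ensembles locally rather than switching them wholesale, which shaped
the synthetic-study design below.

## Ensemble landscape analysis

For landscape views each sampled structure is reduced to its per-nucleotide
unpaired indicator vector (length n), not the flattened n² pair matrix; on
binary vectors Manhattan distance equals squared Euclidean distance, so PCA
on these vectors orders structures the same way either choice would.  PCA is
fitted on the pooled WT + mutant ensembles, all structures are projected on
PC1/PC2, and k-means (seeded, default k = 4, silhouette-based selection
available) assigns clusters; per-variant cluster occupancies summarise
repartitioning.  The "cluster centroid structure" is the medoid — the real
sampled structure nearest its cluster mean in PC space — because an
arithmetic mean of binary vectors is not a structure.  Cluster-size ties
resolve to the lowest cluster index.

## ROC benchmarking

Experimental labels follow the median-split rule: mutants ranked by eSDC
descending, the top floor(m/2) labelled disruptive, ties broken by variant
id.  Cutoffs step through the distinct predicted scores (tied scores cross
together), TPR/FPR points get (0,0) and (1,1) endpoints, and the AUC is the
trapezoidal integral — verified to equal pairwise concordance for tie-free
scores.  Because datasets differ in size, the summary AUC is computed by
repeated subsampling: every replicate pools all mutants of the designated
full-pool set with `per_set` mutants drawn without replacement from each
other set; the mean and SD over (default 5000, seeded) replicates are
reported.  Labels are recomputed inside each replicate by default (keeping
classes balanced, as the 50% rule implies); planted-truth labels are
available for synthetic validation.  Sampling within a replicate is without
replacement — this is repeated subsampling rather than a bootstrap proper,
and the SD is the spread over subsamples.

## The synthetic study

The generator produces a mutate-and-map compendium in which the engine is
the ground-truth physics.  Each RNA is laid out as `S · loop · rc(S) · loop
· S` (default stem 12 nt, loops 12 nt, n = 60): the central block can close
an isoenergetic hairpin with either flank.  Stems use only A/U and loops
only C — in a G-free molecule loops cannot pair at all and a broken stem
rung cannot be rescued by an off-target partner.  Blocks are rejected unless
their composition is balanced (35–65% A) with homopolymer runs ≤ 3, both
registers carry ≥ 10% Boltzmann mass (measured at the loop-closing pair,
which every configuration using a register contains), and the MFE adopts one
register cleanly.

Because the energy model has no stacking, the ensemble interpolates between
the registers through a ladder of isoenergetic split configurations rather
than jumping bimodally; the mutations are designed around this.  A planted
*disruptor* is a double substitution (the strongest mutations in real
mutate-and-map compendia are doubles) breaking one deep and one shallow rung
of the adopted register; the deep (loop-closing) rungs take part in every
partial configuration of the hairpin, so their loss reweights the entire
split ladder towards the competitor.  A planted *neutral* is a single
substitution in the inert loops, with the competing register's outer rungs
as fallback.  Every candidate is verified against the engine before
acceptance: a disruptor must flip the MFE to the competing register, move
the MFE paired/unpaired pattern at ≥ 8 of 60 positions and shift the
ensemble unpaired-probability vector by a pSDC-style score ≥ 0.32; a neutral
must keep the register, move ≤ 2 pattern positions and shift ≤ 0.30.
Positions are unique across the mutant set, classes are recorded as ground
truth, and sequence/mutation drawing walks a deterministic seed chain until
a sequence accommodates the requested counts.

SHAPE is simulated from each variant's MFE structure: reactivities are
truncated-normal draws (lower bound 0, hence right-skewed) around a paired
mean of 0.15 or unpaired mean of 0.85.  The default noise sd is 0.15,
chosen so that six-replicate "within" eSDC null distributions sit clearly
below planted-disruptor eSDC values, mirroring the separation seen in real
replicate data; a dropout fraction (default 0) becomes missing values.  The
default study is 5 RNAs × 30 mutants with 20% disruptors and 6 WT
replicates.

What passing the recovery test shows — and what it does not: the
low-noise study (sd 0.1) run through simulate → normalize → cap → eSDC →
pSDC(bpp) → subsampled ROC recovers the planted classes with mean AUC
≥ 0.95 against planted truth, and collapses to chance (AUC in [0.4, 0.6])
when the structural signal is removed from the reactivities
(paired mean = unpaired mean).  This validates the statistical machinery end
to end.  It does not measure predictive power on real RNAs: the pSDC
predictor shares the folding engine with the generator, so its near-perfect
AUC here is by construction; and the simulator omits instrument systematics
(signal decay, correlated noise, frameshifts), so robustness to those is
untested.

## Numerical and interface conventions

Positions are 1-based everywhere, matching mutation strings like `C77G`
(dot-separated for doubles, `U22G.A196G`).  Pairs are stored (i, j) with
i < j.  Reactivity files use a long TSV dialect (`rna_id variant_id
replicate position nucleotide reactivity`, `NA` for missing) or a wide CSV
(`position` plus one column per variant, replicates suffixed `__r2`).
Profile state moves only raw → normalized → capped.  All stochastic stages
take explicit seeds; the pipeline driver expands one global seed into
per-stage seeds via `numpy.random.SeedSequence.spawn`, and identical configs
reproduce outputs byte for byte.

## Known limitations

* The pair-energy model is deliberately minimal; conclusions about real
  RNAs require external predictors, which are integrated only through their
  ensemble files.
* eSDC is a global statistic; small local structure changes with functional
  consequences can score near zero by design.
* The replicate null is built from (or transferred between) capped profiles
  and assumes replicate exchangeability; systematic batch effects violate it.
* With few replicates the p-value grid is coarse (k/16 for six replicates);
  bootstrap augmentation smooths reporting but cannot add information.
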