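"""Synthetic riboSNitch studies with known ground truth.

The generator emulates a mutate-and-map SHAPE compendium at a scale where the
built-in folding engine is the ground-truth physics:

* a *switchable* sequence — a stem block and its reverse complement arranged
  as ``S · loop · rc(S) · loop · S`` so the central block can close a hairpin
  with either flank.  The two registers share the central block and are
  isoenergetic; structures interpolate between them through a ladder of
  split configurations, and the engine places substantial mass on both sides.
  Stems use only A/U and loops only C: in a G-free molecule the loops cannot
  pair at all, and a broken stem rung cannot be rescued by an off-target
  partner.  Blocks are drawn from the seed until the ensemble occupies both
  registers and the minimum-energy structure is a clean single register.
* planted mutations — *disruptors* are double substitutions that break one
  deep (loop-closing) and one shallow rung of the adopted register, flipping
  the minimum-energy structure to the competing register and dragging the
  Boltzmann ensemble with it; *neutrals* are single substitutions in the
  inert loops.  Every candidate is verified against the engine before
  acceptance, on both the conformation (MFE flip / retention) and the
  ensemble (unpaired-probability shift).
* simulated SHAPE — reactivities drawn from a truncated normal around a
  paired mean (default 0.15) or unpaired mean (default 0.85), truncated at
  zero so the distribution is right-skewed like real SHAPE data; a dropout
  fraction becomes missing.  The generating structure is the variant's MFE.

Everything is reproducible from (config, seed).  The simulator does not model
capillary-electrophoresis artifacts, signal decay along the read, or
position-correlated noise, so passing tests demonstrate the pipeline's
statistical machinery, not robustness to real instrument systematics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .esdc import esdc_table
from .fold import (
    FoldEngine,
    MutationSpec,
    RnaSequence,
    SecondaryStructure,
    apply_mutation,
    write_fasta,
)
from .shape import MutantCollection, ReactivityProfile, prepare_collection, write_profiles

__all__ = [
    "NoiseModel",
    "StudyConfig",
    "SyntheticRna",
    "SyntheticStudy",
    "make_switchable_sequence",
    "plant_mutations",
    "simulate_shape",
    "build_study",
    "study_to_labeled_sets",
    "true_flexibility",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: bases each base can pair with (including GU wobble)
_PARTNERS = {"A": {"U"}, "U": {"A", "G"}, "G": {"C", "U"}, "C": {"G"}}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


@dataclass
class NoiseModel:
    """Truncated-normal reactivity noise around per-class means."""

    paired_mean: float = 0.15
    unpaired_mean: float = 0.85
    sd: float = 0.15
    dropout: float = 0.0


@dataclass
class StudyConfig:
    n_rnas: int = 5
    n_mutants: int = 30
    disruptor_fraction: float = 0.2
    seq_len: int = 60
    stem_len: int = 12
    wt_replicates: int = 6
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        noise = d.pop("noise", {})
        cfg = cls(**d)
        if isinstance(noise, dict):
            cfg.noise = NoiseModel(**noise)
        return cfg


def make_switchable_sequence(
    n: int = 60,
    seed: int = 0,
    engine: FoldEngine | None = None,
    stem_len: int | None = None,
    min_occupancy: float = 0.10,
    max_tries: int = 500,
) -> tuple[RnaSequence, SecondaryStructure, SecondaryStructure]:
    """A sequence whose ensemble splits between two competing hairpins.

    Returns the sequence and the two register structures.  Acceptance
    requires each register to carry at least ``min_occupancy`` Boltzmann
    mass (measured at its loop-closing pair, which every configuration using
    that register contains) and the MFE to adopt one register cleanly (at
    least all-but-one of its rungs, at most one rung of the competitor), so
    that planted register flips are well defined.
    """
    engine = engine or FoldEngine()
    L = stem_len if stem_len is not None else max(4, round(n / 5))
    loop = (n - 3 * L) // 2
    if loop < engine.min_loop or n != 3 * L + 2 * loop:
        raise ValueError(f"cannot lay out n={n} as 3*{L} stems + 2 loops >= {engine.min_loop}")
    rng = np.random.default_rng(seed)
    reg1 = SecondaryStructure(  # 5' flank paired with the central block
        n=n, pairs=frozenset((t, 2 * L + loop + 1 - t) for t in range(1, L + 1))
    )
    reg2 = SecondaryStructure(  # central block paired with the 3' flank
        n=n,
        pairs=frozenset(
            (L + loop + s, 3 * L + 2 * loop + 1 - s) for s in range(1, L + 1)
        ),
    )
    max_run = 3
    for _ in range(max_tries):
        block = "".join(rng.choice(list("AU"), size=L))
        # low-complexity blocks fold sloppily: keep the composition balanced
        # and homopolymer runs short so the registers are sharply defined
        if not (0.35 <= block.count("A") / L <= 0.65):
            continue
        if any(b * (max_run + 1) in block for b in "AU"):
            continue
        residues = block + "C" * loop + _revcomp(block) + "C" * loop + block
        seq = RnaSequence(id=f"switch{seed}", residues=residues)
        occ1, occ2 = _register_occupancy(seq, (reg1, reg2), engine)
        if occ1 < min_occupancy or occ2 < min_occupancy:
            continue
        mfe = engine.mfe_structure(seq)
        ov = sorted([len(mfe.pairs & reg1.pairs), len(mfe.pairs & reg2.pairs)])
        if ov[1] >= L - 1 and ov[0] <= 1:
            return seq, reg1, reg2
    raise RuntimeError(f"no switchable sequence found in {max_tries} tries (seed {seed})")


def _register_occupancy(
    seq: RnaSequence,
    registers: tuple[SecondaryStructure, SecondaryStructure],
    engine: FoldEngine,
) -> tuple[float, float]:
    """Boltzmann mass on each register: the exact probability of its
    loop-closing pair, which every configuration using the register keeps."""
    P = engine.pair_probabilities(seq).p
    occ = []
    for r in registers:
        i, j = min(r.pairs, key=lambda ij: ij[1] - ij[0])
        occ.append(float(P[i - 1, j - 1]))
    return occ[0], occ[1]


def true_flexibility(seq: RnaSequence, engine: FoldEngine) -> np.ndarray:
    """Per-nucleotide unpaired probability of the exact Boltzmann ensemble."""
    from .ensemble import pairing_vector

    return pairing_vector(engine.pair_probabilities(seq))


def plant_mutations(
    seq: RnaSequence,
    n_mut: int,
    disruptor_fraction: float,
    seed: int,
    engine: FoldEngine | None = None,
    registers: tuple[SecondaryStructure, SecondaryStructure] | None = None,
    min_disr_flips: int = 8,
    max_neut_flips: int = 2,
    min_disr_shift: float = 0.32,
    max_neut_shift: float = 0.30,
) -> list[tuple[MutationSpec, int]]:
    """Plant ``n_mut`` mutations with known classes (1 = disruptor).

    A *disruptor* is a double substitution breaking one deep and one shallow
    rung of the register the WT adopts; it is accepted only if, under the
    engine, (i) the mutant MFE overlaps the competing register more than the
    original one and moves the per-nucleotide paired/unpaired pattern at
    >= ``min_disr_flips`` positions, and (ii) the ensemble
    unpaired-probability vector moves by a pSDC-style score
    >= ``min_disr_shift``.  A *neutral* is a single substitution at a loop
    position, accepted only if the register is retained, the MFE pattern
    moves at <= ``max_neut_flips`` positions and the ensemble score stays
    <= ``max_neut_shift``.  Positions are unique across the returned set.
    """
    engine = engine or FoldEngine()
    rng = np.random.default_rng(seed)
    from .ensemble import pairing_vector, structure_binary_vector

    wt_vec = pairing_vector(engine.pair_probabilities(seq))
    wt_mfe = engine.mfe_structure(seq)
    wt_bin = structure_binary_vector(wt_mfe)
    sqrt_n = float(np.sqrt(seq.n))

    if registers is not None:
        ov = [len(wt_mfe.pairs & r.pairs) for r in registers]
        dom, oth = (registers[0], registers[1]) if ov[0] >= ov[1] else (registers[1], registers[0])
        reg_pos = {p for r in registers for pr in r.pairs for p in pr}
        loop_pos = sorted(set(range(1, seq.n + 1)) - reg_pos)
        shared = {p for i, j in registers[0].pairs for p in (i, j)} & {
            p for i, j in registers[1].pairs for p in (i, j)
        }
        partner_of = {}
        for r in registers:
            for i, j in r.pairs:
                partner_of.setdefault(i, j)
                partner_of.setdefault(j, i)
        # flank of the adopted register, loop-closing rungs first
        flank = []
        for i, j in sorted(dom.pairs, key=lambda ij: ij[1] - ij[0]):
            flank.extend(p for p in (i, j) if p not in shared)
        half = len(flank) // 2
        # primary: one deep + one shallow rung; fallbacks: every other pair,
        # ordered so rungs nearest the loop (strongest effect) come first
        disr_candidates = [(flank[k], flank[k + half]) for k in range(half)]
        disr_candidates += sorted(
            ((flank[a], flank[b]) for a in range(len(flank)) for b in range(a + 1, len(flank))),
            key=lambda ab: flank.index(ab[0]) + flank.index(ab[1]),
        )
        # neutrals: inert loop positions first; then the competing register's
        # flank, outermost rungs first — weakening the register the molecule
        # does not adopt leaves the conformation unchanged (each candidate is
        # still verified below)
        oth_flank = []
        for i, j in sorted(oth.pairs, key=lambda ij: ij[1] - ij[0]):
            oth_flank.extend(p for p in (i, j) if p not in shared)
        neut_candidates = list(loop_pos) + oth_flank[::-1]
    else:
        dom = oth = None
        partner_of = {i: j for i, j in wt_mfe.pairs} | {j: i for i, j in wt_mfe.pairs}
        paired = sorted(partner_of)
        rng.shuffle(paired)
        disr_candidates = [tuple(paired[i : i + 2]) for i in range(0, len(paired) - 1, 2)]
        neut_candidates = sorted(set(range(1, seq.n + 1)) - set(partner_of))
        rng.shuffle(neut_candidates)

    n_disr = round(n_mut * disruptor_fraction)
    n_neut = n_mut - n_disr

    def evaluate(m: MutationSpec):
        """(register flipped?, MFE pattern flips, ensemble shift score)."""
        mut_seq = apply_mutation(seq, m)
        vec = pairing_vector(engine.pair_probabilities(mut_seq))
        shift = (1.0 - float(np.corrcoef(wt_vec, vec)[0, 1])) * sqrt_n
        mfe = engine.mfe_structure(mut_seq)
        flips = int(np.sum(structure_binary_vector(mfe) != wt_bin))
        if dom is None:
            flipped = True if flips >= min_disr_flips else (
                False if flips <= max_neut_flips else None
            )
        else:
            flipped = len(mfe.pairs & oth.pairs) > len(mfe.pairs & dom.pairs)
        return flipped, flips, shift

    used = set()

    def breaking_alt(pos: int) -> str:
        # prefer C: in the generator's G-free molecules it can pair nothing,
        # so the break cannot be rescued by a new off-target pair
        ref = seq.residues[pos - 1]
        q = seq.residues[partner_of[pos] - 1]
        alts = [b for b in "CAGU" if b != ref and q not in _PARTNERS[b]]
        return alts[0]

    disruptors = []
    for positions in disr_candidates:
        if len(disruptors) >= n_disr:
            break
        if used & set(positions):
            continue
        subs = tuple((seq.residues[p - 1], p, breaking_alt(p)) for p in sorted(positions))
        m = MutationSpec(subs)
        flipped, flips, shift = evaluate(m)
        if flipped and flips >= min_disr_flips and shift >= min_disr_shift:
            disruptors.append(m)
            used.update(positions)
    if len(disruptors) < n_disr:
        raise RuntimeError(f"only planted {len(disruptors)}/{n_disr} disruptors (seed {seed})")

    neutrals = []
    for pos in neut_candidates:
        if len(neutrals) >= n_neut:
            break
        if pos in used:
            continue
        ref = seq.residues[pos - 1]
        alts = [b for b in "ACGU" if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            m = MutationSpec(((ref, pos, alt),))
            flipped, flips, shift = evaluate(m)
            if flipped is False and flips <= max_neut_flips and shift <= max_neut_shift:
                neutrals.append(m)
                used.add(pos)
                break
    if len(neutrals) < n_neut:
        raise RuntimeError(f"only planted {len(neutrals)}/{n_neut} neutrals (seed {seed})")
    out = [(m, 1) for m in disruptors] + [(m, 0) for m in neutrals]
    rng.shuffle(out)
    return out


def simulate_shape(
    structure,
    noise: NoiseModel | None = None,
    replicates: int = 1,
    seed: int = 0,
    rna_id: str = "synthetic",
    variant_id: str = "WT",
) -> list[ReactivityProfile]:
    """Simulated raw SHAPE profiles for a known structure.

    ``structure`` may be a :class:`SecondaryStructure` or a per-nucleotide
    unpaired-probability vector; the per-position mean interpolates between
    ``paired_mean`` and ``unpaired_mean``.  Values are truncated-normal draws
    bounded below at 0; a ``dropout`` fraction of positions is set missing.
    Each replicate uses an independently derived seed.
    """
    noise = noise or NoiseModel()
    if isinstance(structure, SecondaryStructure):
        from .ensemble import structure_binary_vector

        unpaired = structure_binary_vector(structure)
    else:
        unpaired = np.asarray(structure, dtype=float)
    n = unpaired.size
    means = noise.paired_mean + (noise.unpaired_mean - noise.paired_mean) * unpaired
    seeds = np.random.SeedSequence(seed).spawn(replicates)
    profiles = []
    for rep, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)
        if noise.sd > 0:
            a = (0.0 - means) / noise.sd  # truncation at zero, in sd units
            vals = truncnorm.rvs(a, np.inf, loc=means, scale=noise.sd, random_state=rng)
        else:
            vals = means.copy()
        if noise.dropout > 0:
            vals[rng.random(n) < noise.dropout] = np.nan
        profiles.append(
            ReactivityProfile(
                rna_id=rna_id,
                variant_id=variant_id,
                replicate=rep,
                positions=np.arange(1, n + 1),
                reactivities=vals,
            )
        )
    return profiles


@dataclass
class SyntheticRna:
    rna_id: str
    sequence: RnaSequence
    registers: tuple
    mutants: list
    collection: MutantCollection  # raw profiles, WT replicated
    truth: pd.DataFrame  # variant_id, truth


@dataclass
class SyntheticStudy:
    config: StudyConfig
    rnas: list


def build_study(config: StudyConfig, out_dir=None) -> SyntheticStudy:
    """Generate the full study; optionally write one directory per RNA.

    Each RNA directory gets ``sequence.fa``, ``mutations.txt``,
    ``reactivities.tsv`` (long TSV, raw state) and ``truth.csv``.  Profiles
    are simulated from each variant's MFE structure.  Output is
    deterministic for a given config.
    """
    engine = FoldEngine()
    top = np.random.SeedSequence(config.seed)
    rnas = []
    for r, rna_ss in enumerate(top.spawn(config.n_rnas)):
        sub = rna_ss.generate_state(4)  # four derived 32-bit seeds
        rna_id = f"RNA{r + 1}"
        # a drawn sequence may not accommodate the requested mutant counts;
        # walk a deterministic seed chain until one does
        for retry in range(20):
            try:
                seq, reg1, reg2 = make_switchable_sequence(
                    n=config.seq_len,
                    seed=(int(sub[0]) + retry * 7919) % 2**31,
                    engine=engine,
                    stem_len=config.stem_len,
                )
                seq = RnaSequence(id=rna_id, residues=seq.residues)
                mutants = plant_mutations(
                    seq,
                    config.n_mutants,
                    config.disruptor_fraction,
                    seed=(int(sub[1]) + retry) % 2**31,
                    engine=engine,
                    registers=(reg1, reg2),
                )
                break
            except RuntimeError:
                if retry == 19:
                    raise
        profiles = simulate_shape(
            engine.mfe_structure(seq),
            noise=config.noise,
            replicates=config.wt_replicates,
            seed=int(sub[2]) % 2**31,
            rna_id=rna_id,
            variant_id="WT",
        )
        mut_seeds = np.random.SeedSequence(int(sub[3]) % 2**31).spawn(len(mutants))
        for (mspec, _), ms in zip(mutants, mut_seeds):
            mut_seq = apply_mutation(seq, mspec)
            profiles.extend(
                simulate_shape(
                    engine.mfe_structure(mut_seq),
                    noise=config.noise,
                    replicates=1,
                    seed=int(ms.generate_state(1)[0]) % 2**31,
                    rna_id=rna_id,
                    variant_id=mspec.label,
                )
            )
        collection = MutantCollection(rna_id=rna_id, profiles=profiles, wt_sequence=seq.residues)
        truth = pd.DataFrame(
            {"variant_id": [m.label for m, _ in mutants], "truth": [c for _, c in mutants]}
        )
        rnas.append(SyntheticRna(rna_id, seq, (reg1, reg2), mutants, collection, truth))
    study = SyntheticStudy(config=config, rnas=rnas)
    if out_dir is not None:
        _write_study(study, out_dir)
    return study


def _write_study(study: SyntheticStudy, out_dir) -> None:
    for rna in study.rnas:
        d = os.path.join(str(out_dir), rna.rna_id)
        os.makedirs(d, exist_ok=True)
        write_fasta([rna.sequence], os.path.join(d, "sequence.fa"))
        with open(os.path.join(d, "mutations.txt"), "w") as fh:
            for m, _ in rna.mutants:
                fh.write(m.label + "\n")
        write_profiles(rna.collection, os.path.join(d, "reactivities.tsv"), "long-tsv")
        rna.truth.to_csv(os.path.join(d, "truth.csv"), index=False)


def study_to_labeled_sets(
    study: SyntheticStudy,
    engine: FoldEngine | None = None,
    cap: float = 1.0,
    with_psdc: bool = True,
):
    """Run normalize -> cap -> eSDC (and exact-bpp pSDC) on every study RNA.

    Returns benchmark-ready :class:`~sdckit.benchmark.LabeledMutantSet`
    objects carrying esdc, psdc_bpp and planted truth per mutant; the first
    RNA is flagged as the full-pool set.
    """
    from .benchmark import LabeledMutantSet
    from .psdc import psdc_bpp

    engine = engine or FoldEngine()
    sets = []
    for idx, rna in enumerate(study.rnas):
        capped = prepare_collection(rna.collection, cap=cap)
        table = esdc_table(capped, n=rna.sequence.n)
        if with_psdc:
            psdc_vals = {}
            for mspec, _ in rna.mutants:
                mut_seq = apply_mutation(rna.sequence, mspec)
                psdc_vals[mspec.label] = psdc_bpp(
                    rna.sequence, mut_seq, engine, variant_id=mspec.label
                ).psdc
            table["psdc_bpp"] = table["variant_id"].map(psdc_vals)
        table = table.merge(rna.truth, on="variant_id", how="left")
        sets.append(LabeledMutantSet(rna.rna_id, table, full_pool=(idx == 0)))
    return sets
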