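"""Self-contained RNA secondary-structure engine and external-predictor adapters.

The engine implements a deliberately simple nested base-pairing model — pair
energies GC = -3, AU = -2, GU = -1 (arbitrary units), no stacking, minimum
hairpin loop of 3 unpaired nucleotides, Boltzmann factor exp(-E/kT) with kT
configurable (default 1).  The model is small enough that exhaustive
enumeration can verify every quantity exactly, yet rich enough that single
substitutions can flip an ensemble between competing hairpin registers, which
is the phenomenon the disruption metrics are built to detect.

Three quantities are exposed per sequence:

* the MFE structure (minimum-energy nested structure, deterministic tie-break);
* exact base-pair probabilities via inside/outside dynamic programming in log
  space (the partition-function recursion is the unambiguous "first nucleotide
  unpaired or paired to k" decomposition);
* i.i.d. Boltzmann samples by stochastic traceback of the same recursion.

External predictors (RNAsubopt, sFold, ...) are integrated only through file
parsing of their dot-bracket ensemble output, never by shelling out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RnaSequence",
    "MutationSpec",
    "SecondaryStructure",
    "StructureEnsemble",
    "FoldEngine",
    "parse_mutation",
    "apply_mutation",
    "read_fasta",
    "read_dotbracket_ensemble",
    "write_dotbracket_ensemble",
]

ALPHABET = "ACGU"

DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A, C, G, U}; T is coerced to U on construction."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", res)
        if not res:
            raise ValueError("empty sequence")
        bad = set(res) - set(ALPHABET)
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in sequence {self.id!r}")

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MutationSpec:
    """One or more point substitutions, e.g. C77G or U22G.A196G (1-based)."""

    substitutions: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for _, p, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("substitution positions must be distinct")
        for ref, pos, alt in self.substitutions:
            if ref not in ALPHABET or alt not in ALPHABET:
                raise ValueError(f"invalid base in substitution {ref}{pos}{alt}")
            if pos < 1:
                raise ValueError("positions are 1-based")

    @property
    def label(self) -> str:
        return ".".join(f"{r}{p}{a}" for r, p, a in self.substitutions)


_MUT_TOKEN = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_mutation(spec: str, max_substitutions: int | None = 2) -> MutationSpec:
    """Parse a dot-separated mutation string like ``"U22G.A196G"``."""
    tokens = spec.strip().split(".")
    subs = []
    for tok in tokens:
        m = _MUT_TOKEN.match(tok)
        if not m:
            raise ValueError(f"malformed mutation token {tok!r} in {spec!r}")
        ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        ref = "U" if ref == "T" else ref
        alt = "U" if alt == "T" else alt
        if ref not in ALPHABET or alt not in ALPHABET:
            raise ValueError(f"invalid base in mutation token {tok!r}")
        subs.append((ref, pos, alt))
    if max_substitutions is not None and len(subs) > max_substitutions:
        raise ValueError(
            f"{spec!r} has {len(subs)} substitutions, limit is {max_substitutions}"
        )
    return MutationSpec(tuple(subs))


def apply_mutation(seq: RnaSequence, mutation: MutationSpec) -> RnaSequence:
    """Substitute the listed bases, checking each reference base first."""
    residues = list(seq.residues)
    for ref, pos, alt in mutation.substitutions:
        if pos > len(residues):
            raise ValueError(f"position {pos} beyond sequence of length {len(residues)}")
        if residues[pos - 1] != ref:
            raise ValueError(
                f"reference mismatch at position {pos}: sequence has "
                f"{residues[pos - 1]}, mutation expects {ref}"
            )
        residues[pos - 1] = alt
    new_id = f"{seq.id}|{mutation.label}" if mutation.substitutions else seq.id
    return RnaSequence(id=new_id, residues="".join(residues))


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs (1-based, i < j) over n nucleotides."""

    n: int
    pairs: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))

    def validate(self, min_loop: int = 3) -> None:
        seen: set[int] = set()
        plist = sorted(self.pairs)
        for i, j in plist:
            if not (1 <= i < j <= self.n):
                raise ValueError(f"pair ({i},{j}) out of range for n={self.n}")
            if j - i - 1 < min_loop:
                raise ValueError(f"pair ({i},{j}) violates minimum loop {min_loop}")
            if i in seen or j in seen:
                raise ValueError(f"nucleotide reused in pair ({i},{j})")
            seen.update((i, j))
        for a in range(len(plist)):
            i, j = plist[a]
            for b in range(a + 1, len(plist)):
                k, l = plist[b]
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    @property
    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def to_dotbracket(self) -> str:
        chars = ["."] * self.n
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        stack: list[int] = []
        pairs = set()
        for idx, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {idx}")
                pairs.add((stack.pop(), idx))
            elif ch != ".":
                raise ValueError(f"invalid character {ch!r} at position {idx}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        return cls(n=len(db), pairs=frozenset(pairs))

    def base_pair_distance(self, other: "SecondaryStructure") -> int:
        return len(self.pairs ^ other.pairs)


@dataclass
class StructureEnsemble:
    """An ordered multiset of structures sampled (or read) for one sequence."""

    sequence: RnaSequence
    structures: list[SecondaryStructure]
    engine: str = "unknown"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("ensemble must contain at least one structure")
        n = self.sequence.n
        for s in self.structures:
            if s.n != n:
                raise ValueError("all structures must share the sequence length")

    @property
    def size(self) -> int:
        return len(self.structures)


# ---------------------------------------------------------------------------
# the engine

_NEG_INF = -np.inf


class FoldEngine:
    """Nested-structure thermodynamics under the built-in pair-energy model."""

    def __init__(
        self,
        kT: float = 1.0,
        min_loop: int = 3,
        pair_energies: dict | None = None,
    ) -> None:
        if kT <= 0:
            raise ValueError("kT must be positive")
        self.kT = float(kT)
        self.min_loop = int(min_loop)
        self.pair_energies = dict(DEFAULT_PAIR_ENERGIES if pair_energies is None else pair_energies)
        self._cache: dict[str, _Folded] = {}

    def _folded(self, seq: RnaSequence) -> "_Folded":
        f = self._cache.get(seq.residues)
        if f is None:
            f = _Folded(seq.residues, self)
            if len(self._cache) > 64:  # keep memory bounded across many mutants
                self._cache.clear()
            self._cache[seq.residues] = f
        return f

    def _energy_matrix(self, residues: str) -> np.ndarray:
        n = len(residues)
        E = np.full((n, n), np.inf)
        for i in range(n):
            for j in range(i + self.min_loop + 1, n):
                e = self.pair_energies.get((residues[i], residues[j]))
                if e is not None:
                    E[i, j] = e
        return E

    def mfe_structure(self, seq: RnaSequence) -> SecondaryStructure:
        """Minimum-energy structure; co-optimal ties resolved to the structure
        whose sorted pair list is lexicographically smallest."""
        return self._folded(seq).mfe()

    def mfe_energy(self, seq: RnaSequence) -> float:
        return self._folded(seq).mfe_energy

    def partition_log(self, seq: RnaSequence) -> float:
        """log of the full partition function Z."""
        return self._folded(seq).logZ_total

    def pair_probabilities(self, seq: RnaSequence):
        """Exact Boltzmann pair-probability matrix (:class:`PairProbabilityMatrix`)."""
        from .ensemble import PairProbabilityMatrix

        p = self._folded(seq).pair_probabilities()
        return PairProbabilityMatrix(n=seq.n, p=p, provenance="exact")

    def sample_structures(self, seq: RnaSequence, size: int, seed: int) -> StructureEnsemble:
        """``size`` i.i.d. Boltzmann samples via seeded stochastic traceback."""
        if size < 1:
            raise ValueError("size must be >= 1")
        f = self._folded(seq)
        rng = np.random.default_rng(seed)
        structures = [f.sample(rng) for _ in range(size)]
        return StructureEnsemble(
            sequence=seq, structures=structures, engine="builtin", seed=seed
        )


class _Folded:
    """Per-sequence DP tables: MFE, inside, outside, sampling."""

    def __init__(self, residues: str, engine: FoldEngine) -> None:
        self.residues = residues
        self.n = len(residues)
        self.engine = engine
        self.E = engine._energy_matrix(residues)  # pair energies, inf if unpairable
        self.W = -self.E / engine.kT  # log Boltzmann pair weights, -inf if unpairable
        self._Z: np.ndarray | None = None
        self._M: np.ndarray | None = None
        self._bpp: np.ndarray | None = None
        self._samp_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def Z(self) -> np.ndarray:
        if self._Z is None:
            self._inside()
        return self._Z

    @property
    def logZ_total(self) -> float:
        return float(self.Z[0, self.n - 1]) if self.n else 0.0

    @property
    def M(self) -> np.ndarray:
        if self._M is None:
            self._mfe_dp()
        return self._M

    @property
    def mfe_energy(self) -> float:
        return float(self.M[0, self.n - 1]) if self.n else 0.0

    # -- inside (partition function), log space -----------------------------
    def _inside(self) -> None:
        n = self.n
        # Z[a, b] = log partition function of interval [a, b] (0-based,
        # inclusive); empty/inverted intervals stay at 0 = log 1.
        Z = np.zeros((n + 2, n + 2))
        for span in range(n):
            for i in range(n - span):
                j = i + span
                best = Z[i + 1, j]
                ks = np.nonzero(np.isfinite(self.W[i, i : j + 1]))[0] + i
                if ks.size:
                    terms = self.W[i, ks] + Z[i + 1, ks - 1] + Z[ks + 1, j]
                    best = np.logaddexp(best, _logsumexp(terms))
                Z[i, j] = best
        self._Z = Z

    # -- outside + pair probabilities ---------------------------------------
    def pair_probabilities(self) -> np.ndarray:
        if self._bpp is not None:
            return self._bpp
        n, Z, W = self.n, self.Z, self.W
        O = np.full((n, n), _NEG_INF)
        logP = np.full((n, n), _NEG_INF)
        if n:
            O[0, n - 1] = 0.0
        for span in range(n - 1, -1, -1):
            for i in range(n - span):
                j = i + span
                o = O[i, j]
                if o == _NEG_INF:
                    continue
                if i + 1 <= j:
                    O[i + 1, j] = np.logaddexp(O[i + 1, j], o)
                ks = np.nonzero(np.isfinite(W[i, i : j + 1]))[0] + i
                if not ks.size:
                    continue
                left = Z[i + 1, ks - 1]  # inside of [i+1, k-1]
                right = Z[ks + 1, j]  # inside of [k+1, j]
                base = o + W[i, ks]
                np.logaddexp.at(logP[i], ks, base + left + right)
                np.logaddexp.at(O[i + 1], ks - 1, base + right)
                inner = ks[ks < j]
                if inner.size:
                    np.logaddexp.at(
                        O[:, j], inner + 1, base[ks < j] + left[ks < j]
                    )
        p = np.exp(logP - self.logZ_total)
        p = p + p.T
        self._bpp = p
        return p

    # -- MFE ----------------------------------------------------------------
    def _mfe_dp(self) -> None:
        n = self.n
        M = np.zeros((n + 2, n + 2))
        for span in range(n):
            for i in range(n - span):
                j = i + span
                best = M[i + 1, j]
                ks = np.nonzero(np.isfinite(self.E[i, i : j + 1]))[0] + i
                if ks.size:
                    paired = self.E[i, ks] + M[i + 1, ks - 1] + M[ks + 1, j]
                    best = min(best, paired.min())
                M[i, j] = best
        self._M = M

    def mfe(self) -> SecondaryStructure:
        # Greedy traceback: among co-optimal branches prefer pairing the 5'
        # nucleotide, and to the smallest partner.  Because pair energies are
        # strictly negative no co-optimal pair list is a prefix of another, so
        # this yields the lexicographically smallest sorted pair list.
        n, M, E = self.n, self.M, self.E
        pairs = []
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j:
                continue
            target = M[i, j]
            chosen = None
            ks = np.nonzero(np.isfinite(E[i, i : j + 1]))[0] + i
            for k in ks:
                if E[i, k] + M[i + 1, k - 1] + M[k + 1, j] == target:
                    chosen = int(k)
                    break
            if chosen is None:
                stack.append((i + 1, j))
            else:
                pairs.append((i + 1, chosen + 1))
                stack.append((i + 1, chosen - 1))
                stack.append((chosen + 1, j))
        return SecondaryStructure(n=n, pairs=frozenset(pairs))

    # -- stochastic traceback -----------------------------------------------
    def _choices(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Branch partners (-1 = leave i unpaired) and cumulative probabilities."""
        cached = self._samp_cache.get((i, j))
        if cached is not None:
            return cached
        Z, W = self.Z, self.W
        ks = np.nonzero(np.isfinite(W[i, i : j + 1]))[0] + i
        logs = [Z[i + 1, j]]
        partners = [-1]
        if ks.size:
            logs.extend(W[i, ks] + Z[i + 1, ks - 1] + Z[ks + 1, j])
            partners.extend(ks.tolist())
        logs = np.asarray(logs) - Z[i, j]
        cum = np.cumsum(np.exp(logs))
        cum[-1] = 1.0
        out = (np.asarray(partners), cum)
        if len(self._samp_cache) < 200_000:
            self._samp_cache[(i, j)] = out
        return out

    def sample(self, rng: np.random.Generator) -> SecondaryStructure:
        pairs = []
        stack = [(0, self.n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j:
                continue
            partners, cum = self._choices(i, j)
            k = int(partners[np.searchsorted(cum, rng.random(), side="right")])
            if k == -1:
                stack.append((i + 1, j))
            else:
                pairs.append((i + 1, k + 1))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
        return SecondaryStructure(n=self.n, pairs=frozenset(pairs))


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if m == _NEG_INF:
        return _NEG_INF
    return float(m + np.log(np.sum(np.exp(v - m))))


# ---------------------------------------------------------------------------
# file adapters

_DB_TOKEN = re.compile(r"^[.()\[\]{}<>]+$")


def read_fasta(path) -> list[RnaSequence]:
    from Bio import SeqIO

    return [RnaSequence(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: list[RnaSequence], path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n{s.residues}\n")


def read_dotbracket_ensemble(path, seq: RnaSequence, min_loop: int = 3) -> StructureEnsemble:
    """Parse one structure per line of external-predictor output.

    Header lines (``>``) and lines carrying only sequence letters or energies
    are ignored; a line whose first whitespace token looks like dot-bracket is
    parsed and validated.  Malformed structures are reported with their line
    number.
    """
    structures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith((">", "#", ";")):
                continue
            token = line.split()[0]
            if not _DB_TOKEN.match(token):
                continue
            try:
                s = SecondaryStructure.from_dotbracket(token)
                if s.n != seq.n:
                    raise ValueError(
                        f"structure length {s.n} != sequence length {seq.n}"
                    )
                s.validate(min_loop=min_loop)
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            structures.append(s)
    if not structures:
        raise ValueError(f"{path}: no dot-bracket structures found")
    return StructureEnsemble(sequence=seq, structures=structures, engine="external")


def write_dotbracket_ensemble(ensemble: StructureEnsemble, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ensemble.sequence.id}\n{ensemble.sequence.residues}\n")
        for s in ensemble.structures:
            fh.write(s.to_dotbracket() + "\n")
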