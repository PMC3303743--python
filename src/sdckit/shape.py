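"""Reading, normalizing and capping per-nucleotide SHAPE reactivity profiles.

SHAPE (selective 2'-hydroxyl acylation analyzed by primer extension) reports
per-nucleotide backbone flexibility: unpaired nucleotides react strongly, paired
ones weakly.  Profiles pass through three states:

``raw``        as parsed from file, arbitrary scale;
``normalized`` divided by the 2%/8% box-plot factor so typical reactive
               positions sit near 1;
``capped``     negatives clipped to 0 and values clipped at a cap (default 1),
               so that downstream correlations compare pairing *pattern*
               rather than peak intensity.

Two plain-text dialects are supported:

* ``long-tsv`` — columns ``rna_id  variant_id  replicate  position  nucleotide
  reactivity`` (tab separated, header required, ``NA`` for missing);
* ``wide-csv`` — first column ``position``, one column per variant, replicate
  number suffixed ``__r2``, ``__r3``, ... (no suffix means replicate 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ReactivityProfile",
    "MutantCollection",
    "read_reactivity_table",
    "write_profiles",
    "normalize_profile",
    "cap_profile",
]

STATES = ("raw", "normalized", "capped")

#: variant labels recognised as the wild-type reference
WT_NAMES = frozenset({"WT", "wt", "wildtype", "wild-type", "WILDTYPE"})


def is_wt(variant_id: str) -> bool:
    return variant_id in WT_NAMES


@dataclass
class ReactivityProfile:
    """Per-nucleotide SHAPE reactivities for one (variant, replicate).

    Positions are 1-based and strictly increasing; missing reactivities are
    NaN and propagate (they are excluded pairwise in correlations).
    """

    rna_id: str
    variant_id: str
    replicate: int
    positions: np.ndarray
    reactivities: np.ndarray
    state: str = "raw"
    nucleotides: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.reactivities = np.asarray(self.reactivities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.reactivities.shape:
            raise ValueError("positions and reactivities must be 1-D and equal length")
        if self.positions.size and (
            np.any(np.diff(self.positions) <= 0) or self.positions[0] < 1
        ):
            raise ValueError("positions must be 1-based, unique and sorted")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.reactivities)))

    def values_at(self, positions: np.ndarray) -> np.ndarray:
        """Reactivities aligned to ``positions`` (NaN where not measured)."""
        out = np.full(len(positions), np.nan)
        idx = {int(p): i for i, p in enumerate(self.positions)}
        for k, p in enumerate(positions):
            i = idx.get(int(p))
            if i is not None:
                out[k] = self.reactivities[i]
        return out

    def copy(self) -> "ReactivityProfile":
        return replace(
            self,
            positions=self.positions.copy(),
            reactivities=self.reactivities.copy(),
            nucleotides=None if self.nucleotides is None else self.nucleotides.copy(),
        )


@dataclass
class MutantCollection:
    """All profiles measured for one RNA construct under one condition."""

    rna_id: str
    profiles: list[ReactivityProfile] = field(default_factory=list)
    wt_sequence: str | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def variant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.variant_id, None)
        return list(seen)

    @property
    def wt_variant(self) -> str:
        wts = [v for v in self.variant_ids if is_wt(v)]
        if len(wts) != 1:
            raise ValueError(
                f"collection must contain exactly one WT variant, found {wts!r}"
            )
        return wts[0]

    def get(self, variant_id: str, replicate: int = 1) -> ReactivityProfile:
        for p in self.profiles:
            if p.variant_id == variant_id and p.replicate == replicate:
                return p
        raise KeyError(f"no profile for ({variant_id!r}, replicate {replicate})")

    def replicates_of(self, variant_id: str) -> list[ReactivityProfile]:
        reps = [p for p in self.profiles if p.variant_id == variant_id]
        return sorted(reps, key=lambda p: p.replicate)

    def common_positions(self) -> np.ndarray:
        if not self.profiles:
            return np.array([], dtype=int)
        common = set(self.profiles[0].positions.tolist())
        for p in self.profiles[1:]:
            common &= set(p.positions.tolist())
        return np.array(sorted(common), dtype=int)

    def map_profiles(self, fn) -> "MutantCollection":
        return MutantCollection(
            rna_id=self.rna_id,
            profiles=[fn(p) for p in self.profiles],
            wt_sequence=self.wt_sequence,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# normalization / capping


def normalization_factor(values: np.ndarray) -> float:
    """2%/8% box-plot normalization factor.

    The top ``ceil(0.02 m)`` non-missing reactivities are treated as outliers;
    the factor is the mean of the next ``ceil(0.08 m)`` values.  Counts use
    ceilings so the rule is deterministic at small m.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    m = v.size
    if m == 0:
        raise ValueError("no non-missing values")
    if np.all(v == v[0]):
        raise ValueError("degenerate profile: all values equal")
    n_out = math.ceil(0.02 * m)
    n_avg = math.ceil(0.08 * m)
    ordered = np.sort(v)[::-1]
    band = ordered[n_out : n_out + n_avg]
    factor = float(np.mean(band))
    if factor <= 0:
        raise ValueError("degenerate profile: non-positive normalization factor")
    return factor


def normalize_profile(profile: ReactivityProfile, min_valid: int = 25) -> ReactivityProfile:
    """Divide a raw profile by its 2%/8% factor (state raw -> normalized)."""
    if profile.state != "raw":
        raise ValueError(f"expected state 'raw', got {profile.state!r}")
    if profile.n_valid < min_valid:
        raise ValueError(
            f"need >= {min_valid} non-missing values to normalize, have {profile.n_valid}"
        )
    factor = normalization_factor(profile.reactivities)
    out = profile.copy()
    out.reactivities = out.reactivities / factor
    out.state = "normalized"
    return out


def cap_profile(profile: ReactivityProfile, cap: float = 1.0) -> ReactivityProfile:
    """Clip negatives to 0 and values above ``cap`` to ``cap`` (-> capped).

    Capping at one makes the WT/mutant correlation reflect changes in the
    peaking pattern rather than differences in peak intensity.
    """
    if profile.state != "normalized":
        raise ValueError(f"expected state 'normalized', got {profile.state!r}")
    out = profile.copy()
    out.reactivities = np.clip(out.reactivities, 0.0, cap)
    out.state = "capped"
    return out


def prepare_collection(collection: MutantCollection, cap: float = 1.0) -> MutantCollection:
    """Normalize then cap every profile (each profile independently)."""
    return collection.map_profiles(lambda p: cap_profile(normalize_profile(p), cap=cap))


# ---------------------------------------------------------------------------
# file I/O

LONG_COLUMNS = ["rna_id", "variant_id", "replicate", "position", "nucleotide", "reactivity"]


def read_reactivity_table(path, dialect: str = "long-tsv") -> MutantCollection:
    """Parse a reactivity table into a :class:`MutantCollection` (state raw).

    Unparseable numeric cells become missing.  Duplicate
    (variant, replicate, position) rows and a missing WT variant are hard
    errors.
    """
    if dialect == "long-tsv":
        return _read_long(path)
    if dialect == "wide-csv":
        return _read_wide(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long(path) -> MutantCollection:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long-tsv missing columns: {missing}")
    df["replicate"] = df["replicate"].astype(int)
    df["position"] = df["position"].astype(int)
    df["reactivity"] = pd.to_numeric(df["reactivity"], errors="coerce")
    dup = df.duplicated(subset=["variant_id", "replicate", "position"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate entry for ({row['variant_id']}, r{row['replicate']}, "
            f"position {row['position']})"
        )
    rna_ids = df["rna_id"].unique()
    if len(rna_ids) != 1:
        raise ValueError(f"expected a single rna_id per file, found {list(rna_ids)}")
    profiles = []
    for (variant, rep), grp in df.groupby(["variant_id", "replicate"], sort=True):
        grp = grp.sort_values("position")
        nts = grp["nucleotide"].to_numpy(dtype=object)
        profiles.append(
            ReactivityProfile(
                rna_id=str(rna_ids[0]),
                variant_id=str(variant),
                replicate=int(rep),
                positions=grp["position"].to_numpy(),
                reactivities=grp["reactivity"].to_numpy(dtype=float),
                nucleotides=nts if np.any(nts != "") else None,
            )
        )
    coll = MutantCollection(rna_id=str(rna_ids[0]), profiles=profiles)
    coll.wt_variant  # raises if no (or ambiguous) WT
    return coll


def _split_variant_column(name: str) -> tuple[str, int]:
    if "__r" in name:
        variant, _, rep = name.rpartition("__r")
        return variant, int(rep)
    return name, 1


def _read_wide(path) -> MutantCollection:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "position":
        raise ValueError("wide-csv must start with a 'position' column")
    positions = df["position"].astype(int).to_numpy()
    if np.any(np.diff(positions) <= 0):
        bad = positions[1:][np.diff(positions) <= 0][0]
        raise ValueError(f"duplicate or unsorted position {bad}")
    rna_id = _stem(path)
    profiles = []
    for col in df.columns[1:]:
        variant, rep = _split_variant_column(col)
        profiles.append(
            ReactivityProfile(
                rna_id=rna_id,
                variant_id=variant,
                replicate=rep,
                positions=positions.copy(),
                reactivities=pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float),
            )
        )
    coll = MutantCollection(rna_id=rna_id, profiles=profiles)
    coll.wt_variant
    return coll


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_profiles(collection: MutantCollection, path, dialect: str = "long-tsv") -> None:
    """Serialize a collection; round-trip safe up to float formatting.

    The per-profile state is stored in a ``# state:`` header comment for
    long-tsv (wide-csv cannot carry it and always re-reads as raw).
    """
    if dialect == "long-tsv":
        rows = []
        states = {p.state for p in collection.profiles}
        for p in collection.profiles:
            nts = p.nucleotides if p.nucleotides is not None else [""] * len(p.positions)
            for pos, nt, r in zip(p.positions, nts, p.reactivities):
                rows.append(
                    {
                        "rna_id": p.rna_id,
                        "variant_id": p.variant_id,
                        "replicate": p.replicate,
                        "position": pos,
                        "nucleotide": nt,
                        "reactivity": "NA" if np.isnan(r) else repr(float(r)),
                    }
                )
        df = pd.DataFrame(rows, columns=LONG_COLUMNS)
        with open(path, "w") as fh:
            if len(states) == 1:
                fh.write(f"# state: {states.pop()}\n")
            df.to_csv(fh, sep="\t", index=False)
    elif dialect == "wide-csv":
        positions = collection.common_positions()
        data = {"position": positions}
        for p in collection.profiles:
            name = p.variant_id if p.replicate == 1 else f"{p.variant_id}__r{p.replicate}"
            data[name] = p.values_at(positions)
        pd.DataFrame(data).to_csv(path, index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_profiles(path, dialect: str = "long-tsv") -> MutantCollection:
    """Read back files written by :func:`write_profiles`, restoring state."""
    state = "raw"
    if dialect == "long-tsv":
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# state:"):
            state = first.split(":", 1)[1].strip()
            import io

            with open(path) as fh:
                body = io.StringIO("".join(fh.readlines()[1:]))
            coll = _read_long(body)
            for p in coll.profiles:
                p.state = state
            return coll
    return read_reactivity_table(path, dialect)
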