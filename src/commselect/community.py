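"""Species pools, communities, compatibility constraints and composition distances.

A community is a small set of species drawn from a fixed, ordered pool — the
"genome" on which the selection algorithm operates.  Certain species pairs are
indistinguishable on the selective plates used to disassemble communities, so
those pairs may never be co-inoculated; the :class:`CompatibilityMap` records
them and every community-generating operation respects it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpeciesPool",
    "CompatibilityMap",
    "Community",
    "DEFAULT_SPECIES",
    "DEFAULT_FORBIDDEN_PAIRS",
    "default_pool",
    "default_compatibility",
    "validate_community",
    "enumerate_allowed",
    "count_allowed",
    "composition_distance",
    "generate_initial_round",
]

#: The 11-species pool used in the metal-working-fluid degradation experiment,
#: in fixed order.  The order defines presence-vector coordinates, CSV column
#: order and lexicographic enumeration order for the lifetime of a run.
DEFAULT_SPECIES: tuple[tuple[str, str], ...] = (
    ("Sw", "Staphylococcus warneri"),
    ("At1", "Agrobacterium tumefaciens MWF001"),
    ("Ct", "Comamonas testosteroni MWF001"),
    ("Ml", "Microbacterium liquefaciens MWF001"),
    ("Af", "Alcaligenes faecalis"),
    ("Ac", "Aeromonas caviae"),
    ("Ea", "Enterococcus avium"),
    ("Kp", "Klebsiella pneumoniae"),
    ("Pf", "Pseudomonas fulva"),
    ("Pr", "Providencia rettgeri"),
    ("At2", "Agrobacterium tumefaciens C58"),
)

#: Species pairs that cannot be told apart on the selective plates and are
#: therefore never co-inoculated.
DEFAULT_FORBIDDEN_PAIRS: tuple[tuple[str, str], ...] = (
    ("Ct", "At2"),
    ("Af", "Ct"),
    ("Ml", "Sw"),
    ("Ml", "Ea"),
    ("Ac", "Pf"),
    ("Ct", "Kp"),
)


class InputError(ValueError):
    """Invalid user-supplied data (unknown acronym, malformed file, bad value)."""


class ConfigurationError(ValueError):
    """A run configuration that cannot be satisfied."""


@dataclass(frozen=True)
class SpeciesPool:
    """An ordered collection of unique species acronyms.

    Parameters
    ----------
    species
        Acronyms in fixed order; the order defines the coordinates of every
        presence vector derived from this pool.
    display_names
        Optional mapping acronym -> full name; purely cosmetic.
    """

    species: tuple[str, ...]
    display_names: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.species) != len(set(self.species)):
            raise InputError("species acronyms must be unique")
        if any(not s for s in self.species):
            raise InputError("species acronyms must be non-empty")

    def __len__(self) -> int:
        return len(self.species)

    def __contains__(self, acronym: str) -> bool:
        return acronym in self.species

    def index(self, acronym: str) -> int:
        try:
            return self.species.index(acronym)
        except ValueError:
            raise InputError(f"unknown species acronym: {acronym!r}") from None

    def check_members(self, members: Iterable[str]) -> None:
        unknown = sorted(set(members) - set(self.species))
        if unknown:
            raise InputError(f"unknown species acronym(s): {', '.join(unknown)}")

    def sorted_members(self, members: Iterable[str]) -> tuple[str, ...]:
        """Members in pool order (the canonical serialization order)."""
        self.check_members(members)
        mset = set(members)
        return tuple(s for s in self.species if s in mset)

    def presence_vector(self, members: Iterable[str]) -> np.ndarray:
        """0/1 vector over pool coordinates; popcount equals ``len(members)``."""
        self.check_members(members)
        mset = set(members)
        return np.array([1 if s in mset else 0 for s in self.species], dtype=np.int8)


@dataclass(frozen=True)
class CompatibilityMap:
    """Unordered species pairs that may never appear in the same community."""

    forbidden_pairs: frozenset[frozenset[str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]], pool: SpeciesPool | None = None) -> "CompatibilityMap":
        out = set()
        for a, b in pairs:
            if a == b:
                raise InputError(f"self-pair not allowed: {a!r}")
            if pool is not None:
                pool.check_members((a, b))
            out.add(frozenset((a, b)))
        return cls(frozenset(out))

    def forbids(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.forbidden_pairs

    def violations(self, members: Iterable[str]) -> list[tuple[str, str]]:
        """Every forbidden pair contained in ``members``, sorted for determinism."""
        mset = set(members)
        hits = [tuple(sorted(p)) for p in self.forbidden_pairs if p <= mset]
        return sorted(hits)

    def is_allowed(self, members: Iterable[str]) -> bool:
        return not self.violations(members)


def default_pool() -> SpeciesPool:
    return SpeciesPool(
        species=tuple(a for a, _ in DEFAULT_SPECIES),
        display_names={a: n for a, n in DEFAULT_SPECIES},
    )


def default_compatibility() -> CompatibilityMap:
    return CompatibilityMap.from_pairs(DEFAULT_FORBIDDEN_PAIRS)


TREATMENTS = ("selection", "random", "propagule", "migrant_pool", "control")


@dataclass(frozen=True)
class Community:
    """A species set with bookkeeping identity.

    ``members`` is the genome; ``community_id`` identifies the physical culture
    (two communities with equal members but different ids are the *same
    composition* for analysis purposes).
    """

    members: frozenset[str]
    community_id: str
    round_index: int = 0
    treatment: str = "selection"
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.round_index < 0:
            raise InputError("round_index must be non-negative")
        if self.treatment not in TREATMENTS:
            raise InputError(f"unknown treatment {self.treatment!r}")

    def size(self) -> int:
        return len(self.members)

    def with_members(self, members: Iterable[str], **overrides) -> "Community":
        kwargs = dict(
            members=frozenset(members),
            community_id=self.community_id,
            round_index=self.round_index,
            treatment=self.treatment,
            parent_id=self.parent_id,
        )
        kwargs.update(overrides)
        return Community(**kwargs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_community(
    community: Community | Iterable[str],
    cmap: CompatibilityMap,
    pool: SpeciesPool | None = None,
) -> tuple[bool, list[tuple[str, str]]]:
    """Check a community for forbidden (plate-indistinguishable) pairs.

    Returns ``(ok, violations)`` where ``violations`` lists every forbidden
    pair contained in the community.  An empty community is trivially valid.
    """
    members = community.members if isinstance(community, Community) else frozenset(community)
    if pool is not None:
        pool.check_members(members)
    bad = cmap.violations(members)
    return (not bad, bad)


def enumerate_allowed(pool: SpeciesPool, cmap: CompatibilityMap, k: int) -> list[frozenset[str]]:
    """All k-subsets of the pool containing no forbidden pair.

    Output is deterministic: lexicographic in the pool ordering, each allowed
    subset exactly once.
    """
    if k < 0 or k > len(pool):
        raise InputError(f"k={k} out of range for a pool of {len(pool)} species")
    out = []
    for combo in itertools.combinations(pool.species, k):
        if cmap.is_allowed(combo):
            out.append(frozenset(combo))
    return out


def count_allowed(pool: SpeciesPool, cmap: CompatibilityMap, k: int) -> int:
    """Number of allowed k-subsets, by inclusion–exclusion over forbidden pairs.

    Independent of :func:`enumerate_allowed` (which is the brute-force oracle
    it is cross-checked against): for each subset S of forbidden pairs, the
    k-subsets containing every pair in S number C(n - |union S|, k - |union S|),
    signed by (-1)^|S|.  Subsets whose species union already exceeds k
    contribute nothing, and neither does any superset, so those branches of
    the subset lattice are pruned.
    """
    if k < 0 or k > len(pool):
        raise InputError(f"k={k} out of range for a pool of {len(pool)} species")
    pairs = [tuple(sorted(p)) for p in sorted(cmap.forbidden_pairs, key=sorted)]
    n = len(pool)
    total = 0

    def descend(start: int, union: frozenset, sign: int) -> None:
        nonlocal total
        total += sign * comb(n - len(union), k - len(union))
        for j in range(start, len(pairs)):
            grown = union | frozenset(pairs[j])
            if len(grown) <= k:
                descend(j + 1, grown, -sign)

    descend(0, frozenset(), 1)
    return total


def composition_distance(
    a: Community | Iterable[str],
    b: Community | Iterable[str],
    pool: SpeciesPool,
) -> tuple[float, int]:
    """Hamming distance between two compositions over a common pool.

    Returns ``(mismatch_fraction, substitution_count)``: the fraction of pool
    coordinates whose presence differs, and the number of species exchanges
    needed to turn ``a`` into ``b`` (``|a \\ b|``; for equal-size communities
    this is half the mismatch count).  Both conventions are in routine use, so
    both are always returned.
    """
    ma = a.members if isinstance(a, Community) else frozenset(a)
    mb = b.members if isinstance(b, Community) else frozenset(b)
    pool.check_members(ma)
    pool.check_members(mb)
    mismatches = len(ma ^ mb)
    return mismatches / len(pool), len(ma - mb)


def generate_initial_round(
    pool: SpeciesPool,
    cmap: CompatibilityMap,
    n_communities: int,
    k: int,
    rng: np.random.Generator,
    *,
    treatment: str = "selection",
    round_index: int = 0,
    max_retries: int = 10_000,
) -> list[Community]:
    """Draw the starting generation: legal k-subsets covering every pool species.

    Uniform rejection sampling from the allowed set, followed by a coverage
    repair pass: while some species is uncovered, a slot whose composition is
    duplicated (or, failing that, a random slot) is replaced by an allowed
    community containing the rarest uncovered species.
    """
    allowed = enumerate_allowed(pool, cmap, k)
    if not allowed:
        raise ConfigurationError("no legal community exists for this pool/compatibility map")
    covered_all = set().union(*allowed)
    if covered_all != set(pool.species):
        missing = sorted(set(pool.species) - covered_all)
        raise ConfigurationError(f"species can never be covered: {', '.join(missing)}")

    draws = [allowed[rng.integers(len(allowed))] for _ in range(n_communities)]

    by_species = {s: [c for c in allowed if s in c] for s in pool.species}
    for _ in range(max_retries):
        uncovered = [s for s in pool.species if not any(s in d for d in draws)]
        if not uncovered:
            break
        # rarest uncovered species first: fewest allowed communities host it
        target = min(uncovered, key=lambda s: (len(by_species[s]), pool.index(s)))
        counts: dict[frozenset, int] = {}
        for d in draws:
            counts[d] = counts.get(d, 0) + 1
        dup_slots = [i for i, d in enumerate(draws) if counts[d] > 1]
        slot = int(rng.choice(dup_slots)) if dup_slots else int(rng.integers(len(draws)))
        pick = by_species[target][int(rng.integers(len(by_species[target])))]
        draws[slot] = pick
    else:
        raise ConfigurationError(
            f"could not cover all {len(pool)} species in {n_communities} communities "
            f"of size {k} after {max_retries} repair attempts"
        )

    return [
        Community(
            members=d,
            community_id=f"r{round_index}-{treatment[0]}{i:02d}",
            round_index=round_index,
            treatment=treatment,
        )
        for i, d in enumerate(draws)
    ]
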