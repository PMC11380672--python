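"""Synthetic community-function landscapes.

Maps a species composition to a simulated assay outcome — final per-species
abundances, survival, a COD reading and hence a degradation percent — so the
selection engine can be exercised and benchmarked entirely in silico.

The model is a deliberately simple single-endpoint one (no time-resolved
dynamics): each species has a monoculture degradation effect ``d`` (percent
points) and a monoculture log10 final abundance ``b``; pairwise matrices
``A`` (growth effects, log10 units) and ``B`` (degradation epistasis, percent
points) perturb these in co-culture.  Survival is a threshold on realized
log-abundance, and only survivors contribute to degradation.  This is the
simplest form able to express the four archetypes seen in the real system:
strong degraders, weak degraders facilitated by partners, free-riders, and
competitors that drive partners extinct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .community import (
    Community,
    CompatibilityMap,
    InputError,
    SpeciesPool,
    default_pool,
    enumerate_allowed,
)
from .scoring import AssayMeasurement

__all__ = [
    "LandscapeModel",
    "simulate_outcomes",
    "make_fixture",
    "true_optimum",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("paper11", "additive", "killer", "flat")


@dataclass(frozen=True)
class LandscapeModel:
    """A composition -> (COD, abundances) map with configurable noise.

    Attributes
    ----------
    species : tuple of acronyms in pool order.
    d : per-species monoculture degradation effect, percent points, in [-20, 100].
    b : per-species monoculture log10 final abundance (log10 CFU/ml), in [0, 12].
    A : growth-effect matrix; ``A[i, j]`` is the effect of j's presence on i's
        final log10 abundance.  Zero diagonal; need not be symmetric.
    B : degradation epistasis; percent points added to the additive sum when
        i and j co-occur and both survive.  Zero diagonal; symmetric.
    cod_control : abiotic-control COD, g/l (inside the assay's 1-15 g/l range).
    sigma_growth : growth noise SD, log10 units.
    sigma_measure : measurement noise SD on the degradation-percent scale.
    detection_threshold : log10 CFU/ml below which a species reads as extinct.
    contamination_rate : per-species per-community probability of a spurious
        detection at the threshold abundance.
    d_max : ceiling on community degradation, percent.
    """

    species: tuple[str, ...]
    d: np.ndarray
    b: np.ndarray
    A: np.ndarray
    B: np.ndarray
    cod_control: float = 12.0
    sigma_growth: float = 0.3
    sigma_measure: float = 5.0
    detection_threshold: float = 3.0
    contamination_rate: float = 0.0
    d_max: float = 95.0

    def __post_init__(self) -> None:
        n = len(self.species)
        for name in ("d", "b", "A", "B"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.d.shape != (n,) or self.b.shape != (n,):
            raise InputError("d and b must have one entry per species")
        if self.A.shape != (n, n) or self.B.shape != (n, n):
            raise InputError("A and B must be square in the pool size")
        if np.any(np.diag(self.A) != 0) or np.any(np.diag(self.B) != 0):
            raise InputError("A and B must have zero diagonal")
        if not np.allclose(self.B, self.B.T):
            raise InputError("B must be symmetric")
        if np.any(self.d < -20) or np.any(self.d > 100):
            raise InputError("d entries must lie in [-20, 100]")
        if np.any(self.b < 0) or np.any(self.b > 12):
            raise InputError("b entries must lie in [0, 12]")
        if not 1.0 <= self.cod_control <= 15.0:
            raise InputError("cod_control must lie in the assay range 1-15 g/l")
        if self.sigma_growth < 0 or self.sigma_measure < 0:
            raise InputError("noise SDs must be non-negative")

    def pool(self) -> SpeciesPool:
        return SpeciesPool(species=self.species)

    def index(self, acronym: str) -> int:
        try:
            return self.species.index(acronym)
        except ValueError:
            raise InputError(f"species {acronym!r} not in landscape") from None

    def noise_free(self) -> "LandscapeModel":
        """Copy with all stochastic elements switched off."""
        return replace(self, sigma_growth=0.0, sigma_measure=0.0, contamination_rate=0.0)

    # -- JSON persistence ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "species": list(self.species),
            "d": self.d.tolist(),
            "b": self.b.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "cod_control": self.cod_control,
            "sigma_growth": self.sigma_growth,
            "sigma_measure": self.sigma_measure,
            "detection_threshold": self.detection_threshold,
            "contamination_rate": self.contamination_rate,
            "d_max": self.d_max,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LandscapeModel":
        payload = json.loads(text)
        payload["species"] = tuple(payload["species"])
        return cls(**payload)


def _deterministic_survivors(model: LandscapeModel, idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free realized log-abundances and survival mask for member indices."""
    L = np.array([model.b[i] + sum(model.A[i, j] for j in idx if j != i) for i in idx])
    return L, L >= model.detection_threshold


def _raw_degradation(model: LandscapeModel, surviving_idx: list[int]) -> float:
    total = float(np.sum(model.d[surviving_idx]))
    for a in range(len(surviving_idx)):
        for b_ in range(a + 1, len(surviving_idx)):
            total += float(model.B[surviving_idx[a], surviving_idx[b_]])
    return float(np.clip(total, -20.0, model.d_max))


def simulate_outcomes(
    community: Community | Iterable[str],
    model: LandscapeModel,
    rng: np.random.Generator,
) -> tuple[AssayMeasurement, dict[str, float]]:
    """Grow a community on the landscape and read out the assay.

    Returns the COD measurement pair and a per-species CFU/ml count map over
    the full pool (zeros for extinct / absent species; contaminants, if any,
    appear at the detection-threshold abundance).
    """
    members = community.members if isinstance(community, Community) else frozenset(community)
    pool = model.pool()
    pool.check_members(members)

    idx = [model.index(s) for s in pool.sorted_members(members)]
    L, _ = _deterministic_survivors(model, idx)
    if model.sigma_growth > 0:
        L = L + rng.normal(0.0, model.sigma_growth, size=len(idx))
    survive = L >= model.detection_threshold
    surviving_idx = [i for i, s in zip(idx, survive) if s]

    d_raw = _raw_degradation(model, surviving_idx)
    noise = rng.normal(0.0, model.sigma_measure) if model.sigma_measure > 0 else 0.0
    cod_sample = max(model.cod_control * (1.0 - (d_raw + noise) / 100.0), 0.0)

    counts = {s: 0.0 for s in model.species}
    for i, l_i, s in zip(idx, L, survive):
        if s:
            counts[model.species[i]] = float(10.0 ** l_i)
    if model.contamination_rate > 0:
        for s in model.species:
            if s not in members and rng.random() < model.contamination_rate:
                counts[s] = float(10.0 ** model.detection_threshold)

    return AssayMeasurement(cod_sample=cod_sample, cod_control=model.cod_control), counts


def expected_outcome(model: LandscapeModel, members: Iterable[str]) -> tuple[float, float, frozenset[str]]:
    """Noise-free (degradation_percent, penalized_score, survivors) of a composition."""
    members = frozenset(members)
    idx = [model.index(s) for s in members]
    _, survive = _deterministic_survivors(model, idx)
    surviving_idx = [i for i, s in zip(idx, survive) if s]
    deg = _raw_degradation(model, surviving_idx)
    f = len(surviving_idx) / len(idx) if idx else 1.0
    return deg, deg * f, frozenset(model.species[i] for i in surviving_idx)


def true_optimum(
    model: LandscapeModel,
    pool: SpeciesPool,
    cmap: CompatibilityMap,
    k: int,
) -> tuple[frozenset[str], float]:
    """Exhaustive noise-free optimum over all allowed k-subsets.

    The brute-force oracle for benchmarking the stochastic search: evaluates
    the expected penalized score of every legal composition and returns the
    argmax, ties broken by enumeration (lexicographic) order.
    """
    best_members: frozenset[str] | None = None
    best_score = -np.inf
    for members in enumerate_allowed(pool, cmap, k):
        _, score, _ = expected_outcome(model, members)
        if score > best_score:
            best_members, best_score = members, score
    assert best_members is not None
    return best_members, float(best_score)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

# Monoculture degradation anchors (percent) for the 11-species fixture.  The
# seven printed values are fixed; Sw, Ml, Kp and Pr are invented plumbing.
_PAPER11_D = {
    "Pf": 66.0, "Ct": 58.0, "At1": 50.0,     # best individual degraders
    "Ac": 11.0,                               # free-rider: poor alone
    "Af": 2.0, "Ea": 2.0, "At2": 4.0,         # worst degraders
    "Sw": 18.0, "Ml": 6.0, "Kp": 28.0, "Pr": 35.0,  # invented mid/low values
}

# Monoculture log10 final abundances (invented; Af deliberately close to the
# detection threshold so that facilitation by At1 is what lets it thrive).
_PAPER11_B = {
    "Sw": 6.5, "At1": 7.0, "Ct": 7.5, "Ml": 5.5, "Af": 3.2, "Ac": 4.0,
    "Ea": 5.0, "Kp": 8.0, "Pf": 7.5, "Pr": 5.5, "At2": 6.0,
}

# Pair-total anchors: realized noise-free degradation of the pair, from which
# the epistasis entry is back-derived as B[i][j] = total - d_i - d_j.
_PAPER11_PAIR_TOTALS = {
    frozenset({"Ac", "Pf"}): 50.0,
    frozenset({"Ac", "Ct"}): 46.0,
    frozenset({"At1", "Ac"}): 13.0,
    frozenset({"At1", "Af"}): 75.0,  # invented: the best-performing pair
}


def make_fixture(name: str, rng: np.random.Generator | None = None) -> LandscapeModel:
    """Build a named benchmark landscape over the default 11-species pool.

    ``paper11``
        Anchored to the printed mono- and co-culture degradation values of the
        real system where available, with documented invented values elsewhere;
        includes the At1->Af growth facilitation (+3.5 logs), an At1/Pr
        extinction motif, and the Ac free-rider motif (growth boosted by the
        strong degraders, degradation epistasis negative).
    ``additive``
        No interactions at all; monoculture effects drawn uniformly on [0, 60].
    ``killer``
        One strong degrader (Sw) drives every partner extinct — exercises the
        extinction penalty.
    ``flat``
        Every species identical; a null landscape where only drift acts.
    """
    pool = default_pool()
    species = pool.species
    n = len(species)
    ix = {s: i for i, s in enumerate(species)}

    if name == "paper11":
        d = np.array([_PAPER11_D[s] for s in species])
        b = np.array([_PAPER11_B[s] for s in species])
        A = np.zeros((n, n))
        # growth facilitation / inhibition motifs
        A[ix["Af"], ix["At1"]] = 3.5    # At1 boosts Af by >3 logs
        A[ix["At1"], ix["Af"]] = -0.5   # Af mildly reduces At1
        A[ix["Pr"], ix["At1"]] = -3.0   # At1/Pr motif: Pr collapses with At1
        A[ix["At1"], ix["Pr"]] = -1.5
        for partner in ("Pf", "Ct", "At1"):   # degraders boost the free-rider
            A[ix["Ac"], ix[partner]] = 1.5
        # degradation epistasis: functional redundancy between degraders, mild
        # interference elsewhere; B[i][j] = -0.6*min(d_i, d_j) - 3, with the
        # three strong degraders competing hard for the same substrate
        B = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                B[i, j] = B[j, i] = -0.6 * min(d[i], d[j]) - 3.0
        for a, c, val in (("At1", "Pf", -45.0), ("Ct", "Pf", -40.0), ("At1", "Ct", -35.0)):
            B[ix[a], ix[c]] = B[ix[c], ix[a]] = val
        for pair, total in _PAPER11_PAIR_TOTALS.items():
            a, c = sorted(pair)
            B[ix[a], ix[c]] = B[ix[c], ix[a]] = total - d[ix[a]] - d[ix[c]]
        return LandscapeModel(species=species, d=d, b=b, A=A, B=B)

    if name == "additive":
        if rng is None:
            rng = np.random.default_rng(0)
        d = rng.uniform(0.0, 60.0, size=n)
        b = np.full(n, 7.0)
        return LandscapeModel(
            species=species, d=d, b=b, A=np.zeros((n, n)), B=np.zeros((n, n)),
            sigma_growth=0.0, sigma_measure=0.0,
        )

    if name == "killer":
        d = np.full(n, 20.0)
        d[ix["Sw"]] = 60.0  # the aggressor degrades well alone
        b = np.full(n, 7.0)
        A = np.zeros((n, n))
        for s in species:
            if s != "Sw":
                A[ix[s], ix["Sw"]] = -6.0  # Sw drives every partner extinct
        return LandscapeModel(species=species, d=d, b=b, A=A, B=np.zeros((n, n)))

    if name == "flat":
        return LandscapeModel(
            species=species, d=np.full(n, 30.0), b=np.full(n, 7.0),
            A=np.zeros((n, n)), B=np.zeros((n, n)),
        )

    raise InputError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
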