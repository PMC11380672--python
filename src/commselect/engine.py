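"""The disassembly-selection algorithm and its comparator strategies.

One round of the method: (1) grow the planned communities, (2) measure each
one's degradation percent, (3) select the top-k by degradation and plate them
on selective media, which reveals extinctions and yields the penalized
community score, (4) refresh the per-species working-stock ledger from the
best-scoring plated community containing each species, and (5) sample the
next generation's compositions from the plated parents in proportion to their
penalized scores, then substitute one member ("invasion") in a fixed number of
offspring under compatibility and coverage constraints.

Two-stage scoring is deliberate: the plated set is chosen on the *unpenalized*
degradation percent (the penalty is only computable after plating), while
offspring sampling uses the *penalized* score.  A ``penalty_at_selection``
switch exposes the alternative; in simulation mode survival is observable for
every community, so the switch is honored exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .community import (
    Community,
    CompatibilityMap,
    ConfigurationError,
    InputError,
    SpeciesPool,
    enumerate_allowed,
    generate_initial_round,
)
from .landscape import LandscapeModel, simulate_outcomes
from .runio import AuditLog, derive_seed
from .scoring import (
    AssayMeasurement,
    CommunityScore,
    SurvivalRecord,
    community_score,
    degradation_percent,
    detect_survival,
)

__all__ = [
    "SelectionConfig",
    "RoundResult",
    "StockLedger",
    "DegenerateDistributionError",
    "select_top_k",
    "parent_distribution",
    "sample_offspring",
    "apply_invasions",
    "update_stock_ledger",
    "run_round",
    "run_experiment",
    "comparator_step",
]

logger = logging.getLogger("commselect")

_INVASION_RETRY_CAP = 10_000
_TARGET_REDRAW_CAP = 200

#: Sentinel for a working stock that still comes from the ancestral freezer.
ANCESTOR = ("ancestor", -1)


class DegenerateDistributionError(ValueError):
    """All floored scores are zero: no score-proportional distribution exists."""


class _RetryTargets(ConfigurationError):
    """Internal: the drawn invasion-target set is unsatisfiable but another may work."""


@dataclass(frozen=True)
class SelectionConfig:
    """Run configuration; defaults reproduce the published experimental design."""

    n_communities: int = 29
    top_k: int = 10
    n_invaded: int = 21
    community_size: int = 4
    n_rounds: int = 18
    treatment: str = "selection"
    master_seed: int = 0
    probability_floor: float = 0.0
    penalty_at_selection: bool = False
    detection_limit: float = 1e3

    def __post_init__(self) -> None:
        if self.top_k > self.n_communities:
            raise ConfigurationError("top_k must not exceed n_communities")
        if self.n_invaded > self.n_communities:
            raise ConfigurationError("n_invaded must not exceed n_communities")
        if self.probability_floor < 0:
            raise ConfigurationError("probability_floor must be non-negative")


@dataclass
class RoundResult:
    """One measured generation: plans, measurements, the plated subset, scores."""

    round_index: int
    treatment: str
    communities: list[Community]
    measurements: dict[str, AssayMeasurement]
    degradation: dict[str, float]
    plated_ids: list[str]
    survival: dict[str, SurvivalRecord]
    scores: dict[str, CommunityScore]

    def community(self, cid: str) -> Community:
        for c in self.communities:
            if c.community_id == cid:
                return c
        raise KeyError(cid)


@dataclass
class StockLedger:
    """Per-species provenance of the current working stock.

    Maps each species to ``(source_community_id, source_round)``; seeded with
    an ancestor sentinel before the first round.  When a species is detected
    in at least one plated community of a round, its stock is refreshed from
    the highest-penalized-score such community; otherwise the previous entry
    (the closest previous round) carries over.
    """

    source: dict[str, tuple[str, int]] = field(default_factory=dict)

    @classmethod
    def initial(cls, pool: SpeciesPool) -> "StockLedger":
        return cls(source={s: ANCESTOR for s in pool.species})


# ---------------------------------------------------------------------------
# Step 3: choose the plated set
# ---------------------------------------------------------------------------

def select_top_k(
    degradation: Mapping[str, float],
    k: int,
    *,
    treatment: str = "selection",
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Ids of the k communities to plate.

    Selection-like treatments take the k highest degradation percents
    (deterministic tie-break: ascending community id); the random control
    draws k ids uniformly without replacement and needs ``rng``.
    """
    if k > len(degradation):
        raise ConfigurationError(f"k={k} exceeds the {len(degradation)} measured communities")
    ids = sorted(degradation)
    if treatment == "random":
        if rng is None:
            raise InputError("random treatment requires an rng")
        picks = rng.choice(len(ids), size=k, replace=False)
        return [ids[i] for i in picks]
    return sorted(ids, key=lambda c: (-degradation[c], c))[:k]


def parent_distribution(
    scores: Sequence[float],
    mode: str = "proportional",
    floor: float = 0.0,
) -> np.ndarray:
    """Normalize penalized scores into offspring-sampling probabilities.

    Proportional mode floors each score at ``floor`` and normalizes; if every
    floored score is zero there is nothing to normalize and a
    :class:`DegenerateDistributionError` is raised (callers may fall back to
    uniform).  Uniform mode ignores the scores entirely.
    """
    n = len(scores)
    if n == 0:
        raise InputError("empty score list")
    if mode == "uniform":
        return np.full(n, 1.0 / n)
    if mode != "proportional":
        raise InputError(f"unknown distribution mode {mode!r}")
    floored = np.maximum(np.asarray(scores, dtype=float), floor)
    total = floored.sum()
    if total <= 0:
        raise DegenerateDistributionError(
            "all community scores are <= 0 after flooring; no proportional distribution"
        )
    return floored / total


def sample_offspring(
    parents: Sequence[Community],
    p: np.ndarray,
    n: int,
    rng: np.random.Generator,
    *,
    round_index: int,
    treatment: str,
) -> list[Community]:
    """Draw n offspring compositions with replacement, proportional to ``p``.

    Offspring copy their parent's member set exactly (heredity) and record the
    parent id; they receive fresh ids in the new round.
    """
    if len(p) != len(parents):
        raise InputError("probability vector length must match the parent list")
    draws = rng.choice(len(parents), size=n, p=np.asarray(p, dtype=float))
    out = []
    for i, j in enumerate(draws):
        parent = parents[int(j)]
        out.append(
            Community(
                members=parent.members,
                community_id=f"r{round_index}-{treatment[0]}{i:02d}",
                round_index=round_index,
                treatment=treatment,
                parent_id=parent.community_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Step 5b: invasions (the mutation operator)
# ---------------------------------------------------------------------------

def _legal_removals(members: frozenset[str], invader: str, cmap: CompatibilityMap) -> list[str]:
    """Residents whose removal lets ``invader`` join legally."""
    out = []
    for r in sorted(members):
        if cmap.is_allowed((members - {r}) | {invader}):
            out.append(r)
    return out


def apply_invasions(
    offspring: list[Community],
    pool: SpeciesPool,
    cmap: CompatibilityMap,
    n_invaded: int,
    rng_targets: np.random.Generator,
    rng_invader: np.random.Generator,
    audit: AuditLog | None = None,
) -> tuple[list[Community], list[dict]]:
    """Substitute one member in ``n_invaded`` randomly chosen offspring.

    Species not yet represented anywhere in the offspring set are introduced
    first, into random designated communities that can legally host them;
    remaining designated communities receive a uniform-random invader that is
    absent from the community and compatible with the residents left after a
    uniform-random removal.  After all invasions, meta-community coverage is
    re-checked (a removal can orphan a species) and repaired by re-drawing the
    offending invasion; every repair is logged.

    Postconditions: exactly ``n_invaded`` offspring differ from their parent
    composition by one substitution, all pool species appear somewhere, no
    forbidden pair occurs, and community size is preserved.

    Two bounded fallbacks keep the constraint set satisfiable: if every legal
    host for an uncovered species fell outside the drawn target set, the
    target set is redrawn; and if *no* offspring admits the species by a
    single legal substitution (every community carries two or more of its
    forbidden partners), one designated community is rebuilt as the closest
    legal composition containing it — an audited ``coverage-override`` that
    exceeds one substitution.
    """
    if n_invaded > len(offspring):
        raise ConfigurationError("n_invaded exceeds the number of offspring")
    last_error: ConfigurationError | None = None
    for redraw in range(_TARGET_REDRAW_CAP):
        targets = [
            int(t) for t in rng_targets.choice(len(offspring), size=n_invaded, replace=False)
        ]
        try:
            return _invade(offspring, pool, cmap, targets, rng_targets, rng_invader, audit)
        except _RetryTargets as exc:
            # the drawn target set cannot satisfy the coverage constraint
            # (every legal host landed outside it); draw a fresh set
            last_error = exc
            if audit is not None:
                audit.append(
                    offspring[0].round_index, "invasion_target_redraw", reason=str(exc)
                )
    raise ConfigurationError(
        f"no satisfiable invasion target set after {_TARGET_REDRAW_CAP} redraws: {last_error}"
    )


def _invade(
    offspring: list[Community],
    pool: SpeciesPool,
    cmap: CompatibilityMap,
    targets: list[int],
    rng_targets: np.random.Generator,
    rng_invader: np.random.Generator,
    audit: AuditLog | None,
) -> tuple[list[Community], list[dict]]:
    mutated = list(offspring)
    invasion_log: list[dict] = []
    # (community index) -> (removed, invader) so repairs can re-draw
    planned: dict[int, tuple[str, str]] = {}

    def represented() -> set[str]:
        out: set[str] = set()
        for c in mutated:
            out |= c.members
        return out

    def do_invasion(t: int, removed: str, invader: str, reason: str) -> None:
        parent_members = offspring[t].members
        mutated[t] = offspring[t].with_members((parent_members - {removed}) | {invader})
        planned[t] = (removed, invader)
        rec = {
            "community_id": offspring[t].community_id,
            "removed": removed,
            "invader": invader,
            "reason": reason,
        }
        invasion_log.append(rec)
        if audit is not None:
            audit.append(offspring[t].round_index, "invasion", **rec)

    # -- branch 1: coverage-mandated invaders --------------------------------
    unused = list(targets)
    missing = [s for s in pool.species if s not in represented()]
    for sp in missing:
        hosts = [
            t for t in unused
            if sp not in offspring[t].members and _legal_removals(offspring[t].members, sp, cmap)
        ]
        if not hosts:
            anywhere = [
                t for t in range(len(offspring))
                if sp not in offspring[t].members
                and _legal_removals(offspring[t].members, sp, cmap)
            ]
            if anywhere:
                raise _RetryTargets(
                    f"no designated offspring can legally host uncovered species {sp!r}"
                )
            # No offspring at all admits a legal single substitution (every
            # community carries two or more of the species' forbidden
            # partners).  Rebuild one designated community as the legal
            # composition containing the species that is closest to its
            # parent; logged, since it exceeds one substitution.
            if not unused:
                raise _RetryTargets(f"no unused invasion slot left for species {sp!r}")
            t = unused[int(rng_targets.integers(len(unused)))]
            parent_members = offspring[t].members
            k = len(parent_members)
            candidates = [c for c in enumerate_allowed(pool, cmap, k) if sp in c]
            if not candidates:
                raise ConfigurationError(f"species {sp!r} occurs in no legal community")
            dmin = min(len(parent_members - c) for c in candidates)
            closest = [c for c in candidates if len(parent_members - c) == dmin]
            pick = closest[int(rng_invader.integers(len(closest)))]
            mutated[t] = offspring[t].with_members(pick)
            planned[t] = ("*", sp)
            rec = {
                "community_id": offspring[t].community_id,
                "removed": sorted(parent_members - pick),
                "invader": sorted(pick - parent_members),
                "reason": "coverage-override",
            }
            invasion_log.append(rec)
            if audit is not None:
                audit.append(offspring[t].round_index, "invasion", **rec)
            unused.remove(t)
            continue
        t = hosts[int(rng_targets.integers(len(hosts)))]
        removals = _legal_removals(offspring[t].members, sp, cmap)
        removed = removals[int(rng_invader.integers(len(removals)))]
        do_invasion(t, removed, sp, "coverage")
        unused.remove(t)

    # -- branch 2: random invaders -------------------------------------------
    for t in unused:
        members = offspring[t].members
        for attempt in range(_INVASION_RETRY_CAP):
            removed = sorted(members)[int(rng_invader.integers(len(members)))]
            candidates = [
                s for s in pool.species
                if s not in members and cmap.is_allowed((members - {removed}) | {s})
            ]
            if candidates:
                invader = candidates[int(rng_invader.integers(len(candidates)))]
                do_invasion(t, removed, invader, "random")
                break
        else:
            raise ConfigurationError(
                f"no legal invasion found for {offspring[t].community_id} "
                f"after {_INVASION_RETRY_CAP} attempts"
            )

    # -- coverage repair: a removal may have orphaned a species ---------------
    for attempt in range(_INVASION_RETRY_CAP):
        orphans = [s for s in pool.species if s not in represented()]
        if not orphans:
            break
        sp = orphans[0]
        hosts = [
            t for t in targets
            if sp not in mutated[t].members
            and sp not in offspring[t].members
            and _legal_removals(offspring[t].members, sp, cmap)
        ]
        if not hosts:
            raise _RetryTargets(f"coverage repair impossible for species {sp!r}")
        t = hosts[int(rng_targets.integers(len(hosts)))]
        removals = _legal_removals(offspring[t].members, sp, cmap)
        removed = removals[int(rng_invader.integers(len(removals)))]
        do_invasion(t, removed, sp, "coverage-repair")
    else:
        raise _RetryTargets("coverage repair did not converge")

    return mutated, invasion_log


# ---------------------------------------------------------------------------
# Step 4: stock ledger
# ---------------------------------------------------------------------------

def update_stock_ledger(ledger: StockLedger, round_result: RoundResult) -> StockLedger:
    """Refresh working stocks from the round's plated communities.

    Each species detected in at least one plated community is re-stocked from
    the highest-penalized-score such community (ties by ascending community
    id); species detected nowhere keep their previous source — the stock from
    the closest previous round.
    """
    new = dict(ledger.source)
    for sp in new:
        best: tuple[float, str] | None = None
        for cid in round_result.plated_ids:
            rec = round_result.survival[cid]
            if sp in rec.detected:
                score = round_result.scores[cid].penalized_score
                if best is None or score > best[0] or (score == best[0] and cid < best[1]):
                    best = (score, cid)
        if best is not None:
            new[sp] = (best[1], round_result.round_index)
    return StockLedger(source=new)


# ---------------------------------------------------------------------------
# Steps 1-5 wired together
# ---------------------------------------------------------------------------

def measure_round(
    communities: list[Community],
    config: SelectionConfig,
    model: LandscapeModel,
    rng_landscape: np.random.Generator,
    rng_plated: np.random.Generator,
    *,
    treatment: str | None = None,
) -> RoundResult:
    """Grow, assay and plate one generation (Steps 1-3)."""
    treatment = treatment or config.treatment
    measurements: dict[str, AssayMeasurement] = {}
    degradation: dict[str, float] = {}
    all_counts: dict[str, dict[str, float]] = {}
    for c in communities:
        m, counts = simulate_outcomes(c, model, rng_landscape)
        measurements[c.community_id] = m
        degradation[c.community_id] = degradation_percent(m)
        all_counts[c.community_id] = counts

    if config.penalty_at_selection and treatment != "random":
        penalized = {}
        for c in communities:
            rec = detect_survival(c.members, all_counts[c.community_id], config.detection_limit)
            penalized[c.community_id] = degradation[c.community_id] * rec.f
        plated = select_top_k(penalized, config.top_k, treatment=treatment, rng=rng_plated)
    else:
        plated = select_top_k(degradation, config.top_k, treatment=treatment, rng=rng_plated)

    survival = {
        cid: detect_survival(
            next(c for c in communities if c.community_id == cid).members,
            all_counts[cid],
            config.detection_limit,
        )
        for cid in plated
    }
    scores = {cid: community_score(degradation[cid], survival[cid]) for cid in plated}
    return RoundResult(
        round_index=communities[0].round_index,
        treatment=treatment,
        communities=list(communities),
        measurements=measurements,
        degradation=degradation,
        plated_ids=list(plated),
        survival=survival,
        scores=scores,
    )


def next_round_plan(
    round_result: RoundResult,
    config: SelectionConfig,
    pool: SpeciesPool,
    cmap: CompatibilityMap,
    rng_offspring: np.random.Generator,
    rng_targets: np.random.Generator,
    rng_invader: np.random.Generator,
    audit: AuditLog | None = None,
) -> list[Community]:
    """Generate the next generation's compositions (Step 5) from a measured round."""
    treatment = round_result.treatment
    parents = [round_result.community(cid) for cid in round_result.plated_ids]

    if treatment in ("propagule", "migrant_pool"):
        return comparator_step(round_result, treatment, config)

    if treatment == "random":
        p = parent_distribution([0.0] * len(parents), mode="uniform")
    else:
        penalized = [round_result.scores[cid].penalized_score for cid in round_result.plated_ids]
        try:
            p = parent_distribution(penalized, mode="proportional", floor=config.probability_floor)
        except DegenerateDistributionError:
            warnings.warn(
                f"round {round_result.round_index}: all penalized scores <= 0; "
                "falling back to uniform parent sampling",
                stacklevel=2,
            )
            logger.warning(
                "round %d: degenerate score distribution, uniform fallback",
                round_result.round_index,
            )
            p = parent_distribution([0.0] * len(parents), mode="uniform")
    if audit is not None:
        audit.append(
            round_result.round_index,
            "parent_distribution",
            treatment=treatment,
            plated_ids=round_result.plated_ids,
            probabilities=[float(x) for x in p],
        )

    offspring = sample_offspring(
        parents, p, config.n_communities, rng_offspring,
        round_index=round_result.round_index + 1, treatment=treatment,
    )
    if audit is not None:
        audit.append(
            round_result.round_index,
            "offspring",
            treatment=treatment,
            parents=[c.parent_id for c in offspring],
        )
    mutated, _ = apply_invasions(
        offspring, pool, cmap, config.n_invaded, rng_targets, rng_invader, audit
    )
    return mutated


def comparator_step(
    round_result: RoundResult,
    strategy: str,
    config: SelectionConfig,
) -> list[Community]:
    """Alternative offspring rules used as baselines in the field.

    ``propagule`` propagates each selected parent's composition unchanged (a
    dilution transfer: no invasion, no size change), cycling through the
    selected parents to fill the rack.  ``migrant_pool`` pools the selected
    parents and redistributes, so every offspring carries the union of the
    parents' members (the size constraint is relaxed).
    """
    parents = [round_result.community(cid) for cid in round_result.plated_ids]
    t = round_result.round_index + 1
    if strategy == "propagule":
        return [
            Community(
                members=parents[i % len(parents)].members,
                community_id=f"r{t}-p{i:02d}",
                round_index=t,
                treatment="propagule",
                parent_id=parents[i % len(parents)].community_id,
            )
            for i in range(config.n_communities)
        ]
    if strategy == "migrant_pool":
        union = frozenset().union(*(p.members for p in parents))
        return [
            Community(
                members=union,
                community_id=f"r{t}-m{i:02d}",
                round_index=t,
                treatment="migrant_pool",
                parent_id=None,
            )
            for i in range(config.n_communities)
        ]
    raise InputError(f"unknown comparator strategy {strategy!r}")


def run_round(
    communities: list[Community],
    config: SelectionConfig,
    model: LandscapeModel,
    pool: SpeciesPool,
    cmap: CompatibilityMap,
    ledger: StockLedger,
    *,
    treatment: str | None = None,
    audit: AuditLog | None = None,
) -> tuple[RoundResult, list[Community], StockLedger]:
    """Execute one full round: measure, select, disassemble, ledger, generate.

    All randomness is drawn from per-stage substreams derived from the config's
    master seed, the round index and the treatment, so identical inputs give
    identical plans.
    """
    treatment = treatment or config.treatment
    t = communities[0].round_index
    rngs = {
        stage: np.random.default_rng(
            derive_seed(config.master_seed, t, f"{treatment}/{stage}")
        )
        for stage in ("landscape", "plated_choice", "offspring", "invasion_targets", "invader_identity")
    }
    result = measure_round(
        communities, config, model, rngs["landscape"], rngs["plated_choice"], treatment=treatment
    )
    if audit is not None:
        audit.append(t, "plated", treatment=treatment, plated_ids=result.plated_ids)
    new_ledger = update_stock_ledger(ledger, result)
    plan = next_round_plan(
        result, config, pool, cmap,
        rngs["offspring"], rngs["invasion_targets"], rngs["invader_identity"], audit,
    )
    return result, plan, new_ledger


def run_experiment(
    config: SelectionConfig,
    model: LandscapeModel,
    pool: SpeciesPool | None = None,
    cmap: CompatibilityMap | None = None,
    treatments: Sequence[str] = ("selection", "random"),
    audit: AuditLog | None = None,
) -> dict[str, list[RoundResult]]:
    """Run the full multi-round experiment for each treatment.

    All treatments start from the same randomly generated round-0 communities
    (re-labelled per treatment), then evolve independently.  With ``n_rounds``
    transitions, each treatment yields ``n_rounds + 1`` measured rounds.
    """
    if pool is None:
        pool = model.pool()
    if cmap is None:
        cmap = CompatibilityMap()
    rng0 = np.random.default_rng(derive_seed(config.master_seed, 0, "initial"))
    base = generate_initial_round(
        pool, cmap, config.n_communities, config.community_size, rng0
    )
    results: dict[str, list[RoundResult]] = {}
    for treatment in treatments:
        plan = [
            replace(
                c,
                treatment=treatment,
                community_id=f"r0-{treatment[0]}{i:02d}",
            )
            for i, c in enumerate(base)
        ]
        ledger = StockLedger.initial(pool)
        rounds: list[RoundResult] = []
        for _ in range(config.n_rounds):
            result, plan, ledger = run_round(
                plan, config, model, pool, cmap, ledger, treatment=treatment, audit=audit
            )
            rounds.append(result)
        # final generation is measured but not propagated
        t = plan[0].round_index
        rng_land = np.random.default_rng(
            derive_seed(config.master_seed, t, f"{treatment}/landscape")
        )
        rng_plated = np.random.default_rng(
            derive_seed(config.master_seed, t, f"{treatment}/plated_choice")
        )
        rounds.append(
            measure_round(plan, config, model, rng_land, rng_plated, treatment=treatment)
        )
        results[treatment] = rounds
    return results
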