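"""Descriptive and model-based analyses of selection runs.

Covers the standard readouts of a community-selection experiment: Hill-number
evenness of plated communities, species representation against a null
expectation, trajectories of the x best scores per round, composition distance
to the best community, a presence/absence linear model of the function
landscape, and mono- vs co-culture interaction inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import Community, InputError, SpeciesPool, composition_distance
from .engine import RoundResult

__all__ = [
    "EvennessResult",
    "InteractionEstimate",
    "PresenceModel",
    "evenness",
    "expected_representation",
    "representation_table",
    "top_x_trajectory",
    "distance_to_best",
    "fit_presence_model",
    "interaction_matrix",
]


@dataclass(frozen=True)
class EvennessResult:
    """Hill number of order 1 and its normalization to (0, 1]."""

    effective_number: float
    evenness: float


def evenness(counts: Mapping[str, float] | Sequence[float]) -> EvennessResult:
    """Effective species number (Hill number of order 1) and normalized evenness.

    ``1D = exp(-sum p_k ln p_k)`` over *detected* species (zero counts are
    excluded; 0·ln 0 is treated as 0), and evenness = 1D / S where S is the
    number of detected species, so a perfectly even community scores 1.  A
    single-species community has evenness 1 by convention.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    if np.any(values < 0):
        raise InputError("abundances must be non-negative")
    values = values[values > 0]
    if values.size == 0:
        raise InputError("evenness undefined for all-zero counts")
    p = values / values.sum()
    d1 = float(np.exp(-np.sum(p * np.log(p))))
    s = values.size
    return EvennessResult(effective_number=d1, evenness=1.0 if s == 1 else d1 / s)


def expected_representation(
    n_rounds_window: int,
    communities_per_round: int,
    community_size: int,
    pool_size: int,
) -> float:
    """Per-species appearance count expected by chance in a window of rounds.

    Total species-slots in the window divided evenly over the pool:
    ``window * communities * size / pool``; with the default design's last five
    rounds of ten plated four-species communities over 11 species this is the
    familiar 18.18.
    """
    if pool_size <= 0:
        raise InputError("pool_size must be positive")
    if min(n_rounds_window, communities_per_round, community_size) <= 0:
        raise InputError("window, community count and size must be positive")
    return n_rounds_window * communities_per_round * community_size / pool_size


def representation_table(
    run: Sequence[RoundResult],
    pool: SpeciesPool,
    window: int = 5,
    sd_mode: str = "empirical",
) -> pd.DataFrame:
    """Observed vs expected per-species appearances among plated communities.

    Counts each species' appearances in the plated communities of the last
    ``window`` rounds and flags it ``over`` / ``under`` / ``within`` one
    standard deviation of the chance expectation.  The band uses the empirical
    SD of the observed per-species counts by default (``sd_mode='empirical'``);
    ``'binomial'`` uses the SD of the per-slot occupancy null instead.
    """
    if window <= 0 or window > len(run):
        raise InputError(f"window must be in 1..{len(run)}")
    tail = run[-window:]
    observed = {s: 0 for s in pool.species}
    n_plated = 0
    size = None
    for rr in tail:
        for cid in rr.plated_ids:
            members = rr.community(cid).members
            size = len(members) if size is None else size
            n_plated += 1
            for s in members:
                observed[s] += 1
    expected = expected_representation(
        len(tail), n_plated // len(tail), size or 0, len(pool)
    )
    counts = np.array([observed[s] for s in pool.species], dtype=float)
    if sd_mode == "empirical":
        sd = float(np.std(counts, ddof=1))
    elif sd_mode == "binomial":
        q = (size or 0) / len(pool)
        sd = float(np.sqrt(n_plated * q * (1 - q)))
    else:
        raise InputError(f"unknown sd_mode {sd_mode!r}")
    flags = [
        "over" if c > expected + sd else "under" if c < expected - sd else "within"
        for c in counts
    ]
    return pd.DataFrame(
        {
            "species": list(pool.species),
            "observed": counts.astype(int),
            "expected": expected,
            "sd": sd,
            "flag": flags,
        }
    )


def top_x_trajectory(run: Sequence[RoundResult], x: int) -> pd.DataFrame:
    """Per-round mean of the x best degradation percents."""
    rows = []
    for rr in run:
        scores = sorted(rr.degradation.values(), reverse=True)
        if x > len(scores):
            raise InputError(f"x={x} exceeds the {len(scores)} communities in round {rr.round_index}")
        rows.append({"round": rr.round_index, "mean_top_x": float(np.mean(scores[:x]))})
    return pd.DataFrame(rows)


def distance_to_best(
    run: Sequence[RoundResult] | Iterable[tuple[frozenset[str], float]],
    pool: SpeciesPool,
) -> pd.DataFrame:
    """Substitution distance from every tested composition to the best one.

    The best composition is the one with the highest degradation averaged over
    all instances of the same species set (ties broken lexicographically in
    pool order).  Returns one row per distinct composition with its mean
    degradation and its distance to the best.
    """
    records: list[tuple[frozenset[str], float]] = []
    run = list(run)
    if run and isinstance(run[0], RoundResult):
        for rr in run:
            for c in rr.communities:
                records.append((c.members, rr.degradation[c.community_id]))
    else:
        records = [(frozenset(m), float(s)) for m, s in run]
    if not records:
        raise InputError("no scored communities")
    by_comp: dict[frozenset[str], list[float]] = {}
    for members, score in records:
        by_comp.setdefault(members, []).append(score)
    means = {m: float(np.mean(v)) for m, v in by_comp.items()}
    best = min(means, key=lambda m: (-means[m], pool.sorted_members(m)))
    rows = []
    for members in sorted(means, key=lambda m: (-means[m], pool.sorted_members(m))):
        frac, subs = composition_distance(members, best, pool)
        rows.append(
            {
                "composition": "+".join(pool.sorted_members(members)),
                "mean_degradation": means[members],
                "mismatch_fraction": frac,
                "substitutions": subs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presence/absence landscape regression
# ---------------------------------------------------------------------------

@dataclass
class PresenceModel:
    """OLS fit of degradation percent on species presence/absence."""

    species: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r_train: float
    r2_train: float
    r_test: float
    r2_test: float
    rank_deficient: bool

    def predict(self, members: Iterable[str]) -> float:
        return self.intercept + sum(self.coefficients[s] for s in members)


def _design(records: Sequence[tuple[frozenset[str], float]], pool: SpeciesPool, intercept: bool):
    X = np.array([[1.0] * intercept + [1.0 if s in m else 0.0 for s in pool.species] for m, _ in records])
    y = np.array([v for _, v in records], dtype=float)
    return X, y


def _pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if pred.size < 2 or np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(stats.pearsonr(pred, obs).statistic)


def fit_presence_model(
    records: Sequence[tuple[frozenset[str] | set[str], float]],
    pool: SpeciesPool,
    regime: str = "all",
    intercept: bool = True,
) -> PresenceModel:
    """Fit degradation ~ presence/absence by OLS under a train/test regime.

    Regimes: ``all`` trains and evaluates on everything in-sample;
    ``mono_pair_train`` trains on records of richness <= 2 and tests on the
    larger communities; ``community_train`` does the reverse.  Goodness of fit
    is the Pearson correlation between predicted and observed degradation on
    the regime's test set — both r and r² are reported, r² is the headline.
    A rank-deficient design is fitted by pseudo-inverse and flagged.
    """
    records = [(frozenset(m), float(v)) for m, v in records]
    if regime == "all":
        train = test = records
    elif regime == "mono_pair_train":
        train = [r for r in records if len(r[0]) <= 2]
        test = [r for r in records if len(r[0]) > 2]
    elif regime == "community_train":
        train = [r for r in records if len(r[0]) > 2]
        test = [r for r in records if len(r[0]) <= 2]
    else:
        raise InputError(f"unknown regime {regime!r}")
    if not train or not test:
        raise InputError(f"regime {regime!r}: empty train or test set")

    X, y = _design(train, pool, intercept)
    rank = np.linalg.matrix_rank(X)
    deficient = rank < X.shape[1]
    if deficient:
        import warnings

        warnings.warn(
            f"presence design is rank-deficient (rank {rank} < {X.shape[1]}); "
            "coefficients from pseudo-inverse are not unique",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    icpt = float(beta[0]) if intercept else 0.0
    coefs = dict(zip(pool.species, beta[1:] if intercept else beta))

    def predict_set(recs):
        Xe, ye = _design(recs, pool, intercept)
        return Xe @ beta, ye

    pred_tr, obs_tr = predict_set(train)
    pred_te, obs_te = predict_set(test)
    r_tr = _pearson(pred_tr, obs_tr)
    r_te = _pearson(pred_te, obs_te)
    return PresenceModel(
        species=pool.species,
        intercept=icpt,
        coefficients={k: float(v) for k, v in coefs.items()},
        r_train=r_tr,
        r2_train=r_tr**2,
        r_test=r_te,
        r2_test=r_te**2,
        rank_deficient=bool(deficient),
    )


# ---------------------------------------------------------------------------
# Interaction inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionEstimate:
    """Growth effect of a partner on a focal species, from plate counts."""

    focal: str
    partner: str
    log2_fc: float
    p_value: float
    p_adj: float
    significant: bool
    flagged: bool  # a zero count was substituted by the detection limit


def interaction_matrix(
    mono: Mapping[str, Sequence[float]],
    co: Mapping[tuple[str, str], Sequence[float]],
    alpha: float = 0.05,
    detection_limit: float = 1.0,
) -> list[InteractionEstimate]:
    """Infer pairwise growth interactions from mono- vs co-culture CFU counts.

    For each ordered (focal, partner) pair the interaction is the log2
    fold-change of the focal species' mean CFU/ml in co-culture vs
    monoculture.  Significance comes from a two-sample Welch t-test on
    log-counts, Benjamini-Hochberg adjusted across all tested pairs; zero
    counts are guarded by substituting ``detection_limit`` and flagging the
    estimate.  The two directions of a pair are estimated independently.
    """
    estimates = []
    pvals = []
    for (focal, partner), co_counts in sorted(co.items()):
        if focal not in mono:
            raise InputError(f"no monoculture counts for focal species {focal!r}")
        mono_counts = np.asarray(mono[focal], dtype=float)
        co_counts = np.asarray(co_counts, dtype=float)
        if np.any(mono_counts < 0) or np.any(co_counts < 0):
            raise InputError("CFU counts must be non-negative")
        flagged = bool(np.any(mono_counts == 0) or np.any(co_counts == 0))
        mono_counts = np.maximum(mono_counts, detection_limit)
        co_counts = np.maximum(co_counts, detection_limit)
        log_mono = np.log2(mono_counts)
        log_co = np.log2(co_counts)
        lfc = float(log_co.mean() - log_mono.mean())
        if len(log_mono) >= 2 and len(log_co) >= 2:
            p = float(stats.ttest_ind(log_co, log_mono, equal_var=False).pvalue)
            if np.isnan(p):  # zero variance in both groups
                p = 1.0 if lfc == 0 else 0.0
        else:
            p = float("nan")
        estimates.append((focal, partner, lfc, p, flagged))
        pvals.append(p)

    valid = [i for i, p in enumerate(pvals) if not np.isnan(p)]
    adj = {i: float("nan") for i in range(len(pvals))}
    if valid:
        _, p_adj, *_ = multipletests([pvals[i] for i in valid], method="fdr_bh")
        adj.update(dict(zip(valid, p_adj)))
    return [
        InteractionEstimate(
            focal=f,
            partner=pt,
            log2_fc=lfc,
            p_value=p,
            p_adj=adj[i],
            significant=bool(not np.isnan(adj[i]) and adj[i] < alpha),
            flagged=fl,
        )
        for i, (f, pt, lfc, p, fl) in enumerate(estimates)
    ]
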