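"""Coalition-based and permutation-sampled multiperturbation Shapley analysis.

Players are white-matter bundles (plus the rest-of-brain compound);
a perturbation configuration is a binary state vector (0 = perturbed,
i.e., fully damaged; 1 = intact), and the coalition is the set of
intact players.  The characteristic function v maps a configuration to
task performance — here, the prediction of a classifier trained on
observed lesion-behavior pairs.

A player's contribution is its Shapley value

    phi_i = sum_{S not containing i} |S|! (M-|S|-1)! / M! * [v(S u {i}) - v(S)],

the average over all player orderings of the player's marginal effect
when it joins the coalition of its predecessors.  With M small the sum
is enumerated exactly (coalition-based analysis); otherwise orderings
are sampled uniformly, giving an unbiased estimator whose per-player
standard error shrinks with the number of sampled permutations.
Robustness to the particular patient sample is assessed by
bootstrapping patients, retraining the predictor, and re-estimating
contributions on each resample.

Interaction terms between players are deliberately not computed.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .disconnection import ROB
from .predictor import GradedDataset, Predictor, PredictorSpec, train

__all__ = [
    "CharacteristicFunction",
    "ContributionResult",
    "exact_shapley",
    "shapley_from_orderings",
    "estimated_shapley",
    "bootstrap_contributions",
    "normalize_contributions",
    "flag_significance",
    "classify_contributors",
]

logger = logging.getLogger(__name__)

#: above this player count full enumeration (2^M configurations) is refused
EXACT_LIMIT = 20
#: up to this player count the characteristic function is pre-tabulated
TABULATE_LIMIT = 16


class CharacteristicFunction:
    """v: configuration -> performance, with caching over bitmasks.

    ``evaluator`` takes an (n, M) array of binary configurations and
    returns n performance values; results are cached under integer
    bitmasks (bit i set = player i intact), so repeated coalitions —
    ubiquitous in permutation sampling — cost one lookup.
    """

    def __init__(self, evaluator, n_players: int, player_names=None):
        self.evaluator = evaluator
        self.M = int(n_players)
        self.player_names = (
            tuple(player_names)
            if player_names is not None
            else tuple(f"player_{i + 1}" for i in range(self.M))
        )
        if len(self.player_names) != self.M:
            raise ValueError("player_names length must equal n_players")
        self._cache: dict[int, float] = {}
        self._table: np.ndarray | None = None

    @classmethod
    def from_predictor(cls, predictor: Predictor) -> "CharacteristicFunction":
        return cls(
            evaluator=lambda configs: predictor.predict(configs).astype(float),
            n_players=predictor.n_players,
            player_names=predictor.player_names,
        )

    def _mask_to_config(self, masks: np.ndarray) -> np.ndarray:
        return (masks[:, None] >> np.arange(self.M)[None, :]) & 1

    def values_for_masks(self, masks) -> np.ndarray:
        """Values for integer coalition bitmasks, evaluating misses in batch."""
        masks = np.asarray(masks, dtype=np.int64)
        if self._table is not None:
            return self._table[masks]
        missing = [m for m in np.unique(masks) if int(m) not in self._cache]
        if missing:
            configs = self._mask_to_config(np.asarray(missing)).astype(float)
            vals = np.asarray(self.evaluator(configs), dtype=float)
            for m, v in zip(missing, vals):
                self._cache[int(m)] = float(v)
        return np.array([self._cache[int(m)] for m in masks])

    def __call__(self, states) -> float:
        states = np.asarray(states).ravel()
        if states.shape != (self.M,):
            raise ValueError(f"configuration length must be {self.M}")
        if not set(np.unique(states)) <= {0, 1}:
            raise ValueError("configuration must be binary")
        mask = int(np.dot(states.astype(np.int64), 1 << np.arange(self.M)))
        return float(self.values_for_masks([mask])[0])

    def tabulate(self) -> np.ndarray:
        """Evaluate and cache all 2^M configurations (small M only)."""
        if self._table is None:
            if self.M > TABULATE_LIMIT:
                raise ValueError(f"refusing to tabulate 2^{self.M} configurations")
            masks = np.arange(2**self.M, dtype=np.int64)
            configs = self._mask_to_config(masks).astype(float)
            self._table = np.asarray(self.evaluator(configs), dtype=float)
        return self._table


def exact_shapley(v: CharacteristicFunction) -> np.ndarray:
    """Coalition-based Shapley values by full enumeration.

    Exact for M <= 20; satisfies efficiency identically:
    ``phi.sum() == v(all intact) - v(none intact)``.
    """
    M = v.M
    if M > EXACT_LIMIT:
        raise ValueError(
            f"M={M} too large for enumeration; use estimated_shapley instead"
        )
    table = v.tabulate() if M <= TABULATE_LIMIT else None
    if table is None:  # 16 < M <= 20: stream without storing the config matrix
        table = v.values_for_masks(np.arange(2**M, dtype=np.int64))
    masks = np.arange(2**M, dtype=np.int64)
    sizes = np.zeros(2**M, dtype=np.int64)
    for i in range(M):
        sizes += (masks >> i) & 1
    fact = np.array([math.factorial(k) for k in range(M + 1)], dtype=float)
    coef = fact[np.arange(M)] * fact[M - np.arange(M) - 1] / fact[M]  # by |S|
    phi = np.empty(M)
    for i in range(M):
        without = masks[((masks >> i) & 1) == 0]
        gains = table[without | (1 << i)] - table[without]
        phi[i] = float(np.dot(coef[sizes[without]], gains))
    return phi


def shapley_from_orderings(v: CharacteristicFunction, orderings) -> np.ndarray:
    """Marginal-contribution matrix for explicit player orderings.

    Row p, column i holds v(predecessors of i in ordering p, plus i)
    minus v(predecessors), with all players not yet entered perturbed.
    Averaging rows over *all* M! orderings reproduces the exact Shapley
    values; each row sums to v(grand) - v(empty) by telescoping.
    """
    orderings = np.asarray(orderings, dtype=int)
    if orderings.ndim != 2 or orderings.shape[1] != v.M:
        raise ValueError(f"orderings must be (n, {v.M})")
    n = orderings.shape[0]
    bits = 1 << orderings.astype(np.int64)  # (n, M) bit of each entering player
    prefix = np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(bits, axis=1)], axis=1
    )  # (n, M+1) coalition bitmask after each entry
    vals = v.values_for_masks(prefix.ravel()).reshape(n, v.M + 1)
    gains = np.diff(vals, axis=1)  # marginal of the player entering at each step
    marg = np.empty((n, v.M))
    rows = np.arange(n)[:, None]
    marg[rows, orderings] = gains
    return marg


def estimated_shapley(
    v: CharacteristicFunction, n_perms: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampled Shapley estimate with standard errors.

    Samples ``n_perms`` player orderings uniformly and averages each
    player's marginal contributions; the estimator is unbiased and the
    returned SE is the across-permutation standard error.  Efficiency
    holds exactly for every sample.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    rng = np.random.default_rng(seed)
    orderings = np.array([rng.permutation(v.M) for _ in range(n_perms)])
    marg = shapley_from_orderings(v, orderings)
    values = marg.mean(axis=0)
    if n_perms > 1:
        se = marg.std(axis=0, ddof=1) / math.sqrt(n_perms)
    else:
        se = np.full(v.M, np.nan)
    return values, se


@dataclass(frozen=True)
class ContributionResult:
    """Bootstrap-stabilised contribution estimates for one test.

    ``mean`` averages the per-resample Shapley estimates; ``boot_sd``
    is their dispersion across resamples (the error bars of the usual
    contribution bar plots) and ``mean_se`` the averaged
    within-resample estimator SE — both dispersion readings are kept.
    """

    test: str
    player_names: tuple[str, ...]
    mean: np.ndarray
    boot_sd: np.ndarray
    mean_se: np.ndarray
    replicates: np.ndarray  # (n_boot, M) per-resample estimates
    n_perms: int
    normalized: np.ndarray = None
    significant: np.ndarray | None = None
    level: float | None = None
    interval_reliable: bool = True

    @property
    def n_boot(self) -> int:
        return self.replicates.shape[0]

    @property
    def sign(self) -> np.ndarray:
        return np.where(self.mean >= 0, "positive", "negative")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "player": list(self.player_names),
                "test": self.test,
                "mean": self.mean,
                "boot_sd": self.boot_sd,
                "mean_se": self.mean_se,
                "normalized": self.normalized,
                "sign": self.sign,
            }
        )
        if self.significant is not None:
            frame["significant"] = self.significant
        return frame


def normalize_contributions(raw: np.ndarray, mode: str = "sum_abs") -> np.ndarray:
    """Scale contributions to a comparable magnitude across tests.

    ``sum_abs`` (default) divides by the L1 norm, preserving signs so
    absolute normalized values sum to 1; ``efficiency`` divides by the
    raw sum, i.e., by the estimate of v(grand) - v(empty).
    """
    raw = np.asarray(raw, dtype=float)
    if mode == "sum_abs":
        denom = np.abs(raw).sum()
    elif mode == "efficiency":
        denom = raw.sum()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom == 0:
        raise ValueError("cannot normalize all-zero contributions")
    return raw / denom


def bootstrap_contributions(
    dataset: GradedDataset,
    spec: PredictorSpec = PredictorSpec(),
    n_boot: int = 1000,
    n_perms: int = 1000,
    seed: int = 0,
    normalization: str = "sum_abs",
    max_redraws: int = 100,
) -> ContributionResult:
    """Bootstrap the estimated Shapley analysis over patient resamples.

    Each of ``n_boot`` resamples draws patients with replacement at the
    original size, retrains the predictor, and runs the permutation
    estimator with ``n_perms`` sampled orderings.  Resamples whose
    labels collapse to a single class cannot train a classifier and are
    redrawn (logged, capped at ``max_redraws`` consecutive failures).
    """
    if n_boot < 1 or n_perms < 1:
        raise ValueError("n_boot and n_perms must be >= 1")
    rng = np.random.default_rng(seed)
    M = dataset.n_players
    reps = np.empty((n_boot, M))
    ses = np.empty((n_boot, M))
    redraws = 0
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, dataset.n, size=dataset.n)
            if len(np.unique(dataset.y[idx])) == 2:
                break
            redraws += 1
        else:
            raise RuntimeError(
                f"{dataset.test}: no two-class bootstrap resample in "
                f"{max_redraws} redraws"
            )
        predictor = train(dataset.subset(idx), spec)
        v = CharacteristicFunction.from_predictor(predictor)
        if M <= TABULATE_LIMIT:
            v.tabulate()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        reps[b], ses[b] = estimated_shapley(v, n_perms=n_perms, seed=sub_seed)
    if redraws:
        logger.info("%s: redrew %d single-class bootstrap resample(s)",
                    dataset.test, redraws)
    mean = reps.mean(axis=0)
    boot_sd = reps.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(M)
    return ContributionResult(
        test=dataset.test,
        player_names=dataset.player_names,
        mean=mean,
        boot_sd=boot_sd,
        mean_se=ses.mean(axis=0),
        replicates=reps,
        n_perms=n_perms,
        normalized=normalize_contributions(mean, normalization),
    )


def flag_significance(result: ContributionResult, level: float = 0.05) -> ContributionResult:
    """Flag players whose bootstrap percentile interval excludes zero.

    Uses the central (1 - level) interval of the per-resample estimates
    (percentiles 100*level/2 and 100*(1 - level/2)).  With fewer than
    20 resamples the interval is too coarse to trust and the result is
    marked unreliable.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    reliable = result.n_boot >= 20
    if not reliable:
        warnings.warn(
            f"{result.test}: only {result.n_boot} bootstrap resamples; "
            "percentile interval unreliable",
            stacklevel=2,
        )
    lo = np.percentile(result.replicates, 100 * level / 2, axis=0)
    hi = np.percentile(result.replicates, 100 * (1 - level / 2), axis=0)
    significant = (lo > 0) | (hi < 0)
    return replace(
        result, significant=significant, level=level, interval_reliable=reliable
    )


def classify_contributors(
    results: dict[str, ContributionResult], include_rob: bool = False
) -> pd.DataFrame:
    """Cross-test classification into task-invariant and task-dependent.

    A player is task-invariant positive (negative) when it is
    significant with that sign in *every* test; any other pattern is
    task-dependent, with per-test signs reported ("+", "-", or "n.s.").
    The RoB player is diagnostic rather than anatomical and is excluded
    unless requested.
    """
    if len(results) < 2:
        raise ValueError("need results for at least 2 tests")
    player_sets = {r.player_names for r in results.values()}
    if len(player_sets) != 1:
        raise ValueError("results carry mismatched player sets")
    for test, r in results.items():
        if r.significant is None:
            raise ValueError(f"{test}: run flag_significance first")
    players = list(next(iter(player_sets)))
    tests = list(results)
    rows = []
    for i, player in enumerate(players):
        if player == ROB and not include_rob:
            continue
        signs = {}
        for test in tests:
            r = results[test]
            if not r.significant[i]:
                signs[test] = "n.s."
            else:
                signs[test] = "+" if r.mean[i] > 0 else "-"
        values = set(signs.values())
        if values == {"+"}:
            cls = "task-invariant positive"
        elif values == {"-"}:
            cls = "task-invariant negative"
        else:
            cls = "task-dependent"
        rows.append({"player": player, **signs, "classification": cls})
    return pd.DataFrame(rows).set_index("player")
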