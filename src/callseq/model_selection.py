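"""Markov-order comparison by leave-one-out cross-validation.

Each candidate order (0 = the memoryless chance model, then 1, 2, 3) is
scored by holding out one sequence at a time, fitting the chain on the
rest, and evaluating the held-out sequence's log-likelihood with add-k
smoothing over a grid of smoothing constants.  Adjacent orders are then
compared through per-sequence log-likelihood differences: the mean
difference with a +-2 standard-error band, per smoothing constant.  An
order is preferred when its band against the next-simpler model sits
strictly above zero for most smoothing constants while the next-richer
model's band does not.

The token alphabet is fixed from the full corpus before folding, so a
held-out sequence can contain unseen *transitions* (handled by smoothing)
but never unseen *symbols*.  Leave-one-out fits are computed by
subtracting the held-out sequence's transition counts from the full-corpus
counts, which is exactly equivalent to refitting without it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_io import CallSequence
from .errors import ValidationError
from .markov import MarkovModel, StateSpace, fit_markov, transition_windows

DEFAULT_K_GRID = (0.001, 0.01, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class CVConfig:
    orders: tuple[int, ...] = (0, 1, 2, 3)
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    include_stop: bool = True

    def __post_init__(self) -> None:
        if list(self.orders) != sorted(self.orders):
            raise ValidationError("orders must be sorted ascending")
        if any(m < 0 for m in self.orders):
            raise ValidationError("orders must be >= 0")
        if any(k <= 0 for k in self.k_grid):
            raise ValidationError("smoothing constants must be > 0 for cross-validation")


@dataclass
class CVResult:
    """Held-out log-likelihoods, one per (sequence, order, k) cell."""

    loglik: np.ndarray  # shape (n_sequences, n_orders, n_k)
    orders: tuple[int, ...]
    k_grid: tuple[float, ...]
    include_stop: bool
    n_sequences: int
    metadata: dict = field(default_factory=dict)


@dataclass
class PairwiseComparison:
    """Per-sequence LOO differences between each order and the next-simpler one.

    ``mean``/``se`` have shape (n_pairs, n_k); the band is mean +- 2*se.
    Standard errors are computed across held-out sequences at each k.
    """

    pairs: tuple[tuple[int, int], ...]  # (higher order, lower order)
    k_grid: tuple[float, ...]
    mean: np.ndarray
    se: np.ndarray
    n: int

    @property
    def lower(self) -> np.ndarray:
        return self.mean - 2.0 * self.se

    @property
    def upper(self) -> np.ndarray:
        return self.mean + 2.0 * self.se

    def to_dict(self) -> dict:
        out: dict = {"n_sequences": self.n, "k_grid": list(self.k_grid), "pairs": []}
        for i, (hi, lo) in enumerate(self.pairs):
            out["pairs"].append(
                {
                    "orders": [hi, lo],
                    "mean": [float(x) for x in self.mean[i]],
                    "se": [float(x) for x in self.se[i]],
                    "lower": [float(x) for x in self.lower[i]],
                    "upper": [float(x) for x in self.upper[i]],
                }
            )
        return out


@dataclass(frozen=True)
class SelectionReport:
    selected: int
    warning: bool
    verdicts: dict


def _heldout_loglik(
    model: MarkovModel,
    seq: CallSequence,
    k_grid: np.ndarray,
    D: int,
) -> np.ndarray:
    """Log-likelihood of ``seq`` under the model minus its own counts.

    Vectorized over the smoothing grid: each transition contributes
    ``log((c + k) / (tot + k*D))`` with ``c``/``tot`` taken from the
    training fold obtained by decrementing the held-out contributions.
    """
    windows = transition_windows(seq.tokens, model.order, model.space)
    own: Counter = Counter(windows)
    own_hist: Counter = Counter(h for h, _ in windows)
    c = np.empty(len(windows))
    tot = np.empty(len(windows))
    for i, (h, d) in enumerate(windows):
        c[i] = model.count(h, d) - own[(h, d)]
        tot[i] = model.total(h) - own_hist[h]
    # shape (n_transitions, n_k)
    num = c[:, None] + k_grid[None, :]
    den = tot[:, None] + k_grid[None, :] * D
    return np.log(num / den).sum(axis=0)


def loo_cv(
    sequences: Sequence[CallSequence],
    cfg: CVConfig | None = None,
    space: StateSpace | None = None,
) -> CVResult:
    """Leave-one-out cross-validation over the configured orders and k grid.

    Deterministic: no randomness is involved, and the result depends only
    on the corpus and the configuration.
    """
    cfg = cfg or CVConfig()
    sequences = list(sequences)
    if len(sequences) < 2:
        raise ValidationError("leave-one-out needs at least 2 sequences")
    if space is None:
        space = StateSpace.from_sequences(sequences, include_stop=cfg.include_stop)
    elif space.include_stop != cfg.include_stop:
        raise ValidationError("state space include_stop disagrees with CV config")
    k_grid = np.asarray(cfg.k_grid, dtype=float)
    D = space.n_destinations
    ll = np.empty((len(sequences), len(cfg.orders), len(k_grid)))
    for oi, m in enumerate(cfg.orders):
        full = fit_markov(sequences, m, space)
        for si, seq in enumerate(sequences):
            ll[si, oi] = _heldout_loglik(full, seq, k_grid, D)
    return CVResult(
        loglik=ll,
        orders=tuple(cfg.orders),
        k_grid=tuple(cfg.k_grid),
        include_stop=cfg.include_stop,
        n_sequences=len(sequences),
        metadata={
            "n_tokens": sum(s.length for s in sequences),
            "se_unit": "held-out sequences",
            "state_space": list(space.tokens),
        },
    )


def pairwise_differences(result: CVResult) -> PairwiseComparison:
    """Mean and standard error of per-sequence LOO differences, per k.

    Pairs each order in the result with its immediate predecessor in the
    order list (e.g. 1 vs 0, 2 vs 1, 3 vs 2).
    """
    if len(result.orders) < 2:
        raise ValidationError("need at least two orders to compare")
    n = result.n_sequences
    pairs = tuple(
        (result.orders[i], result.orders[i - 1]) for i in range(1, len(result.orders))
    )
    mean = np.empty((len(pairs), len(result.k_grid)))
    se = np.empty_like(mean)
    for i in range(len(pairs)):
        diffs = result.loglik[:, i + 1, :] - result.loglik[:, i, :]
        mean[i] = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=1) if n > 1 else np.zeros(len(result.k_grid))
        se[i] = sd / np.sqrt(n)
    return PairwiseComparison(pairs=pairs, k_grid=result.k_grid, mean=mean, se=se, n=n)


def select_order(
    comparison: PairwiseComparison, rule: str = "band-majority"
) -> SelectionReport:
    """Pick the best-supported order from the pairwise bands.

    Default rule: the highest order whose band against the next-lower
    order is strictly positive (lower bound > 0) for a majority of
    smoothing constants, provided the next-higher comparison is not also
    strictly positive for a majority.  If no order qualifies, the lowest
    order is returned with a warning flag.
    """
    if rule != "band-majority":
        raise ValidationError(f"unknown selection rule: {rule!r}")
    n_k = len(comparison.k_grid)
    majority = n_k / 2.0
    # supported[m] : band of (m vs next lower) strictly positive for most k
    supported: dict[int, bool] = {}
    verdicts: dict = {}
    for i, (hi, lo) in enumerate(comparison.pairs):
        positive_k = int((comparison.lower[i] > 0).sum())
        supported[hi] = positive_k > majority
        verdicts[f"{hi}_vs_{lo}"] = {
            "strictly_positive_k": positive_k,
            "n_k": n_k,
            "supported": supported[hi],
        }
    orders = [comparison.pairs[0][1]] + [hi for hi, _ in comparison.pairs]
    for m in reversed(orders):
        if m == orders[0]:
            break  # lowest order only selectable via fallback
        higher = [o for o in orders if o > m]
        next_higher_ok = (not higher) or (not supported.get(min(higher), False))
        if supported.get(m, False) and next_higher_ok:
            return SelectionReport(selected=m, warning=False, verdicts=verdicts)
    return SelectionReport(selected=orders[0], warning=True, verdicts=verdicts)
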