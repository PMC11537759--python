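"""Fixed-order Markov chains over call sequences with Start/Stop states.

A sequence of tokens ``c1..cn`` is modelled as a walk that begins in a
reserved Start state and (optionally) ends in a reserved Stop state.  For
an order-``m`` model each sequence is padded with ``m`` Start symbols so
the first real token is predicted from an all-Start history, and every
sequence contributes ``n + 1`` transitions when Stop is modelled
(``n`` without Stop).  Order 0 is the memoryless relative-frequency
("chance") model: a single empty history whose distribution is the
destination frequency.

Deviation from chance is scored per observed transition: given ``n_h``
departures from a history and ``n_hd`` of them arriving at destination
``d``, the default statistic is the log binomial probability of seeing
``n_hd`` arrivals in ``n_h`` trials at the chance rate of ``d``.  It is
bounded above by 0 and penalizes both over- and under-represented
transitions.  A likelihood-ratio alternative is available behind the
``mode`` switch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation_io import CallSequence
from .errors import ValidationError

START = "Start"
STOP = "Stop"


@dataclass(frozen=True)
class StateSpace:
    """Token alphabet plus the reserved Start/Stop boundary states.

    Start is never a destination; Stop (when ``include_stop``) is never a
    source.  ``destinations`` is the outcome space every conditional
    distribution lives on.
    """

    tokens: tuple[str, ...]
    start_symbol: str = START
    stop_symbol: str = STOP
    include_stop: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if self.start_symbol in self.tokens or self.stop_symbol in self.tokens:
            raise ValidationError("start/stop symbols must not appear among tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValidationError("duplicate tokens in state space")

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[CallSequence], include_stop: bool = True
    ) -> "StateSpace":
        tokens = sorted({t for s in sequences for t in s.tokens})
        return cls(tokens=tuple(tokens), include_stop=include_stop)

    @property
    def destinations(self) -> tuple[str, ...]:
        if self.include_stop:
            return self.tokens + (self.stop_symbol,)
        return self.tokens

    @property
    def n_destinations(self) -> int:
        return len(self.destinations)

    def padded(self, tokens: Sequence[str], m: int) -> tuple[str, ...]:
        """The order-``m`` padded stream for one sequence."""
        tail = (self.stop_symbol,) if self.include_stop else ()
        return (self.start_symbol,) * m + tuple(tokens) + tail


@dataclass
class MarkovModel:
    """Order-``m`` transition counts and maximum-likelihood probabilities."""

    order: int
    space: StateSpace
    counts: dict[tuple[str, ...], dict[str, int]]
    probs: dict[tuple[str, ...], dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.probs = {}
        for h, dests in self.counts.items():
            total = sum(dests.values())
            if total > 0:
                self.probs[h] = {d: c / total for d, c in dests.items()}

    def total(self, history: tuple[str, ...]) -> int:
        return sum(self.counts.get(history, {}).values())

    def count(self, history: tuple[str, ...], destination: str) -> int:
        return self.counts.get(history, {}).get(destination, 0)

    def prob(self, history: tuple[str, ...], destination: str) -> float:
        """MLE transition probability; 0 for unseen pairs under a seen history."""
        return self.probs.get(history, {}).get(destination, 0.0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "order": self.order,
            "tokens": list(self.space.tokens),
            "start_symbol": self.space.start_symbol,
            "stop_symbol": self.space.stop_symbol,
            "include_stop": self.space.include_stop,
            "counts": {
                "|".join(h): dict(sorted(dests.items()))
                for h, dests in sorted(self.counts.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovModel":
        payload = json.loads(Path(path).read_text())
        space = StateSpace(
            tokens=tuple(payload["tokens"]),
            start_symbol=payload["start_symbol"],
            stop_symbol=payload["stop_symbol"],
            include_stop=payload["include_stop"],
        )
        counts = {
            tuple(h.split("|")): {d: int(c) for d, c in dests.items()}
            for h, dests in payload["counts"].items()
        }
        return cls(order=payload["order"], space=space, counts=counts)


@dataclass(frozen=True)
class ChanceModel:
    """Memoryless relative-frequency distribution over destinations."""

    dist: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"chance distribution sums to {total}, not 1")

    def p(self, destination: str) -> float:
        return self.dist.get(destination, 0.0)


@dataclass(frozen=True)
class TransitionStats:
    """One observed transition with its chance-deviation score.

    ``loglik`` is <= 0; more negative means the observed count is harder
    to reconcile with the chance rate of the destination.
    """

    history: tuple[str, ...]
    destination: str
    tp: float
    count: int
    loglik: float
    mode: str = "binomial"


def _validate_tokens(sequences: Sequence[CallSequence], space: StateSpace) -> None:
    known = set(space.tokens)
    for seq in sequences:
        for t in seq.tokens:
            if t not in known:
                raise ValidationError(f"token {t!r} not in state space {space.tokens}")


def transition_windows(
    tokens: Sequence[str], m: int, space: StateSpace
) -> list[tuple[tuple[str, ...], str]]:
    """(history, destination) pairs contributed by one sequence at order m."""
    stream = space.padded(tokens, m)
    return [(stream[i - m : i], stream[i]) for i in range(m, len(stream))]


def fit_markov(
    sequences: Sequence[CallSequence], m: int, space: StateSpace | None = None
) -> MarkovModel:
    """Fit an order-``m`` chain by counting padded transition windows.

    Every sequence is padded with ``m`` Start symbols (and one Stop symbol
    when the space includes Stop); probabilities are count ratios per
    history.  ``m = 0`` yields a single empty history holding the
    destination relative-frequency distribution.
    """
    if m < 0:
        raise ValidationError(f"order must be >= 0, got {m}")
    if space is None:
        space = StateSpace.from_sequences(sequences)
    _validate_tokens(sequences, space)
    counts: dict[tuple[str, ...], dict[str, int]] = {}
    for seq in sequences:
        for history, dest in transition_windows(seq.tokens, m, space):
            row = counts.setdefault(history, {})
            row[dest] = row.get(dest, 0) + 1
    return MarkovModel(order=m, space=space, counts=counts)


def chance_model(
    sequences: Sequence[CallSequence], space: StateSpace | None = None
) -> ChanceModel:
    """Relative frequency of each destination over all destination slots.

    Destination slots are the padded-stream positions predicted by the
    model: every token, plus one Stop per sequence when Stop is modelled.
    Start never occupies a destination slot.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValidationError("cannot estimate a chance model from an empty corpus")
    if space is None:
        space = StateSpace.from_sequences(sequences)
    _validate_tokens(sequences, space)
    counts: dict[str, int] = {}
    for seq in sequences:
        for tok in seq.tokens:
            counts[tok] = counts.get(tok, 0) + 1
        if space.include_stop:
            counts[space.stop_symbol] = counts.get(space.stop_symbol, 0) + 1
    total = sum(counts.values())
    return ChanceModel(dist={d: counts.get(d, 0) / total for d in space.destinations})


def binomial_chance_loglik(n_hd: int, n_h: int, p: float) -> float:
    """log P(Binomial(n_h, p) = n_hd); -inf when p = 0 with n_hd > 0."""
    if p <= 0.0:
        return 0.0 if n_hd == 0 else -math.inf
    if p >= 1.0:
        return 0.0 if n_hd == n_h else -math.inf
    return float(sps.binom.logpmf(n_hd, n_h, p))


def chance_loglik(
    model: MarkovModel, chance: ChanceModel, mode: str = "binomial"
) -> list[TransitionStats]:
    """Score every observed transition against the chance model.

    ``mode="binomial"`` (default): log binomial probability of the
    observed arrival count at the chance rate — bounded by 0, penalizing
    deviations in either direction.  ``mode="ratio"``: the log-likelihood
    ratio ``n_hd * log(p_chance / tp)``, which is <= 0 only for
    over-represented transitions; provided for comparison and recorded in
    each stat's ``mode`` field.
    """
    if mode not in ("binomial", "ratio"):
        raise ValidationError(f"unknown chance-loglik mode: {mode!r}")
    out: list[TransitionStats] = []
    for history in sorted(model.counts):
        n_h = model.total(history)
        for dest in sorted(model.counts[history]):
            n_hd = model.counts[history][dest]
            if n_hd == 0:
                continue
            tp = n_hd / n_h
            p = chance.p(dest)
            if mode == "binomial":
                ll = binomial_chance_loglik(n_hd, n_h, p)
            else:
                ll = -math.inf if p == 0.0 else n_hd * math.log(p / tp)
            out.append(
                TransitionStats(
                    history=history, destination=dest, tp=tp, count=n_hd,
                    loglik=ll, mode=mode,
                )
            )
    return out


def sequence_loglik(model: MarkovModel, seq: CallSequence, k: float = 0.0) -> float:
    """Log-likelihood of one sequence under the model with add-k smoothing.

    Each padded transition contributes ``log((count + k) / (total + k*D))``
    where ``D`` is the number of possible destinations; histories never
    seen in training score as the uniform smoothed distribution.  With
    ``k = 0`` an unseen transition makes the result -inf.
    """
    if k < 0:
        raise ValidationError(f"smoothing constant k must be >= 0, got {k}")
    space = model.space
    _validate_tokens([seq], space)
    D = space.n_destinations
    total_ll = 0.0
    for history, dest in transition_windows(seq.tokens, model.order, space):
        num = model.count(history, dest) + k
        den = model.total(history) + k * D
        if num == 0.0 or den == 0.0:
            return -math.inf
        total_ll += math.log(num / den)
    return total_ll


@dataclass
class AdjacencyTable:
    """Matrix view of a fitted model: transition probability and chance score.

    Rows are histories (Start first, then alphabetical), columns the
    destinations.  Zero-count cells carry tp = 0 and an empty loglik.
    """

    tp: pd.DataFrame
    loglik: pd.DataFrame
    count: pd.DataFrame
    mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.tp.index:
            for d in self.tp.columns:
                ll = self.loglik.loc[h, d]
                rows.append(
                    {
                        "history": h,
                        "destination": d,
                        "count": int(self.count.loc[h, d]),
                        "tp": float(self.tp.loc[h, d]),
                        "loglik": "" if pd.isna(ll) else float(ll),
                        "mode": self.mode,
                    }
                )
        return pd.DataFrame(rows, columns=["history", "destination", "count", "tp", "loglik", "mode"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _history_sort_key(space: StateSpace):
    def key(h: tuple[str, ...]):
        # Start sorts before every token
        return tuple((0, "") if s == space.start_symbol else (1, s) for s in h)

    return key


def adjacency_table(
    model: MarkovModel, stats: Sequence[TransitionStats] | None = None
) -> AdjacencyTable:
    """Complete transition grid for an order-1 or order-2 model.

    Order 1 rows are Start plus every token (even unobserved ones); order
    2 rows are the histories with positive counts.  Columns always span
    the full destination set.
    """
    if model.order not in (1, 2):
        raise ValidationError("adjacency tables are defined for orders 1 and 2")
    space = model.space
    if model.order == 1:
        histories = [(space.start_symbol,)] + [(t,) for t in sorted(space.tokens)]
    else:
        histories = sorted(model.counts, key=_history_sort_key(space))
    dest_cols = list(space.destinations)
    index = ["-".join(h) for h in histories]

    tp = pd.DataFrame(0.0, index=index, columns=dest_cols)
    count = pd.DataFrame(0, index=index, columns=dest_cols)
    ll = pd.DataFrame(np.nan, index=index, columns=dest_cols)
    for h, label in zip(histories, index):
        for d in dest_cols:
            c = model.count(h, d)
            count.loc[label, d] = c
            tp.loc[label, d] = model.prob(h, d)
    mode = "binomial"
    if stats:
        mode = stats[0].mode
        for s in stats:
            label = "-".join(s.history)
            if label in ll.index and s.destination in ll.columns:
                ll.loc[label, s.destination] = s.loglik
    return AdjacencyTable(tp=tp, loglik=ll, count=count, mode=mode)
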