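"""Seeded synthetic corpora: token sequences and time-stamped call logs.

Two layers are generated.  First, token sequences are sampled by walking
a user-specified fixed-order Markov chain from an all-Start history until
Stop (or a hard length cap).  Second, each token is expanded into a bout
of repeated calls with explicit onsets/offsets, with silent pauses chosen
so the segmentation rules recover the generated sequences exactly: gaps
within bouts and between tokens are at most the segmentation threshold,
gaps between sequences exceed it.  This makes the generator a round-trip
oracle for the whole annotation pipeline as well as a ground-truth source
for transition-recovery and order-selection studies.

Besides the fully general :class:`GeneratorSpec`, three ready-made chains
are provided: a marmoset-like order-2 repertoire preset (illustrative,
not calibrated to any recording data), and two benchmark chains with
known order (a strongly second-order "return" chain and a plain
first-order chain) for order-recovery simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .annotation_io import CallRecord, CallSequence, SegmentationConfig
from .errors import ValidationError
from .markov import StateSpace

TransitionTable = Mapping[tuple[str, ...], Mapping[str, float]]


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to sample annotation logs with known structure.

    ``transition_probs`` maps each length-``order`` history (tuples over
    Start and tokens) to a destination distribution over tokens and Stop.
    Timing defaults keep within-sequence pauses at or under the 0.5 s
    segmentation threshold and between-sequence pauses above it.
    ``bout_size_dist`` draws the number of repeated calls per bout
    (default: geometric with mean 2).
    """

    space: StateSpace
    order: int
    transition_probs: TransitionTable
    n_sequences: int = 100
    bout_size_dist: Callable[[np.random.Generator], int] | None = None
    call_duration: float = 0.1
    within_bout_gap: float = 0.2
    between_token_gap: float = 0.3
    between_sequence_gap: float = 2.0
    max_length: int = 50
    seed: int = 0
    individual: str = "sim01"
    session: str = "s01"
    context: str = "synthetic"
    segmentation_max_gap: float = 0.5

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValidationError("order must be >= 0")
        if self.n_sequences < 1:
            raise ValidationError("n_sequences must be >= 1")
        g = self.segmentation_max_gap
        if not (0 < self.within_bout_gap <= g and 0 < self.between_token_gap <= g):
            raise ValidationError(
                f"within/between-token gaps must lie in (0, {g}] to survive segmentation"
            )
        if self.between_sequence_gap <= g:
            raise ValidationError(
                f"between_sequence_gap must exceed the segmentation threshold {g}"
            )
        if self.call_duration <= 0:
            raise ValidationError("call_duration must be > 0")
        for h, dist in self.transition_probs.items():
            if len(h) != self.order:
                raise ValidationError(
                    f"history {h} has length {len(h)}, expected order {self.order}"
                )
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"distribution for history {h} sums to {total}")
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"negative probability in history {h}")
            if self.space.start_symbol in dist:
                raise ValidationError("Start can never be a destination")

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(max_gap=self.segmentation_max_gap)


def _default_bout_sizes(rng: np.random.Generator) -> int:
    # geometric on {1, 2, ...} with mean 2
    return int(rng.geometric(0.5))


def _walk(spec: GeneratorSpec, rng: np.random.Generator) -> tuple[str, ...]:
    space = spec.space
    history = (space.start_symbol,) * spec.order
    initial = spec.transition_probs.get(history, {})
    if initial.get(space.stop_symbol, 0.0) >= 1.0 - 1e-12:
        raise ValidationError(
            "the all-Start history puts all its mass on Stop; sequences must "
            "contain at least one token"
        )
    tokens: list[str] = []
    while len(tokens) < spec.max_length:
        try:
            dist = spec.transition_probs[history]
        except KeyError:
            raise ValidationError(
                f"no transition distribution defined for history {history}"
            ) from None
        dests = sorted(dist)
        probs = np.array([dist[d] for d in dests])
        dest = dests[rng.choice(len(dests), p=probs / probs.sum())]
        if dest == space.stop_symbol:
            if not tokens:
                # sequences have at least one token by definition; condition
                # the first draw on not stopping (rejection keeps the chain
                # otherwise untouched)
                continue
            break
        tokens.append(dest)
        if spec.order > 0:
            history = history[1:] + (dest,)
    else:
        warnings.warn(
            f"sequence hit the max_length cap of {spec.max_length} before Stop",
            stacklevel=2,
        )
    return tuple(tokens)


def generate_sequences(spec: GeneratorSpec) -> list[CallSequence]:
    """Sample ``spec.n_sequences`` token sequences from the chain.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    return [
        CallSequence(
            tokens=_walk(spec, rng),
            individual=spec.individual,
            session=spec.session,
            context=spec.context,
        )
        for _ in range(spec.n_sequences)
    ]


def generate_annotation_log(
    spec: GeneratorSpec,
) -> tuple[list[CallRecord], list[CallSequence]]:
    """Sample sequences and expand them into a timed annotation log.

    Each token becomes a bout of ``bout_size_dist`` calls of
    ``call_duration`` seconds separated by ``within_bout_gap``; tokens are
    separated by ``between_token_gap`` and sequences by
    ``between_sequence_gap``.  Returns the records (onset-sorted, one
    stream) and the ground-truth sequences they encode.
    """
    rng = np.random.default_rng(spec.seed)
    sequences = [
        CallSequence(
            tokens=_walk(spec, rng),
            individual=spec.individual,
            session=spec.session,
            context=spec.context,
        )
        for _ in range(spec.n_sequences)
    ]
    bout_sizes = spec.bout_size_dist or _default_bout_sizes
    records: list[CallRecord] = []
    t = 0.0
    for seq in sequences:
        for ti, token in enumerate(seq.tokens):
            if ti > 0:
                t += spec.between_token_gap
            n_calls = int(bout_sizes(rng))
            if n_calls < 1:
                raise ValidationError("bout_size_dist must return integers >= 1")
            for ci in range(n_calls):
                if ci > 0:
                    t += spec.within_bout_gap
                records.append(
                    CallRecord(
                        individual=spec.individual,
                        session=spec.session,
                        context=spec.context,
                        call_type=token,
                        onset=round(t, 9),
                        offset=round(t + spec.call_duration, 9),
                    )
                )
                t += spec.call_duration
        t += spec.between_sequence_gap
    return records, sequences


# ---------------------------------------------------------------------------
# ready-made chains


def _expand_order2(
    space: StateSpace,
    initial: Mapping[str, float],
    base_rows: Mapping[str, Mapping[str, float]],
    overrides: Mapping[tuple[str, str], Mapping[str, float]],
) -> dict[tuple[str, str], dict[str, float]]:
    """Build a full order-2 table from per-token base rows plus overrides."""
    start = space.start_symbol
    table: dict[tuple[str, str], dict[str, float]] = {(start, start): dict(initial)}
    for prev1 in space.tokens:
        for prev2 in (start, *space.tokens):
            row = overrides.get((prev2, prev1), base_rows[prev1])
            table[(prev2, prev1)] = dict(row)
    return table


MARMOSET_TOKENS = ("chirp", "ek", "phee", "trill", "tsk", "twitter", "whistle")


def marmoset_like_preset(n_sequences: int = 2000, seed: int = 0) -> GeneratorSpec:
    """An illustrative order-2 chain over the 7-type marmoset repertoire.

    The chain is shaped to echo qualitative features of marmoset call
    streams — a length profile dominated by unigrams with a tail to about
    nine tokens, whistles that almost always terminate a sequence, tsk
    continuing to ek far more often than stopping, and chirp-initiated
    bigrams returning to chirp — without being calibrated to any
    recording dataset.  Self-transitions have zero mass, matching
    bout-collapsed tokens.
    """
    space = StateSpace(tokens=MARMOSET_TOKENS, include_stop=True)
    initial = {
        "chirp": 0.24, "ek": 0.01, "phee": 0.30, "trill": 0.20,
        "tsk": 0.06, "twitter": 0.14, "whistle": 0.05,
    }
    base = {
        "chirp": {"Stop": 0.60, "phee": 0.11, "trill": 0.10, "tsk": 0.07,
                  "twitter": 0.06, "ek": 0.06},
        "ek": {"Stop": 0.74, "phee": 0.09, "chirp": 0.10, "tsk": 0.07},
        "phee": {"Stop": 0.73, "trill": 0.10, "chirp": 0.06, "twitter": 0.06,
                 "tsk": 0.05},
        "trill": {"Stop": 0.65, "phee": 0.18, "chirp": 0.07, "twitter": 0.05,
                  "tsk": 0.05},
        "tsk": {"ek": 0.66, "Stop": 0.24, "phee": 0.05, "chirp": 0.05},
        "twitter": {"Stop": 0.70, "phee": 0.05, "trill": 0.10, "chirp": 0.10,
                    "tsk": 0.05},
        "whistle": {"Stop": 0.95, "ek": 0.05},
    }
    overrides = {
        # chirp-x bigrams tend to return to chirp
        ("chirp", "ek"): {"chirp": 0.75, "Stop": 0.10, "phee": 0.08, "tsk": 0.07},
        ("chirp", "phee"): {"chirp": 0.50, "Stop": 0.40, "trill": 0.05, "tsk": 0.05},
        ("chirp", "trill"): {"chirp": 0.85, "Stop": 0.05, "phee": 0.05, "tsk": 0.05},
        ("chirp", "twitter"): {"chirp": 0.55, "Stop": 0.40, "phee": 0.05},
        ("chirp", "tsk"): {"ek": 0.53, "chirp": 0.29, "Stop": 0.13, "phee": 0.05},
        # tsk-ek mostly terminates, sometimes restarts on chirp/phee
        ("tsk", "ek"): {"Stop": 0.67, "chirp": 0.17, "phee": 0.11, "tsk": 0.05},
    }
    table = _expand_order2(space, initial, base, overrides)
    return GeneratorSpec(
        space=space, order=2, transition_probs=table,
        n_sequences=n_sequences, seed=seed, max_length=12,
    )


def order2_benchmark_spec(n_sequences: int = 1000, seed: int = 0) -> GeneratorSpec:
    """A strongly second-order chain whose structure no first-order chain matches.

    Three tokens; after any bigram (x, y) the walk returns to x with high
    probability (an a-b-a "framing" pattern).  The first-order marginal
    next-token distribution is nearly uniform over the non-adjacent
    tokens, so the second-order structure is non-factorizable: LOO order
    selection should recover order 2.
    """
    tokens = ("a", "b", "c")
    space = StateSpace(tokens=tokens, include_stop=True)
    start = space.start_symbol
    table: dict[tuple[str, str], dict[str, float]] = {
        (start, start): {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}
    }
    for prev1 in tokens:
        others = [t for t in tokens if t != prev1]
        table[(start, prev1)] = {others[0]: 0.35, others[1]: 0.35, "Stop": 0.30}
        for prev2 in tokens:
            if prev2 == prev1:
                continue
            third = next(t for t in tokens if t not in (prev1, prev2))
            # return to prev2 with high probability
            table[(prev2, prev1)] = {prev2: 0.70, third: 0.05, "Stop": 0.25}
    return GeneratorSpec(
        space=space, order=2, transition_probs=table,
        n_sequences=n_sequences, seed=seed, max_length=30,
    )


def order1_benchmark_spec(n_sequences: int = 1000, seed: int = 0) -> GeneratorSpec:
    """A plain first-order chain with marked token-to-token preferences.

    The next token depends only on the current one, so LOO order
    selection should settle on order 1.
    """
    tokens = ("a", "b", "c")
    space = StateSpace(tokens=tokens, include_stop=True)
    table: dict[tuple[str, ...], dict[str, float]] = {
        (space.start_symbol,): {"a": 0.5, "b": 0.3, "c": 0.2},
        ("a",): {"b": 0.55, "c": 0.10, "Stop": 0.35},
        ("b",): {"c": 0.50, "a": 0.10, "Stop": 0.40},
        ("c",): {"a": 0.45, "b": 0.10, "Stop": 0.45},
    }
    return GeneratorSpec(
        space=space, order=1, transition_probs=table,
        n_sequences=n_sequences, seed=seed, max_length=30,
    )


def order0_benchmark_spec(n_sequences: int = 1000, seed: int = 0) -> GeneratorSpec:
    """A memoryless generator: every position draws from one fixed distribution."""
    tokens = ("a", "b", "c")
    space = StateSpace(tokens=tokens, include_stop=True)
    table: TransitionTable = {(): {"a": 0.3, "b": 0.2, "c": 0.1, "Stop": 0.4}}
    return GeneratorSpec(
        space=space, order=0, transition_probs=table,
        n_sequences=n_sequences, seed=seed, max_length=30,
    )
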