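"""Reading annotated call logs and segmenting them into bouts and sequences.

The unit of analysis is the *call sequence*: an ordered run of call-type
tokens.  Repeated calls of the same type separated by silent pauses of at
most ``max_gap`` seconds (default 0.5 s) form a *bout*, which collapses to
a single token; bouts separated by pauses of at most ``max_gap`` join into
one sequence, and a longer pause starts a new sequence.  Segmentation is
performed independently within each (individual, session) stream, so
sequences never span recording sessions.

Also provided here: a min-count filter for rare call types, summary tables
(sequence lengths, top n-grams) and Cohen's kappa for inter-observer
reliability of the annotations.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

#: default mapping from logical field names to annotation-file column names
DEFAULT_COLUMNS: Mapping[str, str] = {
    "individual": "individual",
    "session": "session",
    "context": "context",
    "call_type": "call_type",
    "onset": "onset_s",
    "offset": "offset_s",
}


@dataclass(frozen=True)
class CallRecord:
    """One annotated call: who produced it, when, and of which type."""

    individual: str
    session: str
    context: str
    call_type: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValidationError(f"onset must be >= 0, got {self.onset}")
        if self.offset < self.onset:
            raise ValidationError(
                f"offset ({self.offset}) < onset ({self.onset}) for "
                f"{self.call_type} by {self.individual}/{self.session}"
            )


@dataclass(frozen=True)
class SegmentationConfig:
    """Gap rule for bout and sequence construction.

    ``max_gap`` is the longest silent pause (seconds) that still joins two
    calls into a bout, or two bouts into a sequence.  With
    ``boundary_inclusive`` (the default) a pause exactly equal to
    ``max_gap`` joins.
    """

    max_gap: float = 0.5
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValidationError(f"max_gap must be > 0, got {self.max_gap}")

    def joins(self, gap: float) -> bool:
        """Whether a silent pause of ``gap`` seconds joins its neighbours."""
        return gap <= self.max_gap if self.boundary_inclusive else gap < self.max_gap


@dataclass(frozen=True)
class Bout:
    """A run of same-type calls collapsed to one token."""

    call_type: str
    start: float
    end: float
    n_calls: int
    individual: str
    session: str
    context: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError("bout end < start")
        if self.n_calls < 1:
            raise ValidationError("bout must contain at least one call")


@dataclass(frozen=True)
class CallSequence:
    """An ordered, bout-collapsed run of call-type tokens."""

    tokens: tuple[str, ...]
    individual: str = ""
    session: str = ""
    context: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ValidationError("a sequence must contain at least one token")
        object.__setattr__(self, "tokens", tuple(self.tokens))

    @property
    def length(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class ReliabilityResult:
    """Cohen's kappa with its ingredients."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int


def read_annotations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> list[CallRecord]:
    """Read a delimited annotation log into sorted :class:`CallRecord` rows.

    Parameters
    ----------
    path
        CSV/TSV file with one row per annotated call.
    column_map
        Mapping from the logical field names (``individual``, ``session``,
        ``context``, ``call_type``, ``onset``, ``offset``) to the column
        names used in the file.  Unmentioned fields fall back to the
        defaults in :data:`DEFAULT_COLUMNS`.
    delimiter
        Field separator; inferred from the file when omitted.

    Returns
    -------
    Records sorted by (individual, session, onset); ties keep file order.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"annotation file not found: {path}")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown field(s) in column_map: {sorted(unknown)}")
        cols.update(column_map)

    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)

    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"column(s) {missing} not found in {path.name}; present: {list(df.columns)}"
        )

    records: list[CallRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        raw = dict(zip(df.columns, row))
        times = {}
        for fld in ("onset", "offset"):
            try:
                times[fld] = float(raw[cols[fld]])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {row_number}: cannot parse {fld} value {raw[cols[fld]]!r} as seconds"
                ) from exc
        try:
            records.append(
                CallRecord(
                    individual=str(raw[cols["individual"]]),
                    session=str(raw[cols["session"]]),
                    context=str(raw[cols["context"]]),
                    call_type=str(raw[cols["call_type"]]),
                    onset=times["onset"],
                    offset=times["offset"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row_number}: {exc}") from exc

    records.sort(key=lambda r: (r.individual, r.session, r.onset))
    return records


def filter_rare_call_types(
    records: Sequence[CallRecord], min_count: int
) -> tuple[list[CallRecord], list[str]]:
    """Drop call types occurring fewer than ``min_count`` times overall.

    Returns the kept records (original order) and the sorted list of
    removed type labels.  With ``min_count=2`` this reproduces the usual
    practice of excluding singleton types from repertoire-wide analyses.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    counts = Counter(r.call_type for r in records)
    removed = sorted(t for t, c in counts.items() if c < min_count)
    kept = [r for r in records if counts[r.call_type] >= min_count]
    return kept, removed


def _stream_key(r: CallRecord) -> tuple[str, str]:
    return (r.individual, r.session)


def segment_bouts(
    records: Sequence[CallRecord], cfg: SegmentationConfig | None = None
) -> list[Bout]:
    """Merge consecutive same-type calls into bouts per (individual, session).

    The silent pause between two calls is ``next.onset - current.offset``.
    A pause the config joins *and* an unchanged call type extend the
    current bout; otherwise the bout closes.  Overlapping calls within one
    stream (negative pause) are a hard error.
    """
    cfg = cfg or SegmentationConfig()
    bouts: list[Bout] = []
    by_stream: dict[tuple[str, str], list[CallRecord]] = {}
    for r in records:
        by_stream.setdefault(_stream_key(r), []).append(r)

    for key in sorted(by_stream):
        stream = sorted(by_stream[key], key=lambda r: r.onset)
        current: list[CallRecord] = []
        for r in stream:
            if current:
                gap = r.onset - current[-1].offset
                if gap < 0:
                    raise ValidationError(
                        f"overlapping calls in stream {key}: "
                        f"{current[-1].call_type} ends at {current[-1].offset} but "
                        f"{r.call_type} starts at {r.onset}"
                    )
                if r.call_type == current[-1].call_type and cfg.joins(gap):
                    current.append(r)
                    continue
                bouts.append(_close_bout(current))
                current = [r]
            else:
                current = [r]
        if current:
            bouts.append(_close_bout(current))
    return bouts


def _close_bout(calls: list[CallRecord]) -> Bout:
    first, last = calls[0], calls[-1]
    return Bout(
        call_type=first.call_type,
        start=first.onset,
        end=last.offset,
        n_calls=len(calls),
        individual=first.individual,
        session=first.session,
        context=first.context,
    )


def build_sequences(
    bouts: Sequence[Bout], cfg: SegmentationConfig | None = None
) -> list[CallSequence]:
    """Join bouts into call sequences using the inter-bout pause rule.

    The pause between bouts is ``next.start - current.end``; a pause the
    config joins keeps the sequence going, otherwise a new sequence starts.
    A sequence's context label is taken from its first bout.
    """
    cfg = cfg or SegmentationConfig()
    sequences: list[CallSequence] = []
    by_stream: dict[tuple[str, str], list[Bout]] = {}
    for b in bouts:
        by_stream.setdefault((b.individual, b.session), []).append(b)

    for key in sorted(by_stream):
        stream = sorted(by_stream[key], key=lambda b: b.start)
        run: list[Bout] = []
        for b in stream:
            if run and not cfg.joins(b.start - run[-1].end):
                sequences.append(_close_sequence(run))
                run = [b]
            else:
                run.append(b)
        if run:
            sequences.append(_close_sequence(run))
    return sequences


def _close_sequence(run: list[Bout]) -> CallSequence:
    first = run[0]
    return CallSequence(
        tokens=tuple(b.call_type for b in run),
        individual=first.individual,
        session=first.session,
        context=first.context,
    )


def segment(
    records: Sequence[CallRecord], cfg: SegmentationConfig | None = None
) -> list[CallSequence]:
    """Convenience composition: records -> bouts -> sequences."""
    cfg = cfg or SegmentationConfig()
    return build_sequences(segment_bouts(records, cfg), cfg)


def sequence_length_table(sequences: Iterable[CallSequence]) -> dict[int, int]:
    """Count sequences by token length (1 = unigram, 2 = bigram, ...)."""
    return dict(sorted(Counter(s.length for s in sequences).items()))


def top_ngrams(
    sequences: Iterable[CallSequence], n: int, limit: int = 10
) -> list[tuple[tuple[str, ...], int]]:
    """Most frequent adjacent token n-grams, never crossing sequence ends.

    Ranked by descending count; ties break lexicographically on the tokens.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if limit < 1:
        raise ValidationError(f"limit must be >= 1, got {limit}")
    counts: Counter[tuple[str, ...]] = Counter()
    for seq in sequences:
        toks = seq.tokens
        for i in range(len(toks) - n + 1):
            counts[toks[i : i + n]] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:limit]


def cohens_kappa(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> ReliabilityResult:
    """Cohen's kappa for two raters' categorical labels of the same items.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the raters' marginal label frequencies over
    the pooled label set.  Perfect agreement returns kappa = 1 even when
    p_e = 1 (both raters constant).
    """
    if len(labels_a) != len(labels_b):
        raise ValidationError(
            f"label lists differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n == 0:
        raise ValidationError("label lists must be non-empty")
    po = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    freq_a = Counter(labels_a)
    freq_b = Counter(labels_b)
    pe = sum(freq_a[c] * freq_b.get(c, 0) for c in freq_a) / (n * n)
    kappa = 1.0 if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return ReliabilityResult(
        kappa=kappa, observed_agreement=po, expected_agreement=pe, n_items=n
    )


def sequences_to_frame(sequences: Sequence[CallSequence]) -> pd.DataFrame:
    """Long-format table: one row per token with its sequence id and position."""
    rows = []
    for sid, seq in enumerate(sequences):
        for pos, tok in enumerate(seq.tokens):
            rows.append(
                {
                    "sequence_id": sid,
                    "individual": seq.individual,
                    "session": seq.session,
                    "context": seq.context,
                    "position": pos,
                    "token": tok,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "individual", "session", "context", "position", "token"],
    )


def write_sequences(
    sequences: Sequence[CallSequence], csv_path: str | Path, summary_path: str | Path | None = None
) -> None:
    """Write sequences as long-format CSV plus an optional JSON summary."""
    sequences_to_frame(sequences).to_csv(csv_path, index=False)
    if summary_path is not None:
        token_counts = Counter(t for s in sequences for t in s.tokens)
        summary = {
            "n_sequences": len(sequences),
            "n_tokens": sum(token_counts.values()),
            "length_table": {str(k): v for k, v in sequence_length_table(sequences).items()},
            "repertoire_counts": dict(sorted(token_counts.items())),
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2, sort_keys=True))


def records_to_frame(records: Sequence[CallRecord]) -> pd.DataFrame:
    """Annotation-log table in the default column dialect."""
    return pd.DataFrame(
        [
            {
                "individual": r.individual,
                "session": r.session,
                "context": r.context,
                "call_type": r.call_type,
                "onset_s": r.onset,
                "offset_s": r.offset,
            }
            for r in records
        ],
        columns=list(DEFAULT_COLUMNS.values()),
    )
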