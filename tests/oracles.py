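"""Independent brute-force references used to check the implementation.

These deliberately avoid the package's counting code paths: they pad and
enumerate windows with plain Python loops and nested dicts.
"""

from collections import defaultdict


def brute_force_transition_probs(token_lists, m, include_stop=True,
                                 start="Start", stop="Stop"):
    """Enumerate padded windows of every sequence and normalize counts."""
    counts = defaultdict(lambda: defaultdict(int))
    for tokens in token_lists:
        stream = [start] * m + list(tokens) + ([stop] if include_stop else [])
        for i in range(m, len(stream)):
            history = tuple(stream[i - m : i])
            counts[history][stream[i]] += 1
    probs = {}
    for h, row in counts.items():
        total = sum(row.values())
        probs[h] = {d: c / total for d, c in row.items()}
    return {h: dict(row) for h, row in counts.items()}, probs


def brute_force_ngram_counts(token_lists, n):
    """Adjacent n-gram tally within each sequence only."""
    counts = defaultdict(int)
    for tokens in token_lists:
        for i in range(len(tokens) - n + 1):
            counts[tuple(tokens[i : i + n])] += 1
    return dict(counts)
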