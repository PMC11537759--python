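import numpy as np
import pytest

from callseq.annotation_io import CallRecord, CallSequence


@pytest.fixture
def tiny_corpus():
    """Two sequences: [chirp, trill] and [chirp] — 5 padded transitions."""
    return [CallSequence(("chirp", "trill")), CallSequence(("chirp",))]


@pytest.fixture
def annotation_csv(tmp_path):
    """A small annotation log: two streams, bouts and sequence breaks."""
    path = tmp_path / "log.csv"
    path.write_text(
        "individual,session,context,call_type,onset_s,offset_s\n"
        "m1,s1,forage,chirp,0.0,0.1\n"
        "m1,s1,forage,chirp,0.3,0.4\n"     # same bout (gap 0.2)
        "m1,s1,forage,trill,0.7,0.9\n"     # new bout, same sequence (gap 0.3)
        "m1,s1,forage,phee,2.0,2.5\n"      # new sequence (gap 1.1)
        "m2,s1,rest,phee,0.0,0.5\n"
        "m2,s1,rest,phee,1.2,1.6\n"        # gap 0.7 > 0.5: separate sequence
    )
    return path


def random_corpus(rng: np.random.Generator, max_sequences=10, max_tokens=6):
    """A small random corpus over a random alphabet, for oracle checks."""
    alphabet = [f"t{i}" for i in range(rng.integers(2, max_tokens + 1))]
    n = int(rng.integers(1, max_sequences + 1))
    seqs = []
    for _ in range(n):
        length = int(rng.integers(1, 7))
        toks = [alphabet[rng.integers(len(alphabet))]]
        while len(toks) < length:
            nxt = alphabet[rng.integers(len(alphabet))]
            if nxt != toks[-1]:  # mimic bout-collapsed tokens
                toks.append(nxt)
        seqs.append(CallSequence(tuple(toks)))
    return seqs
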