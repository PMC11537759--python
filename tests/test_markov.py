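"""Markov fitting, chance model, chance-deviation scores, smoothing."""

import math

import numpy as np
import pytest

from callseq.annotation_io import CallSequence
from callseq.errors import ValidationError
from callseq.markov import (
    StateSpace,
    adjacency_table,
    binomial_chance_loglik,
    chance_loglik,
    chance_model,
    fit_markov,
    sequence_loglik,
)
from oracles import brute_force_transition_probs


class TestFitMarkov:
    def test_order1_hand_counted(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        assert model.prob(("Start",), "chirp") == pytest.approx(1.0)
        assert model.prob(("chirp",), "trill") == pytest.approx(0.5)
        assert model.prob(("chirp",), "Stop") == pytest.approx(0.5)
        assert model.prob(("trill",), "Stop") == pytest.approx(1.0)

    def test_order0_is_destination_frequency(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 0)
        assert model.probs[()] == pytest.approx(
            {"chirp": 0.4, "trill": 0.2, "Stop": 0.4}
        )

    def test_rows_normalize(self, tiny_corpus):
        for m in (0, 1, 2, 3):
            model = fit_markov(tiny_corpus, m)
            for row in model.probs.values():
                assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_token_rejected(self, tiny_corpus):
        space = StateSpace(tokens=("chirp",))
        with pytest.raises(ValidationError, match="trill"):
            fit_markov(tiny_corpus, 1, space)

    def test_short_sequence_still_contributes_at_high_order(self):
        model = fit_markov([CallSequence(("a",))], 3)
        assert model.count(("Start", "Start", "Start"), "a") == 1
        assert model.count(("Start", "Start", "a"), "Stop") == 1

    @pytest.mark.parametrize("include_stop", [True, False])
    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_matches_brute_force_enumeration(self, include_stop, m):
        from conftest import random_corpus

        rng = np.random.default_rng(42 + m)
        for _ in range(100):
            seqs = random_corpus(rng)
            space = StateSpace.from_sequences(seqs, include_stop=include_stop)
            model = fit_markov(seqs, m, space)
            counts, probs = brute_force_transition_probs(
                [s.tokens for s in seqs], m, include_stop
            )
            assert model.counts == counts
            assert set(model.probs) == set(probs)
            for h in probs:
                assert model.probs[h] == pytest.approx(probs[h])

    def test_order2_marginalizes_to_order1(self):
        from conftest import random_corpus

        rng = np.random.default_rng(3)
        for _ in range(50):
            seqs = random_corpus(rng)
            space = StateSpace.from_sequences(seqs)
            m1 = fit_markov(seqs, 1, space)
            m2 = fit_markov(seqs, 2, space)
            marginal: dict = {}
            for (_, recent), row in ((h, r) for h, r in m2.counts.items()):
                agg = marginal.setdefault((recent,), {})
                for d, c in row.items():
                    agg[d] = agg.get(d, 0) + c
            assert marginal == m1.counts


class TestChanceModel:
    def test_tiny_corpus_destination_slots(self, tiny_corpus):
        chance = chance_model(tiny_corpus)
        assert dict(chance.dist) == pytest.approx(
            {"chirp": 0.4, "trill": 0.2, "Stop": 0.4}
        )

    def test_single_type_without_stop(self):
        space = StateSpace(tokens=("phee",), include_stop=False)
        chance = chance_model([CallSequence(("phee",))], space)
        assert chance.p("phee") == pytest.approx(1.0)

    def test_recovers_sampling_frequencies(self):
        rng = np.random.default_rng(0)
        tokens = ["a", "b", "c"]
        p = np.array([0.5, 0.3, 0.2])
        seqs = [
            CallSequence((tokens[i],)) for i in rng.choice(3, size=10_000, p=p)
        ]
        space = StateSpace(tokens=tuple(tokens), include_stop=False)
        chance = chance_model(seqs, space)
        for tok, true_p in zip(tokens, p):
            se = math.sqrt(true_p * (1 - true_p) / 10_000)
            assert abs(chance.p(tok) - true_p) < 3 * se

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            chance_model([])


class TestChanceLoglik:
    def test_certain_event_scores_zero(self):
        assert binomial_chance_loglik(10, 10, 1.0) == 0.0

    def test_worked_binomial_value(self):
        # P(Bin(4, 0.5) = 2) = 6/16 = 0.375
        assert binomial_chance_loglik(2, 4, 0.5) == pytest.approx(
            math.log(0.375), abs=1e-12
        )

    def test_zero_chance_with_observations_is_minus_inf(self):
        assert binomial_chance_loglik(3, 10, 0.0) == -math.inf

    @pytest.mark.parametrize("p", [0.1 * i for i in range(1, 10)])
    def test_unimodal_and_nonpositive(self, p):
        for n_h in (1, 5, 17, 50):
            values = [binomial_chance_loglik(x, n_h, p) for x in range(n_h + 1)]
            assert all(v <= 0 for v in values)
            peak = int(np.argmax(values))
            assert abs(peak - n_h * p) <= 1  # mode of a binomial
            assert all(values[i] >= values[i + 1] for i in range(peak, n_h))
            assert all(values[i] <= values[i + 1] for i in range(peak))

    def test_stats_cover_observed_transitions(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        stats = chance_loglik(model, chance_model(tiny_corpus))
        keyed = {(s.history, s.destination): s for s in stats}
        assert set(keyed) == {
            (("Start",), "chirp"), (("chirp",), "trill"),
            (("chirp",), "Stop"), (("trill",), "Stop"),
        }
        for s in stats:
            assert s.loglik <= 0
            assert s.tp == pytest.approx(s.count / model.total(s.history))

    def test_ratio_mode_recorded(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        stats = chance_loglik(model, chance_model(tiny_corpus), mode="ratio")
        assert all(s.mode == "ratio" for s in stats)
        s = next(x for x in stats if x.history == ("trill",))
        # n_hd * log(p_chance / tp) = 1 * log(0.4 / 1.0)
        assert s.loglik == pytest.approx(math.log(0.4))


class TestSequenceLoglik:
    def test_hand_traced_unsmoothed(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        ll = sequence_loglik(model, CallSequence(("chirp",)), k=0.0)
        assert ll == pytest.approx(math.log(1.0) + math.log(0.5))

    def test_large_k_approaches_uniform(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        D = model.space.n_destinations
        seq = CallSequence(("chirp", "trill"))
        ll = sequence_loglik(model, seq, k=1e9)
        assert ll == pytest.approx(-(seq.length + 1) * math.log(D), rel=1e-6)

    def test_smoothing_rescues_unseen_transition(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        seq = CallSequence(("trill", "chirp"))  # trill->chirp never observed
        assert sequence_loglik(model, seq, k=0.0) == -math.inf
        assert math.isfinite(sequence_loglik(model, seq, k=0.5))

    def test_negative_k_rejected(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        with pytest.raises(ValidationError):
            sequence_loglik(model, tiny_corpus[0], k=-0.1)

    def test_higher_order_dominates_chance_on_training_data(self):
        from conftest import random_corpus

        rng = np.random.default_rng(21)
        for _ in range(20):
            seqs = random_corpus(rng)
            space = StateSpace.from_sequences(seqs)
            m1 = fit_markov(seqs, 1, space)
            m0 = fit_markov(seqs, 0, space)
            ll1 = sum(sequence_loglik(m1, s, k=0.0) for s in seqs)
            ll0 = sum(sequence_loglik(m0, s, k=0.0) for s in seqs)
            assert ll1 >= ll0 - 1e-9


class TestAdjacencyTable:
    def test_order1_shape_over_full_repertoire(self):
        tokens = ("chirp", "ek", "phee", "trill", "tsk", "twitter", "whistle")
        seqs = [CallSequence((t,)) for t in tokens]
        space = StateSpace(tokens=tokens)
        model = fit_markov(seqs, 1, space)
        table = adjacency_table(model)
        assert table.tp.shape == (8, 8)  # Start + 7 rows; 7 tokens + Stop cols
        assert list(table.tp.index)[0] == "Start"
        assert list(table.tp.columns)[-1] == "Stop"

    def test_rows_with_counts_sum_to_one(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        table = adjacency_table(model)
        sums = table.tp.sum(axis=1)
        for label in table.tp.index:
            total = table.count.loc[label].sum()
            expected = 1.0 if total > 0 else 0.0
            assert sums[label] == pytest.approx(expected)

    def test_cells_match_model_probs(self, tiny_corpus):
        model = fit_markov(tiny_corpus, 1)
        stats = chance_loglik(model, chance_model(tiny_corpus))
        table = adjacency_table(model, stats)
        assert table.tp.loc["chirp", "trill"] == pytest.approx(0.5)
        assert table.tp.loc["trill", "chirp"] == 0.0
        assert np.isnan(table.loglik.loc["trill", "chirp"])  # zero-count cell

    def test_csv_round_trip_serializable(self, tiny_corpus, tmp_path):
        import pandas as pd

        model = fit_markov(tiny_corpus, 1)
        stats = chance_loglik(model, chance_model(tiny_corpus))
        out = tmp_path / "adj.csv"
        adjacency_table(model, stats).to_csv(out)
        df = pd.read_csv(out)
        assert set(df.columns) == {"history", "destination", "count", "tp", "loglik", "mode"}
        assert len(df) == 3 * 3  # (Start, chirp, trill) x (chirp, trill, Stop)
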