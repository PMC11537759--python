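# callseq

Markov-chain analysis of animal call sequences, built around the common
marmoset (*Callithrix jacchus*) vocal repertoire. Given time-stamped call
annotations — one row per call with its type, onset and offset — the
package segments the stream into bouts and call sequences, fits
fixed-order Markov chains with Start/Stop boundary states, quantifies how
far each observed transition deviates from a relative-frequency chance
model, estimates Bayesian (Dirichlet) transition posteriors, and selects
the best-supported Markov order by leave-one-out cross-validation with
additive smoothing.

It is aimed at bioacousticians and behavioural ecologists who annotate
vocal recordings and want a reproducible, testable path from raw
annotation logs to transition matrices and model comparison, without
touching audio.

## The model

**Segmentation.** Repeated calls of the same type separated by silent
pauses ≤ 0.5 s form a *bout*, which collapses to a single token.
Consecutive bouts with pauses ≤ 0.5 s join into one *call sequence*; a
longer pause starts a new sequence. Streams are segmented independently
per (individual, session).

**Markov chains.** A sequence c₁…cₙ is padded with m Start symbols and a
Stop symbol; an order-m chain models p(cᵢ | cᵢ₋ₘ…cᵢ₋₁) by
maximum-likelihood count ratios. Order 0 is the memoryless
relative-frequency ("chance") model. Start captures which calls initiate
sequences; Stop captures which calls terminate them.

**Chance deviation.** For a history h with n_h departures, n_hd of which
arrive at destination d, the score is log P(Bin(n_h, p_d) = n_hd) with
p_d the chance rate of d. It is ≤ 0, equals 0 only for a certain event,
and grows more negative the harder the observed count is to reconcile
with chance — in either direction.

**Bayesian alternative.** Each history's next-state distribution gets a
symmetric Dirichlet(α) prior; the posterior is Dirichlet(counts + α),
with closed-form means and credible intervals from seeded draws.

**Order selection.** Each order m ∈ {0,1,2,3} is scored by leave-one-out
cross-validation: hold out one sequence, fit on the rest, evaluate the
held-out log-likelihood with add-k smoothing, p(d|h) = (c_hd + k)/(c_h +
kD). Adjacent orders are compared by the mean per-sequence difference
with a ±2 SE band per smoothing constant k; the selected order is the
highest one whose band against the next-simpler model is strictly
positive for most k while the next-richer model's band is not.

Call types can also be collapsed into contextual categories (Alarm:
whistle; Food: chirp; Contact: phee, trill, twitter; Mobbing: ek, tsk)
and the same machinery run at category level.

## Worked example

The synthetic marmoset-like preset is an order-2 chain over the 7-type
repertoire (chirp, ek, phee, trill, tsk, twitter, whistle):

```python
from callseq import (fit_markov, chance_model, chance_loglik,
                     CVConfig, loo_cv, pairwise_differences, select_order)
from callseq.synthetic import marmoset_like_preset, generate_annotation_log
from callseq.annotation_io import segment, sequence_length_table

spec = marmoset_like_preset(n_sequences=2000, seed=1)
records, _ = generate_annotation_log(spec)          # timed call log
sequences = segment(records, spec.segmentation_config())
print("calls:", len(records), " sequences:", len(sequences))
print("length table:", sequence_length_table(sequences))

model = fit_markov(sequences, m=1)
stats = chance_loglik(model, chance_model(sequences))
for s in stats:
    if s.history == ("tsk",) and s.destination == "ek":
        print(f"tp(tsk->ek) = {s.tp:.2f}   loglik = {s.loglik:.1f}")
    if s.history == ("whistle",) and s.destination == "Stop":
        print(f"tp(whistle->Stop) = {s.tp:.2f}   loglik = {s.loglik:.1f}")

report = select_order(pairwise_differences(loo_cv(sequences, CVConfig())))
print("selected Markov order:", report.selected)
```

prints

```
calls: 6900  sequences: 2000
length table: {1: 1300, 2: 352, 3: 195, 4: 71, 5: 38, 6: 19, 7: 13, 8: 5, 9: 3, 10: 3, 12: 1}
tp(tsk->ek) = 0.63   loglik = -374.6
tp(whistle->Stop) = 0.96   loglik = -71.2
selected Markov order: 2
```

Reading this: the corpus is dominated by single-call sequences with a
tail of longer combinations. The mobbing call *tsk* continues to *ek*
with probability 0.63, and the very negative chance-deviation score says
this co-occurrence is far in excess of what the calls' base rates
predict; *whistle* almost always ends its sequence. Cross-validation
prefers the second-order model — the generating chain is order 2, and
its structure (e.g. chirp-x bigrams returning to chirp) is not reducible
to first-order transitions.

The same pipeline runs from the shell:

```bash
callseq simulate --n-sequences 2000 --seed 1 --out log.csv
callseq segment log.csv --out sequences.csv --summary summary.json
callseq fit log.csv --order 1 --out adjacency.csv
callseq compare log.csv --orders 0,1,2,3 --k 0.001,0.01,0.1,0.5,1 --out cmp.json
```

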