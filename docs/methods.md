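# Methods

## Segmentation model

The raw unit is an annotated call: (individual, session, context,
call_type, onset, offset) in seconds. Two rules build the analysis units:

* **Bouts.** Consecutive calls of the *same* type whose silent pause
  (next onset − current offset) is at most `max_gap` merge into one bout.
* **Sequences.** Consecutive bouts whose pause (next bout start −
  current bout end) is at most `max_gap` join one sequence; a longer
  pause opens a new one.

`max_gap` defaults to 0.5 s, the conventional inter-call threshold for
marmoset call combinations, and the boundary is inclusive by default (a
pause of exactly 0.5 s joins); both are configurable in
`SegmentationConfig`. Segmentation is done per (individual, session)
stream — focal recordings are bounded sessions, so sequences never span
streams — and overlapping calls within a stream are a hard error rather
than silently merged, since overlap should have been excluded at
annotation time. Because same-type neighbours within the gap always
merge, bout-collapsed sequences can never contain adjacent duplicate
tokens; this surfaces later as an exactly-zero diagonal in the
first-order call-type transition matrix.

Rare call types are removed by a generic min-count filter (default:
types occurring fewer than 2 times in the whole dataset) *before*
segmentation, so a dropped singleton cannot break a sequence in two
places asymmetrically across analyses.

## Markov chains with boundary states

For order m, each sequence c₁…cₙ is padded to
Startᵐ c₁ … cₙ Stop (the Stop symbol is optional via
`StateSpace.include_stop`). Every position after the padding contributes
one (history, destination) window, so a sequence yields n + 1
transitions at every order when Stop is modelled — including order 3
windows for a unigram, whose history is then partly Start. Probabilities
are maximum-likelihood count ratios per history. Order 0 has the single
empty history; its distribution over destinations is the corpus
relative-frequency ("chance") distribution.

The chance model is measured over *destination slots* of the padded
streams: every token occurrence plus one Stop per sequence (when Stop is
modelled). This keeps the chance distribution on exactly the outcome
space the transitions are scored against; a flag-controlled no-Stop
variant is available throughout.

## Chance-deviation score

The per-transition deviation statistic is the log binomial probability

  loglik(h → d) = log P(Bin(n_h, p_d) = n_hd),

with n_h the departures from history h, n_hd the arrivals at d, and p_d
the chance rate of d. Properties that motivated this default: it is
bounded above by 0, attains 0 only for a certain event, penalizes both
over- and under-represented transitions, and scales with the amount of
evidence (large, strongly non-chance cells get values in the hundreds of
negative log units). A likelihood-ratio mode, n_hd · log(p_d / tp), is
available behind `mode="ratio"`; note it is nonpositive only for
over-represented transitions. The mode used is recorded in every output
row. A transition observed at chance probability 0 scores −∞ rather than
raising.

## Smoothed sequence likelihood

Held-out scoring uses additive smoothing over the full cross-product of
possible histories and destinations: p(d|h) = (c_hd + k)/(c_h + kD),
where D is the number of possible destinations (tokens + Stop when
modelled). A history never seen in training therefore scores as the
uniform distribution 1/D. With k = 0 an unseen transition gives −∞ —
which is why cross-validation requires k > 0.

## Leave-one-out order comparison

For each held-out sequence, each order m ∈ {0,1,2,3} (configurable) and
each k in the grid {0.001, 0.01, 0.1, 0.5, 1.0}, the held-out
log-likelihood is computed under the model fitted to the remaining
sequences. The token alphabet is fixed from the full corpus before
folding: held-out sequences can contain unseen transitions (smoothing
handles those) but never unseen symbols. Leave-one-out fits are obtained
by subtracting the held-out sequence's own transition counts from the
full-corpus counts — algebraically identical to refitting, and verified
against explicit refits in the tests.

Adjacent orders are compared by per-sequence differences
loglik_m − loglik_{m−1}: their mean, the standard error across held-out
sequences (sample SD/√n, recorded in output metadata as the SE unit),
and the mean ± 2 SE band, per k. The selection rule picks the highest
order whose band against the next-simpler model is strictly positive
(lower bound > 0) for a strict majority of k values while the
next-richer comparison is not; if no order qualifies the lowest order is
returned with a warning flag. The whole comparison is deterministic.

**A boundary-state subtlety.** Any corpus of non-empty sequences has
P(Stop | Start-history) = 0, while the order-0 chance model gives Stop
its marginal frequency. A first-order model therefore genuinely beats
order 0 even on tokens drawn i.i.d., purely from the sequence-boundary
structure. This is a property of the Start/Stop representation, not an
artifact of the estimator: memorylessness in the padded-with-Stop
representation is only attainable by the no-Stop variant, and the
order-0 recovery property is accordingly tested there. It never inflates
selection beyond order 1.

## Bayesian transition posteriors

Each history's next-state distribution receives an independent symmetric
Dirichlet(α) prior over the full destination set (α = 1 by default,
exposed in `BayesConfig`). The posterior is Dirichlet(c + α): means are
closed-form, (c_d + α)/(Σc + Dα), so the point estimates are exact and
deterministic; equal-tailed credible intervals (95% by default) come
from seeded Dirichlet draws (4000 by default). As α → 0 or counts grow,
means converge to the MLE — on well-sampled histories the Bayesian and
MLE tables are practically identical, which the tests check at the 0.01
level for histories with hundreds of observations. Interval calibration
is checked by drawing truths from the prior, simulating counts, and
measuring empirical coverage.

## Contextual categories

The default scheme maps whistle→Alarm, chirp→Food,
phee/trill/twitter→Contact, ek/tsk→Mobbing. Mapping is token-for-token
and adjacent identical categories are *not* collapsed — two different
mobbing calls in a row are a real Mobbing→Mobbing self-transition, and
collapsing would erase exactly the self-loop the category analysis is
interested in. An optional filter drops whole sequences containing a
given category (e.g. Alarm) from higher-order category analyses, since a
call type absent from longer sequences contributes nothing there. Custom
schemes load from small YAML/JSON files.

## Synthetic data

The generator samples token sequences by walking a user-specified
fixed-order chain from the all-Start history until Stop (hard cap
`max_length`, with a warning rather than rejection, so generation always
terminates). Because sequences are non-empty by definition, a Stop drawn
at the first slot is rejected and redrawn; this conditions the corpus on
length ≥ 1 and is the source of the boundary effect described above.
Sequences are then laid out on a timeline: each token becomes a bout of
geometric(mean 2) calls of 0.1 s separated by 0.2 s; tokens are 0.3 s
apart, sequences 2.0 s apart. Gaps are fixed constants so round-trip
tests are exact: any generated log segments back to its ground-truth
sequences token for token, and this is the module's central tested
property (100 randomized specs).

Three ready-made chains define the study conditions:

* `marmoset_like_preset` — an order-2 chain over the 7-type repertoire
  shaped to echo qualitative features of marmoset call streams:
  unigram-dominated lengths with a tail to ~9 tokens (cap 12), whistle
  terminating with probability 0.95, tsk→ek at 0.66, tsk-ek mostly
  ending, and chirp-x bigrams returning to chirp at 0.5–0.87. It is
  illustrative, not calibrated to any recording dataset.
* `order2_benchmark_spec` — a 3-token "return" chain (after bigram
  (x, y), go back to x with probability 0.70, Stop 0.25) whose
  first-order marginals are nearly uninformative: the canonical
  non-factorizable second-order structure for order-recovery studies.
* `order1_benchmark_spec` / `order0_benchmark_spec` — a plain
  first-order chain and an i.i.d. token source.

What the generator does *not* emulate: acoustic variability and
classification error, per-individual repertoire differences, behavioural
context switching within a session, annotation jitter, and sequence
lengths beyond the cap. Passing tests therefore demonstrate correctness
of the segmentation, estimation and selection machinery under clean
conditions — not robustness of the biology to noisy annotation.

## Problem sizes and numerical choices

Order-recovery runs use 1000 sequences per corpus and 20 seeded
replicates per generator, with the default k grid; these sizes give
decisive bands for the benchmark chains while keeping the whole suite
fast. Probability rows are validated to sum to 1 within 1e-9; the
closed-form posterior means and the worked binomial value are asserted
to 1e-12. Ties in n-gram ranking break lexicographically. Zero-count
adjacency cells serialize as tp = 0 with an empty loglik field rather
than NaN. All randomness flows through seeded NumPy generators; the
pipeline stamps outputs with a hash of the analysis configuration and
reruns are byte-identical.

## Known limitations

Fixed-order chains only: no variable-length Markov trees, hidden states
or grammar induction. The chance-deviation statistic is a per-cell
descriptive score, not a corrected hypothesis test across cells. The
Dirichlet prior is symmetric and shared across histories (no hierarchy
across individuals). Selection compares only adjacent orders and
inherits the discreteness of the band rule near the support boundary.
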