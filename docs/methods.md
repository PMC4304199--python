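# Methods

## Model

Documents are bags of words. Under LDA with `T` topics, document `d` draws a
topic mixture `θ_d ~ Dirichlet(α·1_T)`, topic `k` draws a word distribution
`φ_k ~ Dirichlet(β·1_V)`, and each of the `n_d` tokens draws a topic
`z ~ Cat(θ_d)` then a word `w ~ Cat(φ_z)`. Inference integrates `θ` and `φ`
out (collapsed Gibbs): each token's assignment is resampled from

    P(z_i = k | z_-i, w) ∝ (n_dk^-i + α) · (n_kw^-i + β) / (n_k^-i + Vβ)

where the `-i` counts exclude token `i`. Point estimates are the smoothed
ratios `θ_dk = (n_dk + α)/(n_d + Tα)` and `φ_kw = (n_kw + β)/(n_k + Vβ)`,
taken from the final sweep by default (averaging retained samples is
available via `fit(..., average=True)`; averaging mixes topic labels across
samples only if the chain relabels, which it effectively never does on
corpora this size, but the single-sample default avoids the issue entirely
and is what the reported tables assume).

Defaults: `α = 0.1`, `β = 0.01` (sparse mixtures and topics), 1000 sweeps,
500 burn-in, every 10th sample retained. The sampler's inner loop is a numba
kernel; each sweep is seeded by a splitmix64 mix of the run seed and the
sweep index, so runs are bit-reproducible and a single `gibbs_sweep` call is
a pure function of (state, seed).

## Likelihood and model-order selection

With `φ` integrated out, `log p(w | z)` has the closed per-topic
Dirichlet-multinomial form

    Σ_k [ logΓ(Vβ) − V·logΓ(β) + Σ_w logΓ(n_kw + β) − logΓ(n_k + Vβ) ].

`estimate_log_likelihood` turns post-burn-in samples of this quantity into
the harmonic-mean estimate of the marginal likelihood `p(w)`, computed in
log space with a log-sum-exp guard. On enumerable instances the estimate is
within 0.01 nats of the exact marginal (the test suite checks 0.1).

The number of topics is **not** selected by that estimator. The harmonic
mean is consistent but heavy-tailed, and its well-known overestimation bias
grows with model dimension; on corpora of this shape (on the order of 100
documents of 200–400 tokens over a vocabulary of ~200 words) its argmax over
a topic grid degenerates to the largest candidate `T`, because finer topic
partitions can absorb per-document multinomial sampling noise and the
harmonic mean never charges for them. `select_num_topics` therefore scores
each candidate `T` by the posterior-mean **joint** log-likelihood
`log p(w, z) = log p(w|z) + log p(z)`, whose document-side
Dirichlet-multinomial term prices the fragmentation of documents across
topics. On synthetic corpora with 5 true topics this score peaks at 5 over
the grid {2, 5, 10, 20} (measured, e.g., −98141 at T=5 vs −99219 at T=10 and
−102040 at T=20) while the harmonic-mean score increases monotonically. Each
grid value is fitted with a fresh deterministic seed derived from the run
seed; ties break toward the smaller `T`.

## Preprocessing

Tokenization lowercases, splits on non-letters, and drops every
whitespace-delimited unit containing a digit ("5-fold" disappears entirely
rather than leaving "fold"). Three vocabulary filters follow: a bundled
English stop-word list (overridable; treated as data so results are
bit-reproducible), an explicit extra-removal list for hand-picked ubiquitous
words, and removal of words whose document frequency is strictly greater
than 0.8 (such words carry no discriminative signal). No stemming or
lemmatization. Documents left empty by filtering are kept at zero length so
row alignment with external tables survives, and their ids are reported.

## Seed-topic identification and flagging

Given seed drugs `S`, the seed topic is `argmax_j θ̄_j` with
`θ̄ = mean_{d∈S} θ_d`; ties break to the lowest topic index (as do all
ranking ties — documented, stable). The baseline is the mean of the
remaining entries of `θ̄`, equivalently `(1 − θ̄_j)/(T − 1)`.

Enrichment is tested by permutation: the statistic is the max-over-topics of
the seed mean; the null permutes each seed document's `θ` row independently
(topic labels carry no drug-specific information); `p = (1 + #{perm ≥ obs})
/ (1 + n_perm)` with `n_perm = 999` by default, so `p ∈ (0, 1]`. The
published significance claims name no test, so a permutation design is this
package's choice; it is exact up to Monte Carlo error and assumption-free.

Flagging applies the top-`k` criterion (`k = 3`): a non-seed drug is flagged
when the seed topic ranks among its `k` most probable topics. Flagged lists
are ordered by the seed topic's probability, descending.

## Verification

Evidence matching is case-insensitive substring search of lexicon phrases in
a whitespace-normalized evidence section. Substring (not token-boundary)
matching is the default because the lexicon mixes unigrams and multiword
phrases; "fatal" therefore also hits "fatality", which is accepted and can
be disabled with `word_boundary=True`. The shipped lexicon expands
"fatal/death" into its two component phrases. Drugs lacking the evidence
section are tiered `section_missing`, distinct from
`no_section_evidence`. External evidence tiers (regulatory labels,
spontaneous-report systems, literature) are deliberately out of scope; a
user-supplied annotation mapping can be attached to the summary.

## Synthetic corpora

The generator emulates the target regime: 100 documents of 200–400 content
words over a 200-word vocabulary, 5 topics, 26 seed documents. Topics are
symmetric-Dirichlet draws with `β_true = 0.05` (sparse, well-separated);
document mixtures use `α_true = 0.1`. The mixture sparsity is a deliberate
realism choice — per-drug narratives are dominated by one injury pattern —
and it is also what keeps the corpus informative end to end: with diffuse
mixtures (e.g. `α_true = 0.5`), documents of this length over so small a
vocabulary contain nearly every frequent word, pushing each topic's
characteristic words past the 0.8 document-frequency cutoff so that
preprocessing would strip exactly the discriminative vocabulary.

Seed documents get `+0.5` probability mass on the planted topic before
renormalization, putting their mean planted-topic probability near 0.5
against a 0.2 background — the direction of the worked example's 0.36 vs
0.02 contrast without asserting its values. Documents with true
planted-topic mass above 0.3 are "positive"; their evidence section contains
a lexicon phrase with probability 0.9 (0.1 otherwise), embedded in filler.
Vocabulary words are letter-only synthetic strings ("waa", "wab", …) —
digit-bearing tokens would be dropped by the tokenizer — and the last six
double as the evidence lexicon, so verification runs without English text.
Optional stop-word injection (`stopword_rate`) exercises the stop-word
filter; it lengthens rendered documents beyond the content-word range when
enabled (default off). Generation is a pure function of (spec, seed).

What passing synthetic tests do **not** show: real narratives have burstier
word use, correlated sections, section-length confounds and curated
vocabulary far larger than 200 words; recovery and sensitivity numbers on
the generator are upper bounds on what identical settings achieve on real
corpora.

## Numerical and design notes

- All counts are exact integers; `recount()` from `z` is the consistency
  oracle and is checked after every sweep in the tests.
- `θ`/`φ` rows sum to 1 within 1e-9 and are strictly positive by smoothing.
- Argmax and sort ties break to the lowest index everywhere.
- Degenerate inputs: empty documents get uniform `θ` rows; empty topics get
  uniform `φ` rows; `T = 1` makes every conditional `[1.0]` and sweeps are
  identities; seed-topic identification requires `T ≥ 2` (no baseline
  otherwise).
- Problem sizes in the test and acceptance runs (tiny enumerable instances;
  the default synthetic spec with 20 replicates; 10^5 thinned posterior
  samples) are chosen so the whole suite completes in a few minutes on one
  CPU while keeping Monte Carlo error well inside the asserted tolerances.
- The packaged worked-example table encodes only each drug's four largest
  topic probabilities; unlisted cells are zero. The truncation error is
  bounded by the printed fourth-ranked values and is absorbed by the
  two-decimal comparisons used on it.

## Known limitations

- No variational inference, asymmetric priors, streaming, or hyperparameter
  optimization (`α`, `β` fixed, as in the motivating analysis).
- The harmonic-mean marginal-likelihood estimate is reported per fit but is
  not a reliable between-model criterion; use the joint score (the default
  in `select_num_topics`).
- Substring evidence matching can overcount (documented above); lexicon
  quality drives verification quality.
- English-only tokenization; no handling of hyphenation variants beyond
  splitting on non-letters.
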