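# Methods

This note records the modeling assumptions, parameter choices and
numerical conventions of `threadstance`, and what the synthetic
experiments do and do not demonstrate.

## Tasks and data model

A corpus is a set of threads; a thread is a strictly time-ordered
sequence of posts (ties broken by post id), each with an author id and
raw text. Debate detection is sequence labeling over a thread's posts:
binary (debate / non-debate) or 4-class (CAM debate, breast-cancer
debate, other debate, non-debate), trained as two separate models.
Stance classification (pro-CAM / con-CAM) is defined only for posts
labeled as CAM debate and treats posts independently.

Preprocessing replaces emoticons from a fixed table with `EMO_*` code
tokens, strips other non-ASCII content, splits sentences with a
rule-based segmenter (terminal `.?!` followed by whitespace and a
capital, guarded by an abbreviation list), lowercases, and keeps
`? ! , ; :` as tokens because several engineered features count them;
sentence-final periods are dropped. The segmenter is deliberately
simple and frozen — golden-file tests depend on its exact output — and
is *not* a model of any external toolkit's behavior.

## The sequence model

- **Encoder.** Word embeddings (d = 50 by default) are initialized
  from CBOW vectors trained on the unlabeled corpus and fine-tuned
  during supervised training. Convolution uses the Frobenius inner
  product of a `d × k` filter with each width-k window, a bias, and
  tanh; max-over-time pooling takes one scalar per filter. Defaults:
  100 filters per width, widths 2–5 (h = 400). Out-of-vocabulary
  words map to a dedicated trainable embedding column; posts shorter
  than the widest filter are right-padded with zero columns (the
  padding is not trainable).
- **Highway layer** on the pooled vector, `z = t ⊙ tanh(A_H l + b_H) +
  (1 − t) ⊙ l` with `t = σ(A_T l + b_T)`; tanh was chosen as the
  transform nonlinearity to match the surrounding activations, and the
  gate bias is initialized at −1 so the carry path dominates early
  training.
- **LSTM** over the thread's post representations, hidden size
  m = 100 by default (a free choice; the task defines no value), zero
  initial state, forget-gate bias initialized at +1.
- **Output.** A softmax with one weight vector per label sized to the
  LSTM hidden dimension m. The per-post label distribution is computed
  from the hidden state *after* consuming the post, i.e.
  `Pr(y_t | p_{1:t})`; training minimizes the summed negative
  log-likelihood of each thread's label sequence.
- **Optimization.** Plain SGD, one thread per update
  (backpropagation through time over the full thread), learning rate
  0.05, global-norm gradient clipping at 5, 30 epochs by default,
  thread order shuffled each epoch by a seeded generator. All
  arithmetic is float64; with a fixed seed and a single worker, runs
  are bit-reproducible.
- **Ties.** Exact probability ties resolve to the first class in the
  ordering, which places the conservative class (NON_DEBATE, or
  PRO_CAM for stance — the majority stance) first.

The stance classifier reuses the CNN encoder with a softmax directly
on the pooled vector; no highway layer or recurrence.

Analytic gradients for every parameter group (embeddings, filters,
highway, LSTM, softmax) are hand-derived and verified against central
finite differences; the gradient check reports the norm-relative error
`‖a − n‖ / max(‖a‖, ‖n‖)` per parameter array, which avoids spurious
blow-ups on entries at the round-off floor of the difference quotient.

## Engineered-feature baseline

L1-penalized (lasso) logistic regression over, per post: thread-level
features (post count, distinct authors, mean post length); post-level
counts — mentions of other thread participants' author ids (whole-token,
case-insensitive), positive/negative sentiment adjectives from two
fixed lists expanded by a fixed suffix table (-s, -ly, and the
-ed ↔ -ing swap, e.g. frustrated → frustrating), CAM keywords from a
fixed 10-term list, non-stopword token overlap with the previous post
(multiset intersection), question and exclamation marks, time since
the previous post (clipped at 30 days so single huge gaps do not
dominate z-scoring), a signature flag (taken from the input data when
present, otherwise 0), agree counts, and disagree counts where an
"agree" preceded within two tokens by a negator (not, don't, dont,
never, cannot, can't) counts as disagreement; and lexical features —
LDA topic proportions (k = 15, α = 0.5, β = 0.05), the mean CBOW
vector, and the cosine similarity of each with the previous post's
vector (0 for the first post or when a vector is zero).

LDA is fitted by variational Bayes (scikit-learn); inference for a new
post runs a fixed 50-iteration EM over the frozen topic-word matrix,
so a fitted topic model is fully defined by its arrays and needs no
randomness at prediction time. CBOW is a single-threaded numpy
implementation with negative sampling (5 noise words, unigram^0.75
noise distribution, window 5, linearly decaying learning rate),
deterministic per seed.

Features are z-scored with statistics from the training fold only.
The penalty strength λ multiplies `‖w‖₁` against the summed log-loss
(the intercept is unpenalized); when unspecified it is chosen by an
inner stratified 3-fold accuracy grid.

## Evaluation protocol

Precision, recall and F are reported on the percent scale for a stated
positive class; zero-division cases return 0 with a warning. F is the
harmonic mean, so the all-positive baseline has recall 100 and
precision equal to class prevalence — at 16.3% prevalence F = 28.0,
at 30.9% F = 47.2, identities the test suite verifies through the
metrics code. Cross-validation partitions *threads* (never posts)
into k = 5 shuffled folds: the sequence model reads a post's full
preceding context, so post-level folds would leak test posts into
training context. Confidence intervals assume normality:
mean ± z₀.₉₇₅ · sd/√n over the 25 F scores obtained by re-randomizing
the fold assignment 5 times — re-randomized assignments, not a
bootstrap, which is one reading of a protocol that is ambiguous
between the two.

## Synthetic forum generator

The generator emulates the statistical structure the method assumes,
not English. Threads draw a topic-specific unigram distribution
(plus shared function words); a per-thread debate budget with mean
ρ·length is packed into episodes of 2–6 consecutive posts by 2–3
alternating authors and shuffled among the background posts, so the
expected debate prevalence equals the configured rate ρ with no
thread-edge bias, and every debate run has length ≥ 2 with ≥ 2 distinct
authors (a debate requires interaction). Defaults: 200 threads of
8–20 posts, ρ = 0.25, and a pro:con stance mixture of 0.68 inside CAM
episodes (the supportive-stance share observed in communities of this
kind), with both stances forced to appear in every CAM episode.

The context-dependence strength γ gates content cues: with
probability γ a debate post carries cues — the episode's opening post
an overt provocation (a mention of another participant, an
agree/disagree phrase, topic-type keywords, punctuation), later posts
only sparse reply cues (usually a mention, sometimes a phrase), and
CAM-debate posts stance-lexicon tokens. Crucially, background posts
emit the same cue types at fixed label-independent noise rates
(mentions 12%, questions 10%, polite agreement 5%, therapy keywords
10%, stance words 8%): single cues are ambiguous evidence, so per-post
classification is intrinsically imperfect while the run structure
makes context informative. At γ = 0 debate posts are textually
indistinguishable from background, so debate labels are independent of
content and any content-based classifier degenerates to the majority
predictor.

What passing tests on this generator show: that the implementation
can exploit cross-post context when it exists, and gains nothing when
it does not. What they do not show: performance on real forum text,
which has grammar, topic drift, sarcasm, quoting conventions and
annotation noise the generator does not model.

## Experiment scale

The reference experiments (`threadstance.experiments`, used by the
test suite and `scripts/acceptance.py`) run the full architecture at
reduced dimensions — 16-dim embeddings, 16 filters for each width
2–4, LSTM hidden size 16, 6 epochs, CBOW 8 iterations, 10 LDA topics —
so that a 2 × 5-fold comparison on a 200-thread corpus completes in a
few minutes on one core. Six epochs is deliberately short: it is
enough for the sequence model to exploit real cues (mean 5-fold F ≈ 80
at γ = 0.8, ≈ 11–14 points above the lasso baseline across seeds)
while stopping before the network memorizes label noise, which is what
lets the γ = 0 ablation collapse cleanly to the majority predictor.
The separability ("overfit") checks use 20 posts and ≤ 200 epochs.

## Known limitations

- The CNN–LSTM is unidirectional: a post's label distribution uses
  preceding posts only, so the first post of an episode gets no
  context benefit.
- Binary and 4-class debate models are trained separately; no shared
  parameters or multi-task objective.
- The baseline's signature feature depends on the input data carrying
  an author-signature flag; no extraction heuristic is attempted.
- `sample_for_coding` uses largest-remainder proportional allocation
  with a one-post-per-thread floor; other allocations satisfying the
  same coverage constraint exist.
- No GPU path, no minibatching across threads, no pretrained language
  models — the package optimizes for auditability over speed.
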