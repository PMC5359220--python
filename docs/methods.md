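# Methods

## Model

`hybridcat` simulates binary category judgments ("member" / "non-member")
about six-dimensional discrete stimuli under an explicit three-feature
rule, by trial-level competition between two classification procedures
that share one declarative memory.

**Declarative memory.** Each stored item (the rule, or a training
exemplar) is a chunk with a list of reference timestamps. Its activation
when queried at time `now` is the sum of (i) base-level activation
`ln(sum_j (now - t_j)^-d)` — a power-law-decayed trace of how often and
recently the chunk was used; (ii) for exemplar chunks, a partial-matching
score summing `+1` per feature the probe shares with the chunk and `-1`
per mismatch (scale 1); and (iii) transient logistic noise of scale
`s_act`, drawn independently per candidate per query. The
highest-activation candidate is retrieved iff its noisy activation clears
the threshold `tau`; retrieval takes `F e^(-A)` seconds, failure takes
`F e^(-tau)` seconds. For a single candidate this reduces exactly to the
logistic retrieval-probability form, which the test suite verifies by
Monte Carlo.

**Rule route.** Retrieves the rule chunk (cued by kind; no partial
matching over stimulus features) and answers "member" iff all three
rule-relevant features carry their required symbols. If retrieval fails
the response is a fair guess. The route never reads the irrelevant
dimensions, so it is structurally blind to the similarity manipulation.

**Exemplar route.** Cues memory with the full feature vector; a
successful retrieval of any training exemplar yields "member" (all stored
exemplars are category members), a failure yields a slow "no" carrying
the failure latency. This is the single-retrieval reading of an
exemplar-based random-walk process: one memory race per trial, not an
iterated accumulation (an explicit non-goal here).

**Route choice.** Each route carries a utility `U = P G - C + eps`
(`P = successes/(successes+failures)`, logistic noise of scale `s_util`);
the larger draw runs the trial. `bias_to_states(target)` inverts this
mechanism: it solves, by Brent root-finding on the exact two-draw win
probability (computed by numerical quadrature — the difference of two
logistic variables is not logistic), for the deterministic utility gap
giving the requested long-run exemplar share, and splits it symmetrically
around `P = 0.5`. Shares 0 and 1 clamp the estimates to the ends of
[0, 1]; the resulting utility gap of `G` makes a noise flip astronomically
unlikely (~e^-20), so these shares are deterministic in practice. In
supervised mode the used route's success or failure count is incremented
by the trial's true correctness (guesses are charged to the rule route,
which was the route selected); in unsupervised mode counts never change.

**Session.** The rule chunk is laid down at t = 0; the 12 training items
are presented three times each (555 ms encoding + inter-trial interval
per presentation, fresh shuffled order per pass), each presentation
appending a reference. After a retention gap, 96 test trials run in four
blocks of 24, six per compliance x similarity cell per block, shuffled
per run. Response time per trial = encoding (555 ms) + retrieval (or
failure) latency + two production firings + motor execution. Test items
are never stored; exemplar references are frozen after training, while
the rule chunk is strengthened on every successful use (this produces the
across-block speed-up and keeps the exemplar route's decision structure
stationary — with exemplar strengthening on, a frequently retrieved
exemplar's base level would cross the threshold mid-session and the
noise-free chance structure of the orthogonal design would dissolve).

## Stimulus generator

The generator emulates the rule-application materials structurally rather
than item-by-item: dimensions 0–2 are rule-relevant; dimensions 3–4 carry
similarity as a value *pair* (three trained pairs partition the training
set into thirds; three never-trained pairs mirror that structure for
low-similarity items, so the test set itself is similarity-balanced);
dimension 5 takes values unseen in training and unique within a group, so
every test item differs from every training item and from every other
test item. Non-compliant items violate exactly one rule dimension, with
the violated dimension balanced (8 per dimension per cell). Consequently
every item in a condition has an identical match-count multiset against
the training set — high-similarity items match one training third on 5 of
6 features (compliant) or 4 of 6 (non-compliant), low-similarity items
match every training item on 3 or 2 — and, noise-free, the exemplar route
accepts exactly the high-similarity half of the test set: 48 errors of
96, enforced as an exact test. Default alphabets are 6 symbols per
dimension (12 on the uniqueness dimension, the minimum guaranteeing
novelty plus within-group uniqueness).

What the generator does *not* emulate: pictorial rendering, perceptual
confusability, any secondary structure of the original item lists beyond
these match-count constraints. Model results here depend only on
match-count structure, so passing tests support the simulation logic, not
claims about perceptual encoding of real stimuli.

## Parameters

| parameter | default | units | status |
|---|---|---|---|
| `d` (base-level decay) | 0.5 | – | architecture default |
| `tau` (retrieval threshold) | 0 | activation | architecture default |
| `F` (latency factor) | 1 | s | architecture default |
| match / mismatch increment | +1 / −1, scale 1 | activation | task convention |
| `encode_s` | 0.555 | s | task convention |
| `step_s`, `motor_s` | 0.05, 0.21 | s | stage constants; cancel in RT differences |
| `G` (goal value) | 20 | s-equivalent | conventional; only relative utility matters |
| `s_util` (utility noise) | 1.0 | utility | unidentified: the share inversion conditions on it exactly |
| `iti_s` | 2 | s | procedural choice |
| `s_act` (activation noise) | 0.25 | activation | calibrated |
| `n_rule_rehearsals` | 9 | count | calibrated |
| `retention_gap_s` | 90 | s | calibrated |
| `prior_strength` (n0) | 100 | count | calibrated (supervised errors only) |
| `n_runs` | 50 | count | replication count for all reported means |

**Calibration** (`scripts/calibrate.py`). Four quantities have no
architectural default and are not identifiable a priori: the activation
noise scale, how well-practised the rule chunk is by test time (rehearsal
count), how aged the memory traces are at test (retention gap), and the
prior strength of the route-utility estimates. The first three were fixed
by a grid search minimising squared relative deviation of the
*unsupervised* sweep summaries (mean errors and RT effects at shares 0,
0.1, 0.5, 1.0) from their reference values, with the `s_act` grid limited
to the regime in which the design's retrieval-success structure — and
hence the error backbone — survives. The prior strength was then fixed by
matching the *supervised mean-error* references only, so the supervised
reaction-time behaviour is a genuine prediction of the frozen model, not
a fit.

## Numerical choices

- Logistic noise is sampled by inverse-CDF from the run's seeded
  generator; every run is a pure function of (config, master seed), with
  per-run and per-sweep-cell sub-seeds spawned via `SeedSequence`.
- Ties among equal noisy activations (possible only at `s_act = 0`) break
  uniformly at random.
- An RT cell with no correct trials is NaN, never imputed; condition
  means over runs use only runs where the effect is defined and report
  that count. At exemplar share 1.0 with the calibrated noise, a
  substantial fraction of runs have no correct low-similarity compliant
  trials at all.
- The similarity tables are min–max normalised to [0, 1] per table; only
  ordinal claims are made of them.
- Reported summaries use 50 replications x 96 trials per condition and a
  22-cell share x regime sweep (~10^5 simulated trials), a few minutes on
  one CPU.

## Known limitations

- **Reaction-time scale.** With the single-retrieval exemplar route, the
  error pattern and the RT-effect pattern are mutually constrained in a
  way that admits no joint solution: keeping exemplar-route accuracy at
  chance (the orthogonal design's structural signature, ~48 errors at
  share 1.0) requires activation noise small relative to the 2-unit
  activation gaps, and then a *correct* response to a low-similarity
  compliant item is necessarily a rare near-threshold retrieval costing
  ~`F` seconds. The simulated RT similarity effect therefore grows
  convexly with exemplar-route share (tens of ms at share 0.1, several
  hundred ms at share 1.0) rather than saturating around ~200 ms. Larger
  noise shrinks the effect but collapses the error structure. Within this
  architecture the only fix is a different latency model (e.g. an
  iterated-retrieval random walk), which is out of scope here.
- Feedback in supervised mode necessarily drives the model off the
  exemplar route, shrinking the similarity effect across blocks; the
  model cannot show simultaneously low errors and a large, stable
  similarity effect under feedback. This is a property of utility-based
  route competition, not of the calibration.
- Exemplar traces are frozen at test; incremental storage of classified
  test items is not simulated (the test set's similarity balance implies
  storage would not change the similarity structure on average — see the
  test-reference similarity tables — but the dynamics are unmodelled).
- Costs `C` are fixed per run (1.5 s per route, typical completion
  times); cost learning is not modelled.
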