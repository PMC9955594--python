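# Methods

## Model and assumptions

`castvote` implements rational sequential decision-making on a binary
question with one correct option. The assumptions are deliberately strong
and should be kept in mind when interpreting any output:

- Each respondent's *primary choice* is an independent Bernoulli draw,
  correct with probability equal to their ability p_n, with
  0.5 < p_n < 1 (a coin-flipper and an infallible respondent are both
  excluded; the open bounds are enforced by `AbilityProfile`).
- All abilities are common knowledge, every respondent observes all
  earlier answers (never the primary choices behind them), and every
  respondent maximises their *own* conditional probability of being
  correct, knowing that all predecessors did the same. Group-optimal
  (social-planner) behaviour is a different problem and is not modelled.
- Options are labelled relative to the first answer (`s` = same option as
  the first respondent, `t` = the other). The simulator and the
  enumeration oracle additionally carry an absolute truth label that the
  agents never see.

Under these assumptions the optimal answer of respondent n reduces to a
log-odds-weighted comparison over *casting voters* only — predecessors
whose answer equals their primary choice. The package's core recursion
(`run_sequence` / `optimal_answer`) classifies each respondent as casting
or non-casting and is, by the package's own brute-force check
(`bayes_optimal_answer`, which enumerates all antecedent primary-choice
vectors consistent with the observed answers and maximises the full
posterior), exactly equivalent to Bayesian-optimal behaviour. That
equivalence is asserted in the test suite for every primary-choice vector
on equal-ability chains and on seeded random distinct-ability profiles of
up to six respondents.

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `tol` | 1e-9 | log-domain tolerance for tie detection in all likelihood comparisons (dimensionless, log-odds units) |
| `n_runs` | 10 000 | Monte-Carlo replicates per simulation |
| `seed` | 0 (library) / CLI flag | master seed; one independent substream is spawned per replicate |
| `n_max` | 201 | search ceiling for the effective number of voters |
| p-grid | 0.55 … 0.95, step 0.05 | default ability grid for sweeps |

10,000 replicates make the binomial standard error of an accuracy
estimate at most 0.005, small enough to separate consecutive odd-order
performance steps for the abilities of interest; the same count is used
for the walk-absorption statistics.

## Tie handling

The generic theory assumes all subset odds products are distinct, and a
tie rule is only ever *needed* when abilities coincide. The package
applies one rule universally: when the absolute casting-vote log-odds
margin equals the respondent's own weight within `tol`, either option is
equally likely to be correct and the respondent adopts their primary
choice — and is classified a casting voter, since their answer reveals
that choice. For equal abilities this reproduces the "answer `s` when
|S| + 1 ≥ |T|" convention and makes the casting-vote difference
d = |S| − |T| a random walk on {−2, …, 2} absorbed at ±2; both the
absorption and its order-3 earliest hit are hard-asserted per run in
`d_walk_statistics`, not estimated. Validating full subset-product
distinctness is exponential, so `strict_distinct` profiles check pairwise
distinctness only and a tie event on such a profile logs a WARNING
(equal-ability profiles log the same event at DEBUG, because there ties
are the defined behaviour, occur on nearly every step, and a warning per
step would be noise).

## Numerical choices

- All likelihood comparisons are made in log space; conditional
  performance is computed as a two-term logistic of the log-likelihood
  gap, so chains of any length cannot underflow.
- `exact_curve` enumerates in the absolute truth frame and prunes on the
  casting classification: the chain state is the log-odds margin toward
  the correct option, which branches only at casting voters. States are
  merged on margins rounded to 12 decimals. The unpruned 2^n route
  (`exact_mean_performance`) is kept as an internal consistency check and
  agrees to 1e-12.
- `exact_curve(believed=...)` separates the abilities agents *use in
  their decision rules* from the abilities that govern correctness. The
  closed-form expert results fall out of the same engine: an aware expert
  uses their true weight (and is casting at |d| = 2 exactly when
  q > pi_max(p)); an unaware expert is modelled by a believed profile in
  which everyone, including the expert, carries the ordinary ability.
- The effective number of voters is defined as the *smallest odd n* whose
  simple-majority accuracy reaches pi_max(p): the defining equality
  generically has no integer solution. The real-valued threshold is
  exposed separately (`crossing_ability`, bisection via
  `scipy.optimize.bisect`, xtol 1e-10; for n = 5 it reproduces
  (3 + √3)/6 to nine decimals). The binomial tail uses
  `scipy.stats.binom.sf`.
- Computed effective committee sizes on the default grid are 7 for
  p < (3+√3)/6 and 5 above it (three voters never suffice:
  3p² − 2p³ − pi_max(p) has no root inside (0.5, 1)). Any prose summary
  that attaches the smaller committee to the *lower* ability range has it
  backwards; the package reports only computed values.
- Mean performance for equal abilities uses the parity index
  k = (n+1)/2 for odd n, n/2 for even n, which makes orders 2m−1 and 2m
  plateau in pairs — a direct consequence of absorption happening only at
  odd d-transitions.

## RNG discipline

`simulate` and `d_walk_statistics` spawn one `numpy` `SeedSequence` child
per replicate from the master seed and consume draws identically, so the
two functions see bit-identical trajectories for the same seed and
per-replicate results do not depend on execution order. Reports embed the
seed, and identical inputs reproduce bit-identical reports.

## What the generators emulate — and what they do not

`generate_profile` produces the three stock families the theory is
organised around: equal abilities, one expert among equals, and random
pairwise-distinct abilities (rejection-sampled uniform draws on
(0.55, 0.95) with a minimum gap of 0.01). These are idealised study
conditions: real groups feature miscalibrated or unknown abilities,
partial observation of predecessors, confidence signalling, deception and
self-chosen timing — none of which is modelled. Passing tests therefore
certify the mathematics of the idealised model, not predictions about
human groups.

## Known limitations

- Full enumeration is capped at 20 respondents; the pruned recursion
  handles long chains only as far as its state space stays small (always,
  for equal-ability and single-expert profiles; worst case 2^(#casting)
  for adversarial heterogeneous profiles).
- The brute-force optimal-weighting check is capped at 20 voters (2^N
  bipartitions).
- `three_person_analysis` treats ability ties within `tol` by the
  universal tie rule and warns; boundary cases between regions inherit
  the tolerance of the log-odds comparison.
- Problem sizes in the test suite (chains up to N = 20, oracle profiles
  up to N = 6 with all 2^(N−1) primary vectors, 10,000-replicate
  simulations) were chosen so the full mathematical claims are exercised
  while the suite stays fast; they are stated in the tests themselves.
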