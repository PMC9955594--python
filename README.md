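# castvote

Optimal sequential decision-making on binary questions, analysed through
**casting votes**.

`castvote` is for researchers in collective behaviour, social learning and
decision theory who want a reference implementation of the rational
(accuracy-maximising) model of sequential opinion formation: *N* respondents
answer a binary question (one correct option) in a fixed order; respondent
*n* privately holds a *primary choice* — correct with probability equal to
their ability *p<sub>n</sub>* ∈ (0.5, 1) — observes all earlier public
answers, and answers to maximise their own probability of being correct,
knowing everyone's abilities and that all predecessors behaved the same way.

## The model in brief

Label the first respondent's option *s* and the other *t*. The optimal rule
is a weighted vote with log-odds weights
*r\*<sub>n</sub>* = log[*p<sub>n</sub>*/(1 − *p<sub>n</sub>*)], but only over
**casting voters** — predecessors whose answer equals (and therefore
reveals) their primary choice. With *S* and *T* the casting voters who
answered *s* and *t*, respondent *n* compares

&nbsp;&nbsp;&nbsp;&nbsp;Δ = Σ<sub>m∈S</sub> *r\*<sub>m</sub>* − Σ<sub>m∈T</sub> *r\*<sub>m</sub>*

with their own weight *r\*<sub>n</sub>*: if |Δ| < *r\*<sub>n</sub>* their
primary choice is decisive (they are a casting voter themselves); otherwise
they follow the heavier side and reveal nothing. Non-casting voters drop out
of every likelihood — the likelihood that *s* is correct is
∏<sub>S</sub>*p<sub>m</sub>* ∏<sub>T</sub>(1 − *p<sub>m</sub>*), regardless
of how many followers tagged along. The respondent's maximised (conditional)
probability of being correct is the larger hypothesis weight over their sum,
always in [0.5, 1].

Consequences the package computes exactly, in closed form and by simulation:

- **Equal abilities** *p*: the casting-vote difference d = |S| − |T| is a
  random walk absorbed at ±2; mean performance of the *n*-th respondent is
  E[π<sub>n</sub>] = [*p*² + *p*(1 − *p*)(1 − 2*p*)(2*p*(1 − *p*))^(k−1)] / [*p*² + (1 − *p*)²],
  k = ⌈n/2⌉, rising from *p* to the bound
  π<sub>max</sub>(*p*) = *p*²/(*p*² + (1 − *p*)²) — a bound already matched
  by a *simultaneous* majority of only 5–7 independent voters (the
  *effective number of voters*, with threshold (3 + √3)/6 ≈ 0.79 between the
  two committee sizes).
- **Three respondents**: a complete case analysis of who follows whom,
  including the discontinuous drop in the third respondent's accuracy when
  the first respondent is abler than the second (the second then becomes a
  follower and reveals nothing).
- **One expert** of ability *q* among equals: performance *q* at any order
  if the expert knows *q* ≥ π<sub>max</sub>(*p*); otherwise the damped form
  π<sub>max</sub> − (π<sub>max</sub> − *q*)(2*p*(1 − *p*))^(k−1), which
  *decreases* with order for a strong but unaware expert.

## Worked example

A single chain with abilities (0.9, 0.6, 0.7) and primary choices
(s, t, t):

```
$ castvote run --abilities 0.9,0.6,0.7 --primaries s,t,t
index,ability,primary,answer,is_casting,conditional_performance
1,0.9,s,s,True,0.9
2,0.6,t,s,False,0.857142857143
3,0.7,t,s,False,0.794117647059
```

The first respondent's ability (0.9) beats everyone else's, so both
followers discard their primary *t* and copy *s* — an information cascade.
Their conditional performances (0.857, 0.794) are the posterior
probabilities that *s* is correct given what each saw; averaged over
primary-choice randomness, everyone's mean performance is exactly 0.9.

Monte-Carlo for nine equals of ability 0.7 (10,000 seeded runs):

```
$ castvote simulate --kind equal --p 0.7 --n 9 --runs 10000 --seed 42
# max_abs_d: 2
# cascade_rate: 0.5751
order,ability,accuracy,se,casting_fraction
1,0.7,0.7089,0.00454269512514,1
3,0.7,0.7868,0.0040956777217,0.4249
5,0.7,0.8208,0.00383519699624,0.1817
9,0.7,0.8411,0.00365582808677,0.0314
```

(every second row elided). Accuracy climbs at odd orders toward
π<sub>max</sub>(0.7) ≈ 0.845 but never reaches it: the casting-vote
difference is absorbed at ±2 (`max_abs_d: 2`), after which everyone
follows. The closed-form values (0.7, 0.784, 0.8193, 0.8403) sit within
three standard errors of every estimate. Compare with simultaneous
committees:

```
$ castvote effective-n --p-grid 0.6,0.7,0.8,0.9
p,pi_max,n_e,majority_at_ne
0.6,0.692307692308,7,0.710208
0.7,0.844827586207,7,0.873964
0.8,0.941176470588,5,0.94208
0.9,0.987804878049,5,0.99144
```

— an endless sequential chain is worth at most a seven-person simultaneous
vote. Other subcommands: `exact` (pruned exact enumeration for any
profile), `three-person` (phase structure of the three-respondent case as
data), `expert` (order-vs-performance for an expert among equals), `sweep`,
and `run`/`simulate` accept YAML profile files. The same functionality is
importable (`castvote.run_sequence`, `castvote.exact_curve`,
`castvote.simulate`, ...).

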