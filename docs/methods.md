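# Methods

## Model and assumptions

`healthtraj` operationalises health-trajectory management over a register of
patients with binary positive lifestyle factors and a binary adverse event
(early reoperation after TKA). The method rests on four assumptions: factors
are (at least partly) modifiable; every factor combination defines a group of
similar patients exposed to a similar risk; that risk is quantifiable per
combination; and combinations — hence groups — overlap, more specific
combinations giving smaller groups. Formal concept analysis is the natural
machinery: groups are formal concepts of the patients × factors context, and
the concept lattice orders them from the most general group (top, "no common
factors") to the most specific (bottom).

Analysis is always within one sex × age stratum (females split at 71 years,
males at 66, boundary ages counting as "younger"), because the strata have
materially different event rates; the lattice, risks and queries never mix
strata.

## Binarisation

Raw register fields map to five positive factors:

| factor | rule | default |
|---|---|---|
| `NoSmoking` | smoking ∈ {never, ex} | — |
| `lowBMI` | BMI < cutoff | cutoff 30 kg/m² |
| `Activity` | UCLA category ≥ threshold | threshold 5 (inactive = 1–4) |
| `Sport` | any of recreational / competitive / professional | — |
| `LongDistWalk` | can walk 1000 m | — |

The UCLA threshold follows the definition of the analysed factor (activity =
categories above four); the scale's descriptive "active = 4–6" wording is
not used. BMI exactly 30 is obese (the "31–35" band label in register tables
is display text). Unknown (`NA`) sport or walking values default to
`factor_absent` — the patient is not credited the protective factor but
stays in every denominator, which biases risk estimates conservatively;
`drop_record` is available as an alternative policy.

## Lattice construction

Concept intents are exactly the closed attribute sets; they are enumerated
with NextClosure in lectic order, which yields each concept exactly once in
O(|concepts| · |G| · |M|²) without storing candidate sets. The attribute
count is capped at 16 — the method is designed for a handful of binary
factors, and 2^|M| candidate intents must stay enumerable. Covering edges
are computed as the transitive reduction of strict intent inclusion by the
direct cubic scan (concept counts here are ≤ 2^5 + 1, so nothing faster is
warranted). For serialisation, concepts are always ordered by
(|intent|, lexicographic intent), making every output diff-stable. The test
suite cross-checks both enumeration and covering edges against brute-force
oracles (closure of every attribute subset; pairwise-inclusion definition of
covering) on randomized contexts.

A bottom concept with empty extent (no patient has all factors) is kept for
lattice structure but carries no risk row and is excluded from trajectories,
rankings and exports: the method is empirical and does not extrapolate to
unobserved factor combinations.

## Risk smoothing

Small concepts can have zero events, and a raw 0 % is not a usable estimate.
Each concept's proportion is shrunk toward the stratum rate with
pseudo-count mass *m*:

p_adj = (k + m·p_total) / (n + m), implemented in the algebraically
equivalent form p_total + (k − n·p_total)/(n + m) so the whole-stratum fixed
point is exact in floating point.

Properties (all tested): the whole-stratum concept is unchanged; groups
above the stratum rate are pulled down and groups below it up; zero-event
groups get strictly positive risk whenever the stratum has events; p_adj →
p_emp as m → 0 and → p_total as m → ∞; p_adj is strictly increasing in k at
fixed n. The default m = 10 means a concept of ten patients sits halfway
between its raw proportion and the stratum rate; m is exposed in
`SmoothingConfig` and on every CLI command. The mechanism is a design choice
of this package — it is the simplest estimator satisfying all the qualitative
requirements above — so absolute smoothed risks are not comparable with any
particular register analysis, only their structure is.

Reliability classes: a concept holding at least 10 % of the stratum
(configurable) is `green`; otherwise a zero-event concept is `red` (its
estimate is prior-driven); everything else is `yellow`. The share test takes
precedence, so a large zero-event group is still judged by its size.

## Edge labels and trajectories

The percent label of a lattice edge is 100·(p_from − p_to)/max(p_from,
p_to), rounded half-away-from-zero to an integer, positive for reductions.
Using the larger probability as denominator in both directions makes adding
and removing the same factor report the same magnitude — the convention that
reproduces all the printed worked-example labels simultaneously. The
undefined case p_from = p_to = 0 (possible only in a stratum with no events)
raises in `edge_reduction`; ranking code maps it to a flat 0 instead of
failing.

Trajectories follow covering edges only (one closure step at a time;
multi-factor changes appear as chained steps), require strictly decreasing
p_adj with an absolute tie tolerance of 1e−12, and are capped by default at
one step per attribute. Enumeration returns every valid chain including the
trivial singleton, so the set is prefix-closed by construction; output order
is final risk ascending, then length, then intent sequence. What-if queries
recompute the placement of the modified factor set and report the signed
change; a multi-factor improvement is additionally decomposed into one
shortest covering-edge path (whose individual steps need not be monotone —
only trajectories are).

## Synthetic data

The simulator emulates the register's study conditions: four strata of
670/520/275/420 patients, per-stratum factor prevalences equal to the
published marginals, and per-stratum no-factor baselines calibrated so the
marginal stratum rate equals the published 4.0 %/4.8 %/10.9 %/6.4 % given
the protective effects (baseline = rate / Π_j (1 − prev_j·(1 − r_j))).
Factors are Bernoulli draws, independent by default because only marginal
prevalences are published; an optional single-latent Gaussian copula
(`correlation`) induces positive co-occurrence for stress tests. The outcome
is Bernoulli with probability baseline × Π risk ratios of present factors,
clipped to [0, 1]; risk ratios are multiplicative (not odds ratios) so they
compare directly with edge reductions. The default protective risk ratio is
0.7 per factor — a moderate effect chosen once as realistic for lifestyle
factors. Raw fields (BMI value, UCLA category, smoking level, ages inside
the stratum ranges) are back-filled consistently with the drawn binary
factors; the simulator does not generate `NA` sport/walk values.

The deterministic fixture reproduces the published per-stratum category
counts cell-for-cell (BMI bands, smoking, activity, sport including the NA
rows, reoperations; 1885 patients in total). Long-distance walking is absent
from the published table; prevalences of 14 % (older females) and 22 %
(older males) are stated in the text, and 20 % is used for the other strata.
The joint distribution is unknown, so each column is filled independently
and shuffled with a seed-0 generator; reoperation events are then assigned
to the patients with the fewest protective factors (ties by position). That
allocation makes protective trends point the right way qualitatively but is
the strongest possible confounding-free pattern, so fixture effect sizes are
illustrative only. The UCLA middle band is coded as category 5 so the
published band counts coincide with the `Activity` factor counts — the
reading consistent with the published in-text activity prevalences.

What passing tests show, and do not show: the synthetic cohorts have
independent (or exchangeably correlated) factors and exactly multiplicative
effects, so parameter recovery there validates the estimator's arithmetic
and ranking logic, not its behaviour under real-world confounding,
selection, or non-multiplicative interactions.

## Parameter-recovery study design

Recovery runs use one 50 000-patient stratum, baseline 0.10, twenty seeds,
risk ratios (0.4, 0.55, 0.7, 0.85, 1.0) and **equal** prevalences (0.4),
because the risk observed from the top concept for a single-factor group
scales as r/(1 − prev·(1 − r)) — monotone in r only at fixed prevalence, so
unequal prevalences can legitimately reorder concept-level risks relative to
the risk ratios. The ranking check is per-seed (≥ 95 % of seeds must match);
the ±0.05 accuracy check is on the per-factor mean across seeds, since a
single-seed estimate has a sampling SE of ~0.02–0.03 and one hundred
simultaneous single-seed checks would fail by chance alone.

## Numerical and degenerate-input choices

* All user-facing percentages round half-away-from-zero (via `decimal`),
  matching clinical reporting conventions; Python's built-in banker's
  rounding is never used for display values.
* Empty-extent concepts: kept in the lattice, no risk row, excluded from
  moves/trajectories/exports; placements onto them are flagged `in_data =
  False` and rendered as "no data for this combination".
* `empirical_risk(·, 0)` returns NaN as the undefined-marker rather than
  raising, so tables can carry the row.
* Duplicate patient ids, unknown attributes, attribute counts over 16,
  removing a factor the patient lacks, and adding one they already have are
  all hard errors.
* Exports are pure functions of (lattice, risks, format); node ids follow
  the sorted concept order, so identical inputs give byte-identical files.
  DOT output is written by a small deterministic emitter (the graphviz
  ecosystem writers are not dependency-free); GraphML round-trips through
  networkx with attribute types preserved.

## Known limitations

* The method is descriptive: no confidence intervals, hypothesis tests or
  covariate adjustment on concept risks; confounding between correlated
  factors is not controlled.
* Only binary factors are supported (≤ 16); many-valued or fuzzy scaling is
  out of scope.
* Trajectories carry no temporal or adherence model — they order factor
  changes by risk, not by feasibility.
* The fixture's joint factor distribution and event allocation are
  synthetic constructions constrained only by published marginals; analyses
  of real registers will differ in all joint quantities.
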