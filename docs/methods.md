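# Methods

## The combinatorial object

A decomposition is a cyclic sequence of positive integers (knob-to-knob
distances) over a distance alphabet, summing to the period. Two
conventions define "non-redundant":

1. **Rotational equivalence.** `[3,3,4]`, `[3,4,3]` and `[4,3,3]`
   describe the same repeating contact pattern; only one representative
   is reported. We fix the lexicographically smallest rotation as the
   canonical representative — any deterministic choice works, and this
   one makes set comparisons and file outputs stable.
2. **Primitivity.** A sequence that is a repetition of a shorter one
   (`[3,4,3,4] = [3,4]×2`) describes the shorter period and is excluded.
   A sequence is primitive exactly when its number of distinct rotations
   equals its part count.

The default alphabet is {3, 4, 7}: the two sub-helical contact spacings
compatible with the ~3.6-residues-per-turn α-helix, plus the full heptad
7 = 3+4. The alphabet is configurable everywhere (distances must be
integers ≥ 2, strictly increasing); all defaults and golden counts pin
it to {3, 4, 7}.

## Enumeration by concatenation

For each period `i` from the smallest distance upward:

* if `i` is itself an alphabet distance, `[i]` is a member;
* for every split `i = x + (i−x)` with `min ≤ x ≤ i/2`, every
  concatenation of a stored rotational copy of a decomposition of `x`
  with one of `i−x` is a candidate. A candidate is rejected if it is
  non-primitive or any rotation of an already-accepted member of period
  `i`; on acceptance all its rotational copies are stored, so later
  duplicates are recognised by a set lookup.

Concatenating *rotational copies* on both sides (rather than canonical
representatives only) is deliberate: completeness — that every primitive
rotation class of mass `i` arises from some such concatenation — is not
assumed but *verified*, by exact agreement with two independent routes
for every period up to 60 (test suite and acceptance script):

* **Brute force.** Depth-first generation of all ordered alphabet
  sequences summing to the period; rotation classes are merged by
  popping a sequence, removing all its rotations from the pool, and
  keeping the class iff it is primitive.
* **Möbius counting.** With `L(m, k)` the number of ordered compositions
  of `m` into exactly `k` alphabet parts, the number of primitive
  rotation classes is `P(n) = Σ_k (1/k) Σ_{d | gcd(n,k)} μ(d) L(n/d, k/d)`.
  All arithmetic is exact (Python big integers, sympy's μ and divisor
  lists); the per-`k` sums are asserted to be divisible by `k`.

A consistency identity ties the linear and cyclic worlds together and is
tested for all `n ≤ 60`: every ordered sequence of mass `n` is a unique
rotation of a unique primitive class of some divisor period, hence
`x[n] = Σ_{d|n} Σ_{D ∈ P(d)} len(D.parts)`.

Explicit enumeration refuses periods above a cap (default 80, override
available) because the member count grows like `1.29ⁿ/n`; counting has
no cap and is instant at periods in the hundreds. The test suite and the
acceptance checks run the three-way verification to period 60, which
keeps the exhaustive brute-force sweep to a few million sequences and
well inside a couple of minutes on one core; the construction itself is
verified by the same property at every smaller period, and nothing about
it changes character beyond that range.

## Classification

Run lengths of 3s and of 4s are counted **cyclically** (wrap-around), so
`demanding` (a run ≥ 2, i.e. an adjacent 3+3 or 4+4) and `long run`
(a run ≥ 3) are rotation-class properties. Linear counting on the
canonical representative would agree on the published spot checks but
would depend on the representative chosen; cyclic counting is the
well-defined choice. Edge conventions: a single-part sequence `[v]` has
run length 1 (no self-wrap), an all-equal sequence has run length equal
to its part count, and runs of 7 are ignored by both classifiers — a 7
is a full heptad and imposes no extra strain.

## Extraction from knob tracks

Residue indices are 0-based (readers accept `--one-based` and convert).
Occasionally contact detection marks two neighbouring residues, giving a
unit distance that is an artefact, not a period feature. The collapse
rule keeps, from any such pair, the residue closest to the N-terminus;
implemented as a greedy N→C scan (keep the first position; keep each
later one iff it is ≥ 2 residues past the last kept one). For runs of
three or more consecutive contact residues — beyond the pairwise case
the rule was designed for — the same scan keeps every other residue, and
the result is flagged (`long_collapse`) so such tracks can be audited.

The extracted decomposition is the **full observed distance list**
(period = total span): observed periods run an order of magnitude above
the smallest distances, so reduction to the primitive rotation class is
a separate, opt-in step (`--reduce`). Distances outside the alphabet
(2, 5, 6, 8, ...; 1 is impossible after collapse) are kept and flagged
as irregular rather than dropped, so a fraction-regular statistic can be
formed downstream.

## Two-group comparison

Per metric, a Levene test decides at α = 0.05 whether the demanding and
non-demanding groups may share a variance; Student's pooled t-test is
used when they may, Welch's t-test (Welch–Satterthwaite df) otherwise.
Choices where the procedure is underdetermined, fixed once:

* Levene centring = **median** (the Brown–Forsythe variant, the default
  of the routine this gate mirrors); `center="mean"` is available.
* The variance gate's α defaults to 0.05 and is exposed as `--alpha`.
* Both t-tests are two-sided.
* No multiple-testing correction across the three metrics.
* `max_period_dev` is the highest **absolute** deviation of local
  periodicity from 3.5. A signed "highest deviation" reading is
  conceivable; absolute deviation is the symmetric, range-like choice
  consistent with the other two metrics, and the comparison machinery is
  agnostic to which is supplied.

The gate makes the overall procedure a two-stage test; its operating
characteristics are checked by simulation, not assumed: under the null
(both groups from one normal) the rejection rate at α = 0.05 stays
within three-sigma binomial error of 0.05 over 2000 seeded replicates,
and at the observed effect scale (means 0.112 vs 0.071, sd 0.05, 25 per
group) simulated power is well above one half.

## Synthetic data

`generate_knob_track` inverts extraction: positions are cumulative sums
of a chosen decomposition repeated `repeats` times; with probability
`unit_pair_rate` per knob (after the first — the first must stay the
track's origin), a partner residue is inserted one position downstream.
This is the only irregularity with a fully specified handling rule, so
it is the only noise injected by default; extraction of a noisy track
recovers the clean one exactly, which the suite asserts at rate 1.0.

`generate_metrics_table` draws the three metrics per group from
independent normals, clipping negatives to 0 (all three are
non-negative by construction). Defaults mirror the observed data shapes:
25 demanding of 2284 records, and group means 0.112/0.071 (period
deviation), 0.109/0.085 (period range), 0.713/0.622 Å (radius range).
Only the means and group sizes have observed anchors; the spreads are
free parameters, set once at sd 0.05 for the two periodicity metrics and
0.35 Å for the radius range — roughly half the group mean, a realistic
dispersion for range-type geometry summaries, and wide enough that the
radius-range comparison is *not* a foregone rejection. The default
unit-pair rate is 0.05, matching the rarity of unit distances among
observed irregular distances.

What the generator does **not** emulate: correlation between the three
metrics within a structure, any dependence of the metrics on the
specific decomposition (only on its demanding label), non-normal or
heteroskedastic metric distributions, and irregular-distance patterns
beyond unit pairs. Passing tests therefore demonstrate the correctness
and calibration of the machinery, not distributional claims about real
coiled coils.

## Known limitations

* No general Frobenius number for three or more pairwise non-coprime
  distances is attempted; only Sylvester's two-coin formula is provided,
  cross-checked against the linear counter.
* Knob detection from 3D coordinates, database ingestion, and the
  computation of local periodicity/radius profiles are out of scope; the
  package starts from position tracks and metric tables in plain TSV.
* Heteromeric coiled coils with per-chain decompositions are treated as
  independent tracks; no pairing logic.
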