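# Methods

## Problem and model

`ivifmea` ranks medical-error types for remediation from expert judgments of
three attributes: severity (impact of harm), preventability (how readily the
error can be stopped before it reaches a patient, playing the role
detectability plays in classical FMEA) and occurrence/frequency. Judgments
are categorical linguistic codes; every code maps to an interval-valued
intuitionistic fuzzy (IVIF) number `(a, b; c, d)` — membership interval
`[a, b]`, non-membership interval `[c, d]`, `b + d ≤ 1` — whose residual
hesitation interval `π = [1−b−d, 1−a−c]` carries the raters'
indecision through every later step instead of discarding it.

The operational algebra is the standard probabilistic-sum/product pair:

* `x + y = (a₁+a₂−a₁a₂, b₁+b₂−b₁b₂; c₁c₂, d₁d₂)`
* `x · y = (a₁a₂, b₁b₂; c₁+c₂−c₁c₂, d₁+d₂−d₁d₂)`
* `λx = (1−(1−a)^λ, 1−(1−b)^λ; c^λ, d^λ)` for `λ > 0`
* `x^λ = (a^λ, b^λ; 1−(1−c)^λ, 1−(1−d)^λ)` for `λ > 0`

The exponentiation rule is the dual of scalar multiplication; it is the
unique dual choice satisfying `complement(x)^λ = complement(λx)`, it makes
`x^(w₁+w₂) = x^w₁ · x^w₂` exact (the identity behind weight
renormalization), and it reproduces the reference ideal-case and importance
tables from the bundled aggregated inputs. `0^λ` is 0 for `λ > 0`, which is
what collapses the ideal case's lower membership bound to 0.

Multi-rater pooling uses the IIFWA weighted average
`(1−Π(1−a_k)^λ_k, 1−Π(1−b_k)^λ_k; Π c_k^λ_k, Π d_k^λ_k)` with nonnegative
rater weights summing to 1. It is idempotent, permutation-invariant and
componentwise bounded by the inputs. Raters are equally weighted by default
(the assumption used for the bundled case study); when a rater skips a cell
the remaining weights are renormalized within that cell, which preserves the
weight constraint without imputing a rating.

## Scales

Severity and preventability share one six-row vocabulary (grades EI…LI,
numeric codes 1…6 as aliases); all of its IVIF components are strictly
positive because the importance path raises them to fractional powers and a
zero would annihilate every downstream score. Occurrence uses a nine-term
order-of-magnitude ladder ("Rare" < 1 in 10⁸ up to "Extremely High" = 1 in
10), each term owning one probability decade so raw probabilities or
count/exposure pairs classify directly. Bands are half-open `[lo, hi)` with
the top band closed: an exact edge value (e.g. 1/100) joins the
higher-frequency term, the conservative choice for safety screening. The
exposure denominator for count data is always supplied by the caller — the
package never guesses whether it is patients, admissions or tests.

## Rankings

**Index scores** (occurrence known). Each error's weighted RPN
`S^wS · D^wD · O^wO` (defaults `0.387 / 0.334 / 0.279`) is compared to its
ideal case — the same product with occurrence pinned at "Rare" — by the
similarity measure

    S(A,B) = [4 − Σ|Δμ| − Σ|Δν| + Σπ] / [4 + Σ|Δμ| + Σ|Δν| + Σπ],

where the sums run over both interval bounds and `Σπ` adds all four
hesitation bounds of the pair. Ranking is ascending: the error least similar
to "rarely happens" has top priority. `S` is symmetric, lies in `[0, 1]` and
equals 1 iff the operands are equal; high hesitation drives it toward 1.

Two numerical caveats, both verified in the test suite. First, the
entropy-of-median route (`S = E(M(A,B))` with the median operator built from
the four `M_i` quantities) coincides with the ratio form exactly when the
pair shares its non-membership interval — the regime of the defining worked
example — and deviates otherwise, because the `|Δν|` terms enter the two
denominators with opposite signs; the ratio form is the definition used for
scoring, as it is the one that reproduces the bundled reference index table.
Second, the median operator itself can leave the IVIF domain on extreme
pairs (e.g. `(0,0;0,1)` vs `(0,1;0,0)`); this raises a computation error
rather than returning a malformed number.

**Importance scores** (occurrence unknown or untrusted). The
severity × preventability product with renormalized exponents
`wS/(wS+wD), wD/(wS+wD)` is scored by the generalized improved score

    GIS(a,b;c,d) = (a+b)/2 + k₁·a·(1−a−c) + k₂·b·(1−b−d),  k₁+k₂ = 1,

and ranked descending at each point of a `k₁` grid (default
`{0, 0.25, 0.5, 0.75, 1}`), with a stability flag that is true when the
ranking is identical across the grid. GIS is affine in `k₁`, so stability is
equivalent to no pairwise score difference changing sign on the grid. Note
that GIS is **not** confined to `[0, 1]` on the full IVIF domain
(`GIS((0.8,1;0,0), k₁=1) = 1.06`) and is not globally monotone in `a`
(`∂GIS/∂a = ½ + k₁(1−2a−c)` turns negative for large `a`); the score is
therefore neither clamped nor asserted into the unit interval. On the
renormalized importance products of realistic panels, whose hesitation is
moderate, scores stay well inside `[0, 1]`.

Rank ties (in either ranking) break lexicographically by error code, stably.

## Bundled case study

The package ships an 18-error case study spanning the four categories of a
national safety-reporting taxonomy (laboratory, medication,
general/surgical, patient-related), with severity and preventability
pre-aggregated over a 122-member health-worker panel, the survey-derived
attribute weights, and reference index/importance reports for
cross-checking. Raw rater-level data for the panel were never published, so
the aggregated matrices are the earliest reproducible boundary and are
treated as first-class input.

Per-error occurrence levels are likewise not part of the published inputs;
the file `occurrence_levels_derived.csv` was **reverse-derived** by
inverting the reference RPN column under the algebra above (the assignments
land within 0.001 of the printed quadruples for 17 of 18 errors) and is
flagged as derived, not observed.

Known internal inconsistencies of the reference data, shipped verbatim:

* **Error I0a**: its recorded severity `(0.410, 0.528; 0.331, 0.472)` cannot
  reproduce its own reference RPN or importance row (off by up to 0.008); a
  severity `a ≈ 0.434–0.440` would reconcile all tables, so the recorded
  0.410 is almost certainly a transcription slip. The bundled inputs are not
  silently corrected, and the corresponding reproduction test documents the
  mismatch rather than hiding it.
* **Errors I1g vs gd**: their full-precision importance scores differ by
  ~2·10⁻⁴ with a sign flip between `k₁ = 0.75` and `k₁ = 1`, so the
  reference report's fixed ordering of the two (and its claim of rank
  stability across the grid) holds only at 3-decimal rounding; the package's
  stability flag computes False on this data.
* Two aggregated rows print `b + d = 1.001`, one rounding unit over the IVIF
  sum constraint. Validation allows exactly one 10⁻³ unit of slack on the
  sum check (and 10⁻⁹ elsewhere) so that 3-decimal report data load as
  printed.

## Synthetic panels

`synthesize_panel` fabricates rating panels: each rater draws one code per
error and attribute independently from a per-attribute categorical
distribution, with equal rater weights by default or Dirichlet-drawn weights
for stress tests, all from a single seeded generator (fixed seed ⇒ identical
panel). It emulates size and structure of a real expert survey — including
missing-cell handling and weight renormalization — but deliberately not its
harder features: raters are independent and exchangeable, with no
inter-rater correlation, no systematic leniency/severity bias, and no
error-specific expertise. Passing recovery tests (point-mass panels recover
the scale value exactly; a 50/50 mixture at 10⁴ raters matches the IIFWA of
the mixture within 0.01) therefore validates the aggregation arithmetic, not
the sociology of real panels.

## Problem sizes and determinism

All computations are closed-form; the largest routine test aggregates a
10⁴-rater synthetic panel, and the property suites run on 10³ random valid
operands from fixed seeds. `run_analysis` is fully deterministic: the report
metadata digests the input file contents and analysis parameters, and two
runs on identical inputs produce byte-identical reports. Report CSVs round
to 3 decimals to match the reference layout; `report.json` keeps full
precision.

## Limitations

* Attribute weights are consumed as configuration; the survey methodology
  that produced the defaults is out of scope.
* Rater reliability/expertise weighting is not modeled (equal weights, or
  user-supplied ones).
* Alternative accuracy functions and similarity families are not bundled;
  the scoring functions are small and pure, so substituting one is a
  one-function change.
* Trend monitoring of error counts over time is reporting-only; no trend
  statistic is computed.
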