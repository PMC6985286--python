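# Methods

## Model and assumptions

The package treats endpoint (stagnant-phase / steady-state) abundances as
the observable and models pairwise interactions through a linear abundance
balance per focal species. In a binary culture the scaled balance is
x_i^B − x_i^A = b_ij^B x_j^B; in a community of N species it becomes
x_i^C − x_i^A = Σ_{j≠i} b_ij^C x_j^C. The original (per-capita) form divides
both sides by x_i^A. The balance is consistent with a generalized
Lotka–Volterra model evaluated at steady state, but only the endpoint is
used — trajectories are never required to follow gLV dynamics.

Assumptions worth stating explicitly:

* **Endpoint validity.** Cultures have reached stagnant phase; a single
  endpoint per culture (with replicates) carries the interaction signal.
* **"No growth" is a small abundance, not missing data.** An abundance of 0
  (or below the detection limit) is read as presence below detection. This
  is what makes the scaled coefficients well defined at x_i^A = 0.
* **Minimal adjustment.** Among all coefficient vectors satisfying a complex
  community's balance, the realized one is assumed closest (Euclidean) to
  the binary coefficients. The prediction is the orthogonal projection
  b^C = b^B + λx with λ = (d_i − b^B·x)/(x·x).
* **Row-wise comparability of the scaled form.** b-coefficients share the
  hidden factor x_i^A within a focal row i, so they can be compared across
  influencers j and as relative changes, but not across rows. Relative
  changes (b^C − b^B)/b^B are identical between the two forms whenever both
  are defined; the package tests this to 1e−10.

## Identifiability

An ordered pair (i ← j) is classified by four growth flags (i axenic,
j axenic, i in binary, j in binary). The original estimator needs i to grow
axenically and both species to grow in the binary culture; the scaled
estimator needs only the influencer j to grow in the binary culture (the
affected species may be absent axenically, in the binary culture, or both —
the coefficient is then 0 or negative). Flags are the ground truth; the
Roman-numeral case labels I–VIII are a reporting convention: I/II (both
estimators), V/VI (scaled only), IV/VII (neither; parameters), III/VIII
(a species growing axenically but extinguished in co-culture — ecologically
rare, flagged excluded). On the packaged four-member interdependent pattern
this yields 4/12 (original) vs 8/12 (scaled) identifiable coefficients, the
unidentifiable four all involving the doubly-dependent species CT.

Unidentifiable coefficients default to 0 (neutral interaction) and can be
assigned per pair; `strict` mode refuses to predict with unassigned
parameters and names them.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `detection_limit` | 0 | abundance below which growth is called absent (units of the data); at 0, any positive abundance counts as growth. Exposed because published datasets rarely state the limit used. |
| `aggregation` | mean | replicate aggregation before ratio formation (ratio of means); `median` available |
| `form` | scaled | coefficient form; `original` needs axenic growth of every focal species |
| sweep grid | 41 points over [−5, 5] | covers the parameter magnitudes relevant for scaled coefficients of order 1 |
| neutral-sign tolerance | 1e−6 × max row magnitude | separates structural zeros from numerical noise in scenario comparison |
| noise `sigma` | 0.05 | multiplicative lognormal scale (SD of the log perturbation), of the order of the replicate variability reported for qPCR endpoint data |
| abundance scale | log-uniform in [1e4, 1e8] | qPCR-copy-number-like synthetic abundances (unitless) |

Growth calls use *strict* positivity: a species grows iff its aggregate
abundance is > 0 and ≥ the detection limit; with the default limit of 0 an
abundance of exactly 0 is "no growth".

## Numerical choices

* The projection is the closed form above; a row already on the hyperplane
  (|d − b·x| ≤ 1e−12·max(1, |d|)) is returned unchanged, which makes the
  projection exactly idempotent.
* Partners with zero complex abundance remain dimensions of the projection;
  their coefficients are adjusted by λ·0 = 0 (absent neighbors are not
  modulated).
* A focal row whose partners all have zero abundance is a vacuous constraint
  when d_i = 0 (row returned unchanged with a warning) and an inconsistency
  error otherwise.
* Sensitivity slopes are central finite differences at the grid point
  nearest the baseline; trajectories are affine in the swept parameter, so
  the step size is immaterial (checked by vanishing second differences).
* TSV serialization uses 12 significant digits; percentages in reports are
  rounded to one decimal only at presentation.
* Prediction coverage counts coefficient (i, j) in context C as predictable
  iff every binary coefficient of focal row i over partners with nonzero
  complex abundance is estimated (no assignment needed). This is the
  package's explicit convention; other conventions (e.g. requiring the
  whole matrix, or counting per focal row) give different percentages for
  partially identifiable communities.

## Ratio bias and noise

Binary estimators are ratios, and with 3–5 replicates the mean of ratios
differs from the ratio of means. `ratio_bias` enumerates the full Cartesian
product of replicate choices (27 combinations for triplicates) and reports
both aggregates and their relative difference; combinations with zero
denominators are excluded and counted. The pipeline default is ratio of
means: it is defined even when single combinations are degenerate, and the
scaled estimator is linear in its numerator variables, so with a single
denominator replicate the two aggregates coincide exactly.

Measurement noise is modelled as multiplicative lognormal, x → x·exp(ε),
ε ~ N(0, σ²): it preserves the growth/no-growth pattern exactly (zeros stay
zero) and is seed-reproducible. `robustness_curve` reports median and IQR of
elementwise prediction error against a reference over repeated perturbations.

## Synthetic data generator

The generator inverts the model: given a growth pattern and scaled binary
truth coefficients it (1) draws per-species abundance scales, (2) solves the
two-equation endpoint system of each co-growing binary pair simultaneously
(x_i = x_i^A + b_ij x_j, x_j = x_j^A + b_ji x_i) so that estimation on the
generated abundances reproduces the truth exactly at σ = 0, (3) derives the
coefficients that are *forced* by the pattern (an affected species absent
from a binary culture has b = −x_i^A/x_j^B; a species growing alone against
an absent partner keeps x^B = x^A), and (4) constructs complex truth rows as
the projection of the binary truth, optionally displaced by a random vector
*inside* the constraint hyperplane (`adjustment_magnitude`) to emulate
communities that deviate from minimal adjustment while still balancing
abundances. A `steady_state` mode instead solves (I − B)x = x^A so the
binary rows already satisfy every complex constraint (zero-modulation
datasets). A syntrophic pair (co-growth without any axenic growth) is
feasible only on the degenerate ray b_ij·b_ji = 1 with a free abundance
scale; the generator supports it and rejects anything else as infeasible.
Infeasible truths (forcing non-positive abundances or co-growth collapse)
raise a generation error rather than silently clipping.

What the generator emulates: growth-pattern-driven identifiability,
endpoint consistency, replicate noise of lognormal type, qPCR-like abundance
scales. What it does not: temporal dynamics, compositional (relative
abundance) distortion, higher-order interaction terms, non-lognormal error,
or deviations of real communities from the linear endpoint balance itself.
Passing recovery tests therefore demonstrate correctness of the estimators
and projection under the model's own assumptions, not that real communities
obey the minimal-adjustment rule.

## Design choices made where the design was open

* **Case labelling.** The eight-scenario table is stored as growth flags;
  the numeral mapping (documented above) cannot affect identifiability.
* **Simultaneous binary solve.** Sequentially setting each affected species'
  abundance from the partner's draw cannot satisfy both orderings of a
  co-growing pair at once; the 2×2 solve is the only construction under
  which the round-trip invariant holds exactly.
* **Coverage convention** as stated under numerical choices.
* **Parameter selection is left to the user.** Sweeps report profiles and
  slopes; the package deliberately provides no objective criterion for
  picking a value of an unidentifiable coefficient, since any such choice
  encodes external biological evidence.
* **Problem sizes.** Property tests use 100–200 random instances (with 1000
  random feasible competitors per projection instance) and 50 noise trials
  per sigma; these sizes make the Monte-Carlo checks stable at the asserted
  tolerances while keeping the suite fast.

## Known limitations

* Scaled coefficients are not comparable across focal rows; only relative
  statements survive the scaling.
* One balance equation per focal species means the projection, not the data,
  resolves the remaining N−2 degrees of freedom; conclusions inherit the
  minimal-adjustment hypothesis.
* Unidentifiable parameters set to 0 bias predictions toward "no
  interaction"; the sensitivity machinery quantifies, but cannot remove,
  that uncertainty.
* The detection limit applied in published growth/no-growth calls is usually
  unknown; it is exposed as configuration rather than guessed.
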