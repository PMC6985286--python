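# miia — neighbor-dependent microbial interaction inference

Microbial interspecies interactions are context dependent: the way species
*j* affects species *i* changes when new neighbors join the community.
`miia` infers such reorganizations from the most tractable kind of data a
community experiment produces — **endpoint abundances** (stagnant-phase or
steady-state densities, e.g. 16S qPCR copy numbers) of cultures of varying
membership: axenic (one species), binary (two), and complex (three or more).

It is aimed at microbial ecologists and synthetic-community engineers who
have culture-combination endpoint data and want signed, directed interaction
networks per community context, including for consortia whose members
cannot be grown alone (syntrophy).

## The method

**Binary coefficients.** For an ordered pair (i, j) — the effect of
influencer *j* on affected *i* — with axenic abundance x_i^A and binary
co-culture abundances x_i^B, x_j^B:

    a_ij^B = (x_i^B − x_i^A) / (x_i^A · x_j^B)      (original form)
    b_ij^B = (x_i^B − x_i^A) / x_j^B  = x_i^A · a_ij^B   (scaled form)

The original form is the per-capita interaction strength (derivable from a
generalized Lotka–Volterra model at steady state). The **scaled form** stays
defined when i cannot grow axenically (x_i^A = 0, read as presence below the
detection limit) — the common situation for metabolically interdependent
species. Its values are comparable only within a focal row and as relative
changes.

**Minimal interspecies interaction adjustment.** In a complex community C
the focal balance

    x_i^C − x_i^A = Σ_{j≠i} b_ij^C · x_j^C

is one equation in N−1 unknown coefficients: a hyperplane of feasible
solutions. The minimal-adjustment rule selects the point on that hyperplane
closest (Euclidean) to the binary coefficients — an orthogonal projection
with closed form b^C = b^B + λx, λ = (d_i − b^B·x)/(x·x). Both forms give
*identical relative changes* Δ_ij = (b_ij^C − b_ij^B)/b_ij^B, so predictions
of interaction *shifts* do not require axenic data.

**Identifiability and sensitivity.** Pairs whose influencer never grows in
the binary culture are unidentifiable in either form; they become adjustable
parameters (default 0) explored by one-at-a-time sweeps. Two sign rules hold
for positive abundances: a parameter's own predicted coefficient responds
with slope in [0, 1], and every other coefficient of the same focal row
responds with slope ≤ 0 (a compensatory trade-off). Scenario comparison
classifies each predicted edge as robust or case-dependent across parameter
choices.

## Worked example

```python
from miia import MIIA, make_fixture, random_dataset

# four-member consortium where only PT and BA grow axenically and CT grows
# in no binary culture (synthetic data following that growth pattern)
dataset = random_dataset(make_fixture("kato4"), seed=11)
results = MIIA(dataset.observations, assignments={("CT", "CS"): 2.5}).fit()
print(results.summary())
```

prints (abridged):

```
Minimal Interspecies Interaction Adjustment Results
=====================================================
form:                 scaled
species:              BA, CS, CT, PT
cultures observed:    15
binary coefficients:  8/12 estimated (66.7%)
unidentifiable:       BA<-CT, CS<-CT, CT<-CS, PT<-CT
assigned parameters:  CT<-CS=2.5

Binary interaction matrix (row = affected, column = influencer):
       BA     CS CT     PT
BA          0.29  ?  -0.22
CS  0.621         ?  0.291
CT      0      ?         0
PT  -0.85  0.864  ?

Complex-community predictions:
  BA+CS+PT: coverage 100.0%
              BA        CS        PT
    BA       NaN  0.304276 -0.195391
    CS  0.599897       NaN  0.251951
    PT -0.849829  0.863743       NaN
  ...
```

Reading this: 8 of the 12 ordered binary coefficients are estimable in the
scaled form (the four involving CT as a participant are not, because CT
grows in no axenic or binary culture — they are the adjustable parameters);
the CS-PT-BA ternary is fully predictable from data alone (coverage 100%),
and e.g. the effect of CS on PT barely changes from binary (0.864) to
ternary (0.8637) while BA's inhibition of PT persists (−0.85). Sweeps and
scenario robustness are available as `results.sweep("CT<-CS")` and
`results.compare_scenarios([...])`.

The same pipeline is scriptable from a shell:

```sh
miia simulate --fixture kato4 --seed 11 --sigma 0 --out-dir run/
miia estimate run/abundance.tsv --form both --out-dir run/
miia predict run/abundance.tsv run/binary_scaled.tsv --out-dir run/ --graphml
miia sweep run/abundance.tsv run/binary_scaled.tsv --pair 'CT<-CS' --out-dir run/
```

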