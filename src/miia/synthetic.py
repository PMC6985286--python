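"""Model-consistent synthetic communities with known ground truth.

The generator manufactures endpoint abundance sets whose binary cultures
satisfy the scaled pairwise model exactly and whose complex-community
coefficients are, by construction, the orthogonal projection of the binary
truth (optionally displaced *along* the constraint hyperplane to emulate real
communities that deviate from minimal adjustment while still satisfying the
abundance balance).  Two packaged growth-pattern fixtures mirror the
structure of well-studied consortia:

* ``kato4`` — a four-member cellulose-degrader consortium (CS, CT, PT, BA)
  with strong growth interdependencies: only the aerobes PT and BA grow
  axenically, CT grows in no binary culture, and only PT and BA co-grow in
  the CT-PT-BA ternary.
* ``wang3`` — a three-member soil consortium (LL, JL, LP) in which every
  species grows in every membership.

Abundances are unitless, qPCR-copy-number-like (default scale drawn
log-uniformly from [1e4, 1e8]).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .binary import (
    STATUS_ESTIMATED,
    STATUS_UNIDENTIFIABLE,
    BinaryCoefficient,
    BinaryCoefficientSet,
    Pair,
    classify_flags,
)
from .core import CoefficientMatrix, project_row
from .data import (
    CommunityObservation,
    GrowthPattern,
    ObservationSet,
    membership_key,
    parse_membership,
)
from .exceptions import GenerationError, MembershipError
from .replicates import NoiseSpec

FIXTURE_NAMES = ("kato4", "wang3")

#: default abundance scale bounds (log-uniform draw), qPCR-copy-number-like
DEFAULT_ABUNDANCE_RANGE = (1e4, 1e8)

#: lognormal spread of per-species means around the dataset scale
DEFAULT_SPREAD = 0.25


@dataclass(frozen=True)
class GrowthPatternFixture:
    """A named growth/no-growth pattern over a full membership lattice."""

    name: str
    roster: Tuple[str, ...]
    pattern: GrowthPattern


def _all_growth_pattern(roster: Sequence[str]) -> GrowthPattern:
    calls = {}
    for size in range(1, len(roster) + 1):
        for combo in itertools.combinations(roster, size):
            key = membership_key(combo)
            for sp in combo:
                calls[(sp, key)] = True
    return GrowthPattern(calls)


def _kato_pattern() -> GrowthPattern:
    roster = ("BA", "CS", "CT", "PT")
    grows_axenic = {"PT", "BA"}
    binary_growers = {
        ("CS", "PT"): {"CS", "PT"},
        ("BA", "CS"): {"CS", "BA"},
        ("BA", "PT"): {"PT", "BA"},
        ("CT", "PT"): {"PT"},
        ("BA", "CT"): {"BA"},
        ("CS", "CT"): set(),
    }
    ternary_growers = {
        ("CS", "CT", "PT"): {"CS", "CT", "PT"},
        ("BA", "CS", "CT"): {"CS", "CT", "BA"},
        ("BA", "CS", "PT"): {"CS", "PT", "BA"},
        ("BA", "CT", "PT"): {"PT", "BA"},
    }
    calls: Dict[Tuple[str, str], bool] = {}
    for sp in roster:
        calls[(sp, membership_key((sp,)))] = sp in grows_axenic
    for combo, growers in binary_growers.items():
        key = membership_key(combo)
        for sp in combo:
            calls[(sp, key)] = sp in growers
    for combo, growers in ternary_growers.items():
        key = membership_key(combo)
        for sp in combo:
            calls[(sp, key)] = sp in growers
    quaternary = membership_key(roster)
    for sp in roster:
        calls[(sp, quaternary)] = True
    return GrowthPattern(calls)


def make_fixture(name: str) -> GrowthPatternFixture:
    """Return a packaged growth-pattern fixture (``kato4`` or ``wang3``)."""
    if name == "kato4":
        return GrowthPatternFixture("kato4", ("BA", "CS", "CT", "PT"), _kato_pattern())
    if name == "wang3":
        roster = ("JL", "LL", "LP")
        return GrowthPatternFixture("wang3", roster, _all_growth_pattern(roster))
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def make_custom_fixture(
    roster: Sequence[str], grows: Mapping[Tuple[str, str], bool]
) -> GrowthPatternFixture:
    """Build a custom fixture from an explicit growth map."""
    if not grows:
        raise MembershipError("custom fixture requires a non-empty growth map")
    pattern = GrowthPattern(grows)
    roster_t = tuple(sorted(set(roster)))
    if set(pattern.roster) - set(roster_t):
        raise MembershipError("growth map mentions species outside the roster")
    return GrowthPatternFixture("custom", roster_t, pattern)


@dataclass
class SyntheticDataset:
    """Ground-truth coefficients plus generated observations."""

    roster: Tuple[str, ...]
    truth_binary: BinaryCoefficientSet
    truth_complex: Dict[str, CoefficientMatrix]
    observations: ObservationSet
    seed: int
    noise: NoiseSpec
    adjustment_magnitude: float
    clip_events: Tuple[str, ...] = ()

    def truth_json(self) -> str:
        payload = {
            "roster": list(self.roster),
            "seed": self.seed,
            "noise": {
                "sigma": self.noise.sigma,
                "seed": self.noise.seed,
                "n_replicates": self.noise.n_replicates,
            },
            "adjustment_magnitude": self.adjustment_magnitude,
            "clip_events": list(self.clip_events),
            "binary": {
                f"{i}<-{j}": (
                    None
                    if self.truth_binary.coefficients[(i, j)].value is None
                    else self.truth_binary.coefficients[(i, j)].value
                )
                for (i, j) in self.truth_binary.pairs
            },
            "complex": {
                key: {f"{i}<-{j}": v for (i, j), v in sorted(m.entries.items())}
                for key, m in sorted(self.truth_complex.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _solve_binary_pair(
    i: str,
    j: str,
    x_iA: float,
    x_jA: float,
    b_ij: float,
    b_ji: float,
    mu_j: float,
) -> Tuple[float, float]:
    """Simultaneous endpoint abundances of a co-growing binary pair.

    Solves x_i = x_iA + b_ij x_j, x_j = x_jA + b_ji x_i.  A syntrophic pair
    (neither grows axenically) is consistent only on the degenerate ray
    b_ij * b_ji = 1; the free scale is then set by mu_j.
    """
    det = 1.0 - b_ij * b_ji
    if x_iA == 0.0 and x_jA == 0.0:
        if abs(det) > 1e-9:
            raise GenerationError(
                f"syntrophic pair {i}-{j} requires b_ij*b_ji = 1 "
                f"(got {b_ij * b_ji:.6g})"
            )
        if b_ij <= 0 or b_ji <= 0:
            raise GenerationError(
                f"syntrophic pair {i}-{j} requires positive mutual coefficients"
            )
        x_j = mu_j
        return b_ij * x_j, x_j
    if det <= 1e-12:
        raise GenerationError(
            f"binary pair {i}-{j}: truth coefficients give a singular or "
            f"unstable endpoint system (1 - b_ij*b_ji = {det:.3g})"
        )
    x_i = (x_iA + b_ij * x_jA) / det
    x_j = (x_jA + b_ji * x_iA) / det
    return x_i, x_j


def generate_dataset(
    fixture: GrowthPatternFixture,
    truth_binary_values: Mapping[Pair, float],
    seed: int = 0,
    adjustment_magnitude: float = 0.0,
    noise: NoiseSpec | None = None,
    abundance_range: Tuple[float, float] = DEFAULT_ABUNDANCE_RANGE,
    spread: float = DEFAULT_SPREAD,
    complex_mode: str = "random",
    clip_tol: float = 1e-9,
) -> SyntheticDataset:
    """Generate a model-consistent dataset with known ground truth.

    Parameters
    ----------
    fixture
        Growth pattern defining who grows where.
    truth_binary_values
        Scaled binary coefficients for the co-growth pairs (both species grow
        in their binary culture).  Coefficients of pairs whose affected
        species does not grow in the binary culture are forced by endpoint
        consistency (b_ij = -x_iA / x_jB) and derived by the generator; a
        supplied value for such a pair must match.
    adjustment_magnitude
        Euclidean norm of a random displacement applied to each complex truth
        row *within* the constraint hyperplane; 0 makes the complex truth the
        exact projection of the binary truth.
    complex_mode
        ``"random"`` draws complex abundances freely; ``"steady_state"``
        solves (I - B) x = x_A so the binary rows already satisfy every
        complex constraint (no modulation).
    noise
        Multiplicative lognormal replicate noise; default sigma 0 with three
        replicates.
    """
    if complex_mode not in ("random", "steady_state"):
        raise ValueError(f"unknown complex_mode {complex_mode!r}")
    rng = np.random.default_rng(seed)
    noise = noise or NoiseSpec(sigma=0.0, seed=seed, n_replicates=3)
    pattern = fixture.pattern
    roster = fixture.roster
    lo, hi = abundance_range
    if not (0 < lo <= hi):
        raise ValueError("abundance_range must satisfy 0 < lo <= hi")
    scale = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
    mu = {sp: scale * rng.lognormal(0.0, spread) for sp in roster}
    clip_events: List[str] = []

    x_axenic = {
        sp: (mu[sp] if pattern.grows_in(sp, (sp,)) else 0.0) for sp in roster
    }

    # --- binary cultures -------------------------------------------------
    truth_values: Dict[Pair, float] = {}
    abundances: Dict[str, Dict[str, float]] = {
        membership_key((sp,)): {sp: x_axenic[sp]} for sp in roster
    }
    for i, j in itertools.combinations(roster, 2):
        key = membership_key((i, j))
        gBi = pattern.grows_in(i, key)
        gBj = pattern.grows_in(j, key)
        if gBi and gBj:
            try:
                b_ij = float(truth_binary_values[(i, j)])
                b_ji = float(truth_binary_values[(j, i)])
            except KeyError as exc:
                raise GenerationError(
                    f"truth value required for co-growth pair {exc.args[0]}"
                ) from None
            x_i, x_j = _solve_binary_pair(
                i, j, x_axenic[i], x_axenic[j], b_ij, b_ji, mu[j]
            )
            clipped = {}
            for sp, val in ((i, x_i), (j, x_j)):
                if val <= 0:
                    if -clip_tol * scale <= val:
                        # rounding-level negativity: clip and record, but a
                        # co-growing species at abundance 0 contradicts the
                        # pattern, so this remains an error
                        clip_events.append(f"{sp} in {key} clipped to 0")
                    raise GenerationError(
                        f"truth forces non-positive abundance for {sp} "
                        f"in {key} ({val:.6g})"
                    )
                clipped[sp] = val
            abundances[key] = clipped
            truth_values[(i, j)] = b_ij
            truth_values[(j, i)] = b_ji
        elif gBi != gBj:
            grower, dead = (i, j) if gBi else (j, i)
            if x_axenic[grower] <= 0:
                raise GenerationError(
                    f"{grower} grows alone in {key} but has no axenic growth; "
                    "the endpoint model forces x^B = x^A"
                )
            x_g = x_axenic[grower]
            abundances[key] = {grower: x_g, dead: 0.0}
            forced = (0.0 - x_axenic[dead]) / x_g
            supplied = truth_binary_values.get((dead, grower))
            if supplied is not None and not np.isclose(supplied, forced, atol=1e-12):
                raise GenerationError(
                    f"supplied truth for {dead}<-{grower} ({supplied}) conflicts "
                    f"with the endpoint-forced value {forced:.6g}"
                )
            truth_values[(dead, grower)] = forced
        else:
            if x_axenic[i] > 0 or x_axenic[j] > 0:
                raise GenerationError(
                    f"no growth in {key} but a member grows axenically; "
                    "infeasible under the endpoint model"
                )
            abundances[key] = {i: 0.0, j: 0.0}

    truth_binary = BinaryCoefficientSet(roster, "scaled")
    for i, j in itertools.permutations(roster, 2):
        key = membership_key((i, j))
        cls_ = classify_flags(
            pattern.grows_in(i, (i,)),
            pattern.grows_in(j, (j,)),
            pattern.grows_in(i, key),
            pattern.grows_in(j, key),
        )
        if cls_.scaled_ok:
            # store the exactly realized coefficient so estimation on the
            # generated abundances round-trips bit-for-bit at sigma = 0
            realized = (abundances[key][i] - x_axenic[i]) / abundances[key][j]
            truth_binary.add(
                BinaryCoefficient(i, j, realized, "scaled", STATUS_ESTIMATED, cls_.case)
            )
        else:
            truth_binary.add(
                BinaryCoefficient(i, j, None, "scaled", STATUS_UNIDENTIFIABLE, cls_.case)
            )

    # --- complex cultures -------------------------------------------------
    complex_keys = [
        key for key in pattern.memberships if len(parse_membership(key)) >= 3
    ]
    if complex_mode == "steady_state":
        steady = _steady_state_abundances(roster, truth_binary, x_axenic, pattern)
    truth_complex: Dict[str, CoefficientMatrix] = {}
    for key in sorted(complex_keys, key=lambda k: (len(parse_membership(k)), k)):
        members = parse_membership(key)
        if complex_mode == "steady_state":
            x_c = {sp: steady[key][sp] for sp in members}
        else:
            x_c = {
                sp: (mu[sp] * rng.lognormal(0.0, spread)
                     if pattern.grows_in(sp, key) else 0.0)
                for sp in members
            }
        abundances[key] = x_c
        entries: Dict[Pair, float] = {}
        for i in members:
            partners = [j for j in members if j != i]
            x = np.array([x_c[j] for j in partners])
            b_row = truth_binary.row(i, partners)
            d_i = x_c[i] - x_axenic[i]
            row_C, _ = project_row(b_row, x, d_i)
            if adjustment_magnitude > 0 and len(partners) >= 2 and float(x @ x) > 0:
                v = rng.standard_normal(len(partners))
                v -= (v @ x) / (x @ x) * x
                norm = np.linalg.norm(v)
                if norm > 0:
                    row_C = row_C + adjustment_magnitude * v / norm
            for j, val in zip(partners, row_C):
                entries[(i, j)] = float(val)
        truth_complex[key] = CoefficientMatrix(key, "scaled", entries)

    # --- observations with replicate noise ---------------------------------
    noise_rng = np.random.default_rng(noise.seed)
    observations = []
    for key in sorted(abundances):
        members = parse_membership(key)
        obs_values = {}
        for sp in members:
            x = abundances[key][sp]
            if noise.sigma > 0 and x > 0:
                eps = noise_rng.normal(0.0, noise.sigma, size=noise.n_replicates)
                obs_values[sp] = tuple(x * np.exp(eps))
            else:
                obs_values[sp] = (x,) * noise.n_replicates
        observations.append(CommunityObservation(members, obs_values))

    return SyntheticDataset(
        roster=roster,
        truth_binary=truth_binary,
        truth_complex=truth_complex,
        observations=ObservationSet(observations, detection_limit=0.0),
        seed=seed,
        noise=noise,
        adjustment_magnitude=float(adjustment_magnitude),
        clip_events=tuple(clip_events),
    )


def _steady_state_abundances(
    roster: Sequence[str],
    truth_binary: BinaryCoefficientSet,
    x_axenic: Mapping[str, float],
    pattern: GrowthPattern,
) -> Dict[str, Dict[str, float]]:
    """Solve (I - B) x = x_A per complex context so that binary rows satisfy
    the complex constraints exactly (on-hyperplane datasets)."""
    out: Dict[str, Dict[str, float]] = {}
    for key in pattern.memberships:
        members = parse_membership(key)
        if len(members) < 3:
            continue
        growers = [sp for sp in members if pattern.grows_in(sp, key)]
        B = np.zeros((len(growers), len(growers)))
        for a, i in enumerate(growers):
            for b, j in enumerate(growers):
                if i != j:
                    B[a, b] = truth_binary.value(i, j)
        xa = np.array([x_axenic[sp] for sp in growers])
        try:
            x = np.linalg.solve(np.eye(len(growers)) - B, xa)
        except np.linalg.LinAlgError:
            raise GenerationError(
                f"steady-state system singular for context {key}"
            ) from None
        if np.any(x <= 0):
            raise GenerationError(
                f"steady-state abundances non-positive in context {key}; "
                "truth infeasible for on-hyperplane generation"
            )
        ctx = {sp: 0.0 for sp in members}
        ctx.update(dict(zip(growers, x)))
        # non-growing members with axenic growth would violate the endpoint
        # balance (d_i = -x_iA cannot be met by zero partners contribution
        # alone in general); reject such patterns here
        for sp in members:
            if not pattern.grows_in(sp, key) and x_axenic[sp] > 0:
                raise GenerationError(
                    f"steady-state mode cannot satisfy d={sp} in {key}"
                )
        out[key] = ctx
    return out


def random_dataset(
    fixture: GrowthPatternFixture,
    seed: int = 0,
    magnitude_range: Tuple[float, float] = (0.2, 0.9),
    p_negative: float = 0.4,
    max_attempts: int = 50,
    **kwargs,
) -> SyntheticDataset:
    """Draw a feasible random truth for a fixture and generate a dataset.

    Coefficient magnitudes are uniform in ``magnitude_range`` (|b| < 1 keeps
    the binary endpoint system well-posed); signs are negative with
    probability ``p_negative`` except where positivity is required (an
    affected species without axenic growth needs a promotive partner).
    Draws are retried until the endpoint system is feasible.
    """
    rng = np.random.default_rng(seed)
    pattern = fixture.pattern
    roster = fixture.roster
    last_error: Exception | None = None
    for attempt in range(max_attempts):
        truth: Dict[Pair, float] = {}
        for i, j in itertools.combinations(roster, 2):
            key = membership_key((i, j))
            if not (pattern.grows_in(i, key) and pattern.grows_in(j, key)):
                continue
            gAi = pattern.grows_in(i, (i,))
            gAj = pattern.grows_in(j, (j,))
            if not gAi and not gAj:
                b_ij = float(rng.uniform(*magnitude_range))
                truth[(i, j)] = b_ij
                truth[(j, i)] = 1.0 / b_ij  # syntrophic ray
                continue
            for affected, partner_axenic in (((i, j), gAi), ((j, i), gAj)):
                mag = float(rng.uniform(*magnitude_range))
                if not partner_axenic:
                    sign = 1.0  # growth only with partner: promotive
                else:
                    sign = -1.0 if rng.random() < p_negative else 1.0
                truth[affected] = sign * mag
        gen_seed = int(rng.integers(0, 2**31 - 1))
        try:
            return generate_dataset(fixture, truth, seed=gen_seed, **kwargs)
        except GenerationError as exc:
            last_error = exc
    raise GenerationError(
        f"no feasible truth found in {max_attempts} attempts: {last_error}"
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> Tuple[str, str]:
    """Write ``abundance.tsv`` and ``truth.json``; returns the two paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    abundance_path = out / "abundance.tsv"
    truth_path = out / "truth.json"
    dataset.observations.to_tsv(abundance_path)
    truth_path.write_text(dataset.truth_json())
    return str(abundance_path), str(truth_path)
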