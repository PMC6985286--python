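"""One-at-a-time sensitivity analysis over unidentifiable binary coefficients.

When a binary coefficient cannot be estimated (the influencer never grows in
the binary culture), it becomes an adjustable model parameter.  Sweeping one
parameter over a grid and re-running the complex-community projection yields
trajectories of every predicted coefficient as a function of the parameter.
Because the projection is affine in the binary row, trajectories are straight
lines; their slopes have closed forms

    d b_ik^C / d b_ij^B = delta_kj - x_j x_k / ||x||^2

so for positive abundances a parameter's *self*-response slope lies in
[0, 1] and every *cross*-response slope (same focal row, other partner) is
non-positive — a trade-off imposed by the constraint.  The abundance-weighted
slope sum over a focal row vanishes exactly (constraint preservation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binary import STATUS_UNIDENTIFIABLE, BinaryCoefficientSet, Pair
from .core import CoefficientMatrix, predict_community
from .data import ObservationSet, parse_membership
from .exceptions import ConfigError

#: default parameter grid: 41 points spanning [-5, 5]
DEFAULT_GRID = tuple(np.linspace(-5.0, 5.0, 41))

SIGN_LABELS = {1: "positive", 0: "neutral", -1: "negative"}

#: neutral-sign tolerance factor relative to the largest row magnitude
NEUTRAL_TOL_FACTOR = 1e-6


def parse_pair(text: str) -> Pair:
    """Parse the ``affected<-influencer`` pair syntax, e.g. ``"CT<-CS"``."""
    parts = text.split("<-")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ConfigError(
            f"invalid pair syntax {text!r}; expected 'affected<-influencer'"
        )
    i, j = parts[0].strip(), parts[1].strip()
    if i == j:
        raise ConfigError(f"self-pair {text!r} is not allowed")
    return (i, j)


def format_pair(pair: Pair) -> str:
    return f"{pair[0]}<-{pair[1]}"


@dataclass(frozen=True)
class ParameterAssignment:
    """A named scenario: values for (normally unidentifiable) coefficients."""

    values: Mapping[Pair, float]
    label: str = "scenario"

    def __post_init__(self):
        object.__setattr__(
            self, "values", {tuple(k): float(v) for k, v in dict(self.values).items()}
        )

    @classmethod
    def from_dict(cls, spec: Mapping[str, object]) -> "ParameterAssignment":
        """Build from config syntax: ``{"label": ..., "assignments":
        {"CT<-CS": 2.5, ...}}``."""
        unknown = set(spec) - {"label", "assignments"}
        if unknown:
            raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
        raw = spec.get("assignments", {})
        if not isinstance(raw, Mapping):
            raise ConfigError("scenario 'assignments' must be a mapping")
        values = {parse_pair(str(k)): float(v) for k, v in raw.items()}
        return cls(values=values, label=str(spec.get("label", "scenario")))

    def to_dict(self) -> Dict[str, object]:
        return {
            "label": self.label,
            "assignments": {format_pair(p): v for p, v in self.values.items()},
        }


def validate_assignment(
    assignment: ParameterAssignment,
    bset: BinaryCoefficientSet,
    override: bool = False,
) -> None:
    """In strict (non-override) mode, assignment keys must be exactly pairs
    with unidentifiable status."""
    if override:
        for pair in assignment.values:
            if pair not in bset.coefficients:
                raise ConfigError(f"assigned pair {format_pair(pair)} not in roster")
        return
    bad = [
        pair
        for pair in assignment.values
        if pair not in bset.coefficients
        or bset.coefficients[pair].status != STATUS_UNIDENTIFIABLE
    ]
    if bad:
        raise ConfigError(
            "assignment targets identifiable or unknown pairs: "
            + ", ".join(format_pair(p) for p in bad)
        )


@dataclass
class SensitivityProfile:
    """Response of predicted complex coefficients to one swept parameter."""

    parameter: Pair
    grid: np.ndarray
    #: (context, affected, influencer) -> predicted values along the grid
    trajectories: Dict[Tuple[str, str, str], np.ndarray]
    #: finite-difference slope at the baseline grid point (None if undefined)
    slopes: Dict[Tuple[str, str, str], Optional[float]]
    baseline_value: float
    slopes_defined: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        name = format_pair(self.parameter)
        for (context, i, j), values in sorted(self.trajectories.items()):
            for g, v in zip(self.grid, values):
                rows.append((name, g, context, i, j, v))
        return pd.DataFrame(
            rows,
            columns=["parameter", "grid_value", "context", "affected", "influencer", "predicted"],
        )

    def plot(self, ax=None):
        """Plot trajectories against the parameter grid (self-response drawn
        thicker, matching the usual presentation of these sweeps)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for (context, i, j), values in sorted(self.trajectories.items()):
            is_self = (i, j) == self.parameter
            ax.plot(
                self.grid,
                values,
                lw=2.5 if is_self else 1.0,
                label=f"{context}: {format_pair((i, j))}",
            )
        ax.set_xlabel(f"assumed {format_pair(self.parameter)} (binary)")
        ax.set_ylabel("predicted complex coefficient")
        ax.legend(fontsize=7)
        return ax


def profiles_to_frame(profiles: Iterable[SensitivityProfile]) -> pd.DataFrame:
    frames = [p.to_frame() for p in profiles]
    if not frames:
        return pd.DataFrame(
            columns=["parameter", "grid_value", "context", "affected", "influencer", "predicted"]
        )
    return pd.concat(frames, ignore_index=True)


def sweep_parameter(
    bset: BinaryCoefficientSet,
    obs_set: ObservationSet,
    target_pair: Pair,
    grid: Sequence[float] | None = None,
    baseline: ParameterAssignment | None = None,
    contexts: Sequence[str] | None = None,
    override: bool = False,
) -> SensitivityProfile:
    """Sweep one binary coefficient over a grid and re-predict every complex
    context.

    The target must be an unidentifiable pair unless ``override`` is set, in
    which case an estimated coefficient may be varied as well.  ``baseline``
    assigns the remaining unidentifiable parameters (default: all 0).
    """
    target_pair = tuple(target_pair)  # type: ignore[assignment]
    if target_pair not in bset.coefficients:
        raise ConfigError(f"unknown pair {format_pair(target_pair)}")
    status = bset.coefficients[target_pair].status
    if status != STATUS_UNIDENTIFIABLE and not override:
        raise ConfigError(
            f"pair {format_pair(target_pair)} is {status}; pass override=True "
            "to sweep an identified coefficient"
        )
    grid_arr = np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float)
    if grid_arr.ndim != 1 or grid_arr.size == 0:
        raise ConfigError("grid must be a non-empty 1-D sequence")
    if grid_arr.size > 1 and not np.all(np.diff(grid_arr) > 0):
        raise ConfigError("grid must be strictly increasing")
    baseline = baseline or ParameterAssignment({}, label="baseline")
    if contexts is None:
        contexts = obs_set.contexts(min_size=3)

    collected: Dict[Tuple[str, str, str], List[float]] = {}
    for g in grid_arr:
        if override and status != STATUS_UNIDENTIFIABLE:
            bset_g = bset.with_value(target_pair, float(g))
            assignments = dict(baseline.values)
        else:
            bset_g = bset
            assignments = {**baseline.values, target_pair: float(g)}
        for key in contexts:
            cmat = predict_community(bset_g, obs_set, key, assignments)
            for pair, v in sorted(cmat.entries.items()):
                collected.setdefault((key, pair[0], pair[1]), []).append(v)

    trajectories = {k: np.asarray(v) for k, v in collected.items()}

    if override and status != STATUS_UNIDENTIFIABLE:
        base_value = float(bset.coefficients[target_pair].value)  # type: ignore[arg-type]
    else:
        base_value = float(baseline.values.get(target_pair, 0.0))
    slopes: Dict[Tuple[str, str, str], Optional[float]] = {}
    slopes_defined = grid_arr.size > 1
    if slopes_defined:
        idx = int(np.argmin(np.abs(grid_arr - base_value)))
        lo = max(idx - 1, 0)
        hi = min(idx + 1, grid_arr.size - 1)
        dg = grid_arr[hi] - grid_arr[lo]
        for k, traj in trajectories.items():
            slopes[k] = float((traj[hi] - traj[lo]) / dg)
    else:
        slopes = {k: None for k in trajectories}
    return SensitivityProfile(
        parameter=target_pair,
        grid=grid_arr,
        trajectories=trajectories,
        slopes=slopes,
        baseline_value=base_value,
        slopes_defined=slopes_defined,
    )


@dataclass
class RuleReport:
    """Summary of the two sensitivity sign rules.

    Rule 1: the assumed binary coefficient and its own predicted complex
    coefficient correlate positively (self-slope in [0, 1]).
    Rule 2: the assumed coefficient and the other coefficients of the same
    focal row correlate negatively (cross-slopes <= 0).
    """

    self_slopes: Dict[Tuple[str, str, str], float]
    cross_slopes: Dict[Tuple[str, str, str], float]
    violations: List[str]
    weighted_sums: Dict[Tuple[str, str], float]

    @property
    def ok(self) -> bool:
        return not self.violations


def correlation_rules_report(
    profiles: Iterable[SensitivityProfile],
    obs_set: ObservationSet | None = None,
    tol: float = 1e-9,
) -> RuleReport:
    """Check the self-positive / cross-negative slope rules over profiles.

    With an observation set, also reports the abundance-weighted slope sum
    per focal row (an exact algebraic zero for the projection)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile is required")
    self_slopes: Dict[Tuple[str, str, str], float] = {}
    cross_slopes: Dict[Tuple[str, str, str], float] = {}
    violations: List[str] = []
    weighted: Dict[Tuple[str, str], float] = {}
    for prof in profiles:
        if not prof.slopes_defined:
            violations.append(
                f"{format_pair(prof.parameter)}: slopes undefined (grid of length 1)"
            )
            continue
        ti, tj = prof.parameter
        for (context, i, j), slope in prof.slopes.items():
            if i != ti:
                continue  # other focal rows are decoupled from this parameter
            members = parse_membership(context)
            if tj not in members:
                continue  # parameter absent from this context: flat trajectory
            key = (context, i, j)
            if j == tj:
                self_slopes[key] = slope
                if slope < -tol or slope > 1.0 + tol:
                    violations.append(
                        f"self-slope {slope:.3g} outside [0, 1] for "
                        f"{format_pair((i, j))} in {context}"
                    )
            else:
                cross_slopes[key] = slope
                if slope > tol:
                    violations.append(
                        f"cross-slope {slope:.3g} > 0 for {format_pair((i, j))} "
                        f"in {context} (parameter {format_pair(prof.parameter)})"
                    )
        if obs_set is not None:
            for context in {c for (c, i, _) in prof.slopes if i == ti}:
                members = parse_membership(context)
                if tj not in members or ti not in members:
                    continue
                total = 0.0
                for j in members:
                    if j == ti:
                        continue
                    slope = prof.slopes.get((context, ti, j))
                    if slope is None:
                        continue
                    total += obs_set.abundance(j, context) * slope
                weighted[(format_pair(prof.parameter), context)] = total
    return RuleReport(self_slopes, cross_slopes, violations, weighted)


@dataclass
class ScenarioComparison:
    """Edge sign classes across named scenarios and their robustness."""

    labels: Tuple[str, ...]
    #: (context, affected, influencer) -> sign class per scenario (-1/0/+1)
    signs: Dict[Tuple[str, str, str], Tuple[int, ...]]
    classification: Dict[Tuple[str, str, str], str]
    robust_fraction: float
    per_context: Dict[str, float]
    by_size: Dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.signs):
            context, i, j = key
            rows.append(
                (context, i, j)
                + tuple(SIGN_LABELS[s] for s in self.signs[key])
                + (self.classification[key],)
            )
        return pd.DataFrame(
            rows,
            columns=["context", "affected", "influencer"]
            + [f"sign[{lab}]" for lab in self.labels]
            + ["classification"],
        )


def _sign_classes(cmat: CoefficientMatrix, tol_factor: float) -> Dict[Pair, int]:
    """Sign of each entry with a per-row neutral band: |value| below
    tol_factor times the largest magnitude of the focal row is neutral."""
    row_max: Dict[str, float] = {}
    for (i, _), v in cmat.entries.items():
        row_max[i] = max(row_max.get(i, 0.0), abs(v))
    out = {}
    for (i, j), v in cmat.entries.items():
        tol = tol_factor * row_max.get(i, 0.0)
        out[(i, j)] = 0 if abs(v) <= tol else (1 if v > 0 else -1)
    return out


def compare_scenarios(
    bset: BinaryCoefficientSet,
    obs_set: ObservationSet,
    scenarios: Sequence[ParameterAssignment],
    contexts: Sequence[str] | None = None,
    neutral_tol_factor: float = NEUTRAL_TOL_FACTOR,
) -> ScenarioComparison:
    """Classify every predicted edge as robust (same sign class in all
    scenarios) or case-dependent.

    ``contexts`` may mix binary (size-2, passthrough of binary estimates with
    scenario assignments) and complex memberships; defaults to every observed
    context of size >= 2.
    """
    if len(scenarios) < 2:
        raise ValueError("at least two scenarios are required")
    if contexts is None:
        contexts = obs_set.contexts(min_size=2)
    signs: Dict[Tuple[str, str, str], List[int]] = {}
    for scenario in scenarios:
        validate_assignment(scenario, bset, override=True)
        for key in contexts:
            cmat = predict_community(bset, obs_set, key, scenario.values)
            for pair, s in _sign_classes(cmat, neutral_tol_factor).items():
                signs.setdefault((key, pair[0], pair[1]), []).append(s)
    classification = {
        k: ("robust" if len(set(v)) == 1 else "case_dependent")
        for k, v in signs.items()
    }
    n_robust = sum(1 for c in classification.values() if c == "robust")
    per_context: Dict[str, float] = {}
    by_size_counts: Dict[int, List[int]] = {}
    for key in set(k for (k, _, _) in signs):
        edges = [e for e in classification if e[0] == key]
        robust = sum(1 for e in edges if classification[e] == "robust")
        per_context[key] = robust / len(edges)
        size = len(parse_membership(key))
        tot, rob = by_size_counts.get(size, [0, 0])
        by_size_counts[size] = [tot + len(edges), rob + robust]
    by_size = {s: rob / tot for s, (tot, rob) in by_size_counts.items()}
    return ScenarioComparison(
        labels=tuple(s.label for s in scenarios),
        signs={k: tuple(v) for k, v in signs.items()},
        classification=classification,
        robust_fraction=n_robust / len(classification) if classification else float("nan"),
        per_context=per_context,
        by_size=by_size,
    )
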