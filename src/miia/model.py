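"""Model/Results interface tying the inference pipeline together.

``MIIA`` is constructed from an :class:`~miia.data.ObservationSet` (or a
long-format abundance table) and configured with the coefficient form,
detection limit, aggregation mode and default parameter assignments.
``fit()`` estimates the binary coefficients, classifies identifiability,
projects every observed complex community, and returns a
:class:`MIIAResults` carrying the estimates and diagnostics, with
``summary()`` for a quick look and methods for sensitivity sweeps and
scenario comparison.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .binary import (
    BinaryCoefficientSet,
    Pair,
    build_binary_set,
    identifiability_summary,
)
from .core import (
    CoefficientMatrix,
    Modulation,
    RelativeChange,
    modulation,
    predict_all,
    prediction_coverage,
    relative_change,
)
from .data import GrowthPattern, ObservationSet, parse_membership
from .sensitivity import (
    ParameterAssignment,
    ScenarioComparison,
    SensitivityProfile,
    compare_scenarios,
    format_pair,
    sweep_parameter,
)


class MIIA:
    """Minimal interspecies interaction adjustment model.

    Parameters
    ----------
    observations
        Endpoint abundances for axenic, binary and (optionally) complex
        cultures.
    form
        ``"scaled"`` (default; defined without axenic growth, comparable
        within focal rows and as relative changes) or ``"original"``
        (absolute per-capita coefficients, requires axenic growth).
    detection_limit
        Abundance below which a species is called "not growing"; overrides
        the observation set's limit when given.
    assignments
        Default values for unidentifiable binary coefficients, keyed by
        (affected, influencer); anything unassigned defaults to 0.

    Examples
    --------
    >>> from miia import MIIA, make_fixture, random_dataset
    >>> data = random_dataset(make_fixture("wang3"), seed=7)
    >>> res = MIIA(data.observations).fit()
    >>> res.identifiability["n_estimated"]
    6
    """

    def __init__(
        self,
        observations: ObservationSet,
        form: str = "scaled",
        detection_limit: float | None = None,
        aggregation: str | None = None,
        assignments: Mapping[Pair, float] | None = None,
        min_complex_size: int = 3,
    ):
        if detection_limit is not None or aggregation is not None:
            observations = observations.copy(detection_limit=detection_limit)
            if aggregation is not None:
                observations.aggregation = aggregation
        self.observations = observations
        self.form = form
        self.assignments: Dict[Pair, float] = dict(assignments or {})
        self.min_complex_size = int(min_complex_size)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MIIA":
        detection_limit = kwargs.pop("detection_limit", 0.0) or 0.0
        obs = ObservationSet.from_frame(df, detection_limit=detection_limit)
        return cls(obs, **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "MIIA":
        detection_limit = kwargs.pop("detection_limit", 0.0) or 0.0
        obs = ObservationSet.from_tsv(path, detection_limit=detection_limit)
        return cls(obs, **kwargs)

    def fit(self, strict: bool = False) -> "MIIAResults":
        """Estimate binary coefficients and predict all complex contexts.

        In strict mode, an unidentifiable coefficient needed for a prediction
        and not covered by ``assignments`` raises, naming the pair.
        """
        bset = build_binary_set(self.observations, form=self.form)
        complex_matrices = predict_all(
            bset,
            self.observations,
            min_size=self.min_complex_size,
            assignments=self.assignments,
            strict=strict,
        )
        coverage = prediction_coverage(bset, self.observations)
        rel_changes = {
            key: relative_change(bset, cmat, "binary_to_complex")
            for key, cmat in complex_matrices.items()
        }
        modulations = {
            key: modulation(bset, cmat, self.assignments)
            for key, cmat in complex_matrices.items()
        }
        return MIIAResults(
            model=self,
            binary=bset,
            complex=complex_matrices,
            coverage=coverage,
            identifiability=identifiability_summary(bset),
            relative_changes=rel_changes,
            modulations=modulations,
            growth_pattern=self.observations.growth_pattern(),
        )


class MIIAResults:
    """Fitted interaction estimates, identifiability diagnostics and
    per-context predictions."""

    def __init__(
        self,
        model: MIIA,
        binary: BinaryCoefficientSet,
        complex: Dict[str, CoefficientMatrix],
        coverage: Dict[str, float],
        identifiability: Dict[str, object],
        relative_changes: Dict[str, RelativeChange],
        modulations: Dict[str, Modulation],
        growth_pattern: GrowthPattern,
    ):
        self.model = model
        self.binary = binary
        self.complex = complex
        self.coverage = coverage
        self.identifiability = identifiability
        self.relative_changes = relative_changes
        self.modulations = modulations
        self.growth_pattern = growth_pattern

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        ident = self.identifiability
        lines = [
            "Minimal Interspecies Interaction Adjustment Results",
            "=" * 53,
            f"form:                 {self.binary.form}",
            f"species:              {', '.join(self.binary.roster)}",
            f"cultures observed:    {len(self.model.observations)}",
            (
                f"binary coefficients:  {ident['n_estimated']}/{ident['n_total']} "
                f"estimated ({ident['percent_estimated']:.1f}%)"
            ),
        ]
        if ident["unidentifiable_pairs"]:
            lines.append(
                "unidentifiable:       " + ", ".join(ident["unidentifiable_pairs"])
            )
        if self.model.assignments:
            assigned = ", ".join(
                f"{format_pair(p)}={v:g}" for p, v in self.model.assignments.items()
            )
            lines.append(f"assigned parameters:  {assigned}")
        lines.append("")
        lines.append("Binary interaction matrix (row = affected, column = influencer):")
        mat = pd.DataFrame(
            "", index=list(self.binary.roster), columns=list(self.binary.roster)
        )
        for (i, j) in self.binary.pairs:
            coeff = self.binary.coefficients[(i, j)]
            mat.loc[i, j] = "?" if coeff.value is None else f"{coeff.value:.3g}"
        lines.append(mat.to_string())
        if self.complex:
            lines.append("")
            lines.append("Complex-community predictions:")
            for key in sorted(self.complex, key=lambda k: (len(parse_membership(k)), k)):
                lines.append(
                    f"  {key}: coverage {100 * self.coverage.get(key, float('nan')):.1f}%"
                )
                lines.append(
                    "    "
                    + self.complex[key].as_matrix().to_string().replace("\n", "\n    ")
                )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MIIAResults form={self.binary.form!r} "
            f"species={len(self.binary.roster)} "
            f"complex_contexts={len(self.complex)}>"
        )

    # -- downstream analyses ---------------------------------------------------
    def sweep(
        self,
        pair: Pair | str,
        grid: Sequence[float] | None = None,
        baseline: ParameterAssignment | None = None,
        contexts: Sequence[str] | None = None,
        override: bool = False,
    ) -> SensitivityProfile:
        """One-at-a-time sensitivity sweep of a binary coefficient."""
        from .sensitivity import parse_pair

        if isinstance(pair, str):
            pair = parse_pair(pair)
        if baseline is None and self.model.assignments:
            baseline = ParameterAssignment(self.model.assignments, "model-default")
        return sweep_parameter(
            self.binary,
            self.model.observations,
            pair,
            grid=grid,
            baseline=baseline,
            contexts=contexts,
            override=override,
        )

    def compare_scenarios(
        self,
        scenarios: Sequence[ParameterAssignment],
        contexts: Sequence[str] | None = None,
    ) -> ScenarioComparison:
        """Sign-robustness of predicted edges across parameter scenarios."""
        return compare_scenarios(
            self.binary, self.model.observations, scenarios, contexts
        )

    def to_edgelist(self, contexts: Sequence[str] | None = None) -> pd.DataFrame:
        """Signed interaction edge list across contexts (source=influencer,
        target=affected)."""
        from .io import matrices_to_edgelist

        if contexts is None:
            mats = list(self.complex.values())
        else:
            mats = [self.complex[k] for k in contexts]
        return matrices_to_edgelist(mats)
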