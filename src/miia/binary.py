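"""Estimation of binary (pairwise) interaction coefficients.

Two estimators operate on endpoint abundances of axenic and binary cultures.
For an ordered pair (i, j) — the effect of influencer *j* on affected *i* —
with x_i^A the axenic abundance of i and x_i^B, x_j^B the abundances in the
binary co-culture:

* original form:  a_ij^B = (x_i^B - x_i^A) / (x_i^A * x_j^B)
* scaled form:    b_ij^B = (x_i^B - x_i^A) / x_j^B  =  x_i^A * a_ij^B

The scaled form remains defined when species i cannot grow axenically
(x_i^A = 0, read as presence below the detection limit), which is the common
situation for syntrophic partners.  Neither form is defined when the
influencer does not grow in the binary culture (x_j^B = 0); such coefficients
are *unidentifiable* and become adjustable parameters downstream (default 0).

Identifiability is organized into eight growth scenarios (cases I-VIII) over
the growth flags (i axenic, j axenic, i in binary, j in binary).  The flags
are the ground truth for identifiability; the Roman-numeral label is a
reporting convention only.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import GrowthPattern, ObservationSet, membership_key, validate_label
from .exceptions import (
    DataCompletenessError,
    ParseError,
    UnidentifiableError,
)

FORMS = ("original", "scaled")

Pair = Tuple[str, str]


class GrowthCase(enum.Enum):
    """Eight growth scenarios in axenic and binary cultures."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"


#: scenarios deemed ecologically rare (a species growing axenically but
#: extinguished in the binary culture); excluded from routine analysis
EXCLUDED_CASES = frozenset({GrowthCase.III, GrowthCase.VIII})


@dataclass(frozen=True)
class CaseClassification:
    """Growth case of an ordered pair plus identifiability flags."""

    case: GrowthCase
    original_ok: bool
    scaled_ok: bool
    excluded: bool
    #: (i axenic, j axenic, i in binary, j in binary)
    flags: Tuple[bool, bool, bool, bool]


def classify_flags(
    grows_i_axenic: bool,
    grows_j_axenic: bool,
    grows_i_binary: bool,
    grows_j_binary: bool,
) -> CaseClassification:
    """Classify an ordered pair (i <- j) from its four growth flags.

    Identifiability rules (authoritative):

    * original form: i grows axenically AND i grows in binary AND j grows
      in binary;
    * scaled form: j grows in the binary culture.
    """
    gAi, gAj, gBi, gBj = (
        bool(grows_i_axenic),
        bool(grows_j_axenic),
        bool(grows_i_binary),
        bool(grows_j_binary),
    )
    if gBj:
        if gBi:
            if gAi:
                case = GrowthCase.I if gAj else GrowthCase.II
            else:
                case = GrowthCase.V
        else:
            case = GrowthCase.III if gAi else GrowthCase.VI
    else:
        if gBi:
            case = GrowthCase.IV
        else:
            case = GrowthCase.VIII if gAi else GrowthCase.VII
    return CaseClassification(
        case=case,
        original_ok=gAi and gBi and gBj,
        scaled_ok=gBj,
        excluded=case in EXCLUDED_CASES,
        flags=(gAi, gAj, gBi, gBj),
    )


def classify_case(gp: GrowthPattern, i: str, j: str) -> CaseClassification:
    """Classify the ordered pair (i <- j) from a growth pattern.

    Requires growth calls for the axenic cultures {i}, {j} and the binary
    culture {i, j}.
    """
    if i == j:
        raise ValueError("self-interactions are not modelled (i == j)")
    required = [membership_key((i,)), membership_key((j,)), membership_key((i, j))]
    missing = [k for k in required if not any(key == k for _, key in gp.grows)]
    if missing:
        raise DataCompletenessError(missing)
    pair_key = membership_key((i, j))
    return classify_flags(
        gp.grows_in(i, (i,)),
        gp.grows_in(j, (j,)),
        gp.grows_in(i, pair_key),
        gp.grows_in(j, pair_key),
    )


def estimate_original(x_iA: float, x_iB: float, x_jB: float) -> float:
    """Original-form estimator a_ij^B = (x_i^B - x_i^A) / (x_i^A x_j^B)."""
    if x_iA <= 0:
        raise UnidentifiableError(
            "original form requires axenic growth of the affected species "
            f"(x_iA = {x_iA})"
        )
    if x_jB <= 0:
        raise UnidentifiableError(
            f"influencer abundance in the binary culture is zero (x_jB = {x_jB})"
        )
    return (x_iB - x_iA) / (x_iA * x_jB)


def estimate_scaled(x_iA: float, x_iB: float, x_jB: float) -> float:
    """Scaled-form estimator b_ij^B = (x_i^B - x_i^A) / x_j^B.

    x_iA may be zero ("no growth" read as presence below detection).
    """
    if x_jB <= 0:
        raise UnidentifiableError(
            f"influencer abundance in the binary culture is zero (x_jB = {x_jB})"
        )
    return (x_iB - x_iA) / x_jB


STATUS_ESTIMATED = "estimated"
STATUS_UNIDENTIFIABLE = "unidentifiable"
STATUS_ASSIGNED = "assigned_parameter"


@dataclass(frozen=True)
class BinaryCoefficient:
    """One ordered-pair interaction coefficient with provenance."""

    affected: str
    influencer: str
    value: Optional[float]
    form: str
    status: str
    case: Optional[GrowthCase] = None

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.status not in (STATUS_ESTIMATED, STATUS_UNIDENTIFIABLE, STATUS_ASSIGNED):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == STATUS_UNIDENTIFIABLE and self.value is not None:
            raise ValueError("unidentifiable coefficients carry no value")
        if self.status in (STATUS_ESTIMATED, STATUS_ASSIGNED) and self.value is None:
            raise ValueError(f"status {self.status!r} requires a value")


class BinaryCoefficientSet:
    """All ordered-pair coefficients of a species roster, in one form."""

    def __init__(self, roster: Iterable[str], form: str):
        if form not in FORMS:
            raise ValueError(f"unknown form {form!r}")
        self.roster: Tuple[str, ...] = tuple(sorted({validate_label(s) for s in roster}))
        if len(self.roster) < 2:
            raise ValueError("roster must contain at least two species")
        self.form = form
        self.coefficients: Dict[Pair, BinaryCoefficient] = {}

    # -- container ----------------------------------------------------------
    def add(self, coeff: BinaryCoefficient) -> None:
        pair = (coeff.affected, coeff.influencer)
        if coeff.affected == coeff.influencer:
            raise ValueError("diagonal entries are not allowed")
        if coeff.affected not in self.roster or coeff.influencer not in self.roster:
            raise ValueError(f"pair {pair} outside roster {self.roster}")
        if coeff.form != self.form:
            raise ValueError(f"form mismatch: set is {self.form}, got {coeff.form}")
        self.coefficients[pair] = coeff

    def __getitem__(self, pair: Pair) -> BinaryCoefficient:
        return self.coefficients[pair]

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.coefficients

    @property
    def pairs(self) -> Tuple[Pair, ...]:
        return tuple(
            (i, j) for i in self.roster for j in self.roster if i != j
        )

    def is_complete(self) -> bool:
        return all(p in self.coefficients for p in self.pairs)

    def estimated_pairs(self) -> Tuple[Pair, ...]:
        return tuple(
            p for p in self.pairs
            if p in self.coefficients
            and self.coefficients[p].status == STATUS_ESTIMATED
        )

    def unidentifiable_pairs(self) -> Tuple[Pair, ...]:
        return tuple(
            p for p in self.pairs
            if p in self.coefficients
            and self.coefficients[p].status == STATUS_UNIDENTIFIABLE
        )

    def value(
        self,
        i: str,
        j: str,
        assignments: Mapping[Pair, float] | None = None,
        default: float = 0.0,
        strict: bool = False,
    ) -> float:
        """Value of (i <- j); unidentifiable entries come from `assignments`
        (falling back to `default`, usually 0).  In strict mode an
        unassigned unidentifiable pair raises."""
        coeff = self.coefficients[(i, j)]
        if coeff.status == STATUS_UNIDENTIFIABLE:
            if assignments and (i, j) in assignments:
                return float(assignments[(i, j)])
            if strict:
                raise UnidentifiableError(
                    "unassigned unidentifiable coefficient(s)", pairs=[(i, j)]
                )
            return float(default)
        value = float(coeff.value)  # type: ignore[arg-type]
        if assignments and (i, j) in assignments and coeff.status == STATUS_ASSIGNED:
            return float(assignments[(i, j)])
        return value

    def row(
        self,
        i: str,
        partners: Sequence[str],
        assignments: Mapping[Pair, float] | None = None,
        default: float = 0.0,
        strict: bool = False,
    ) -> np.ndarray:
        missing = [
            (i, j)
            for j in partners
            if self.coefficients[(i, j)].status == STATUS_UNIDENTIFIABLE
            and not (assignments and (i, j) in assignments)
        ]
        if strict and missing:
            raise UnidentifiableError(
                "unassigned unidentifiable coefficient(s)", pairs=missing
            )
        return np.array(
            [self.value(i, j, assignments, default) for j in partners], dtype=float
        )

    def with_value(self, pair: Pair, value: float) -> "BinaryCoefficientSet":
        """Copy of the set with one pair's value overridden (used by
        override-mode sensitivity sweeps)."""
        new = BinaryCoefficientSet(self.roster, self.form)
        for p, coeff in self.coefficients.items():
            if p == pair:
                coeff = replace(coeff, value=float(value), status=STATUS_ASSIGNED)
            new.add(coeff)
        if pair not in new.coefficients:
            raise KeyError(f"pair {pair} not in set")
        return new

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j) in self.pairs:
            coeff = self.coefficients.get((i, j))
            if coeff is None:
                continue
            rows.append(
                (
                    i,
                    j,
                    coeff.form,
                    coeff.value if coeff.value is not None else np.nan,
                    coeff.status,
                    coeff.case.value if coeff.case is not None else "",
                )
            )
        return pd.DataFrame(
            rows, columns=["affected", "influencer", "form", "value", "status", "case"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryCoefficientSet":
        required = {"affected", "influencer", "form", "value", "status", "case"}
        if set(df.columns) != required:
            raise ParseError(
                f"binary coefficient table must have columns {sorted(required)}, "
                f"got {sorted(df.columns)}"
            )
        forms = set(df["form"])
        if len(forms) != 1:
            raise ParseError(f"mixed or missing forms in coefficient table: {forms}")
        roster = sorted(set(df["affected"]) | set(df["influencer"]))
        bset = cls(roster, forms.pop())
        for idx, row in df.iterrows():
            value = row["value"]
            value = None if pd.isna(value) else float(value)
            case = GrowthCase(row["case"]) if row["case"] else None
            try:
                bset.add(
                    BinaryCoefficient(
                        affected=str(row["affected"]),
                        influencer=str(row["influencer"]),
                        value=value,
                        form=str(row["form"]),
                        status=str(row["status"]),
                        case=case,
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=int(idx) + 2) from None
        return bset

    @classmethod
    def from_tsv(cls, path) -> "BinaryCoefficientSet":
        try:
            df = pd.read_csv(
                sep="\t",
                filepath_or_buffer=path,
                dtype={"affected": str, "influencer": str, "form": str,
                       "status": str},
                keep_default_na=False,
                na_values=[""],
            )
        except pd.errors.EmptyDataError:
            raise ParseError(f"empty coefficient file: {path}") from None
        except (pd.errors.ParserError, OSError, ValueError) as exc:
            raise ParseError(f"cannot parse coefficient file {path}: {exc}") from None
        df["case"] = df["case"].fillna("")
        return cls.from_frame(df)


def build_binary_set(
    obs_set: ObservationSet, form: str = "scaled", aggregation: str | None = None
) -> BinaryCoefficientSet:
    """Estimate all ordered-pair coefficients of the roster from axenic and
    binary cultures.

    Every species needs an axenic observation and every unordered pair a
    binary observation (zero abundances are valid records).  Pairs whose
    influencer does not grow in the binary culture come out unidentifiable.
    """
    roster = obs_set.species
    if len(roster) < 2:
        raise DataCompletenessError(
            [membership_key((s,)) for s in roster], what="binary cultures"
        )
    required = [membership_key((s,)) for s in roster] + [
        membership_key(p) for p in itertools.combinations(roster, 2)
    ]
    missing = [k for k in required if k not in obs_set.observations]
    if missing:
        raise DataCompletenessError(missing)

    mode = aggregation or obs_set.aggregation
    gp = obs_set.growth_pattern()
    bset = BinaryCoefficientSet(roster, form)
    for i, j in itertools.permutations(roster, 2):
        pair_key = membership_key((i, j))
        cls_ = classify_case(gp, i, j)
        ok = cls_.original_ok if form == "original" else cls_.scaled_ok
        if ok:
            x_iA = obs_set.abundance(i, (i,), mode)
            x_iB = obs_set.abundance(i, pair_key, mode)
            x_jB = obs_set.abundance(j, pair_key, mode)
            estimator = estimate_original if form == "original" else estimate_scaled
            value = estimator(x_iA, x_iB, x_jB)
            coeff = BinaryCoefficient(i, j, value, form, STATUS_ESTIMATED, cls_.case)
        else:
            coeff = BinaryCoefficient(i, j, None, form, STATUS_UNIDENTIFIABLE, cls_.case)
        bset.add(coeff)
    return bset


def identifiability_summary(bset: BinaryCoefficientSet) -> Dict[str, object]:
    """Counts and percentages of estimated vs unidentifiable coefficients."""
    pairs = bset.pairs
    estimated = bset.estimated_pairs()
    unident = bset.unidentifiable_pairs()
    by_case: Dict[str, int] = {}
    for p in pairs:
        coeff = bset.coefficients.get(p)
        if coeff is not None and coeff.case is not None:
            by_case[coeff.case.value] = by_case.get(coeff.case.value, 0) + 1
    n_total = len(pairs)
    n_est = len(estimated)
    return {
        "form": bset.form,
        "n_total": n_total,
        "n_estimated": n_est,
        "n_unidentifiable": len(unident),
        "fraction_estimated": n_est / n_total if n_total else float("nan"),
        "percent_estimated": 100.0 * n_est / n_total if n_total else float("nan"),
        "unidentifiable_pairs": [f"{i}<-{j}" for i, j in unident],
        "cases": by_case,
    }
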