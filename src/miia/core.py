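"""Minimal-adjustment prediction of interactions in complex communities.

For a complex community C and a focal species i, the endpoint abundances
constrain the row of interaction coefficients through a single linear
equation (scaled form):

    x_i^C - x_i^A = sum_{j != i} b_ij^C x_j^C

One equation with N-1 unknowns defines a hyperplane of feasible coefficient
vectors.  The minimal-adjustment rule picks the point on that hyperplane
closest (Euclidean) to the binary coefficients b_ij^B — an orthogonal
projection with the closed form

    b^C = b^B + lambda x,    lambda = (d_i - b^B . x) / (x . x)

where x is the vector of partner abundances in C and d_i the focal
abundance change (d_i = x_i^C - x_i^A scaled; (x_i^C - x_i^A)/x_i^A
original).  The same geometry holds in both coefficient forms because the
scaling by x_i^A is a constant per row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .binary import (
    STATUS_ESTIMATED,
    STATUS_UNIDENTIFIABLE,
    BinaryCoefficientSet,
    Pair,
)
from .data import ObservationSet, membership_key, parse_membership
from .exceptions import (
    DataCompletenessError,
    DegenerateConstraintError,
    InconsistentConstraintError,
    ParseError,
    UnidentifiableError,
)

logger = logging.getLogger(__name__)

#: relative tolerance under which a row is considered already on the
#: constraint hyperplane (no modulation)
ON_PLANE_RTOL = 1e-12


@dataclass
class CoefficientMatrix:
    """Context-tagged interaction matrix; entry (i, j) is the effect of
    influencer j on affected i within one community context."""

    context: str
    form: str
    entries: Dict[Pair, float]

    def __post_init__(self):
        members = parse_membership(self.context)
        self.context = membership_key(members)
        for (i, j) in self.entries:
            if i == j:
                raise ValueError("diagonal entries are not allowed")
            if i not in members or j not in members:
                raise ValueError(f"pair {(i, j)} outside context {self.context!r}")
        self.entries = {p: float(v) for p, v in self.entries.items()}

    @property
    def members(self) -> Tuple[str, ...]:
        return parse_membership(self.context)

    def row(self, i: str) -> Dict[str, float]:
        return {j: v for (a, j), v in self.entries.items() if a == i}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.context, i, j, v, self.form)
            for (i, j), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["context", "affected", "influencer", "value", "form"]
        )

    def as_matrix(self) -> pd.DataFrame:
        """Dense affected x influencer table (NaN diagonal)."""
        members = self.members
        mat = pd.DataFrame(np.nan, index=list(members), columns=list(members))
        for (i, j), v in self.entries.items():
            mat.loc[i, j] = v
        return mat

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def matrices_to_frame(matrices: Iterable[CoefficientMatrix]) -> pd.DataFrame:
    frames = [m.to_frame() for m in matrices]
    if not frames:
        return pd.DataFrame(
            columns=["context", "affected", "influencer", "value", "form"]
        )
    return pd.concat(frames, ignore_index=True)


def matrices_from_frame(df: pd.DataFrame) -> Dict[str, CoefficientMatrix]:
    required = {"context", "affected", "influencer", "value", "form"}
    if set(df.columns) != required:
        raise ParseError(
            f"coefficient matrix table must have columns {sorted(required)}"
        )
    out: Dict[str, CoefficientMatrix] = {}
    for (context, form), group in df.groupby(["context", "form"], sort=True):
        entries = {
            (str(r["affected"]), str(r["influencer"])): float(r["value"])
            for _, r in group.iterrows()
        }
        key = membership_key(parse_membership(str(context)))
        out[key] = CoefficientMatrix(key, str(form), entries)
    return out


@dataclass
class RelativeChange:
    """Relative changes Δ_ij = (after - before)/before of interaction
    coefficients; identical in the original and scaled forms because the
    per-row scaling constant cancels."""

    entries: Dict[Pair, float]
    direction: str
    undefined: Tuple[Pair, ...] = ()

    def __post_init__(self):
        if self.direction not in ("binary_to_complex", "complex_to_binary"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, j, v, self.direction, (i, j) in set(self.undefined))
            for (i, j), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["affected", "influencer", "relative_change", "direction", "undefined"],
        )


@dataclass
class Modulation:
    """Directional interaction shift m_ij = b_ij^C - b_ij^B.

    A nonzero sign means the influence of j on i moved in that direction in
    the complex context; it does not by itself imply a sign change of the
    interaction."""

    context: str
    entries: Dict[Pair, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.context, i, j, v) for (i, j), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["context", "affected", "influencer", "modulation"]
        )


def project_row(
    b_row_B,
    x_partners,
    d_i: float,
    on_plane_rtol: float = ON_PLANE_RTOL,
) -> Tuple[np.ndarray, float]:
    """Orthogonally project a binary coefficient row onto the complex-context
    constraint hyperplane ``b . x = d_i``.

    Returns ``(b_row_C, lambda)``.  Among all vectors satisfying the
    constraint, the result minimizes the Euclidean distance to ``b_row_B``.
    Partners with zero abundance remain dimensions of the projection; their
    coefficients are unchanged (adjusted by ``lambda * 0``).
    """
    b = np.asarray(b_row_B, dtype=float).copy()
    x = np.asarray(x_partners, dtype=float)
    if b.shape != x.shape or b.ndim != 1 or b.size == 0:
        raise ValueError("b_row_B and x_partners must be equal-length 1-D vectors")
    nx2 = float(x @ x)
    d_i = float(d_i)
    if nx2 == 0.0:
        if d_i == 0.0:
            warnings.warn(
                "all partner abundances are zero; constraint is vacuous, "
                "row returned unchanged",
                stacklevel=2,
            )
            return b, 0.0
        raise InconsistentConstraintError(
            "all partner abundances are zero but the focal abundance change "
            f"d_i = {d_i} is nonzero"
        )
    residual = d_i - float(b @ x)
    if abs(residual) <= on_plane_rtol * max(1.0, abs(d_i)):
        return b, 0.0
    lam = residual / nx2
    return b + lam * x, lam


def predict_community(
    bset: BinaryCoefficientSet,
    obs_set: ObservationSet,
    community: Iterable[str] | str,
    assignments: Mapping[Pair, float] | None = None,
    strict: bool = False,
) -> CoefficientMatrix:
    """Predict the interaction matrix of one complex community.

    Unidentifiable binary entries take values from ``assignments`` (default
    0); in strict mode an unassigned unidentifiable entry raises, naming the
    pair.  Communities of size 2 return the binary estimates verbatim.
    """
    members = (
        parse_membership(community)
        if isinstance(community, str)
        else tuple(sorted(set(community)))
    )
    key = membership_key(members)
    unknown = [m for m in members if m not in bset.roster]
    if unknown:
        raise DataCompletenessError(unknown, what="species in the binary set")

    if len(members) < 2:
        raise ValueError("community must have at least two members")
    if len(members) == 2:
        i, j = members
        entries = {
            (i, j): bset.value(i, j, assignments, strict=strict),
            (j, i): bset.value(j, i, assignments, strict=strict),
        }
        return CoefficientMatrix(key, bset.form, entries)

    required = [key] + [membership_key((m,)) for m in members]
    missing = [k for k in required if k not in obs_set.observations]
    if missing:
        raise DataCompletenessError(missing)

    if strict:
        needed = [
            (i, j)
            for i in members
            for j in members
            if i != j
            and bset.coefficients[(i, j)].status == STATUS_UNIDENTIFIABLE
            and not (assignments and (i, j) in assignments)
        ]
        if needed:
            raise UnidentifiableError(
                "unassigned unidentifiable coefficient(s)", pairs=needed
            )

    entries: Dict[Pair, float] = {}
    for i in members:
        partners = [j for j in members if j != i]
        x = np.array([obs_set.abundance(j, key) for j in partners], dtype=float)
        b_row = bset.row(i, partners, assignments, strict=strict)
        x_iA = obs_set.abundance(i, (i,))
        x_iC = obs_set.abundance(i, key)
        if bset.form == "original":
            if x_iA <= 0:
                raise UnidentifiableError(
                    f"original form requires axenic growth of focal species {i!r}"
                )
            d_i = (x_iC - x_iA) / x_iA
        else:
            d_i = x_iC - x_iA
        row_C, lam = project_row(b_row, x, d_i)
        logger.debug(
            "context=%s focal=%s lambda=%.6g d_i=%.6g", key, i, lam, d_i
        )
        for j, v in zip(partners, row_C):
            entries[(i, j)] = float(v)
    return CoefficientMatrix(key, bset.form, entries)


def predict_all(
    bset: BinaryCoefficientSet,
    obs_set: ObservationSet,
    min_size: int = 3,
    assignments: Mapping[Pair, float] | None = None,
    strict: bool = False,
) -> Dict[str, CoefficientMatrix]:
    """Predict matrices for every observed context of size >= min_size."""
    out: Dict[str, CoefficientMatrix] = {}
    for key in obs_set.contexts(min_size=min_size):
        out[key] = predict_community(bset, obs_set, key, assignments, strict)
    return out


def prediction_coverage(
    bset: BinaryCoefficientSet, obs_set: ObservationSet
) -> Dict[str, float]:
    """Per-community fraction of predictable coefficients.

    Coefficient (i, j) in context C counts as predictable iff every binary
    coefficient of focal row i over partners of C with nonzero complex
    abundance has been estimated (no parameter assignment needed).
    """
    coverage: Dict[str, float] = {}
    for key in obs_set.contexts(min_size=3):
        members = parse_membership(key)
        n_total = 0
        n_pred = 0
        for i in members:
            partners = [j for j in members if j != i]
            active = [j for j in partners if obs_set.abundance(j, key) > 0]
            row_ok = all(
                (i, j) in bset.coefficients
                and bset.coefficients[(i, j)].status == STATUS_ESTIMATED
                for j in active
            )
            n_total += len(partners)
            if row_ok:
                n_pred += len(partners)
        coverage[key] = n_pred / n_total if n_total else float("nan")
    return coverage


def _pair_value(
    before: Union[BinaryCoefficientSet, CoefficientMatrix], pair: Pair
) -> Optional[float]:
    if isinstance(before, BinaryCoefficientSet):
        coeff = before.coefficients.get(pair)
        if coeff is None or coeff.status == STATUS_UNIDENTIFIABLE:
            return None
        return float(coeff.value)  # type: ignore[arg-type]
    return before.entries.get(pair)


def relative_change(
    before: Union[BinaryCoefficientSet, CoefficientMatrix],
    after: CoefficientMatrix,
    direction: str = "binary_to_complex",
) -> RelativeChange:
    """Elementwise relative change Δ_ij = (after - before)/before.

    Entries with zero or unavailable denominator are flagged as undefined
    (NaN), never silently dropped.
    """
    entries: Dict[Pair, float] = {}
    undefined = []
    for pair, after_value in after.entries.items():
        before_value = _pair_value(before, pair)
        if before_value is None or before_value == 0.0:
            entries[pair] = float("nan")
            undefined.append(pair)
        else:
            entries[pair] = (after_value - before_value) / before_value
    return RelativeChange(entries, direction, tuple(undefined))


def modulation(
    bset: BinaryCoefficientSet,
    cmat: CoefficientMatrix,
    assignments: Mapping[Pair, float] | None = None,
) -> Modulation:
    """Modulation metric m_ij = b_ij^C - b_ij^B over the matrix support."""
    entries = {
        pair: cvalue - bset.value(*pair, assignments)
        for pair, cvalue in cmat.entries.items()
    }
    return Modulation(cmat.context, entries)
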