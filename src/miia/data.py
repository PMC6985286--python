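"""Endpoint abundance observations for cultures of varying membership.

The basic experimental unit is a *culture*: a set of species grown together
until stagnant phase / steady state, with the endpoint abundance of each
member recorded (possibly in replicate).  Cultures of one species are
*axenic*, of two species *binary*, and of three or more species *complex*
(ternary, quaternary, ...).  Abundances are nonnegative densities in
arbitrary units (e.g. 16S rRNA gene copy number from qPCR); a value of zero
(or below the configured detection limit) means the species did not grow in
that culture, not that the measurement is missing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import MembershipError, ParseError

#: canonical separator in membership keys ("BA+CS+PT")
MEMBER_SEP = "+"

#: exact column set of the long-format abundance table
ABUNDANCE_COLUMNS = ("community", "species", "replicate", "abundance")

_LABEL_RE = re.compile(r"^[^\s,\t+<>]+$")

AGGREGATION_MODES = ("mean", "median")


def validate_label(label: str) -> str:
    """Validate a species label (non-empty, no separators or whitespace)."""
    if not isinstance(label, str) or not label:
        raise MembershipError(f"invalid species label: {label!r}")
    if not _LABEL_RE.match(label):
        raise MembershipError(
            f"species label {label!r} contains whitespace or a reserved "
            "character (tab, comma, '+', '<', '>')"
        )
    return label


def membership_key(members: Iterable[str]) -> str:
    """Canonical, order-independent key for a culture membership.

    Sorted species labels joined by ``+``, e.g. ``membership_key(("PT",
    "CS"))`` -> ``"CS+PT"``.
    """
    labels = sorted({validate_label(m) for m in members})
    if not labels:
        raise MembershipError("membership must contain at least one species")
    return MEMBER_SEP.join(labels)


def parse_membership(key: str) -> Tuple[str, ...]:
    """Inverse of :func:`membership_key`; returns the sorted member tuple."""
    members = tuple(sorted({validate_label(m) for m in key.split(MEMBER_SEP)}))
    if not members:
        raise MembershipError(f"empty membership key: {key!r}")
    return members


def _as_members(members: Iterable[str] | str) -> Tuple[str, ...]:
    if isinstance(members, str):
        return parse_membership(members)
    return tuple(sorted({validate_label(m) for m in members}))


@dataclass(frozen=True)
class CommunityObservation:
    """Endpoint abundances of one culture.

    Parameters
    ----------
    members
        Species grown together in this culture (order irrelevant).
    abundances
        Map species -> replicate abundance values.  Every member must have at
        least one replicate; a recorded value of zero means "did not grow".
    """

    members: Tuple[str, ...]
    abundances: Mapping[str, Tuple[float, ...]]

    def __post_init__(self):
        members = _as_members(self.members)
        object.__setattr__(self, "members", members)
        clean: Dict[str, Tuple[float, ...]] = {}
        for sp, values in dict(self.abundances).items():
            if sp not in members:
                raise MembershipError(
                    f"abundances recorded for {sp!r}, which is not a member "
                    f"of culture {membership_key(members)!r}"
                )
            vals = tuple(float(v) for v in values)
            if not vals:
                raise MembershipError(
                    f"species {sp!r} has no replicate values"
                )
            for v in vals:
                if not math.isfinite(v) or v < 0:
                    raise MembershipError(
                        f"abundance of {sp!r} must be finite and >= 0, "
                        f"got {v!r}"
                    )
            clean[sp] = vals
        missing = [m for m in members if m not in clean]
        if missing:
            raise MembershipError(
                f"no abundance recorded for member(s) {missing} of culture "
                f"{membership_key(members)!r} (record 0 for no growth)"
            )
        object.__setattr__(self, "abundances", clean)

    @property
    def context_size(self) -> int:
        return len(self.members)

    @property
    def key(self) -> str:
        return membership_key(self.members)

    def aggregate(self, species: str, mode: str = "mean") -> float:
        """Aggregate replicate abundances of one member (raw, no detection
        limit applied)."""
        if species not in self.members:
            raise MembershipError(
                f"{species!r} is not a member of culture {self.key!r}"
            )
        if mode not in AGGREGATION_MODES:
            raise ValueError(f"unknown aggregation mode {mode!r}")
        values = np.asarray(self.abundances[species], dtype=float)
        return float(np.mean(values) if mode == "mean" else np.median(values))


def aggregate_abundance(
    obs: CommunityObservation, species: str, mode: str = "mean"
) -> float:
    """Functional alias for :meth:`CommunityObservation.aggregate`."""
    return obs.aggregate(species, mode)


@dataclass(frozen=True)
class GrowthPattern:
    """Boolean growth/no-growth calls per (species, membership)."""

    grows: Mapping[Tuple[str, str], bool]

    def __post_init__(self):
        clean = {}
        for (sp, key), flag in dict(self.grows).items():
            members = parse_membership(key)
            if sp not in members:
                raise MembershipError(
                    f"growth queried for {sp!r} outside membership {key!r}"
                )
            clean[(sp, membership_key(members))] = bool(flag)
        object.__setattr__(self, "grows", clean)

    def grows_in(self, species: str, members: Iterable[str] | str) -> bool:
        key = membership_key(_as_members(members))
        if species not in parse_membership(key):
            raise MembershipError(
                f"{species!r} is not a member of {key!r}"
            )
        try:
            return self.grows[(species, key)]
        except KeyError:
            raise MembershipError(
                f"no growth call recorded for {species!r} in {key!r}"
            ) from None

    @property
    def memberships(self) -> Tuple[str, ...]:
        return tuple(sorted({key for _, key in self.grows}))

    @property
    def roster(self) -> Tuple[str, ...]:
        return tuple(sorted({sp for sp, _ in self.grows}))


class ObservationSet:
    """A collection of culture observations keyed by canonical membership.

    ``detection_limit`` encodes "no growth": an aggregate abundance below the
    limit (or exactly zero) is treated as absence of growth and its effective
    abundance is 0.
    """

    def __init__(
        self,
        observations: Iterable[CommunityObservation] = (),
        detection_limit: float = 0.0,
        aggregation: str = "mean",
    ):
        if detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if aggregation not in AGGREGATION_MODES:
            raise ValueError(f"unknown aggregation mode {aggregation!r}")
        self.detection_limit = float(detection_limit)
        self.aggregation = aggregation
        self.observations: Dict[str, CommunityObservation] = {}
        for obs in observations:
            self.add(obs)

    # -- container protocol -------------------------------------------------
    def add(self, obs: CommunityObservation, replace: bool = False) -> None:
        if obs.key in self.observations and not replace:
            raise MembershipError(
                f"duplicate observation for membership {obs.key!r}"
            )
        self.observations[obs.key] = obs

    def __contains__(self, members) -> bool:
        try:
            key = membership_key(_as_members(members))
        except MembershipError:
            return False
        return key in self.observations

    def __len__(self) -> int:
        return len(self.observations)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservationSet):
            return NotImplemented
        return (
            self.detection_limit == other.detection_limit
            and self.observations.keys() == other.observations.keys()
            and all(
                self.observations[k].abundances == other.observations[k].abundances
                for k in self.observations
            )
        )

    def get(self, members: Iterable[str] | str) -> CommunityObservation:
        key = membership_key(_as_members(members))
        try:
            return self.observations[key]
        except KeyError:
            raise MembershipError(f"no observation for membership {key!r}") from None

    @property
    def species(self) -> Tuple[str, ...]:
        roster: set = set()
        for obs in self.observations.values():
            roster.update(obs.members)
        return tuple(sorted(roster))

    def contexts(self, min_size: int = 1, max_size: int | None = None) -> Tuple[str, ...]:
        keys = []
        for key, obs in self.observations.items():
            if obs.context_size >= min_size and (
                max_size is None or obs.context_size <= max_size
            ):
                keys.append(key)
        return tuple(sorted(keys, key=lambda k: (len(parse_membership(k)), k)))

    def copy(self, detection_limit: float | None = None) -> "ObservationSet":
        return ObservationSet(
            self.observations.values(),
            detection_limit=(
                self.detection_limit if detection_limit is None else detection_limit
            ),
            aggregation=self.aggregation,
        )

    # -- abundance queries --------------------------------------------------
    def raw_abundance(
        self, species: str, members: Iterable[str] | str, mode: str | None = None
    ) -> float:
        return self.get(members).aggregate(species, mode or self.aggregation)

    def abundance(
        self, species: str, members: Iterable[str] | str, mode: str | None = None
    ) -> float:
        """Effective abundance: the replicate aggregate, or 0 when it falls
        below the detection limit (no growth)."""
        raw = self.raw_abundance(species, members, mode)
        if raw <= 0 or raw < self.detection_limit:
            return 0.0
        return raw

    def grows(self, species: str, members: Iterable[str] | str) -> bool:
        return self.abundance(species, members) > 0

    def growth_pattern(self) -> GrowthPattern:
        calls = {}
        for key, obs in self.observations.items():
            for sp in obs.members:
                calls[(sp, key)] = self.grows(sp, key)
        return GrowthPattern(calls)

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.observations):
            obs = self.observations[key]
            for sp in obs.members:
                for r, value in enumerate(obs.abundances[sp], start=1):
                    rows.append((key, sp, r, value))
        return pd.DataFrame(rows, columns=list(ABUNDANCE_COLUMNS))

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, detection_limit: float = 0.0, aggregation: str = "mean"
    ) -> "ObservationSet":
        cols = tuple(df.columns)
        if sorted(cols) != sorted(ABUNDANCE_COLUMNS):
            raise ParseError(
                "abundance table must have exactly the columns "
                f"{ABUNDANCE_COLUMNS}, got {cols}"
            )
        groups: Dict[str, Dict[str, Dict[int, float]]] = {}
        for idx, row in df.iterrows():
            line = int(idx) + 2  # header is line 1
            community = str(row["community"])
            species = str(row["species"])
            try:
                members = parse_membership(community)
                validate_label(species)
            except MembershipError as exc:
                raise ParseError(str(exc), line=line) from None
            if membership_key(members) != community:
                raise ParseError(
                    f"community {community!r} is not in canonical form "
                    f"({membership_key(members)!r})",
                    line=line,
                )
            if species not in members:
                raise ParseError(
                    f"species {species!r} is not a member of {community!r}",
                    line=line,
                )
            try:
                replicate = int(row["replicate"])
                abundance = float(row["abundance"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric replicate/abundance: "
                    f"{row['replicate']!r}, {row['abundance']!r}",
                    line=line,
                ) from None
            if replicate < 1:
                raise ParseError("replicate index must be >= 1", line=line)
            if not math.isfinite(abundance) or abundance < 0:
                raise ParseError(
                    f"abundance must be finite and >= 0, got {abundance}",
                    line=line,
                )
            sp_map = groups.setdefault(community, {}).setdefault(species, {})
            if replicate in sp_map:
                raise ParseError(
                    f"duplicate replicate {replicate} for {species!r} in "
                    f"{community!r}",
                    line=line,
                )
            sp_map[replicate] = abundance
        observations = []
        for community, by_species in groups.items():
            abundances = {
                sp: tuple(v for _, v in sorted(reps.items()))
                for sp, reps in by_species.items()
            }
            observations.append(
                CommunityObservation(parse_membership(community), abundances)
            )
        return cls(observations, detection_limit=detection_limit, aggregation=aggregation)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(
        cls, path, detection_limit: float = 0.0, aggregation: str = "mean"
    ) -> "ObservationSet":
        try:
            df = pd.read_csv(path, sep="\t", dtype={"community": str, "species": str})
        except pd.errors.EmptyDataError:
            raise ParseError(f"empty abundance file: {path}") from None
        except (pd.errors.ParserError, OSError, ValueError) as exc:
            raise ParseError(f"cannot parse abundance file {path}: {exc}") from None
        return cls.from_frame(df, detection_limit=detection_limit, aggregation=aggregation)


def growth_pattern(obs_set: ObservationSet) -> GrowthPattern:
    """Derive the growth/no-growth pattern of an observation set."""
    if len(obs_set) == 0:
        raise MembershipError("observation set is empty")
    return obs_set.growth_pattern()
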