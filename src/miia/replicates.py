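"""Ratio-estimation bias across replicate combinations and noise robustness.

Binary coefficient estimators are ratios of endpoint abundances, and with
small replicate numbers (typically 3-5) the mean of ratios differs from the
ratio of means.  :func:`ratio_bias` quantifies that gap by brute-force
enumeration of every replicate combination.  The default pipeline aggregates
replicates first (ratio of means): the observed differences are small and the
ratio of means stays defined even when individual combinations have zero
denominators.

:func:`perturb_lognormal` applies multiplicative lognormal measurement noise
(x -> x * exp(eps), eps ~ N(0, sigma^2)), which preserves the growth /
no-growth pattern exactly; :func:`robustness_curve` summarizes how prediction
error grows with the noise scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .binary import build_binary_set, estimate_original, estimate_scaled
from .core import CoefficientMatrix, predict_community
from .data import CommunityObservation, ObservationSet
from .exceptions import UnidentifiableError


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal noise: sigma is the standard deviation of the
    natural-log perturbation."""

    sigma: float
    seed: int
    n_replicates: int = 3

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class RatioBiasReport:
    """Mean-of-ratios vs ratio-of-means for one coefficient estimate."""

    form: str
    mean_of_ratios: float
    ratio_of_means: float
    relative_difference_pct: float
    n_combinations: int
    n_excluded: int


def ratio_bias(
    replicates_xiA: Sequence[float],
    replicates_xiB: Sequence[float],
    replicates_xjB: Sequence[float],
    form: str = "scaled",
) -> RatioBiasReport:
    """Compare the mean of per-combination estimates against the estimate on
    per-variable means.

    All combinations of the three replicate lists are enumerated (e.g. 27
    combinations from three triplicate variables); combinations whose
    denominator vanishes are excluded and counted.
    """
    lists = [list(map(float, r)) for r in (replicates_xiA, replicates_xiB, replicates_xjB)]
    if any(not r for r in lists):
        raise ValueError("each replicate list must be non-empty")
    estimator = estimate_scaled if form == "scaled" else estimate_original
    values = []
    n_excluded = 0
    n_combinations = len(lists[0]) * len(lists[1]) * len(lists[2])
    for xiA, xiB, xjB in itertools.product(*lists):
        try:
            values.append(estimator(xiA, xiB, xjB))
        except UnidentifiableError:
            n_excluded += 1
    if not values:
        raise UnidentifiableError(
            "every replicate combination has a zero denominator"
        )
    mean_of_ratios = float(np.mean(values))
    means = [float(np.mean(r)) for r in lists]
    ratio_of_means = estimator(*means)  # raises if the mean denominator is zero
    if ratio_of_means == 0.0:
        rel = 0.0 if mean_of_ratios == 0.0 else float("inf")
    else:
        rel = 100.0 * abs(mean_of_ratios - ratio_of_means) / abs(ratio_of_means)
    return RatioBiasReport(
        form=form,
        mean_of_ratios=mean_of_ratios,
        ratio_of_means=ratio_of_means,
        relative_difference_pct=rel,
        n_combinations=n_combinations,
        n_excluded=n_excluded,
    )


def ratio_bias_table(obs_set: ObservationSet, form: str = "scaled") -> pd.DataFrame:
    """Ratio-bias diagnostics for every estimable ordered pair of a dataset."""
    bset = build_binary_set(obs_set, form=form)
    rows = []
    for (i, j) in bset.estimated_pairs():
        pair_obs = obs_set.get((i, j))
        axenic = obs_set.get((i,))
        try:
            report = ratio_bias(
                axenic.abundances[i],
                pair_obs.abundances[i],
                pair_obs.abundances[j],
                form=form,
            )
        except UnidentifiableError:
            continue
        rows.append(
            (
                i,
                j,
                form,
                report.mean_of_ratios,
                report.ratio_of_means,
                report.relative_difference_pct,
                report.n_combinations,
                report.n_excluded,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "affected",
            "influencer",
            "form",
            "mean_of_ratios",
            "ratio_of_means",
            "relative_difference_pct",
            "n_combinations",
            "n_excluded",
        ],
    )


def perturb_lognormal(obs_set: ObservationSet, spec: NoiseSpec) -> ObservationSet:
    """Return a copy of the observation set with multiplicative lognormal
    noise applied to every replicate value.

    Zeros stay zero, so the growth/no-growth pattern is preserved.  The
    transform is reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    perturbed = []
    for key in sorted(obs_set.observations):
        obs = obs_set.observations[key]
        abundances = {}
        for sp in obs.members:
            values = np.asarray(obs.abundances[sp], dtype=float)
            eps = rng.normal(0.0, spec.sigma, size=values.shape)
            abundances[sp] = tuple(values * np.exp(eps))
        perturbed.append(CommunityObservation(obs.members, abundances))
    return ObservationSet(
        perturbed,
        detection_limit=obs_set.detection_limit,
        aggregation=obs_set.aggregation,
    )


def robustness_curve(
    obs_set: ObservationSet,
    truth: Mapping[str, CoefficientMatrix],
    sigmas: Sequence[float],
    n_trials: int,
    seed: int,
    form: str = "scaled",
    assignments: Mapping[Tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Median and IQR of elementwise |predicted - truth| per noise level.

    For each sigma, ``n_trials`` perturbed copies of the data are pushed
    through the full pipeline (binary estimation + projection) and compared
    against the reference complex matrices.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sigma in sigmas:
        errors = []
        for _ in range(n_trials):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            noisy = perturb_lognormal(
                obs_set, NoiseSpec(sigma=float(sigma), seed=trial_seed)
            )
            bset = build_binary_set(noisy, form=form)
            for key, ref in truth.items():
                cmat = predict_community(bset, noisy, key, assignments)
                for pair, ref_value in ref.entries.items():
                    errors.append(abs(cmat.entries[pair] - ref_value))
        errors_arr = np.asarray(errors)
        q25, q50, q75 = np.percentile(errors_arr, [25, 50, 75])
        rows.append((float(sigma), q50, q75 - q25, q25, q75, errors_arr.size))
    return pd.DataFrame(
        rows,
        columns=["sigma", "median_abs_error", "iqr", "q25", "q75", "n_values"],
    )
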