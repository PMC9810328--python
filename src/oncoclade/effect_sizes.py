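"""Estimation statistics for cross-clade phenotype comparisons.

Group comparisons (e.g. fibroblast population doubling times of one clade
versus other mammals) are summarised as an unpaired mean difference with a
bias-corrected-and-accelerated (BCa) bootstrap confidence interval and a
two-sided permutation test. The permutation statistic is Welch's t —
group sizes in clade-versus-rest comparisons are very unbalanced — with
label reshuffles enumerated exhaustively when feasible and sampled
otherwise (5000 by default).

Also provided: doubling-time extraction from confluence time series
(hours from ~20% to ~40% confluence, linearly interpolated) and fold-
change normalisation of plate readings to the no-drug control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "MeanDiffResult",
    "unpaired_mean_difference",
    "doubling_time_from_confluence",
    "normalize_to_control",
]


@dataclass
class MeanDiffResult:
    difference: float  # test mean - control mean
    ci_low: float
    ci_high: float
    p_value: float
    n_control: int
    n_test: int
    n_boot: int
    n_perm: int
    exact: bool  # permutation null enumerated exhaustively
    seed: int
    degenerate: bool = False


def _welch_t(x, y, axis=-1):
    return stats.ttest_ind(x, y, axis=axis, equal_var=False).statistic


def unpaired_mean_difference(
    control,
    test,
    n_boot: int = 5000,
    n_perm: int = 5000,
    seed: int = 0,
    ci_method: str = "BCa",
) -> MeanDiffResult:
    """Mean(test) - mean(control) with BCa bootstrap CI and permutation p.

    ``ci_method`` may be "BCa" (default) or "percentile". The permutation
    p-value is the fraction of label reshuffles whose |Welch t| is at least
    the observed |t| (exhaustive when the number of distinct reshuffles is
    <= ``n_perm``). Groups that are jointly degenerate (zero variance,
    identical means) yield p = 1 and a zero-width CI, flagged.
    """
    control = np.asarray(control, dtype=float)
    test = np.asarray(test, dtype=float)
    if control.size < 2 or test.size < 2:
        raise ValueError("both groups need at least 2 values")
    if not (np.isfinite(control).all() and np.isfinite(test).all()):
        raise ValueError("group values must be finite")
    diff = float(test.mean() - control.mean())

    pooled = np.concatenate([control, test])
    if np.ptp(pooled) == 0:
        return MeanDiffResult(0.0, 0.0, 0.0, 1.0, control.size, test.size,
                              n_boot, n_perm, exact=True, seed=seed, degenerate=True)

    rng = np.random.default_rng(seed)

    def statistic(c, t, axis=-1):
        return np.mean(t, axis=axis) - np.mean(c, axis=axis)

    boot = stats.bootstrap(
        (control, test),
        statistic,
        n_resamples=n_boot,
        method="BCa" if ci_method == "BCa" else "percentile",
        confidence_level=0.95,
        rng=rng,
        paired=False,
        vectorized=True,
    )
    ci_low, ci_high = float(boot.confidence_interval.low), float(
        boot.confidence_interval.high
    )

    n_total = control.size + test.size
    n_distinct = special.comb(n_total, test.size, exact=True)
    perm = stats.permutation_test(
        (control, test),
        _welch_t,
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=n_perm,
        rng=rng,
        vectorized=True,
    )
    return MeanDiffResult(
        difference=diff,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(perm.pvalue),
        n_control=control.size,
        n_test=test.size,
        n_boot=n_boot,
        n_perm=n_perm,
        exact=n_distinct <= n_perm,
        seed=seed,
    )


def doubling_time_from_confluence(
    hours, confluence, low: float = 20.0, high: float = 40.0
) -> float:
    """Hours to grow from ``low``% to ``high``% confluence.

    Crossing times are linearly interpolated at the first upward crossing
    of each threshold; the series must be time-sorted and span both
    thresholds.
    """
    hours = np.asarray(hours, dtype=float)
    confluence = np.asarray(confluence, dtype=float)
    if hours.size != confluence.size or hours.size < 2:
        raise ValueError("need matched (hours, confluence) series of length >= 2")
    if np.any(np.diff(hours) < 0):
        raise ValueError("series must be sorted by time")

    def crossing(threshold: float) -> float:
        if confluence[0] >= threshold:
            return float(hours[0])
        above = np.nonzero(confluence >= threshold)[0]
        if above.size == 0:
            raise ValueError(f"series never reaches {threshold}% confluence")
        j = above[0]
        h0, h1 = hours[j - 1], hours[j]
        c0, c1 = confluence[j - 1], confluence[j]
        return float(h0 + (threshold - c0) * (h1 - h0) / (c1 - c0))

    t_high = crossing(high)
    t_low = crossing(low)
    return t_high - t_low


def normalize_to_control(
    dose_response: dict[float, list[float]], control_dose: float = 0.0
) -> dict[float, np.ndarray]:
    """Fold change of each dose's responses over the mean control response."""
    if control_dose not in dose_response:
        raise ValueError(f"control dose {control_dose} not present")
    control_mean = float(np.mean(dose_response[control_dose]))
    if control_mean == 0 or not math.isfinite(control_mean):
        raise ValueError("control responses have zero or non-finite mean")
    return {
        dose: np.asarray(values, dtype=float) / control_mean
        for dose, values in dose_response.items()
    }
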