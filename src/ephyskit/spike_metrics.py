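"""Spike-train statistics over epoched trials.

Rasters, peristimulus time histograms (PSTH) with bootstrap confidence
intervals, direction tuning curves, and trial-by-trial noise correlations
with duplicate-unit flagging. Confidence intervals are percentile bootstrap
over trials (seeded); bad trials are excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ephyskit.epochs import TrialSet


def _require_unit(trials: TrialSet, unit: str) -> list[np.ndarray]:
    if unit not in trials.spikes:
        raise KeyError(f"unknown unit {unit!r}; known units: {trials.units}")
    return trials.spikes[unit]


def raster(trials: TrialSet, unit: str) -> list[np.ndarray]:
    """Per-trial relative spike times, in trial order (bad trials included,
    so rows align with the trial set)."""
    return [np.asarray(t, dtype=float) for t in _require_unit(trials, unit)]


@dataclass
class Psth:
    """Trial-averaged binned firing rate with bootstrap confidence band."""

    bin_edges: np.ndarray  # seconds, uniform
    rate: np.ndarray  # spikes/s per bin
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_trials: int
    unit_id: str

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def total_spikes(self) -> float:
        """Sum of rate * width * n_trials: the spike count the PSTH conserves."""
        return float(np.sum(self.rate) * self.bin_width * self.n_trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_s": self.bin_edges[:-1],
                "bin_end_s": self.bin_edges[1:],
                "rate_hz": self.rate,
                "ci_low_hz": self.ci_low,
                "ci_high_hz": self.ci_high,
            }
        )


def _bin_counts(per_trial: Sequence[np.ndarray], edges: np.ndarray) -> np.ndarray:
    """Trials x bins spike-count matrix (half-open bins, last edge exclusive)."""
    counts = np.zeros((len(per_trial), edges.size - 1))
    for i, times in enumerate(per_trial):
        if len(times):
            idx = np.searchsorted(edges, times, side="right") - 1
            ok = (idx >= 0) & (idx < edges.size - 1) & (times < edges[-1])
            np.add.at(counts[i], idx[ok], 1)
    return counts


def psth(
    trials: TrialSet,
    unit: str,
    bin_width: float = 0.010,
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> Psth:
    """PSTH over the full trial window with ``bin_width`` s bins (default
    10 ms) and a percentile-bootstrap confidence band over trials.

    rate(bin) = total spikes in bin / (n_good_trials * bin_width), so
    summing rate * width * n_trials returns the total spike count exactly.
    """
    per_trial_all = _require_unit(trials, unit)
    good = trials.good_trials()
    if good.size == 0:
        raise ValueError("PSTH needs at least one good trial")
    w0, w1 = trials.window
    n_bins_f = (w1 - w0) / bin_width
    n_bins = int(round(n_bins_f))
    if n_bins < 1 or abs(n_bins_f - n_bins) > 1e-6:
        raise ValueError(
            f"bin width {bin_width} s does not divide the window {trials.window}"
        )
    edges = w0 + np.arange(n_bins + 1) * bin_width
    per_trial = [per_trial_all[i] for i in good]
    counts = _bin_counts(per_trial, edges)
    n = len(per_trial)
    rate = counts.sum(axis=0) / (n * bin_width)

    if counts.sum() == 0:
        ci_low = ci_high = np.zeros(n_bins)
    else:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, n_bins))
        for b in range(n_boot):
            pick = rng.integers(0, n, size=n)
            boots[b] = counts[pick].sum(axis=0) / (n * bin_width)
        alpha = (1 - ci_level) / 2
        ci_low = np.quantile(boots, alpha, axis=0)
        ci_high = np.quantile(boots, 1 - alpha, axis=0)

    return Psth(
        bin_edges=edges,
        rate=rate,
        ci_low=ci_low,
        ci_high=ci_high,
        n_trials=n,
        unit_id=unit,
    )


@dataclass
class TuningCurve:
    """Mean spike count per condition (in a count window) with bootstrap CI,
    conditions in the user-specified order."""

    condition_order: list[str]
    mean_count: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    count_window: tuple[float, float]
    unit_id: str

    def preferred_condition(self) -> str:
        return self.condition_order[int(np.argmax(self.mean_count))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition_order,
                "mean_count": self.mean_count,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _counts_in_window(
    per_trial: Sequence[np.ndarray], window: tuple[float, float]
) -> np.ndarray:
    t0, t1 = window
    return np.array(
        [np.count_nonzero((t >= t0) & (t < t1)) for t in per_trial], dtype=float
    )


def tuning_curve(
    trials: TrialSet,
    unit: str,
    condition_order: Sequence[str],
    count_window: tuple[float, float] = (0.0, 0.3),
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> TuningCurve:
    """Mean spike count per condition inside ``count_window`` ``[t0, t1)``,
    with a percentile-bootstrap CI per condition."""
    per_trial = _require_unit(trials, unit)
    w0, w1 = trials.window
    t0, t1 = count_window
    if not (w0 <= t0 < t1 <= w1):
        raise ValueError(
            f"count window {count_window} outside the epoch window {trials.window}"
        )
    rng = np.random.default_rng(seed)
    alpha = (1 - ci_level) / 2
    means, lows, highs = [], [], []
    for cond in condition_order:
        idx = trials.trials_of(cond)
        if idx.size == 0:
            raise ValueError(f"condition {cond!r} has no good trials")
        counts = _counts_in_window([per_trial[i] for i in idx], count_window)
        means.append(counts.mean())
        boots = np.array(
            [
                counts[rng.integers(0, counts.size, size=counts.size)].mean()
                for _ in range(n_boot)
            ]
        )
        lows.append(np.quantile(boots, alpha))
        highs.append(np.quantile(boots, 1 - alpha))
    return TuningCurve(
        condition_order=list(condition_order),
        mean_count=np.array(means),
        ci_low=np.array(lows),
        ci_high=np.array(highs),
        count_window=(t0, t1),
        unit_id=unit,
    )


@dataclass
class NoiseCorrMatrix:
    """Pairwise Pearson correlation of trial-by-trial spike counts.

    ``flags`` lists unit pairs whose correlation exceeds the duplicate
    threshold — on a multi-contact probe these are candidate duplicate
    units picked up by neighboring channels.
    """

    units: list[str]
    r: np.ndarray
    count_window: tuple[float, float]
    flags: list[tuple[str, str, float]] = field(default_factory=list)
    excluded_units: list[str] = field(default_factory=list)

    def pair(self, u1: str, u2: str) -> float:
        return float(self.r[self.units.index(u1), self.units.index(u2)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.units, columns=self.units)


def noise_correlation(
    trials: TrialSet,
    count_window: tuple[float, float] = (0.0, 0.3),
    center: str = "per_condition_mean",
    duplicate_threshold: float = 0.8,
) -> NoiseCorrMatrix:
    """All-pairs noise correlation of spike counts in ``count_window``.

    With ``center='per_condition_mean'`` each condition's mean count is
    subtracted per unit before pooling residuals across conditions (the
    standard noise-correlation definition); ``center='none'`` correlates the
    raw counts — on a single-condition trial set the two coincide up to a
    constant. Units with zero count variance are excluded (and reported);
    pairs above ``duplicate_threshold`` are flagged.
    """
    if center not in ("per_condition_mean", "none"):
        raise ValueError("center must be 'per_condition_mean' or 'none'")
    good = trials.good_trials()
    if good.size < 3:
        raise ValueError("noise correlation needs at least 3 good trials")
    units = trials.units
    counts = np.stack(
        [
            _counts_in_window([trials.spikes[u][i] for i in good], count_window)
            for u in units
        ]
    )  # units x trials

    if center == "per_condition_mean":
        conds = np.array([trials.conditions[i] for i in good])
        resid = counts.astype(float).copy()
        for cond in np.unique(conds):
            m = conds == cond
            resid[:, m] -= resid[:, m].mean(axis=1, keepdims=True)
    else:
        resid = counts.astype(float)

    var = resid.var(axis=1)
    keep = var > 0
    excluded = [u for u, k in zip(units, keep) if not k]
    kept_units = [u for u, k in zip(units, keep) if k]
    if len(kept_units) < 2:
        raise ValueError(
            "noise correlation needs at least 2 units with nonzero count "
            f"variance; excluded: {excluded}"
        )
    r = np.corrcoef(resid[keep])
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    flags = []
    for i in range(len(kept_units)):
        for j in range(i + 1, len(kept_units)):
            if r[i, j] > duplicate_threshold:
                flags.append((kept_units[i], kept_units[j], float(r[i, j])))
    return NoiseCorrMatrix(
        units=kept_units,
        r=r,
        count_window=tuple(count_window),
        flags=flags,
        excluded_units=excluded,
    )
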