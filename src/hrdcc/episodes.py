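"""Haptoglobin-defined inflammation episodes and their cell-count shifts.

An episode is a maximal run of consecutive visits whose haptoglobin
exceeds a threshold (default: baseline + 3 baseline-SD).  Episode
contrasts quantify how a cell population differs between in-episode and
out-of-episode visits; marker correlations test (absence of) association
between a population and haptoglobin, e.g. the immature-granulocyte null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DetectedEpisode:
    animal_id: str
    start: int                # DIM of first above-threshold visit
    end: int                  # DIM of last above-threshold visit
    peak_haptoglobin: float
    n_visits: int

    def contains(self, dim: int) -> bool:
        return self.start <= dim <= self.end


@dataclass
class EpisodeContrast:
    population: str
    in_mean: float | None
    out_mean: float | None
    difference: float | None
    p_value: float | None
    n_in: int
    n_out: int
    reason: str | None = None


def detect_episodes(dims: np.ndarray, haptoglobin: np.ndarray, threshold: float,
                    min_consecutive: int = 2, animal_id: str = "",
                    ) -> list[DetectedEpisode]:
    """Maximal runs of >= ``min_consecutive`` consecutive visits above
    ``threshold``.  A single sub-threshold visit separates two runs."""
    dims = np.asarray(dims)
    hp = np.asarray(haptoglobin, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if np.any(np.diff(dims) < 0):
        raise ValueError("series must be sorted by DIM")
    above = hp > threshold
    episodes: list[DetectedEpisode] = []
    i = 0
    n = len(dims)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_consecutive:
                episodes.append(DetectedEpisode(
                    animal_id, int(dims[i]), int(dims[j]),
                    float(hp[i:j + 1].max()), j - i + 1))
            i = j + 1
        else:
            i += 1
    return episodes


def episode_contrast(dims: np.ndarray, values: np.ndarray,
                     episodes: list, population: str = "",
                     min_visits: int = 3, detrend: bool = False,
                     ) -> EpisodeContrast:
    """In-episode minus out-of-episode mean with a two-sided rank-sum
    test; returns a null contrast (with reason) when either side has
    fewer than ``min_visits`` visits.

    With ``detrend=True`` the comparison runs on residuals from a 4-knot
    spline fitted to the out-of-episode visits only, so a population with
    a strong lactation trend (e.g. declining gamma-delta T cells) is
    contrasted against the animal's own baseline curve rather than the
    pooled raw values.
    """
    dims = np.asarray(dims)
    values = np.asarray(values, dtype=float)
    in_mask = np.array([any(ep.contains(int(d)) for ep in episodes) for d in dims])
    if detrend and (~in_mask).sum() >= 9:
        from .longitudinal import fit_spline4
        fit = fit_spline4(dims[~in_mask], values[~in_mask])
        values = values - np.asarray(fit.predict(dims), dtype=float)
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < min_visits or n_out < min_visits:
        return EpisodeContrast(population, None, None, None, None, n_in, n_out,
                               reason=f"need >= {min_visits} visits on each side")
    inside, outside = values[in_mask], values[~in_mask]
    diff = float(inside.mean() - outside.mean())
    if np.ptp(values) == 0:
        return EpisodeContrast(population, float(inside.mean()),
                               float(outside.mean()), 0.0, 1.0, n_in, n_out)
    p = float(stats.mannwhitneyu(inside, outside, alternative="two-sided").pvalue)
    return EpisodeContrast(population, float(inside.mean()), float(outside.mean()),
                           diff, p, n_in, n_out)


def marker_correlation(x: np.ndarray, y: np.ndarray,
                       ) -> tuple[float, tuple[float, float], float]:
    """Pearson r with a Fisher-z 95% confidence interval and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must be paired and equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(len(x) - 3)
    lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    return float(r), (float(lo), float(hi)), float(p)
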