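"""Normalization, Pearson factor screening, and train/validation splitting.

Features are mapped to [-1, 1] by ``y = 2(x - xmin)/(xmax - xmin) - 1``; the
per-feature (xmin, xmax) pairs are fitted on data (training split only in the
pipeline, to avoid leakage) and invert the map exactly.

The factor screen computes the Pearson correlation of each candidate driver
(environment and fluorescence) with the net photosynthetic rate, using the
population (divide-by-n) standard deviations and covariance — algebraically
identical to the sample (n-1) form, since the n factors cancel in the ratio —
and a two-sided t test with n-2 degrees of freedom for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, DegenerateFeatureError,
                     UndefinedCorrelationError)
from .synthetic import Dataset

#: screening candidates, in reporting order, all correlated against Pn
SCREEN_FACTORS = ["tem", "co2", "par", "rh", "qp", "etr", "phips2",
                  "fvpfmp", "npq", "qn"]
ENV_FACTORS = ["tem", "co2", "par", "rh"]
FLUOR_FACTORS = ["qp", "etr", "phips2", "fvpfmp", "npq", "qn"]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (xmin, xmax) ranges backing the [-1, 1] map."""

    ranges: dict[str, tuple[float, float]]

    def __contains__(self, feature: str) -> bool:
        return feature in self.ranges

    def range_of(self, feature: str) -> tuple[float, float]:
        try:
            return self.ranges[feature]
        except KeyError:
            raise KeyError(f"feature '{feature}' was not fitted") from None


def _as_frame(data) -> pd.DataFrame:
    return data.frame if isinstance(data, Dataset) else pd.DataFrame(data)


def fit_normalization(data, feature_names) -> NormalizationParams:
    """Record min/max per feature; rejects constant (degenerate) features."""
    frame = _as_frame(data)
    ranges = {}
    for name in feature_names:
        if name not in frame.columns:
            raise KeyError(f"feature '{name}' not present in data")
        col = np.asarray(frame[name], dtype=float)
        xmin, xmax = float(np.nanmin(col)), float(np.nanmax(col))
        if not xmax > xmin:
            raise DegenerateFeatureError(
                f"feature '{name}' is constant (min == max == {xmin})")
        ranges[name] = (xmin, xmax)
    return NormalizationParams(ranges=ranges)


def normalize(x, params: NormalizationParams, feature: str | None = None):
    """Map values to [-1, 1]; values outside the fitted range map outside
    [-1, 1] without clipping.

    ``x`` may be a scalar/array (with ``feature`` naming its column) or a
    DataFrame whose fitted columns are all transformed.
    """
    if isinstance(x, pd.DataFrame):
        out = x.copy()
        for name in x.columns:
            if name in params:
                out[name] = normalize(x[name].to_numpy(float), params, name)
        return out
    if feature is None:
        raise KeyError("feature name required for non-DataFrame input")
    xmin, xmax = params.range_of(feature)
    y = 2.0 * (np.asarray(x, dtype=float) - xmin) / (xmax - xmin) - 1.0
    return y if y.ndim else float(y)


def denormalize(y, params: NormalizationParams, feature: str | None = None):
    """Exact inverse of :func:`normalize`."""
    if isinstance(y, pd.DataFrame):
        out = y.copy()
        for name in y.columns:
            if name in params:
                out[name] = denormalize(y[name].to_numpy(float), params, name)
        return out
    if feature is None:
        raise KeyError("feature name required for non-DataFrame input")
    xmin, xmax = params.range_of(feature)
    x = (np.asarray(y, dtype=float) + 1.0) * (xmax - xmin) / 2.0 + xmin
    return x if x.ndim else float(x)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Correlation of one factor with Pn, with its two-sided significance."""

    factor: str
    r: float
    n: int
    p_value: float
    significant: bool
    alpha: float = 0.01


def pearson(x, y, factor: str = "", alpha: float = 0.01) -> CorrelationResult:
    """Pearson r via population moments, with a two-sided t test (n-2 df).

    ``r = S_xy / (S_x S_y)`` where ``S_x``/``S_y`` are divide-by-n standard
    deviations and ``S_xy`` the divide-by-n covariance; the t statistic is
    ``r * sqrt((n-2)/(1-r^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedCorrelationError(
            f"series must be 1-d and equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise UndefinedCorrelationError(f"need n >= 3 samples, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc ** 2) / n)
    sy = np.sqrt(np.sum(yc ** 2) / n)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            f"correlation undefined for constant series"
            f"{' (' + factor + ')' if factor else ''}")
    sxy = np.sum(xc * yc) / n
    r = float(np.clip(sxy / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(factor=factor, r=r, n=n, p_value=p,
                             significant=p < alpha, alpha=alpha)


def correlation_screen(data, alpha: float = 0.01,
                       factors=None) -> list[CorrelationResult]:
    """Correlate every candidate factor with Pn.

    Records with ``valid_fluor == False`` are excluded from fluorescence
    correlations.  Constant factors (relative humidity is fixed by design)
    yield a NaN, non-significant result rather than an error, so they are
    carried through the report but can never be selected.
    """
    frame = _as_frame(data)
    factors = list(SCREEN_FACTORS if factors is None else factors)
    results = []
    for name in factors:
        if name not in frame.columns:
            raise KeyError(f"factor '{name}' not present in data")
        sub = frame
        if name in FLUOR_FACTORS and "valid_fluor" in frame.columns:
            sub = frame[frame["valid_fluor"].astype(bool)]
        x = sub[name].to_numpy(float)
        y = sub["pn"].to_numpy(float)
        keep = ~(np.isnan(x) | np.isnan(y))
        try:
            results.append(pearson(x[keep], y[keep], factor=name, alpha=alpha))
        except UndefinedCorrelationError:
            if x[keep].size >= 3 and np.nanstd(x[keep]) == 0.0:
                results.append(CorrelationResult(
                    factor=name, r=float("nan"), n=int(keep.sum()),
                    p_value=float("nan"), significant=False, alpha=alpha))
            else:
                raise
    return results


def select_factors(results, r_threshold: float,
                   alpha: float = 0.01) -> list[str]:
    """Factors significant at ``alpha`` with |r| >= ``r_threshold``, sorted by
    |r| descending; ties keep input order (stable sort)."""
    if not results:
        raise ConfigurationError("no correlation results to select from")
    kept = [res for res in results
            if res.significant and res.p_value < alpha
            and np.isfinite(res.r) and abs(res.r) >= r_threshold]
    kept.sort(key=lambda res: -abs(res.r))
    return [res.factor for res in kept]


def screen_report(results) -> pd.DataFrame:
    """Correlation screen as a tidy table (factor, r, n, p, significance)."""
    return pd.DataFrame([{
        "factor": res.factor, "r": res.r, "n": res.n,
        "p_value": res.p_value, "significant_0.01": res.significant,
    } for res in results])


# ---------------------------------------------------------------------------
# train / validation split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation index arrays covering [0, n)."""

    train: np.ndarray
    validation: np.ndarray
    seed: int
    fraction: float = 0.8

    def __post_init__(self):
        object.__setattr__(self, "train", np.asarray(self.train, dtype=int))
        object.__setattr__(self, "validation",
                           np.asarray(self.validation, dtype=int))


def train_val_split(n: int, fraction: float = 0.8, seed: int = 0) -> SplitIndices:
    """Seeded uniform random split; ``round(fraction * n)`` train indices."""
    if n < 5:
        raise ConfigurationError(f"need at least 5 samples to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return SplitIndices(train=perm[:n_train], validation=perm[n_train:],
                        seed=seed, fraction=fraction)
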