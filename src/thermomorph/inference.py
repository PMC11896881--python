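"""Morph-constrained bootstrap inference.

Individuals are resampled with replacement, whole record at a time (summary
statistics and complete time series move together), under the constraint
that every colour-morph stratum keeps its original sample size.  Percentile
confidence intervals are read off the replicate distribution; a statistic is
"significant" when its CI excludes zero.

Curve-valued statistics (difference-of-means or Spearman correlation per
time point) reuse one set of resamples across all time points, yielding
coherent confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "AnalysisSubset",
    "BootstrapResult",
    "DifferenceCurve",
    "resample_indices",
    "constrained_resample",
    "bootstrap_ci",
    "difference_curve",
    "correlation_curve",
    "spearman_rho",
    "difference_of_means",
]


@dataclass
class AnalysisSubset:
    """One species x sex analysis unit.

    ``summaries`` maps a column name (e.g. ``heatup_internal``, ``mass``,
    ``brightness``) to a float array aligned with ``ids``/``morph``.
    ``series`` maps a channel name to ``(times, matrix)`` with one matrix
    row per individual, aligned with ``ids``.
    """

    species: str
    sex: str
    ids: np.ndarray
    morph: np.ndarray
    summaries: dict = field(default_factory=dict)
    series: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.morph = np.asarray(self.morph, dtype=object)
        if self.ids.shape != self.morph.shape:
            raise ValueError("ids and morph must have equal length")
        n = self.ids.size
        for name, col in self.summaries.items():
            col = np.asarray(col, dtype=float)
            if col.size != n:
                raise ValueError(f"summary column {name!r} has wrong length")
            self.summaries[name] = col
        for name, (times, matrix) in self.series.items():
            matrix = np.asarray(matrix, dtype=float)
            if matrix.shape[0] != n:
                raise ValueError(f"series {name!r} has wrong row count")
            self.series[name] = (np.asarray(times, dtype=float), matrix)

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def morph_counts(self) -> dict:
        values, counts = np.unique(self.morph.astype(str), return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def morphs_present(self) -> list:
        seen: list = []
        for m in self.morph:
            if m not in seen:
                seen.append(m)
        return seen

    def take(self, idx: np.ndarray) -> "AnalysisSubset":
        """Row-select a view-like copy (used by the resampler)."""
        return AnalysisSubset(
            species=self.species,
            sex=self.sex,
            ids=self.ids[idx],
            morph=self.morph[idx],
            summaries={k: v[idx] for k, v in self.summaries.items()},
            series={k: (t, m[idx]) for k, (t, m) in self.series.items()},
        )


@dataclass
class BootstrapResult:
    label: str
    estimate: float
    replicates: np.ndarray
    level: float
    ci_low: float
    ci_high: float
    n_missing: int
    valid: bool
    seed: int | None = None

    @property
    def excludes_zero(self) -> bool:
        return bool(self.valid and (self.ci_low > 0.0 or self.ci_high < 0.0))


@dataclass
class DifferenceCurve:
    """Per-time-point statistic with a coherent bootstrap confidence band.

    Sign convention for group contrasts: positive means the first group is
    hotter (mean_a - mean_b).
    """

    label: str
    times: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float
    convention: str = "positive => first group hotter"

    def excludes_zero(self) -> np.ndarray:
        return (self.ci_low > 0.0) | (self.ci_high < 0.0)


def _stratum_indices(morph: np.ndarray) -> list[np.ndarray]:
    """Index arrays per morph stratum, in order of first appearance."""
    morph = np.asarray(morph, dtype=object)
    strata = []
    seen = []
    for m in morph:
        if m not in seen:
            seen.append(m)
    for m in seen:
        idx = np.nonzero(morph == m)[0]
        strata.append(idx)
    return strata


def resample_indices(
    morph: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One constrained resample: with replacement within each morph stratum.

    Every stratum contributes exactly its original count; the total subset
    size is therefore preserved.
    """
    strata = _stratum_indices(morph)
    if any(s.size == 0 for s in strata):
        raise ValueError("empty morph stratum")
    parts = [s[rng.integers(0, s.size, s.size)] for s in strata]
    return np.concatenate(parts)


def constrained_resample(
    subset: AnalysisSubset, seed: int | np.random.Generator | None = None
) -> AnalysisSubset:
    """Resample whole individuals with morph strata sizes held fixed."""
    if subset.n == 0:
        raise ValueError("cannot resample an empty subset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return subset.take(resample_indices(subset.morph, rng))


def bootstrap_ci(
    subset: AnalysisSubset,
    statistic_fn,
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    label: str = "",
    max_missing_frac: float = 0.5,
    quantile_method: str = "linear",
) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic_fn`` under constrained resampling.

    The point estimate is computed on the original subset (never resampled).
    Replicates on which the statistic is undefined (NaN) are recorded as
    missing; the result is flagged invalid when more than
    ``max_missing_frac`` of replicates are missing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    estimate = float(statistic_fn(subset))
    strata = _stratum_indices(subset.morph)
    if any(s.size == 0 for s in strata):
        raise ValueError("empty morph stratum")
    replicates = np.empty(B)
    for b in range(B):
        parts = [s[rng.integers(0, s.size, s.size)] for s in strata]
        replicates[b] = statistic_fn(subset.take(np.concatenate(parts)))
    finite = replicates[np.isfinite(replicates)]
    n_missing = B - finite.size
    valid = n_missing <= max_missing_frac * B and finite.size > 0
    if finite.size:
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(finite, [alpha, 1.0 - alpha], method=quantile_method)
    else:
        lo = hi = float("nan")
    return BootstrapResult(
        label=label,
        estimate=estimate,
        replicates=replicates,
        level=level,
        ci_low=float(lo),
        ci_high=float(hi),
        n_missing=int(n_missing),
        valid=bool(valid),
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def difference_of_means(column: str, group_a: str, group_b: str):
    """Statistic factory: mean(column | morph==a) - mean(column | morph==b).

    Available-case means: NaN values inside a group are skipped; NaN is
    returned when a group has no finite value.
    """

    def stat(subset: AnalysisSubset) -> float:
        values = subset.summaries[column]
        mask_a = subset.morph == group_a
        mask_b = subset.morph == group_b
        va = values[mask_a]
        vb = values[mask_b]
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        if va.size == 0 or vb.size == 0:
            return float("nan")
        return float(va.mean() - vb.mean())

    stat.__name__ = f"mean_{group_a}_minus_{group_b}[{column}]"
    return stat


def difference_curve(
    subset: AnalysisSubset,
    group_a: str,
    group_b: str,
    channel: str,
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    quantile_method: str = "linear",
) -> DifferenceCurve:
    """mean_a(t) - mean_b(t) with a coherent bootstrap band.

    One constrained resample is drawn per replicate and evaluated at every
    time point (bands are not bootstrapped independently per t).
    """
    if channel not in subset.series:
        raise ValueError(f"subset has no series {channel!r}")
    times, matrix = subset.series[channel]
    for g in (group_a, group_b):
        if not np.any(subset.morph == g):
            raise ValueError(f"group {g!r} absent from subset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def curve(morph: np.ndarray, mat: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN time cells
            return np.nanmean(mat[morph == group_a], axis=0) - np.nanmean(
                mat[morph == group_b], axis=0
            )

    estimate = curve(subset.morph, matrix)
    strata = _stratum_indices(subset.morph)
    reps = np.empty((B, times.size))
    for b in range(B):
        idx = np.concatenate([s[rng.integers(0, s.size, s.size)] for s in strata])
        reps[b] = curve(subset.morph[idx], matrix[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(reps, [alpha, 1.0 - alpha], axis=0, method=quantile_method)
    return DifferenceCurve(
        label=f"{group_a}-{group_b}[{channel}]",
        times=times,
        estimate=estimate,
        ci_low=lo,
        ci_high=hi,
        level=level,
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Returns NaN when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def _spearman_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Spearman rho of ``x`` against every column of ``Y`` (vectorised)."""
    rx = rankdata(x)
    rY = rankdata(Y, axis=0)
    rx = rx - rx.mean()
    rY = rY - rY.mean(axis=0)
    sx = np.sqrt(np.sum(rx**2))
    sY = np.sqrt(np.sum(rY**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ rY) / (sx * sY)
    rho[~np.isfinite(rho)] = np.nan
    if sx == 0.0:
        rho[:] = np.nan
    return rho


def _spearman_columns_nanaware(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Available-case Spearman per column (slow path for series with NaNs)."""
    out = np.full(Y.shape[1], np.nan)
    for j in range(Y.shape[1]):
        col = Y[:, j]
        valid = np.isfinite(col) & np.isfinite(x)
        if valid.sum() >= 3:
            out[j] = spearman_rho(x[valid], col[valid])
    return out


def correlation_curve(
    subset: AnalysisSubset,
    covariate: str,
    channel: str,
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    quantile_method: str = "linear",
) -> DifferenceCurve:
    """Spearman correlation of a covariate with T(t), per time point.

    Morph strata are preserved in the resamples (same scheme as the group
    contrasts).  Positive means higher-covariate individuals are hotter.
    """
    if covariate not in subset.summaries:
        raise ValueError(f"subset has no covariate {covariate!r}")
    if channel not in subset.series:
        raise ValueError(f"subset has no series {channel!r}")
    cov = subset.summaries[covariate]
    if not np.all(np.isfinite(cov)):
        raise ValueError(f"covariate {covariate!r} has missing values")
    times, matrix = subset.series[channel]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spearman_fn = (
        _spearman_columns_nanaware if np.isnan(matrix).any() else _spearman_columns
    )
    estimate = spearman_fn(cov, matrix)
    strata = _stratum_indices(subset.morph)
    reps = np.empty((B, times.size))
    for b in range(B):
        idx = np.concatenate([s[rng.integers(0, s.size, s.size)] for s in strata])
        reps[b] = spearman_fn(cov[idx], matrix[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(reps, [alpha, 1.0 - alpha], axis=0, method=quantile_method)
    return DifferenceCurve(
        label=f"rho({covariate})[{channel}]",
        times=times,
        estimate=estimate,
        ci_low=lo,
        ci_high=hi,
        level=level,
        convention="positive => higher covariate hotter",
    )
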