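"""Regional hyperemia quantification and nonparametric group comparison.

Relative-CBV maps are averaged over named anatomical masks (cortex,
hippocampus, thalamus, whole slice), summarised as time-normalized areas
under the curve over a protocol window, and compared between groups with
an exact Mann-Whitney U test and Cohen's d effect sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RegionSet",
    "RegionTimeSeries",
    "GroupComparison",
    "default_region_set",
    "spatial_average",
    "normalized_auc",
    "mann_whitney_exact",
    "cohens_d",
    "group_pipeline",
]


@dataclass
class RegionSet:
    """Named boolean masks on the image grid.

    ``whole_slice`` must be present and be a superset of every other mask.
    Masks may overlap; each must be non-empty.
    """

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if "whole_slice" not in self.masks:
            raise ValueError("RegionSet requires a 'whole_slice' mask")
        whole = np.asarray(self.masks["whole_slice"], dtype=bool)
        shape = whole.shape
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != {shape}")
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")
            if not np.all(whole | ~m):
                raise ValueError(f"mask {name!r} is not contained in whole_slice")
            self.masks[name] = m

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.masks["whole_slice"].shape

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks


# Fractional (row, col) bounds of the named regions on a coronal slice.
# Chosen so that the cortex is a superficial band and hippocampus/thalamus
# are progressively deeper structures, mimicking the manually segmented
# regions of a rabbit brain coronal view.
_REGION_BOUNDS: dict[str, tuple[float, float, float, float]] = {
    "cortex": (0.09, 0.30, 0.05, 0.95),
    "hippocampus": (0.40, 0.63, 0.22, 0.78),
    "thalamus": (0.68, 0.91, 0.28, 0.72),
}


def default_region_set(grid_shape: tuple[int, int] = (64, 64),
                       n_depth_layers: int = 0) -> RegionSet:
    """Build the shipped region set on ``grid_shape``.

    Regions are axis-aligned rectangles at fixed fractional positions so
    that their relative areas are grid-independent.  ``n_depth_layers``
    optionally adds equal-depth cortical layer masks (``cortex_layer_i``)
    splitting the cortex band from shallow to deep.
    """
    nz, nx = grid_shape
    masks: dict[str, np.ndarray] = {
        "whole_slice": np.ones(grid_shape, dtype=bool)
    }
    for name, (r0, r1, c0, c1) in _REGION_BOUNDS.items():
        m = np.zeros(grid_shape, dtype=bool)
        m[int(r0 * nz):int(r1 * nz), int(c0 * nx):int(c1 * nx)] = True
        masks[name] = m
    if n_depth_layers:
        r0, r1, c0, c1 = _REGION_BOUNDS["cortex"]
        z0, z1 = int(r0 * nz), int(r1 * nz)
        edges = np.linspace(z0, z1, n_depth_layers + 1).astype(int)
        for i in range(n_depth_layers):
            m = np.zeros(grid_shape, dtype=bool)
            m[edges[i]:edges[i + 1], int(c0 * nx):int(c1 * nx)] = True
            masks[f"cortex_layer_{i}"] = m
    return RegionSet(masks)


@dataclass
class RegionTimeSeries:
    """Spatially averaged relative UfD signal of one region of one subject.

    Times are minutes relative to the start of CPR (t = 0).  ``artifact``
    flags time points dominated by chest-compression motion artefacts;
    these are excluded from AUC integration and peak detection.
    """

    region: str
    times: np.ndarray          # min, strictly increasing
    values: np.ndarray         # relative UfD, %
    subject: str = ""
    artifact: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.artifact is None:
            self.artifact = np.zeros_like(self.times, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
            if self.artifact.shape != self.times.shape:
                raise ValueError("artifact mask length mismatch")

    def clean(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and values with artifact points and NaNs removed."""
        keep = ~self.artifact & np.isfinite(self.values)
        return self.times[keep], self.values[keep]

    def peak(self, t_min: float | None = 0.0, t_max: float | None = None,
             smooth: int = 1) -> float:
        """Maximum relative UfD over the (artifact-free) series.

        ``smooth`` applies a centred moving average of that many points
        before taking the maximum, which suppresses the upward bias of a
        max taken over noisy samples.
        """
        t, v = self.clean()
        if t_min is not None:
            v = v[t >= t_min]
            t = t[t >= t_min]
        if t_max is not None:
            v = v[t <= t_max]
            t = t[t <= t_max]
        if v.size == 0:
            return math.nan
        if smooth > 1 and v.size >= smooth:
            kernel = np.ones(smooth) / smooth
            v = np.convolve(v, kernel, mode="valid")
        return float(np.max(v))


@dataclass
class GroupComparison:
    """Result of a two-group AUC comparison."""

    groups: tuple[str, str]
    auc: dict[str, list[float]]         # per-subject normalized AUC, %
    window: tuple[float, float]         # min
    u_statistic: float
    p_value: float
    alternative: str
    cohens_d: float
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "window_min": list(self.window),
            "auc_pct": {g: [float(x) for x in v] for g, v in self.auc.items()},
            "U": float(self.u_statistic),
            "p": float(self.p_value),
            "alternative": self.alternative,
            "cohens_d": float(self.cohens_d),
            "summary": self.summary,
        }


def spatial_average(values: np.ndarray, mask: np.ndarray) -> float:
    """Mean of defined (finite) pixel values under a boolean mask.

    Undefined pixels (NaN, e.g. masked by the baseline noise floor) are
    excluded.  A region with no defined pixel yields NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    sel = values[mask]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        warnings.warn("region has no defined pixels", stacklevel=2)
        return math.nan
    return float(sel.mean())


def normalized_auc(series: RegionTimeSeries | tuple[np.ndarray, np.ndarray],
                   t_start: float, t_end: float) -> float:
    """Time-normalized area under the relative UfD curve over a window.

    Trapezoidal integral of the series over ``[t_start, t_end]`` divided
    by the window length, so a constant c% series yields c.  Artifact
    points are dropped before integration; the trapezoid interpolates
    linearly across the gap.  Values at the window edges are obtained by
    linear interpolation of the retained samples.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if isinstance(series, RegionTimeSeries):
        t, v = series.clean()
    else:
        t, v = (np.asarray(a, dtype=float) for a in series)
    if t.size < 2:
        raise ValueError("need at least two points")
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError(
            f"window [{t_start}, {t_end}] outside series support "
            f"[{t[0]}, {t[-1]}]")
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    vv = np.concatenate(([np.interp(t_start, t, v)], v[inside],
                         [np.interp(t_end, t, v)]))
    return float(np.trapezoid(vv, tt) / (t_end - t_start))


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_exact(a: Sequence[float], b: Sequence[float],
                       alternative: str = "two_sided",
                       max_exact: int = 10) -> tuple[float, float]:
    """Exact Mann-Whitney U test by full enumeration of group labelings.

    Returns ``(U, p)`` where ``U`` counts pairs with ``a_i > b_j`` plus
    half a count per tie.  For group sizes up to ``max_exact`` the p-value
    is computed from the exact permutation distribution over all
    ``C(n1 + n2, n1)`` assignments of the pooled observations to the two
    groups (ties handled through midranks, so the null distribution is
    that of the observed multiset).  Larger samples fall back on the
    normal approximation with tie correction, with a warning.

    ``alternative`` is one of ``two_sided``, ``greater`` (a tends larger)
    or ``less``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0        # equals #(a_i > b_j) + ties/2
    mu = n1 * n2 / 2.0
    eps = 1e-9

    if n1 <= max_exact and n2 <= max_exact:
        # Exact permutation distribution of U over all labelings.
        idx = range(n1 + n2)
        offset = n1 * (n1 + 1) / 2.0
        us = np.array([sum(ranks[i] for i in comb) - offset
                       for comb in combinations(idx, n1)])
        total = us.size
        if alternative == "greater":
            p = np.count_nonzero(us >= u - eps) / total
        elif alternative == "less":
            p = np.count_nonzero(us <= u + eps) / total
        else:
            p = np.count_nonzero(np.abs(us - mu) >= abs(u - mu) - eps) / total
        return float(u), float(p)

    warnings.warn("sample too large for exact enumeration; using normal "
                  "approximation", stacklevel=2)
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    from scipy.stats import norm
    if alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = float(norm.sf(z))
    elif alternative == "less":
        z = (u - mu + 0.5) / sigma
        p = float(norm.cdf(z))
    else:
        z = (abs(u - mu) - 0.5) / sigma
        p = float(2 * norm.sf(z))
    return float(u), min(p, 1.0)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with the pooled (n1 + n2 - 2)-denominator SD.

    Positive when group ``a`` has the larger mean.  Returns NaN when the
    pooled SD is zero.  By convention d > 0.8 is considered a large
    effect.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    n1, n2 = a.size, b.size
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        warnings.warn("zero pooled SD; effect size undefined", stacklevel=2)
        return math.nan
    return float((a.mean() - b.mean()) / math.sqrt(s2))


def group_pipeline(series_by_group: Mapping[str, Iterable[RegionTimeSeries]],
                   window: tuple[float, float] = (7.0, 37.0),
                   alternative: str = "two_sided") -> GroupComparison:
    """Per-subject normalized AUC over ``window`` followed by U test and d.

    ``series_by_group`` maps exactly two group labels to the per-subject
    region time series.  Also reports median and interquartile range per
    group (the box-plot quantities).
    """
    groups = list(series_by_group)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    aucs: dict[str, list[float]] = {}
    for g in groups:
        vals = [normalized_auc(s, *window) for s in series_by_group[g]]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} needs at least two subjects")
        aucs[g] = vals
    u, p = mann_whitney_exact(aucs[groups[0]], aucs[groups[1]],
                              alternative=alternative)
    d = cohens_d(aucs[groups[0]], aucs[groups[1]])
    summary = {}
    for g in groups:
        q1, med, q3 = np.percentile(aucs[g], [25, 50, 75])
        summary[g] = {"median": float(med), "iqr_low": float(q1),
                      "iqr_high": float(q3), "mean": float(np.mean(aucs[g])),
                      "sd": float(np.std(aucs[g], ddof=1))}
    return GroupComparison(groups=(groups[0], groups[1]), auc=aucs,
                           window=window, u_statistic=u, p_value=p,
                           alternative=alternative, cohens_d=d,
                           summary=summary)
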