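"""Cerebral-autoregulation assessment by PCA of the CBV-vs-MAP cloud.

Paired (relative CBV %, MAP mmHg) samples pooled over the subjects of a
group are standardized and decomposed into two principal axes.  Intact
autoregulation shows as a near-horizontal first axis with a large weight
ratio (CBV flat across MAP: a plateau); a pressure-passive circulation
as a steep but still strongly anisotropic cloud; impaired regulation as
a cloud with no dominant axis relating CBV to MAP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CbvMapCloud", "PCAResult", "standardize_pooled", "pca2",
           "weight_ratio", "autoregulation_report"]


@dataclass
class CbvMapCloud:
    """Paired samples of one animal group.

    ``x`` is MAP (mmHg, the abscissa of the CBV-vs-MAP plane), ``y`` is
    relative CBV / relative UfD (%).
    """

    cbv: np.ndarray                 # %, relative UfD
    map_mmhg: np.ndarray            # mmHg
    group: str = ""
    window_min: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.cbv = np.asarray(self.cbv, dtype=float)
        self.map_mmhg = np.asarray(self.map_mmhg, dtype=float)
        if self.cbv.shape != self.map_mmhg.shape or self.cbv.ndim != 1:
            raise ValueError("cbv and map must be equal-length 1-D arrays")
        if np.any((self.map_mmhg < 0) | (self.map_mmhg > 300)):
            raise ValueError("MAP outside physical bounds (0-300 mmHg)")

    @property
    def n(self) -> int:
        return self.cbv.size


@dataclass
class PCAResult:
    """Principal axes of the standardized (MAP, CBV) cloud.

    ``v1``/``v2`` are unit vectors in the (MAP, CBV) plane with
    ``lambda1 >= lambda2 >= 0`` the associated variances; the sign of
    each vector is fixed so its first nonzero coordinate is nonnegative.
    """

    v1: np.ndarray
    v2: np.ndarray
    lambda1: float
    lambda2: float

    @property
    def angle_deg(self) -> float:
        """Orientation of v1 versus the MAP axis, in (-90, 90] degrees."""
        a = math.degrees(math.atan2(self.v1[1], self.v1[0]))
        if a > 90:
            a -= 180
        elif a <= -90:
            a += 180
        return a


def standardize_pooled(cloud: CbvMapCloud, mode: str = "pooled"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Standardize the cloud to zero mean, returning (map_std, cbv_std).

    ``mode='pooled'`` (default) removes each variable's mean and divides
    both centred variables by the single standard deviation of their
    concatenation, preserving the native anisotropy between CBV and MAP
    spreads.  ``mode='per_variable'`` z-scores each variable separately,
    which forces unit variance on both axes (total PCA weight exactly 2)
    and reduces the axis anisotropy to the correlation alone.
    """
    if cloud.n < 3:
        raise ValueError("need at least 3 samples")
    cx = cloud.map_mmhg - cloud.map_mmhg.mean()
    cy = cloud.cbv - cloud.cbv.mean()
    if mode == "pooled":
        scale = np.std(np.concatenate([cx, cy]), ddof=1)
        if scale == 0:
            raise ValueError("zero spread in both variables")
        return cx / scale, cy / scale
    if mode == "per_variable":
        sx, sy = np.std(cx, ddof=1), np.std(cy, ddof=1)
        if sx == 0 or sy == 0:
            raise ValueError("zero spread in a variable")
        return cx / sx, cy / sy
    raise ValueError(f"unknown mode {mode!r}")


def pca2(x: np.ndarray, y: np.ndarray) -> PCAResult:
    """Eigen-decomposition of the 2x2 sample covariance of (x, y).

    Uses the n-1 denominator; lambda1 + lambda2 equals the covariance
    trace and v1 is orthogonal to v2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need two equal-length arrays of >= 3 samples")
    cov = np.cov(np.vstack([x, y]), ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0:
        raise ValueError("degenerate (rank-0) covariance")
    order = [1, 0]                           # descending
    evals = np.clip(evals[order], 0.0, None)
    vecs = []
    for i in range(2):
        v = evecs[:, order[i]]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        vecs.append(v)
    return PCAResult(v1=vecs[0], v2=vecs[1],
                     lambda1=float(evals[0]), lambda2=float(evals[1]))


def weight_ratio(result: PCAResult) -> float:
    """Anisotropy of the cloud: lambda1 / lambda2 (inf when lambda2 = 0)."""
    if result.lambda2 <= 0:
        return math.inf
    return result.lambda1 / result.lambda2


def autoregulation_report(clouds: dict[str, CbvMapCloud],
                          mode: str = "pooled",
                          angle_flat_deg: float = 15.0,
                          angle_steep_deg: float = 75.0,
                          ratio_high: float = 5.0,
                          ratio_low: float = 3.0) -> dict[str, dict]:
    """Per-group PCA with a three-way autoregulation classification.

    * ``plateau`` - |angle| below ``angle_flat_deg`` and ratio above
      ``ratio_high``: CBV held constant across MAP (intact regulation);
    * ``impaired`` - ratio below ``ratio_low`` (no dominant axis) or v1
      steeper than ``angle_steep_deg`` (CBV varies with no MAP
      counterpart);
    * ``linear_steep`` - everything else: a clear but steep linear
      CBV-MAP relationship (pressure-passive regime).
    """
    report: dict[str, dict] = {}
    for group, cloud in clouds.items():
        x, y = standardize_pooled(cloud, mode=mode)
        res = pca2(x, y)
        ratio = weight_ratio(res)
        angle = res.angle_deg
        if ratio < ratio_low or abs(angle) > angle_steep_deg:
            label = "impaired"
        elif abs(angle) <= angle_flat_deg and ratio >= ratio_high:
            label = "plateau"
        else:
            label = "linear_steep"
        report[group] = {
            "n": cloud.n,
            "v1": [float(res.v1[0]), float(res.v1[1])],
            "v2": [float(res.v2[0]), float(res.v2[1])],
            "lambda1": res.lambda1,
            "lambda2": res.lambda2,
            "ratio": float(ratio) if math.isfinite(ratio) else None,
            "angle_deg": angle,
            "label": label,
        }
    return report
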