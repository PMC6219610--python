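"""Spatiotemporal SVD clutter filtering of IQ blocks.

The block is rearranged into its Casorati matrix (rows = pixels, columns
= frames) and decomposed; tissue clutter, being spatially coherent and
slowly varying, concentrates in the leading singular components, which
are removed to leave the blood signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .synthetic_data import IQBlock

__all__ = ["CasoratiMatrix", "SVDFilterSpec", "to_casorati",
           "from_casorati", "svd_filter", "singular_spectrum"]


@dataclass
class CasoratiMatrix:
    """Space x time rearrangement of an IQ block.

    Rows are pixels in fixed row-major (depth-major) order, columns are
    frames; the flattening is lossless and invertible.
    """

    matrix: np.ndarray             # (nz * nx, nt)
    grid_shape: tuple[int, int]
    frame_rate: float
    t0: float

    def __post_init__(self) -> None:
        nz, nx = self.grid_shape
        if self.matrix.shape[0] != nz * nx:
            raise ValueError("row count does not match grid")


def to_casorati(block: IQBlock) -> CasoratiMatrix:
    """Flatten a block to its Casorati matrix (no copy when possible)."""
    if block.data.size == 0:
        raise ValueError("empty block")
    nz, nx = block.grid_shape
    return CasoratiMatrix(matrix=block.data.reshape(nz * nx, block.n_frames),
                          grid_shape=block.grid_shape,
                          frame_rate=block.frame_rate, t0=block.t0)


def from_casorati(cas: CasoratiMatrix) -> IQBlock:
    """Invert :func:`to_casorati`; the round trip is the identity."""
    nz, nx = cas.grid_shape
    return IQBlock(data=cas.matrix.reshape(nz, nx, -1),
                   frame_rate=cas.frame_rate, t0=cas.t0)


@dataclass(frozen=True)
class SVDFilterSpec:
    """Which singular components to discard.

    ``mode='count'`` removes the leading ``cutoff`` components (the
    default, 2, matches the synthetic two-mode tissue clutter);
    ``mode='energy'`` removes the smallest leading set accounting for at
    least the fraction ``cutoff`` of total energy.  ``high_cutoff``
    optionally also discards components beyond that index (noise floor);
    it is off by default.
    """

    mode: str = "count"
    cutoff: float = 2
    high_cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("count", "energy"):
            raise ValueError("mode must be 'count' or 'energy'")
        if self.mode == "count" and (self.cutoff < 0
                                     or self.cutoff != int(self.cutoff)):
            raise ValueError("count cutoff must be a nonnegative integer")
        if self.mode == "energy" and not 0 <= self.cutoff <= 1:
            raise ValueError("energy cutoff must be a fraction in [0, 1]")
        if self.high_cutoff is not None:
            low = self.cutoff if self.mode == "count" else 0
            if self.high_cutoff <= low:
                raise ValueError("high_cutoff must exceed the low cutoff")


def _temporal_eig(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singular values and right singular vectors via the thin Gram matrix.

    With frames << pixels the nt x nt Gram matrix X^H X is orders of
    magnitude cheaper than a full SVD and yields the identical
    decomposition.  Eigensolves run in double precision regardless of
    the input dtype.
    """
    g = x.conj().T @ x
    g = g.astype(np.complex128)
    evals, v = scipy.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return np.sqrt(evals), v[:, order]


def singular_spectrum(block: IQBlock) -> np.ndarray:
    """Singular values of the block's Casorati matrix, descending."""
    s, _ = _temporal_eig(to_casorati(block).matrix)
    return s


def svd_filter(block: IQBlock, spec: SVDFilterSpec = SVDFilterSpec()
               ) -> tuple[IQBlock, np.ndarray]:
    """Remove leading singular components from a block.

    Returns the filtered block (components with index in
    ``(low, high]``, 0-based exclusive/inclusive) together with the full
    singular-value spectrum.  The filtered and removed parts sum back to
    the original block, and output energy never exceeds input energy.
    A cutoff at or beyond the number of components yields an all-zero
    block with a warning.
    """
    if block.n_frames < 2:
        raise ValueError("need at least 2 frames")
    cas = to_casorati(block)
    x = cas.matrix
    rank = min(x.shape)
    s, v = _temporal_eig(x)

    if spec.mode == "count":
        low = int(spec.cutoff)
    else:
        energy = s ** 2
        total = energy.sum()
        low = int(np.searchsorted(np.cumsum(energy) / max(total, 1e-300),
                                  spec.cutoff) + 1) if total > 0 else 0
    high = spec.high_cutoff if spec.high_cutoff is not None else rank

    if low >= rank:
        warnings.warn("cutoff removes every component; output is zero",
                      stacklevel=2)
        out = np.zeros_like(x, dtype=np.complex128)
    else:
        vkeep = v[:, low:min(high, rank)]
        out = x.astype(np.complex128) @ (vkeep @ vkeep.conj().T)
        if low == 0 and high >= rank:
            out = x.astype(np.complex128)   # identity: avoid projection noise
    filtered = from_casorati(replace(cas, matrix=out))
    filtered.pixel_pitch_axial = block.pixel_pitch_axial
    filtered.pixel_pitch_lateral = block.pixel_pitch_lateral
    filtered.aliased = block.aliased
    return filtered, s
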