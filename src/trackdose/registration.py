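"""Landmark-based affine registration between tissue and detector frames.

The tissue micrograph is acquired before etching and the pit micrograph
after; scratched fiducial markers visible in both let us estimate the
2-D affine map (x, y) -> (a11 x + a12 y + tx, a21 x + a22 y + ty) by least
squares.  Three non-collinear markers determine the transform exactly; four
(the usual field practice) give a residual that doubles as registration QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CollinearMarkersError",
    "MarkerPair",
    "AffineTransform",
    "fit_affine",
    "rms_residual",
    "load_markers",
    "save_markers",
]


class CollinearMarkersError(ValueError):
    """Fewer than three markers, or marker positions (near-)collinear."""


@dataclass(frozen=True)
class MarkerPair:
    """One fiducial seen in both frames (um)."""

    pre_xy_um: tuple[float, float]
    post_xy_um: tuple[float, float]

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.pre_xy_um)) and np.all(np.isfinite(self.post_xy_um))):
            raise ValueError("marker coordinates must be finite")


@dataclass(frozen=True)
class AffineTransform:
    a11: float
    a12: float
    a21: float
    a22: float
    tx: float
    ty: float

    def __post_init__(self) -> None:
        if abs(self.a11 * self.a22 - self.a12 * self.a21) <= 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, points):
        """Map (n, 2) points (or a single (2,) point) through the transform."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix.T + self.translation
        return out[0] if single else out

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """T = self o inner, i.e. T(p) = self(inner(p))."""
        m = self.matrix @ inner.matrix
        t = self.matrix @ inner.translation + self.translation
        return AffineTransform(m[0, 0], m[0, 1], m[1, 0], m[1, 1], t[0], t[1])

    def inverse(self) -> "AffineTransform":
        m = np.linalg.inv(self.matrix)
        t = -m @ self.translation
        return AffineTransform(m[0, 0], m[0, 1], m[1, 0], m[1, 1], t[0], t[1])


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) and isinstance(pairs[0], MarkerPair):
        pre = np.array([p.pre_xy_um for p in pairs], dtype=float)
        post = np.array([p.post_xy_um for p in pairs], dtype=float)
    else:
        pre, post = (np.asarray(a, dtype=float) for a in pairs)
    return pre, post


def fit_affine(pairs) -> AffineTransform:
    """Least-squares affine fit from marker pairs.

    ``pairs`` is a list of :class:`MarkerPair` or a ``(pre, post)`` tuple of
    (n, 2) arrays.  Needs >= 3 non-collinear pre-points; with exactly three
    the fit interpolates, with more it minimises the summed squared residual.
    """
    pre, post = _pairs_to_arrays(pairs)
    if pre.shape[0] < 3:
        raise CollinearMarkersError(
            f"affine fit needs >= 3 marker pairs, got {pre.shape[0]}"
        )
    design = np.column_stack([pre, np.ones(pre.shape[0])])
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] <= 1e-9 * sv[0]:
        raise CollinearMarkersError("marker pre-positions are collinear")
    coef, *_ = np.linalg.lstsq(design, post, rcond=None)
    # coef columns: [x' coefficients, y' coefficients]; rows: x, y, 1
    return AffineTransform(
        a11=coef[0, 0], a12=coef[1, 0], a21=coef[0, 1], a22=coef[1, 1],
        tx=coef[2, 0], ty=coef[2, 1],
    )


def rms_residual(pairs, transform: AffineTransform) -> float:
    """Root-mean-square marker misfit ||T(pre) - post|| in um."""
    pre, post = _pairs_to_arrays(pairs)
    resid = transform.apply(pre) - post
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


_MARKER_COLUMNS = ("pre_x_um", "pre_y_um", "post_x_um", "post_y_um")


def load_markers(path) -> list[MarkerPair]:
    df = pd.read_csv(path)
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker file {path} missing columns: {missing}")
    return [
        MarkerPair((r.pre_x_um, r.pre_y_um), (r.post_x_um, r.post_y_um))
        for r in df.itertuples()
    ]


def save_markers(pairs, path) -> None:
    pre, post = _pairs_to_arrays(pairs)
    pd.DataFrame(
        {
            "pre_x_um": pre[:, 0],
            "pre_y_um": pre[:, 1],
            "post_x_um": post[:, 0],
            "post_y_um": post[:, 1],
        }
    ).to_csv(path, index=False)
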