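"""Monotone calibration between detector response S and LET.

CR-39 batches are calibrated against heavy-ion beams of known LET; the
result is a strictly monotone curve S(L) valid here over 3.5-600 keV/um in
water (3.5 keV/um is the registration threshold of the material).  The curve
is represented as ordered knots and interpolated log-log linearly, which is
exact for power-law responses and well behaved for positive quantities that
span two decades.

The packaged default curve is a synthetic stand-in, the power law

    S = (L / 100 keV um^-1)^(3/2)   on [3.5, 600] keV/um,

chosen to be monotone, near zero at the registration threshold and of order
unity at alpha-particle LETs.  Replace it with a measured knot file
(:func:`load_calibration`) for real detector batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationRangeError",
    "CalibrationCurve",
    "default_curve",
    "load_calibration",
    "save_calibration",
]

DEFAULT_LET_RANGE = (3.5, 600.0)

_COLUMNS = ("let_keV_um", "response_S")


class CalibrationRangeError(ValueError):
    """Response or LET outside the calibrated range."""


@dataclass
class CalibrationCurve:
    """Ordered (LET, S) knots with log-log linear interpolation.

    Attributes
    ----------
    let_knots, response_knots : ndarray
        Strictly increasing, positive, covering ``valid_let_range``.
    valid_let_range : tuple
        LET interval (keV/um) over which the mapping is trusted.
    provenance : str
        Free-text label of where the curve came from.
    n_clipped_high : int
        Counter of responses above the calibrated maximum that were clipped
        to the top of the range by :meth:`let_from_response`.
    """

    let_knots: np.ndarray
    response_knots: np.ndarray
    valid_let_range: tuple[float, float] = DEFAULT_LET_RANGE
    provenance: str = ""
    n_clipped_high: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.let_knots = np.asarray(self.let_knots, dtype=float)
        self.response_knots = np.asarray(self.response_knots, dtype=float)
        if self.let_knots.size < 2 or self.let_knots.size != self.response_knots.size:
            raise ValueError("calibration needs >= 2 (LET, S) knot pairs")
        if np.any(self.let_knots <= 0) or np.any(self.response_knots <= 0):
            raise ValueError("calibration knots must be positive")
        if np.any(np.diff(self.let_knots) <= 0) or np.any(
            np.diff(self.response_knots) <= 0
        ):
            raise ValueError("calibration knots must be strictly increasing in both coordinates")
        lo, hi = self.valid_let_range
        tol = 1e-9
        if self.let_knots[0] > lo * (1 + tol) or self.let_knots[-1] < hi * (1 - tol):
            raise ValueError(
                f"knots [{self.let_knots[0]:g}, {self.let_knots[-1]:g}] do not cover "
                f"valid_let_range {self.valid_let_range}"
            )

    @property
    def response_range(self) -> tuple[float, float]:
        """Response values at the ends of the valid LET range."""
        lo, hi = self.valid_let_range
        return (self._interp_response(lo), self._interp_response(hi))

    def _interp_response(self, let):
        return np.exp(
            np.interp(np.log(let), np.log(self.let_knots), np.log(self.response_knots))
        )

    def response_from_let(self, let_keV_um):
        """Forward map L -> S (needed by the simulator); errors out of range."""
        let = np.asarray(let_keV_um, dtype=float)
        lo, hi = self.valid_let_range
        if np.any(let < lo * (1 - 1e-12)) or np.any(let > hi * (1 + 1e-12)):
            raise CalibrationRangeError(
                f"LET outside calibrated range [{lo:g}, {hi:g}] keV/um"
            )
        s = self._interp_response(np.clip(let, lo, hi))
        return float(s) if s.ndim == 0 else s

    def let_from_response(self, response_S):
        """Inverse map S -> L.

        Responses below the registration threshold (LET < lower bound of
        the valid range) raise :class:`CalibrationRangeError`; responses
        above the calibrated maximum are clipped to the top of the range
        and counted in ``n_clipped_high``.
        """
        s = np.asarray(response_S, dtype=float)
        s_lo, s_hi = self.response_range
        if np.any(s < s_lo * (1 - 1e-9)):
            raise CalibrationRangeError(
                f"response below calibrated threshold S = {s_lo:g} "
                f"(LET < {self.valid_let_range[0]:g} keV/um is undetectable)"
            )
        high = s > s_hi
        n_high = int(np.count_nonzero(high))
        if n_high:
            self.n_clipped_high += n_high
            s = np.minimum(s, s_hi)
        s = np.maximum(s, s_lo)
        let = np.exp(
            np.interp(np.log(s), np.log(self.response_knots), np.log(self.let_knots))
        )
        return float(let) if let.ndim == 0 else let


def default_curve() -> CalibrationCurve:
    """The packaged default (synthetic power-law stand-in) calibration."""
    with resources.files("trackdose.data").joinpath(
        "synthetic_default_calibration.csv"
    ).open() as fh:
        return load_calibration(fh, provenance="packaged synthetic power law S=(L/100)^1.5")


def load_calibration(path, provenance: str | None = None) -> CalibrationCurve:
    """Load a two-column (let_keV_um, response_S) knot file."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"calibration file {path} is empty") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calibration file missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"calibration file {path} has no knots")
    return CalibrationCurve(
        let_knots=df["let_keV_um"].to_numpy(dtype=float),
        response_knots=df["response_S"].to_numpy(dtype=float),
        provenance=provenance if provenance is not None else str(path),
    )


def save_calibration(curve: CalibrationCurve, path) -> None:
    """Write knots losslessly (17 significant digits round-trips float64)."""
    pd.DataFrame(
        {"let_keV_um": curve.let_knots, "response_S": curve.response_knots}
    ).to_csv(path, index=False, float_format="%.17g")
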