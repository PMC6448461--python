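"""Etch-pit geometry: detector response, critical angle, detection efficiency.

An alpha particle crossing a CR-39 surface leaves a latent damage trail that
chemical etching develops into a conical pit with an elliptical surface
aperture.  The aperture axes (major ``D_A``, minor ``D_B``) together with the
bulk removal thickness ``B`` (detector material dissolved during the etch)
determine the dimensionless detector response

    S = sqrt(16 B^2 D_A^2 / (4 B^2 - D_B^2)^2 + 1) - 1,

the track-to-bulk etch-velocity ratio minus one.  ``S`` is the detector's
measurable proxy for the particle's linear energy transfer (LET) and sets the
critical dip angle ``theta_c`` (``sin theta_c = 1/(S+1)``) below which no pit
is revealed, hence the detection efficiency for an isotropic source

    eta = 1 - sin^2 theta_c = ((S+1)^2 - 1) / (S+1)^2.

Coordinate convention used throughout the package: detector-frame positions
are in micrometres, origin at the image top-left pixel centre, x along
columns, y along rows (increasing downward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "DegeneratePitError",
    "EtchConfig",
    "EtchPit",
    "TrackRecord",
    "detector_response",
    "detection_efficiency",
    "critical_angle",
    "detect_pits",
    "build_track_records",
    "read_pit_table",
    "tracks_to_frame",
    "write_track_table",
]


class DegeneratePitError(ValueError):
    """Minor aperture axis reached twice the bulk removal (over-etched pit).

    The response formula's denominator ``4 B^2 - D_B^2`` vanishes there; the
    conical-pit model does not cover such pits.
    """


@dataclass(frozen=True)
class EtchConfig:
    """Chemical-etch parameters.

    ``removal_B_um`` is the bulk removal thickness B in micrometres (surface
    layer dissolved during etching, measured as a thickness change); default
    3.3 +/- 0.7 um for a 2 h etch in 7 M NaOH at 70 degC.
    """

    removal_B_um: float = 3.3
    removal_B_sigma_um: float = 0.7
    protocol: str = "7 M NaOH, 70 degC, 2 h"

    def __post_init__(self) -> None:
        if not self.removal_B_um > 0:
            raise ValueError("removal_B_um must be positive")


@dataclass(frozen=True)
class EtchPit:
    """One detected etch pit: position and elliptical aperture axes (um)."""

    x_um: float
    y_um: float
    major_axis_um: float
    minor_axis_um: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValueError("pit position must be finite")
        if not 0 < self.minor_axis_um <= self.major_axis_um:
            raise ValueError(
                "aperture axes must satisfy 0 < minor <= major, got "
                f"major={self.major_axis_um}, minor={self.minor_axis_um}"
            )


@dataclass(frozen=True)
class TrackRecord:
    """A pit promoted to a dosimetry-ready track.

    ``weight = 1/efficiency_eta`` is the per-track fluence weight that
    corrects the raw pit count for the solid angle lost below the critical
    angle.
    """

    pit: EtchPit
    response_S: float
    theta_c_rad: float
    efficiency_eta: float
    let_keV_um: float
    weight: float


def _removal(etch) -> float:
    """Accept an EtchConfig or a bare removal thickness in um."""
    if isinstance(etch, EtchConfig):
        return etch.removal_B_um
    return float(etch)


def detector_response(major_axis_um, minor_axis_um, etch=EtchConfig()):
    """Detector response S from elliptical aperture axes.

    Parameters
    ----------
    major_axis_um, minor_axis_um : float or array_like
        Aperture axes D_A >= D_B > 0 in micrometres.
    etch : EtchConfig or float
        Etch configuration or bare bulk removal B in micrometres.

    Returns
    -------
    float or ndarray
        S = sqrt(16 B^2 D_A^2 / (4 B^2 - D_B^2)^2 + 1) - 1  (>= 0).

    Raises
    ------
    DegeneratePitError
        If D_B >= 2B (over-etched pit, model breakdown).
    ValueError
        On non-positive axes or major < minor.
    """
    B = _removal(etch)
    da, db = np.broadcast_arrays(
        np.asarray(major_axis_um, dtype=float), np.asarray(minor_axis_um, dtype=float)
    )
    scalar = da.ndim == 0
    da = np.atleast_1d(da)
    db = np.atleast_1d(db)
    if np.any(da <= 0) or np.any(db <= 0):
        raise ValueError("aperture axes must be positive")
    if np.any(da < db):
        raise ValueError("major axis must be >= minor axis")
    if np.any(db >= 2.0 * B):
        raise DegeneratePitError(
            f"minor axis >= 2B = {2.0 * B:g} um: over-etched pit outside the model"
        )
    s = np.sqrt(16.0 * B**2 * da**2 / (4.0 * B**2 - db**2) ** 2 + 1.0) - 1.0
    return float(s[0]) if scalar else s


def detection_efficiency(response_S):
    """Isotropic-source detection efficiency eta = ((S+1)^2 - 1)/(S+1)^2.

    Strictly increasing in S, in [0, 1); eta = 0 at S = 0 (critical angle
    pi/2, nothing registered) and eta -> 1 as S -> inf.
    """
    s = np.asarray(response_S, dtype=float)
    if np.any(s < 0):
        raise ValueError("response_S must be >= 0")
    eta = 1.0 - 1.0 / (s + 1.0) ** 2
    return float(eta) if eta.ndim == 0 else eta


def critical_angle(response_S):
    """Critical dip angle theta_c = arcsin(1/(S+1)), decreasing in S.

    Particles with dip angle (measured from the detector surface plane)
    below theta_c do not form an observable pit.
    """
    s = np.asarray(response_S, dtype=float)
    if np.any(s < 0):
        raise ValueError("response_S must be >= 0")
    th = np.arcsin(1.0 / (s + 1.0))
    return float(th) if th.ndim == 0 else th


def detect_pits(
    gray_image,
    pixel_size_um: float,
    intensity_threshold: int = 138,
    min_area_px: int = 4,
) -> list[EtchPit]:
    """Detect dark etch pits in a grayscale micrograph.

    A deliberately simple detector: global threshold (pit interiors are
    darker than the polished surface), connected components, and the
    moment-equivalent ellipse of each component for the aperture axes.
    Components smaller than ``min_area_px`` pixels, or degenerate (zero
    minor axis), are discarded.
    """
    gray = np.asarray(gray_image)
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    labels = measure.label(gray < intensity_threshold, connectivity=2)
    pits: list[EtchPit] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px or region.axis_minor_length <= 0:
            continue
        row, col = region.centroid
        pits.append(
            EtchPit(
                x_um=col * pixel_size_um,
                y_um=row * pixel_size_um,
                major_axis_um=region.axis_major_length * pixel_size_um,
                minor_axis_um=region.axis_minor_length * pixel_size_um,
            )
        )
    return pits


def build_track_records(
    pits: Iterable[EtchPit],
    etch: EtchConfig,
    curve,
    degenerate: str = "exclude",
) -> tuple[list[TrackRecord], dict[str, int]]:
    """Derive S, theta_c, eta, LET and fluence weight for each pit.

    Pits with ``minor >= 2B`` are excluded by default (``degenerate  =
    "exclude"``) or clamped just inside the model domain (``"clamp"``).
    Pits whose response falls below the calibration threshold (LET <
    lower bound of the curve's valid range) are excluded and counted.

    Returns the track list and a dict of exclusion counts.
    """
    from .calibration import CalibrationRangeError  # local to avoid cycle

    if degenerate not in ("exclude", "clamp"):
        raise ValueError("degenerate must be 'exclude' or 'clamp'")
    B = etch.removal_B_um
    tracks: list[TrackRecord] = []
    excluded = {"degenerate": 0, "below_let_range": 0}
    for pit in pits:
        da, db = pit.major_axis_um, pit.minor_axis_um
        if db >= 2.0 * B:
            if degenerate == "exclude":
                excluded["degenerate"] += 1
                continue
            db = 2.0 * B * (1.0 - 1e-9)
            da = max(da, db)
            pit = EtchPit(pit.x_um, pit.y_um, da, db)
        s = detector_response(da, db, etch)
        try:
            let = curve.let_from_response(s)
        except CalibrationRangeError:
            excluded["below_let_range"] += 1
            continue
        eta = detection_efficiency(s)
        tracks.append(
            TrackRecord(
                pit=pit,
                response_S=s,
                theta_c_rad=critical_angle(s),
                efficiency_eta=eta,
                let_keV_um=let,
                weight=1.0 / eta,
            )
        )
    return tracks, excluded


_PIT_COLUMNS = ("x_um", "y_um", "major_axis_um", "minor_axis_um")


def read_pit_table(path) -> list[EtchPit]:
    """Read a pit table (CSV with x_um, y_um, major_axis_um, minor_axis_um).

    Digitised tables are occasionally unordered; rows with minor > major are
    swapped with a warning rather than rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in _PIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pit table {path} missing columns: {missing}")
    major = df["major_axis_um"].to_numpy(dtype=float)
    minor = df["minor_axis_um"].to_numpy(dtype=float)
    swapped = minor > major
    if swapped.any():
        warnings.warn(
            f"{int(swapped.sum())} pit rows had minor > major; axes swapped",
            stacklevel=2,
        )
        major, minor = np.where(swapped, minor, major), np.where(swapped, major, minor)
    return [
        EtchPit(x, y, a, b)
        for x, y, a, b in zip(df["x_um"], df["y_um"], major, minor)
    ]


def tracks_to_frame(tracks: Sequence[TrackRecord]) -> pd.DataFrame:
    """Flatten TrackRecords into the canonical derived track table."""
    return pd.DataFrame(
        {
            "x_um": [t.pit.x_um for t in tracks],
            "y_um": [t.pit.y_um for t in tracks],
            "major_axis_um": [t.pit.major_axis_um for t in tracks],
            "minor_axis_um": [t.pit.minor_axis_um for t in tracks],
            "response_S": [t.response_S for t in tracks],
            "theta_c_rad": [t.theta_c_rad for t in tracks],
            "eta": [t.efficiency_eta for t in tracks],
            "let_keV_um": [t.let_keV_um for t in tracks],
            "weight": [t.weight for t in tracks],
        }
    )


def write_track_table(tracks: Sequence[TrackRecord], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)
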