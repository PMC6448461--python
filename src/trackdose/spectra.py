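"""LET spectra, absorbed dose, cell-scale dose maps and decay correction.

The fluence in each LET bin is the efficiency-weighted track count per unit
area, ``phi_i = sum_{tracks in bin i} (1/eta) / A``, and the absorbed dose
follows from the spectrum as

    D [Gy] = (1.6e-9 / rho) * sum_i phi_i * L_i,

with ``phi_i`` in cm^-2, ``L_i`` the bin-midpoint LET in keV/um and ``rho``
the specific gravity in g/cm^3 (1.6e-9 converts keV/g to Gy through
1 keV = 1.602e-16 J and the cm/um mix of units).

Dose is mapped at the cell scale by scoring ``L * weight`` in square cells
(default 10 um, comparable to a mammalian cell diameter) and track density
at a coarser survey scale (default 50 um).  All grids are half-open
``[low, high)`` in both axes with the origin at the lower corner of the
registered tissue bounding box.

Exposure windows: tissue sits on the detector only from mount (t1) to
removal (t2), so the observed dose misses decays from injection (t0 = 0) to
t1.  For a nuclide with decay constant ``lambda = ln 2 / T_half`` and
instantaneous uptake, the missed-to-observed ratio is the ratio of decay
counts in the two windows,

    D0 / D = (1 - exp(-lambda t1)) / (exp(-lambda t1) - exp(-lambda t2)),

and the total dose over [t0, t2] is ``observed * (1 + D0/D)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pit_geometry import TrackRecord

__all__ = [
    "DOSE_CONVERSION_GY",
    "DosimetryConfig",
    "DecayModel",
    "LETSpectrum",
    "DoseMap",
    "DensityMap",
    "DoseHistogram",
    "default_let_bin_edges",
    "build_let_spectrum",
    "absorbed_dose",
    "local_dose_map",
    "track_density_map",
    "decay_correction_factor",
    "total_dose",
    "dose_histogram",
    "grid_from_bbox",
    "save_grid",
    "load_grid",
    "save_spectrum",
    "load_spectrum",
]

# Gy per (keV/um * cm^-2) of fluence-LET product, for rho in g/cm^3.
DOSE_CONVERSION_GY = 1.6e-9


@dataclass(frozen=True)
class DosimetryConfig:
    """Dose bookkeeping constants.

    ``rho_g_cm3``: specific gravity of the scored medium (1.0 for soft
    tissue/water).  ``rbe``: scalar relative-biological-effectiveness
    multiplier used only when quoting biologically weighted dose; the
    physical dose is never scaled by it.
    """

    rho_g_cm3: float = 1.0
    rbe: float = 1.0

    def __post_init__(self) -> None:
        if not self.rho_g_cm3 > 0:
            raise ValueError("rho_g_cm3 must be positive")


@dataclass(frozen=True)
class DecayModel:
    """Exponential-decay exposure window (hours).

    Defaults describe 211At (half-life 7.2 h) with slice-and-mount at
    t1 = 12 h after injection (t0 = 0) and tissue removal at t2 = 43 h,
    i.e. a 31 h recording window of roughly four half-lives.
    """

    half_life_h: float = 7.2
    t1_h: float = 12.0
    t2_h: float = 43.0
    t0_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValueError("half_life_h must be positive")
        if not self.t0_h <= self.t1_h < self.t2_h:
            raise ValueError("need t0 <= t1 < t2")

    @property
    def lambda_per_h(self) -> float:
        return np.log(2.0) / self.half_life_h


def default_let_bin_edges(
    lo: float = 3.5, hi: float = 600.0, width: float = 10.0
) -> np.ndarray:
    """Ascending LET bin edges over [lo, hi]; the last bin may be narrower."""
    edges = np.arange(lo, hi, width)
    return np.append(edges, hi)


def _track_arrays(tracks) -> dict[str, np.ndarray]:
    """Normalise a track container to plain arrays.

    Accepts a derived-track DataFrame (columns x_um, y_um, let_keV_um,
    weight, eta) or a sequence of :class:`TrackRecord`.
    """
    if isinstance(tracks, pd.DataFrame):
        out = {
            "x": tracks["x_um"].to_numpy(dtype=float),
            "y": tracks["y_um"].to_numpy(dtype=float),
            "let": tracks["let_keV_um"].to_numpy(dtype=float),
            "weight": tracks["weight"].to_numpy(dtype=float),
        }
        if "eta" in tracks.columns:
            out["eta"] = tracks["eta"].to_numpy(dtype=float)
        else:
            out["eta"] = 1.0 / out["weight"]
        return out
    trks = list(tracks)
    return {
        "x": np.array([t.pit.x_um for t in trks], dtype=float),
        "y": np.array([t.pit.y_um for t in trks], dtype=float),
        "let": np.array([t.let_keV_um for t in trks], dtype=float),
        "weight": np.array([t.weight for t in trks], dtype=float),
        "eta": np.array([t.efficiency_eta for t in trks], dtype=float),
    }


@dataclass
class LETSpectrum:
    """Efficiency-corrected fluence per LET bin over a scored area."""

    bin_edges_keV_um: np.ndarray
    fluence_per_cm2: np.ndarray
    raw_counts: np.ndarray
    area_cm2: float

    @property
    def midpoints_keV_um(self) -> np.ndarray:
        e = self.bin_edges_keV_um
        return 0.5 * (e[:-1] + e[1:])

    @property
    def total_fluence_per_cm2(self) -> float:
        return float(self.fluence_per_cm2.sum())

    @property
    def mode_keV_um(self) -> float:
        """Midpoint of the modal (highest-fluence) bin."""
        return float(self.midpoints_keV_um[int(np.argmax(self.fluence_per_cm2))])

    def __add__(self, other: "LETSpectrum") -> "LETSpectrum":
        if not np.array_equal(self.bin_edges_keV_um, other.bin_edges_keV_um):
            raise ValueError("spectra have different bin edges")
        if not np.isclose(self.area_cm2, other.area_cm2):
            raise ValueError("spectra scored over different areas")
        return LETSpectrum(
            self.bin_edges_keV_um,
            self.fluence_per_cm2 + other.fluence_per_cm2,
            self.raw_counts + other.raw_counts,
            self.area_cm2,
        )


def build_let_spectrum(tracks, area_cm2: float, bin_edges=None) -> LETSpectrum:
    """Histogram tracks into an efficiency-corrected LET spectrum.

    Each track contributes ``1/eta`` to its bin's fluence (tracks steeper
    than the critical angle stand in for the unobserved shallow ones),
    divided by the scored area.
    """
    if not area_cm2 > 0:
        raise ValueError("area_cm2 must be positive")
    edges = default_let_bin_edges() if bin_edges is None else np.asarray(bin_edges, float)
    arr = _track_arrays(tracks)
    if arr["let"].size and (np.any(arr["eta"] <= 0) or np.any(~np.isfinite(arr["weight"]))):
        raise ValueError("tracks with eta = 0 must be excluded before spectrum building")
    counts, _ = np.histogram(arr["let"], bins=edges)
    weighted, _ = np.histogram(arr["let"], bins=edges, weights=arr["weight"])
    return LETSpectrum(edges, weighted / area_cm2, counts.astype(int), float(area_cm2))


def absorbed_dose(spectrum: LETSpectrum, config: DosimetryConfig = DosimetryConfig()) -> float:
    """Absorbed dose in Gy from an LET spectrum (fluence-LET sum)."""
    return float(
        DOSE_CONVERSION_GY
        / config.rho_g_cm3
        * np.sum(spectrum.fluence_per_cm2 * spectrum.midpoints_keV_um)
    )


@dataclass
class DoseMap:
    """Gridded absorbed dose (Gy) with raw track counts alongside.

    ``origin_um`` is the (x, y) of the grid's lower corner; cell (iy, ix)
    covers the half-open square [origin + i*cell, origin + (i+1)*cell).
    ``n_outside`` counts tracks that fell outside the grid (reported, never
    silently dropped).
    """

    origin_um: tuple[float, float]
    cell_size_um: float
    dose_Gy: np.ndarray
    counts: np.ndarray
    n_outside: int = 0


@dataclass
class DensityMap:
    """Gridded integer track counts (survey-scale density map)."""

    origin_um: tuple[float, float]
    bin_size_um: float
    counts: np.ndarray
    n_outside: int = 0


def grid_from_bbox(bbox_um, cell_size_um: float) -> tuple[tuple[float, float], tuple[int, int]]:
    """Grid origin and (ny, nx) shape covering a (xmin, ymin, xmax, ymax) box.

    The origin snaps to the box's lower corner; the shape is the minimal
    integer cell count covering the box extent.
    """
    xmin, ymin, xmax, ymax = bbox_um
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounding box")
    nx = int(np.ceil((xmax - xmin) / cell_size_um))
    ny = int(np.ceil((ymax - ymin) / cell_size_um))
    return (float(xmin), float(ymin)), (ny, nx)


def _bin_indices(x, y, origin_um, size_um, shape):
    ix = np.floor((x - origin_um[0]) / size_um).astype(int)
    iy = np.floor((y - origin_um[1]) / size_um).astype(int)
    inside = (ix >= 0) & (ix < shape[1]) & (iy >= 0) & (iy < shape[0])
    return ix, iy, inside


def local_dose_map(
    tracks,
    origin_um,
    shape,
    cell_size_um: float = 10.0,
    config: DosimetryConfig = DosimetryConfig(),
) -> DoseMap:
    """Score per-cell absorbed dose on a square grid.

    Each in-bounds track deposits ``L * weight`` in its cell; the cell dose
    is ``1.6e-9 / rho * sum(L * weight) / A_cell`` with the cell area in
    cm^2.  Satisfies the energy-bookkeeping identity
    ``sum_cells dose * A * rho / 1.6e-9 == sum_tracks L * weight`` exactly
    (up to floating point) for tracks inside the grid.
    """
    arr = _track_arrays(tracks)
    shape = (int(shape[0]), int(shape[1]))
    esum = np.zeros(shape, dtype=float)
    counts = np.zeros(shape, dtype=int)
    ix, iy, inside = _bin_indices(arr["x"], arr["y"], origin_um, cell_size_um, shape)
    np.add.at(esum, (iy[inside], ix[inside]), arr["let"][inside] * arr["weight"][inside])
    np.add.at(counts, (iy[inside], ix[inside]), 1)
    a_cell_cm2 = (cell_size_um * 1e-4) ** 2
    dose = DOSE_CONVERSION_GY / config.rho_g_cm3 * esum / a_cell_cm2
    return DoseMap(
        origin_um=(float(origin_um[0]), float(origin_um[1])),
        cell_size_um=float(cell_size_um),
        dose_Gy=dose,
        counts=counts,
        n_outside=int(np.count_nonzero(~inside)),
    )


def track_density_map(tracks, origin_um, shape, bin_size_um: float = 50.0) -> DensityMap:
    """Count tracks per square survey bin (default 50 um)."""
    arr = _track_arrays(tracks)
    shape = (int(shape[0]), int(shape[1]))
    counts = np.zeros(shape, dtype=int)
    ix, iy, inside = _bin_indices(arr["x"], arr["y"], origin_um, bin_size_um, shape)
    np.add.at(counts, (iy[inside], ix[inside]), 1)
    return DensityMap(
        origin_um=(float(origin_um[0]), float(origin_um[1])),
        bin_size_um=float(bin_size_um),
        counts=counts,
        n_outside=int(np.count_nonzero(~inside)),
    )


def decay_correction_factor(model: DecayModel) -> float:
    """Missed-to-observed dose ratio D0/D for the exposure window.

    Ratio of decay counts before mounting ([t0, t1]) to decay counts while
    on the detector ([t1, t2]); strictly increasing in t1 at fixed t2.
    """
    lam = model.lambda_per_h
    e1 = np.exp(-lam * (model.t1_h - model.t0_h))
    e2 = np.exp(-lam * (model.t2_h - model.t0_h))
    if e1 - e2 <= 0:
        raise ValueError("degenerate exposure window (t1 == t2)")
    return float((1.0 - e1) / (e1 - e2))


def total_dose(observed, model: DecayModel):
    """Scale observed dose to the full [t0, t2] window: total = observed * (1 + D0/D).

    Works on a scalar dose or cellwise on a :class:`DoseMap` (returns the
    same type).
    """
    factor = 1.0 + decay_correction_factor(model)
    if isinstance(observed, DoseMap):
        return dataclasses.replace(observed, dose_Gy=observed.dose_Gy * factor)
    return observed * factor


@dataclass
class DoseHistogram:
    """Histogram of nonzero map cells by dose."""

    bin_edges_Gy: np.ndarray
    counts: np.ndarray
    mode_Gy: float
    dose_range_Gy: tuple[float, float]
    n_cells: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def dose_histogram(dose_map: DoseMap, bin_width_Gy: float = 0.5) -> DoseHistogram:
    """Histogram nonzero cells of a dose map; reports mode bin and range."""
    if not bin_width_Gy > 0:
        raise ValueError("bin_width_Gy must be positive")
    nz = dose_map.dose_Gy[dose_map.dose_Gy > 0]
    if nz.size == 0:
        return DoseHistogram(np.array([0.0, bin_width_Gy]), np.zeros(1, int), 0.0, (0.0, 0.0), 0)
    n_bins = int(np.floor(nz.max() / bin_width_Gy)) + 1
    edges = bin_width_Gy * np.arange(n_bins + 1)
    idx = np.minimum(np.floor(nz / bin_width_Gy).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mode = float((np.argmax(counts) + 0.5) * bin_width_Gy)
    return DoseHistogram(edges, counts, mode, (float(nz.min()), float(nz.max())), int(nz.size))


# ---------------------------------------------------------------------------
# Plain-text serialisation: grid as whitespace-delimited text plus a JSON
# sidecar holding origin, cell size and units.

def save_grid(grid, basepath) -> None:
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(grid, DoseMap):
        np.savetxt(base.with_suffix(".txt"), grid.dose_Gy, fmt="%.10g")
        np.savetxt(base.with_suffix(".counts.txt"), grid.counts, fmt="%d")
        header = {
            "kind": "dose_map",
            "units": "Gy",
            "origin_um": list(grid.origin_um),
            "cell_size_um": grid.cell_size_um,
            "n_outside": grid.n_outside,
        }
    elif isinstance(grid, DensityMap):
        np.savetxt(base.with_suffix(".txt"), grid.counts, fmt="%d")
        header = {
            "kind": "density_map",
            "units": "tracks/bin",
            "origin_um": list(grid.origin_um),
            "cell_size_um": grid.bin_size_um,
            "n_outside": grid.n_outside,
        }
    else:
        raise TypeError(f"cannot serialise {type(grid).__name__}")
    base.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True))


def load_grid(basepath):
    base = Path(basepath)
    header = json.loads(base.with_suffix(".json").read_text())
    if header["kind"] == "dose_map":
        return DoseMap(
            origin_um=tuple(header["origin_um"]),
            cell_size_um=header["cell_size_um"],
            dose_Gy=np.atleast_2d(np.loadtxt(base.with_suffix(".txt"))),
            counts=np.atleast_2d(np.loadtxt(base.with_suffix(".counts.txt"), dtype=int)),
            n_outside=header["n_outside"],
        )
    if header["kind"] == "density_map":
        return DensityMap(
            origin_um=tuple(header["origin_um"]),
            bin_size_um=header["cell_size_um"],
            counts=np.atleast_2d(np.loadtxt(base.with_suffix(".txt"), dtype=int)),
            n_outside=header["n_outside"],
        )
    raise ValueError(f"unknown grid kind {header['kind']!r}")


def save_spectrum(spectrum: LETSpectrum, path) -> None:
    pd.DataFrame(
        {
            "let_low_keV_um": spectrum.bin_edges_keV_um[:-1],
            "let_high_keV_um": spectrum.bin_edges_keV_um[1:],
            "fluence_per_cm2": spectrum.fluence_per_cm2,
            "raw_counts": spectrum.raw_counts,
        }
    ).to_csv(path, index=False)
    # area rides along in a sidecar so the spectrum is self-describing
    Path(str(path) + ".json").write_text(json.dumps({"area_cm2": spectrum.area_cm2}))


def load_spectrum(path) -> LETSpectrum:
    df = pd.read_csv(path)
    area = json.loads(Path(str(path) + ".json").read_text())["area_cm2"]
    edges = np.append(df["let_low_keV_um"].to_numpy(), df["let_high_keV_um"].iloc[-1])
    return LETSpectrum(
        edges,
        df["fluence_per_cm2"].to_numpy(),
        df["raw_counts"].to_numpy(dtype=int),
        float(area),
    )
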