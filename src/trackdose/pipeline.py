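"""End-to-end orchestration: pits -> LET -> registration -> regions -> dose.

The analysis pipeline reproduces the autoradiography workflow: load a pit
table (or a simulated bundle), derive per-track response/LET/efficiency,
register the detector frame onto the tissue micrograph through the marker
affine, segment tissue/pink/purple regions, count tracks and densities per
region, build the efficiency-corrected LET spectrum, score 10-um dose and
50-um density maps, and decay-correct the observed dose to the full window.
Every intermediate is persisted so each report number can be recomputed
from files; every exclusion (degenerate pits, sub-threshold responses,
out-of-grid or out-of-image tracks) is counted in the report, never
silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration as cal
from . import pit_geometry as pg
from . import registration as reg
from . import segmentation as seg
from . import spectra as sp

__all__ = ["PipelineError", "RunConfig", "RunReport", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage label."""


@dataclass
class RunConfig:
    """Validated inputs and parameters for one analysis run.

    Defaults are the field-standard values: B = 3.3 um removal, 7.2 h
    half-life with a 12-43 h recording window, gray threshold 138/256, the
    printed pink RGB bands, 10-um dose cells and 50-um density bins.
    """

    pit_table: Path
    tissue_image: Path
    markers: Path | None = None
    calibration: Path | None = None  # None -> packaged default curve
    pixel_size_um: float = 0.28
    etch: pg.EtchConfig = field(default_factory=pg.EtchConfig)
    decay: sp.DecayModel = field(default_factory=sp.DecayModel)
    dosimetry: sp.DosimetryConfig = field(default_factory=sp.DosimetryConfig)
    thresholds: seg.SegmentationThresholds = field(default_factory=seg.SegmentationThresholds)
    dose_cell_um: float = 10.0
    density_bin_um: float = 50.0
    let_bin_width_keV_um: float = 10.0
    degenerate_pits: str = "exclude"
    outdir: Path = Path("trackdose_out")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def _path(key):
            v = raw.get(key)
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() else base / p

        kwargs = {}
        for key in ("pit_table", "tissue_image", "markers", "calibration"):
            p = _path(key)
            if p is not None:
                kwargs[key] = p
        for key in (
            "pixel_size_um",
            "dose_cell_um",
            "density_bin_um",
            "let_bin_width_keV_um",
            "degenerate_pits",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "etch" in raw:
            kwargs["etch"] = pg.EtchConfig(**raw["etch"])
        if "decay" in raw:
            kwargs["decay"] = sp.DecayModel(**raw["decay"])
        if "dosimetry" in raw:
            kwargs["dosimetry"] = sp.DosimetryConfig(**raw["dosimetry"])
        if "thresholds" in raw:
            t = raw["thresholds"]
            kwargs["thresholds"] = seg.SegmentationThresholds(
                gray_threshold_8bit=t.get("gray_threshold_8bit", 138),
                pink_red=tuple(t.get("pink_red", (123, 177))),
                pink_green=tuple(t.get("pink_green", (42, 84))),
                pink_blue=tuple(t.get("pink_blue", (94, 139))),
            )
        out = _path("outdir")
        kwargs["outdir"] = out if out is not None else base / "analysis"
        return cls(**kwargs)

    def validate(self) -> None:
        """Check that every referenced input exists before any compute."""
        for label, p in (
            ("pit_table", self.pit_table),
            ("tissue_image", self.tissue_image),
            ("markers", self.markers),
            ("calibration", self.calibration),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.degenerate_pits not in ("exclude", "clamp"):
            raise ValueError("degenerate_pits must be 'exclude' or 'clamp'")


@dataclass
class RunReport:
    """Summary numbers of one run; every entry is recomputable from the
    persisted intermediates in the output directory."""

    n_pits: int = 0
    n_tracks: int = 0
    exclusions: dict = field(default_factory=dict)
    n_let_clipped_high: int = 0
    registration_rms_um: float = 0.0
    regions: dict = field(default_factory=dict)
    concentration_efficiency: float = float("nan")
    concentration_efficiency_sigma: float = float("nan")
    spectrum_mode_keV_um: float = float("nan")
    total_fluence_per_cm2: float = 0.0
    mean_observed_dose_Gy: float = 0.0
    decay_correction_factor: float = float("nan")
    observed_dose_histogram: dict = field(default_factory=dict)
    total_dose_histogram: dict = field(default_factory=dict)
    n_tracks_outside_grid: int = 0
    n_tracks_outside_image: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def _hist_summary(hist: sp.DoseHistogram) -> dict:
    return {
        "mode_Gy": hist.mode_Gy,
        "dose_range_Gy": list(hist.dose_range_Gy),
        "n_nonzero_cells": hist.n_cells,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every analysis stage and persist intermediates + report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    with _stage("calibration"):
        curve = (
            cal.load_calibration(config.calibration)
            if config.calibration is not None
            else cal.default_curve()
        )

    with _stage("pit table"):
        pits = pg.read_pit_table(config.pit_table)
        report.n_pits = len(pits)

    with _stage("track derivation"):
        tracks, excluded = pg.build_track_records(
            pits, config.etch, curve, degenerate=config.degenerate_pits
        )
        report.n_tracks = len(tracks)
        report.exclusions = excluded
        report.n_let_clipped_high = curve.n_clipped_high
        frame = pg.tracks_to_frame(tracks)
        frame.to_csv(outdir / "derived_tracks.csv", index=False)

    with _stage("registration"):
        if config.markers is not None:
            pairs = reg.load_markers(config.markers)
            tissue_to_detector = reg.fit_affine(pairs)
            report.registration_rms_um = reg.rms_residual(pairs, tissue_to_detector)
        else:
            tissue_to_detector = reg.AffineTransform.identity()
        detector_to_tissue = tissue_to_detector.inverse()
        pts = frame[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(pts):
            pts = detector_to_tissue.apply(pts)
        frame = frame.assign(x_um=pts[:, 0] if len(pts) else [], y_um=pts[:, 1] if len(pts) else [])
        frame.to_csv(outdir / "registered_tracks.csv", index=False)

    with _stage("segmentation"):
        rgb = seg.read_rgb_image(config.tissue_image)
        tissue, pink, purple = seg.segment_regions(
            rgb, config.thresholds, config.pixel_size_um
        )
        for mask in (tissue, pink, purple):
            seg.write_mask_png(mask, outdir / f"mask_{mask.label}.png")

    with _stage("region densities"):
        regions = {}
        for mask in (tissue, pink, purple):
            count, n_out = seg.count_tracks_in_mask(frame, mask)
            dens = seg.region_density(count, mask.area_mm2) if mask.area_mm2 > 0 else None
            regions[mask.label] = {
                "track_count": count,
                "area_mm2": mask.area_mm2,
                "density_per_mm2": dens.density_per_mm2 if dens else 0.0,
                "sigma_per_mm2": dens.sigma_per_mm2 if dens else 0.0,
            }
            report.n_tracks_outside_image = n_out
        report.regions = regions
        if regions["pink"]["density_per_mm2"] > 0 and regions["purple"]["density_per_mm2"] > 0:
            ce = seg.concentration_efficiency(
                seg.region_density(regions["pink"]["track_count"], regions["pink"]["area_mm2"]),
                seg.region_density(regions["purple"]["track_count"], regions["purple"]["area_mm2"]),
            )
            report.concentration_efficiency = ce.ratio
            report.concentration_efficiency_sigma = ce.sigma

    with _stage("LET spectrum"):
        area_cm2 = tissue.area_mm2 * 1e-2
        edges = sp.default_let_bin_edges(width=config.let_bin_width_keV_um)
        spectrum = sp.build_let_spectrum(frame, area_cm2, edges)
        sp.save_spectrum(spectrum, outdir / "let_spectrum.csv")
        report.spectrum_mode_keV_um = spectrum.mode_keV_um
        report.total_fluence_per_cm2 = spectrum.total_fluence_per_cm2
        report.mean_observed_dose_Gy = sp.absorbed_dose(spectrum, config.dosimetry)

    with _stage("dose and density maps"):
        rows, cols = np.nonzero(tissue.mask)
        px = tissue.pixel_size_um
        bbox = (
            cols.min() * px,
            rows.min() * px,
            (cols.max() + 1) * px,
            (rows.max() + 1) * px,
        )
        origin, shape = sp.grid_from_bbox(bbox, config.dose_cell_um)
        dose_map = sp.local_dose_map(
            frame, origin, shape, config.dose_cell_um, config.dosimetry
        )
        report.n_tracks_outside_grid = dose_map.n_outside
        sp.save_grid(dose_map, outdir / "dose_map")
        d_origin, d_shape = sp.grid_from_bbox(bbox, config.density_bin_um)
        density = sp.track_density_map(frame, d_origin, d_shape, config.density_bin_um)
        sp.save_grid(density, outdir / "density_map")

    with _stage("decay correction"):
        report.decay_correction_factor = sp.decay_correction_factor(config.decay)
        total_map = sp.total_dose(dose_map, config.decay)
        sp.save_grid(total_map, outdir / "total_dose_map")
        report.observed_dose_histogram = _hist_summary(sp.dose_histogram(dose_map))
        report.total_dose_histogram = _hist_summary(sp.dose_histogram(total_map))

    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True, default=float)
    )
    return report
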