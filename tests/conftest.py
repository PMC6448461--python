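from types import SimpleNamespace

import numpy as np
import pytest

from trackdose.calibration import default_curve
from trackdose.phantom import Ellipse, PhantomConfig, simulate_phantom, write_truth_bundle
from trackdose.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def curve():
    return default_curve()


def small_phantom(seed: int = 3, **overrides) -> PhantomConfig:
    """A 0.5 x 0.5 mm phantom that simulates in well under a second."""
    kwargs = dict(
        image_size_px=(250, 250),
        pixel_size_um=2.0,
        tissue_ellipse=Ellipse(250.0, 250.0, 230.0, 200.0),
        tumor_ellipses=(Ellipse(180.0, 200.0, 90.0, 70.0),),
        activity_normal_per_mm2=18000.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def phantom_run(tmp_path_factory):
    """One default desk-scale phantom simulated and analysed end-to-end.

    Shared session-wide: the simulation (~9e4 decays) and pipeline run take
    a few seconds and several tests only read from the results.
    """
    cfg = PhantomConfig(seed=7)
    image, truth, events = simulate_phantom(cfg)
    outdir = tmp_path_factory.mktemp("phantom")
    paths = write_truth_bundle(outdir, cfg, image, truth, events)
    run_config = RunConfig(
        pit_table=paths["pits"],
        tissue_image=paths["micrograph"],
        markers=paths["markers"],
        pixel_size_um=cfg.pixel_size_um,
        outdir=outdir / "analysis",
    )
    report = run_pipeline(run_config)
    return SimpleNamespace(
        cfg=cfg,
        image=image,
        truth=truth,
        events=events,
        paths=paths,
        run_config=run_config,
        report=report,
    )
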