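import numpy as np
import pytest

from synaps import (
    PhantomConfig,
    build_schedule,
    fiss_config,
    make_phantom,
    pc_config,
    simulate_scan,
)
from synaps.pipeline import run_pipeline


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(PhantomConfig(seed=2))


@pytest.fixture(scope="session")
def small_fiss_sim():
    """Motion-corrupted desk-scale FISS acquisition (600 readouts)."""
    cfg = PhantomConfig(seed=2)
    ph = make_phantom(cfg)
    g = cfg.grid
    sc = fiss_config(
        n_interleaves=25, tr_ms=50.0, fov_mm=g.fov_mm,
        resolution_mm=g.voxel_mm, mode="2d",
    )
    sched = build_schedule(sc, 0.0)
    raw = simulate_scan(ph, sched, noise_sd=0.5, n_coils=4, seed=3)
    return ph, raw


def tiny_pipeline_config(seed=5):
    """A minutes-scale end-to-end configuration (few spokes, 4 phases)."""
    return {
        "seed": seed,
        "n_phases": 4,
        "fiss": {"n_interleaves": 6, "tr_ms": 93.0},
        "pc": {"n_interleaves": 12, "tr_ms": 93.0, "venc_cm_s": 150.0},
        "recon": {"n_iterations": 15},
        "phantom": {"resp_amplitude_mm": [0.0, 0.0, 4.0]},
    }


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """One full desk-scale pipeline run shared by the end-to-end tests."""
    outdir = tmp_path_factory.mktemp("e2e")
    manifest, report = run_pipeline({"seed": 1, "n_phases": 8}, outdir)
    return outdir, manifest, report
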