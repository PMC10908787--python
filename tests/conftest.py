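import numpy as np
import pandas as pd
import pytest

from smlfm3d import benchmark as bench
from smlfm3d import lightfield as lf
from smlfm3d import pipeline
from smlfm3d.optics import OpticalConfig, make_lenslet_geometry
from smlfm3d.simulate import SimConfig, simulate_dataset

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def optics_cfg():
    return OpticalConfig()


@pytest.fixture(scope="session")
def geometry(optics_cfg):
    return make_lenslet_geometry(optics_cfg)


@pytest.fixture(scope="session")
def lf_ctx():
    return pipeline.PipelineContext.create("lightfield")


@pytest.fixture(scope="session")
def astig_ctx():
    return pipeline.PipelineContext.create("astigmatic")


@pytest.fixture(scope="session")
def sparse_lf_dataset(lf_ctx):
    """A shared sparse light-field dataset (0.005 um^-2, 4000 photons)."""
    cfg = SimConfig(density_per_um2=0.005, n_frames=30, photons=4000,
                    modality="lightfield", seed=101)
    return simulate_dataset(cfg, camera=lf_ctx.camera,
                            optics_cfg=lf_ctx.optics_cfg, spec=lf_ctx.spec)


@pytest.fixture(scope="session")
def sparse_lf_locs(lf_ctx, sparse_lf_dataset):
    return pipeline.localize_stack(sparse_lf_dataset.frames, lf_ctx)


def synthetic_view_table(geometry, optics_cfg, n_frames=20, emitters_per_frame=4,
                         noise_nm=15.0, seed=0, views=range(7), z_range=3500.0,
                         view_offsets=None):
    """Noisy per-view 2D localizations generated directly from the parallax
    model (no imaging) -- the oracle input for reconstruction tests."""
    W = lf.shift_vectors(geometry, optics_cfg)
    rng = np.random.default_rng(seed)
    rows = []
    truth = []
    for f in range(n_frames):
        for e in range(emitters_per_frame):
            x, y = rng.uniform(3000, 17000, 2)
            z = rng.uniform(-z_range, z_range)
            truth.append((f, e, x, y, z))
            for v in views:
                p = np.array([x, y]) + z * W[v] + rng.normal(0, noise_nm, 2)
                if view_offsets is not None:
                    p = p + view_offsets[v]
                rows.append((f, v, p[0], p[1], 343.0, 343.0, 571.0, 10.0, noise_nm))
    locs2d = pd.DataFrame(rows, columns=[
        "frame", "view", "x_nm", "y_nm", "sigma_x", "sigma_y",
        "photons", "background", "precision_nm"])
    gt = pd.DataFrame(truth, columns=["frame", "id", "x_nm", "y_nm", "z_nm"])
    return locs2d, gt
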