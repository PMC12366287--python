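import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


from scoph.config import AcquisitionConfig, RunConfig, SynthParams  # noqa: E402


@pytest.fixture
def small_acq():
    """Desk-scale acquisition: 5×5 wells, 512² px, 13 frames over 1 h."""
    return AcquisitionConfig(
        grid_rows=5, grid_cols=5, n_positions=1, image_shape=(512, 512), duration_min=60
    )


def small_run(
    tmp_path,
    lambda_cells=1.716,
    noise_sigma=0.0,
    seed=11,
    n_positions=1,
    grid=5,
    image=512,
    duration=60,
):
    """Run the full pipeline on a small synthetic dataset; returns the result dict."""
    from scoph.pipeline import run_pipeline

    acq = AcquisitionConfig(
        grid_rows=grid,
        grid_cols=grid,
        n_positions=n_positions,
        image_shape=(image, image),
        duration_min=duration,
    )
    synth = SynthParams(seed=seed, lambda_cells=lambda_cells, noise_sigma=noise_sigma)
    cfg = RunConfig.default_synthetic(
        seed=seed, acquisition=acq, synth=synth, output_dir=str(tmp_path / "out")
    )
    return run_pipeline(cfg)


def gaussian_spot(shape, cx, cy, amplitude, sigma):
    """Render a Gaussian spot on a zero background."""
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))


def draw_disks(shape, centers, radius, value, background=0.0):
    """Render uniform bright disks (droplets) on a constant background."""
    img = np.full(shape, background, dtype=float)
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers:
        img[(xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2] = value
    return img
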