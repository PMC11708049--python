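import numpy as np
import pytest

from colidecay import profiles as pf
from colidecay import scene as sc


@pytest.fixture
def exp_lawn_gt():
    """Noise-free exponential lawn: λ = 100 µm, zero YFP baseline."""
    return sc.SceneGroundTruth(
        pixel_size=2.0,
        image_shape=(120, 800),
        producer_colonies=[sc.Colony(center=(110.0, 110.0), radius=100.0)],
        toxin_amplitude=1000.0,
        decay_length=100.0,
        yfp_baseline=0.0,
        yfp_gain=1.0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def exp_profile(exp_lawn_gt):
    """1-µm-sampled radial YFP profile from the colony centre into the lawn."""
    img = sc.render_scene(exp_lawn_gt)
    cx, cy = exp_lawn_gt.producer_colonies[0].center
    return pf.extract_cross_section(img, (cx, cy), (cx + 1000.0, cy), step=1.0)


@pytest.fixture
def synthetic_decay_profile():
    """An aligned analytic decay profile (no rendering): exponential with
    baseline 50 and mild seeded noise, 1-µm sampling."""
    rng = np.random.default_rng(42)
    d = np.arange(0.0, 800.0, 1.0)
    y = 50.0 + 1000.0 * np.exp(-d / 100.0) + rng.normal(0, 5.0, d.size)
    return pf.CrossSectionProfile(
        distances=d,
        intensities={"YFP": y},
        mask=np.ones(d.size, dtype=bool),
        origin_kind="yfp-peak",
    )


@pytest.fixture
def flow_spec():
    return sc.FlowPopulationSpec(n_events=20_000, seed=11)


@pytest.fixture
def clean_reference():
    """Debris/doublet/lysed-free pure reporter sample for gate placement."""
    spec = sc.FlowPopulationSpec(
        n_events=20_000,
        responder_fraction=0.0,
        debris_fraction=0.0,
        doublet_fraction=0.0,
        lysed_fraction=0.0,
        producer_to_reporter_ratio=0.0,
        seed=5,
    )
    return sc.sample_flow_events(spec)
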