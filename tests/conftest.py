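"""Shared fixtures: phantoms and (expensive) pipeline runs, session-scoped."""

import numpy as np
import pytest

from braingac import (
    ExtractionConfig,
    PhantomSpec,
    binarize_head,
    estimate_intensity_range,
    generate_phantom,
    head_threshold,
    run_extraction,
    weak_boundary_spec,
)

TEST_SEED = 7


@pytest.fixture(scope="session")
def standard_phantom():
    """The standard test condition: 128x128x64, 5% noise, 0.2 bias."""
    return generate_phantom(PhantomSpec(seed=TEST_SEED))


@pytest.fixture(scope="session")
def weak_phantom():
    """Standard phantom plus the default weak-boundary arcs."""
    return generate_phantom(weak_boundary_spec(seed=TEST_SEED))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(
        PhantomSpec(seed=TEST_SEED, noise_sd=0.0, bias_amplitude=0.0)
    )


@pytest.fixture(scope="session")
def mid_slice(standard_phantom):
    """Middle axial slice bundle: image, truth, head mask, threshold."""
    vol, truth = standard_phantom
    data = vol.as_float()
    z = data.shape[2] // 2
    rng = estimate_intensity_range(data)
    t = head_threshold(rng, 3.0)
    return {
        "I": data[:, :, z],
        "truth": truth.data[:, :, z],
        "head": binarize_head(data[:, :, z], t),
        "range": rng,
        "t": t,
        "z": z,
    }


@pytest.fixture(scope="session")
def standard_extraction(standard_phantom):
    vol, truth = standard_phantom
    mask, traces, log = run_extraction(vol, ExtractionConfig())
    return {"mask": mask, "traces": traces, "log": log, "truth": truth, "vol": vol}


@pytest.fixture(scope="session")
def weak_runs(weak_phantom):
    """Corrected / uncorrected / classic runs on the weak-boundary phantom."""
    vol, truth = weak_phantom
    out = {"truth": truth, "vol": vol}
    configs = {
        "corrected": ExtractionConfig(correct_leakage=True),
        "uncorrected": ExtractionConfig(correct_leakage=False),
        "classic": ExtractionConfig(
            model="edge", correct_leakage=False, restrict_to_head=False
        ),
    }
    for name, cfg in configs.items():
        mask, traces, _ = run_extraction(vol, cfg)
        out[name] = {"mask": mask, "traces": traces}
    return out


def dice_of(mask, truth) -> float:
    m = np.asarray(mask.data if hasattr(mask, "data") else mask, dtype=bool)
    t = np.asarray(truth.data if hasattr(truth, "data") else truth, dtype=bool)
    tp = np.count_nonzero(m & t)
    return 2 * tp / (m.sum() + t.sum())
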