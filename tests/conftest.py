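import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from resound import (
    SoundscapeParams,
    build_clip_library,
    build_recording_library,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

LIB_SEED = 20260927


@pytest.fixture(scope="session")
def library_dir(tmp_path_factory):
    """Small rendered recording library: 5 species x 3 files, all eligible."""
    out = tmp_path_factory.mktemp("library")
    build_recording_library(
        n_species=5,
        files_per_species=3,
        duration_range=(31.0, 34.0),
        out_dir=out,
        seed=LIB_SEED,
        quality_downgrade_frac=0.0,
        vocal_type_weights={"song": 0.7, "call": 0.3},
    )
    return out


@pytest.fixture(scope="session")
def manifest(library_dir):
    import pandas as pd

    return pd.read_csv(library_dir / "manifest.csv")


@pytest.fixture(scope="session")
def std_library(manifest):
    lib, missing = build_clip_library(manifest, seed=LIB_SEED)
    assert not missing
    return lib


@pytest.fixture()
def short_params():
    """A fast 60 s canvas for unit tests (protocol gain, 2 iterations)."""
    return SoundscapeParams(canvas_s=60.0, n_iter=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
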