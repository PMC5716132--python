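import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from srscone.config import default_config
from srscone.fixtures import make_fixtures
from srscone.misalignment import run_tilt_study
from srscone.synthetic_field import DoseField


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def beam(cfg):
    return cfg.beam


@pytest.fixture(scope="session")
def cones(cfg):
    return cfg.cones


@pytest.fixture(scope="session")
def field5(cfg):
    return DoseField(cfg.beam, cfg.cone(5.0), ssd_mm=1000.0)


@pytest.fixture(scope="session")
def tilt_study_5mm(cfg):
    return run_tilt_study(cfg.beam, cfg.cone(5.0))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, cfg):
    out = tmp_path_factory.mktemp("fixtures") / "set"
    make_fixtures(cfg, out)
    return out
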