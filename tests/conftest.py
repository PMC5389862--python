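import numpy as np
import pytest

from beatchirp.afferents import AfferentParams
from beatchirp.config import RunConfig
from beatchirp.pipeline import run_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full synthetic experiment at the default afferent calibration:
    six beat frequencies spanning the 2-64 Hz contrast, all 8 chirp phases,
    200 trials per condition, fixed seed.  Shared by the trend-suite tests."""
    cfg = RunConfig(
        frequencies=(2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
        seed=1,
        afferent=AfferentParams(n_trials=200),
    )
    outdir = tmp_path_factory.mktemp("default_run")
    return run_experiment(cfg, outdir)


def score_series(result, source, metric):
    """Frequency-indexed series of phase-averaged scores from a run."""
    s = result.scores
    sel = s[(s.source == source) & (s.metric == metric) & (s.phase == "all")]
    return sel.set_index("f_beat")["value"].sort_index()
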