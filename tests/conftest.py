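import logging
import warnings

import numpy as np
import pytest

from cogmap import (
    DecoderConfig,
    IntentionAgentConfig,
    JediConfig,
    JumperConfig,
    compute_rpv_map,
    make_training_windows,
    run_jedi_session,
    run_jumper_session,
    train_decoder,
)
from cogmap.pipeline import make_fixture

logging.getLogger("cogmap").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny():
    """10 units, ~1.5 min of Running — fast structural tests."""
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def tiny_rpv(tiny):
    return compute_rpv_map(tiny["raster"], tiny["trajectory"], tiny["arena"])


@pytest.fixture(scope="session")
def tiny_model(tiny):
    """A quickly trained decoder for structural (not accuracy) tests."""
    cfg = DecoderConfig(max_iter=8)
    w, _, tg = make_training_windows(tiny["raster"], tiny["trajectory"], cfg)
    return train_decoder(w, tg, cfg, tiny["arena"],
                         unit_ids=tiny["ensemble"].unit_ids, seed=0)


@pytest.fixture(scope="session")
def medium():
    """40 units, ~8 min — enough spatial coverage for map-recovery tests."""
    from cogmap import ArenaSpec, make_ensemble, simulate_running_session

    arena = ArenaSpec()
    ensemble = make_ensemble(arena, 40, seed=21)
    traj, raster, trials, lfp = simulate_running_session(
        arena, ensemble, 160, seed=22
    )
    return {
        "arena": arena,
        "ensemble": ensemble,
        "trajectory": traj,
        "raster": raster,
        "trials": trials,
        "lfp": lfp,
    }


@pytest.fixture(scope="session")
def trained():
    """The full-scale study condition: ~40-min Running session, 100 units,
    decoder trained with the default augmentation.  Shared across the
    integration and acceptance tests (training dominates suite runtime)."""
    fx = make_fixture("small", seed=11)
    rpv = compute_rpv_map(fx["raster"], fx["trajectory"], fx["arena"])
    cfg = DecoderConfig()
    w, _, tg = make_training_windows(fx["raster"], fx["trajectory"], cfg)
    model = train_decoder(w, tg, cfg, fx["arena"],
                          unit_ids=fx["ensemble"].unit_ids, seed=7)
    return {"fixture": fx, "rpv": rpv, "model": model, "arena": fx["arena"]}


@pytest.fixture(scope="session")
def jumper_fid1(trained):
    cfg = JumperConfig(n_trials=50)
    trials, raster, streams = run_jumper_session(
        trained["rpv"], trained["model"], IntentionAgentConfig(fidelity=1.0),
        cfg, trained["arena"], seed=3,
    )
    return {"cfg": cfg, "trials": trials, "raster": raster, "streams": streams}


@pytest.fixture(scope="session")
def jumper_fid0(trained):
    cfg = JumperConfig(n_trials=50)
    trials, raster, streams = run_jumper_session(
        trained["rpv"], trained["model"], IntentionAgentConfig(fidelity=0.0),
        cfg, trained["arena"], seed=3,
    )
    return {"cfg": cfg, "trials": trials, "raster": raster, "streams": streams}


@pytest.fixture(scope="session")
def jedi_fid1(trained):
    cfg = JediConfig(n_trials=8)
    agent = IntentionAgentConfig(fidelity=1.0, policy="hold_goal")
    trials, raster, streams = run_jedi_session(
        trained["rpv"], trained["model"], agent, cfg, trained["arena"], seed=5
    )
    return {"cfg": cfg, "trials": trials, "raster": raster, "streams": streams}
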