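"""Shared fixtures: the heavy desk-scale runs are computed once per session."""

import numpy as np
import pytest

from lvotflow.geometry import build_geometry
from lvotflow.pipeline import RunConfig, run_cycle, summarize


@pytest.fixture(scope="session")
def geometries():
    return {mid: build_geometry(mid) for mid in ("N-LV", "S-LV", "DSS-LV")}


@pytest.fixture(scope="session")
def batch_results():
    """Desk-scale cycle runs of the three models (final-cycle records).

    N-LV runs three cycles so cycle-to-cycle periodicity has two samples;
    the comparison models run the default two.
    """
    out = {}
    for mid, ncyc in (("N-LV", 3), ("S-LV", 2), ("DSS-LV", 2)):
        cfg = RunConfig(model_id=mid, n_cycles=ncyc)
        res = run_cycle(cfg)
        out[mid] = (cfg, res, summarize(res, cfg))
    return out


@pytest.fixture(scope="session")
def flutter_result():
    from lvotflow.pipeline import run_lesion_flutter
    return run_lesion_flutter(u_systolic=0.2, t_end=0.06, dt=1e-3,
                              cell_size=1.8e-3, ramp=0.03)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
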