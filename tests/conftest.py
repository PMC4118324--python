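import math

import numpy as np
import pandas as pd
import pytest

import riskmatch as rm

INF = math.inf


@pytest.fixture(scope="session")
def described_cfg():
    return rm.described_scenario()


@pytest.fixture(scope="session")
def small_cfg():
    """Down-scaled reference scenario for fast fitting tests."""
    return rm.described_scenario(n_per_profile=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_cohort(rows):
    """Hand-built cohort table from (id, z, t_exposure, t_final, event) tuples.

    ``z`` is a 3-tuple; ``t_exposure=None`` means never exposed.
    """
    recs = []
    for sid, z, t_e, t_f, ev in rows:
        t_e = INF if t_e is None else float(t_e)
        recs.append(
            {
                "id": sid,
                "z1": z[0],
                "z2": z[1],
                "z3": z[2],
                "t_exposure": t_e,
                "t_final": float(t_f),
                "exposed": int(math.isfinite(t_e)),
                "event": int(ev),
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture()
def toy_cohort():
    """One exposed subject plus three candidate controls (same profile)."""
    return make_cohort(
        [
            (0, (0, 0, 0), 5.0, 15.0, 1),   # exposed at 5
            (1, (0, 0, 0), None, 10.0, 1),  # never exposed, at risk at 5
            (2, (0, 0, 0), 7.0, 12.0, 0),   # exposed later
            (3, (0, 0, 0), None, 3.0, 1),   # exits before 5
        ]
    )
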