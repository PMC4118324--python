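"""Illness-death cohort simulator.

Each subject starts in the initial state at t = 0 and draws four mutually
independent latent times: ``t12`` (time to exposure), ``t13`` (time to the
final event without exposure), ``t23`` (duration from exposure to the final
event, on the clock restarted at exposure) and ``C`` (censoring).  The
observed record ``(t_E, t_i, E, Delta)`` is one of four exclusive cases:

    (C,   C,         0, 0)  if C < min(t12, t13)
    (t13, t13,       0, 1)  if t13 <= min(t12, C)
    (t12, C,         1, 0)  if t12 < min(t13, C) and t12 + t23 > C
    (t12, t12 + t23, 1, 1)  if t12 < t13 and t12 + t23 <= C

with administrative censoring at ``tmax`` folded into C.  For a
never-exposed subject ``t_E`` is recorded as +inf.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .scenarios import PROFILES, ScenarioConfig

__all__ = [
    "IllnessDeathSimulator",
    "sample_transition_times",
    "derive_outcome",
    "simulate_cohort",
]

COHORT_COLUMNS = ["id", "z1", "z2", "z3", "t_exposure", "t_final", "exposed", "event"]


def derive_outcome(t12, t13, t23, C, tmax):
    """Map latent transition times onto the observed record, vectorized.

    Returns ``(t_E, t_i, E, Delta)`` arrays.  Administrative censoring at
    ``tmax`` is applied by replacing C with ``min(C, tmax)`` before the four
    exclusive cases, so every subject is censored at the horizon.  Exact ties
    (measure zero for continuous draws) resolve in the order event < exposure
    < censoring, matching the inequality pattern of the four cases.
    """
    t12, t13, t23, C = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (t12, t13, t23, C))
    )
    if np.any(t12 <= 0) or np.any(t13 <= 0) or np.any(t23 <= 0) or np.any(C <= 0):
        raise ValueError("all latent times must be > 0")
    c_eff = np.minimum(C, tmax)

    # ties (measure zero for continuous draws) resolve as event < exposure
    # < censoring: "<=" where the favoured outcome is on the left
    event_first = t13 <= np.minimum(t12, c_eff)          # final event before exposure
    exposed = (~event_first) & (t12 < t13) & (t12 <= c_eff)
    censored_first = (~event_first) & (~exposed)          # c_eff < min(t12, t13)

    t_e = np.where(exposed, t12, math.inf)
    e_flag = exposed.astype(np.int8)

    t_i = np.where(censored_first, c_eff, 0.0)
    t_i = np.where(event_first, t13, t_i)
    post = t12 + t23
    event_after = exposed & (post <= c_eff)
    t_i = np.where(exposed, np.where(event_after, post, c_eff), t_i)
    delta = (event_first | event_after).astype(np.int8)
    return t_e, t_i, e_flag, delta


def sample_transition_times(config: ScenarioConfig, profile, rng: np.random.Generator, size: int = 1):
    """Draw ``(t12, t13, t23, C)`` for ``size`` subjects of one profile.

    The four draws are mutually independent; C is +inf when the censoring
    scheme is ``none``.  The caller owns and seeds ``rng``.
    """
    t12 = config.spec12.sample(rng, profile, size)
    t13 = config.spec13.sample(rng, profile, size)
    t23 = config.spec23.sample(rng, profile, size)
    c = config.censoring.sample(rng, size)
    return t12, t13, t23, c


class IllnessDeathSimulator(BaseEstimator):
    """Generate cohorts from a three-state illness-death scenario.

    Parameters
    ----------
    scenario : ScenarioConfig
        Transition intensities, covariate effects, censoring and layout.
    random_state : int or numpy Generator, optional
        Seed for :meth:`sample` when no explicit seed is passed.
    """

    def __init__(self, scenario: ScenarioConfig, random_state=None):
        self.scenario = scenario
        self.random_state = random_state

    def sample(self, seed=None) -> pd.DataFrame:
        """Simulate one cohort; returns a data frame with one row per subject.

        Columns: ``id, z1, z2, z3, t_exposure, t_final, exposed, event``
        (``t_exposure`` is +inf for never-exposed subjects).  The scenario
        label and seed are recorded in ``DataFrame.attrs``.
        """
        if seed is None:
            seed = self.random_state
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        cfg = self.scenario
        n = cfg.n_per_profile
        frames = []
        for p_idx, profile in enumerate(PROFILES):
            t12, t13, t23, c = sample_transition_times(cfg, profile, rng, size=n)
            t_e, t_i, e_flag, delta = derive_outcome(t12, t13, t23, c, cfg.tmax)
            ids = np.arange(p_idx * n, (p_idx + 1) * n)
            frames.append(
                pd.DataFrame(
                    {
                        "id": ids,
                        "z1": profile[0],
                        "z2": profile[1],
                        "z3": profile[2],
                        "t_exposure": t_e,
                        "t_final": t_i,
                        "exposed": e_flag,
                        "event": delta,
                    }
                )
            )
        cohort = pd.concat(frames, ignore_index=True)
        cohort.attrs["scenario"] = cfg.label
        cohort.attrs["seed"] = None if isinstance(seed, np.random.Generator) else seed
        return cohort


def simulate_cohort(config: ScenarioConfig, seed=None) -> pd.DataFrame:
    """Functional wrapper around :class:`IllnessDeathSimulator`."""
    return IllnessDeathSimulator(config).sample(seed)


def profile_of(cohort: pd.DataFrame) -> pd.Series:
    """Profile index 0..7 of each subject (lexicographic in z1, z2, z3)."""
    return cohort["z1"] * 4 + cohort["z2"] * 2 + cohort["z3"]
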