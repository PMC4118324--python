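"""Risk-set matching of exposed subjects to not-(yet-)exposed controls.

Two greedy 1:1 matching schemes, both exact on the covariate profile
``(z1, z2, z3)`` and both requiring the control to be event-free at the
formation time:

* **Method 1** (*a posteriori*): the control must never be exposed over the
  whole follow-up — eligibility set
  ``R1(t_Ej) = {i != j : t_i >= t_Ej and t_Ei = +inf}``.
* **Method 2** (*real time*): the control must not yet be exposed at the
  formation time — ``R2(t_Ej) = {i != j : t_i >= t_Ej and t_Ei > t_Ej}``.
  A pair whose control is later exposed is *imperfect*; that control may
  afterwards head her own pair as the exposed member.

Exposed subjects are processed in ascending exposure time; the control is
drawn uniformly at random from the eligible set and consumed (no control
serves twice).  Exposed subjects with an empty eligible set are excluded
and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import profile_of

__all__ = [
    "Pair",
    "PairedDataset",
    "RiskSetMatcher",
    "eligible_set_method1",
    "eligible_set_method2",
    "match_cohort",
    "relative_pair_difference",
]

PAIR_COLUMNS = [
    "pair_id",
    "exposed_id",
    "control_id",
    "t_formation",
    "perfect",
    "z1",
    "z2",
    "z3",
]


@dataclass(frozen=True)
class Pair:
    pair_id: int
    exposed_id: int
    control_id: int
    t_formation: float
    perfect: bool


@dataclass
class PairedDataset:
    """Pairs formed on one cohort by one matching method.

    ``pairs`` is a data frame with columns ``pair_id, exposed_id,
    control_id, t_formation, perfect, z1, z2, z3``; ``unmatched_exposed``
    lists exposed subjects that could not be paired.
    """

    pairs: pd.DataFrame
    method: int
    cohort: pd.DataFrame
    unmatched_exposed: list[int] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def n_imperfect(self) -> int:
        return int((~self.pairs["perfect"].astype(bool)).sum())


def _require_exposed(cohort: pd.DataFrame, j: int) -> pd.Series:
    row = cohort.loc[cohort["id"] == j]
    if row.empty:
        raise KeyError(f"subject {j} not in cohort")
    row = row.iloc[0]
    if not row["exposed"]:
        raise ValueError(f"subject {j} is not exposed")
    return row


def eligible_set_method1(cohort: pd.DataFrame, j: int) -> set[int]:
    """R1: same profile, at risk at t_Ej, never exposed during follow-up."""
    row = _require_exposed(cohort, j)
    t_ej = row["t_exposure"]
    mask = (
        (cohort["id"] != j)
        & (cohort["z1"] == row["z1"])
        & (cohort["z2"] == row["z2"])
        & (cohort["z3"] == row["z3"])
        & (cohort["t_final"] >= t_ej)
        & (~np.isfinite(cohort["t_exposure"]))
    )
    return set(cohort.loc[mask, "id"].tolist())


def eligible_set_method2(cohort: pd.DataFrame, j: int, already_used_controls=()) -> set[int]:
    """R2: same profile, at risk at t_Ej, not yet exposed (strictly) at t_Ej."""
    row = _require_exposed(cohort, j)
    t_ej = row["t_exposure"]
    mask = (
        (cohort["id"] != j)
        & (cohort["z1"] == row["z1"])
        & (cohort["z2"] == row["z2"])
        & (cohort["z3"] == row["z3"])
        & (cohort["t_final"] >= t_ej)
        & (cohort["t_exposure"] > t_ej)
    )
    return set(cohort.loc[mask, "id"].tolist()) - set(already_used_controls)


class RiskSetMatcher(BaseEstimator):
    """Greedy 1:1 exact matcher on the covariate profile.

    Parameters
    ----------
    method : {1, 2}
        1 matches to never-exposed controls (*a posteriori*); 2 matches to
        not-yet-exposed controls (*real time*).
    with_replacement : bool
        Allow a control to serve in several pairs (off by default).
    random_state : int or numpy Generator, optional
        Source of randomness for the uniform control draw.
    """

    def __init__(self, method: int = 2, with_replacement: bool = False, random_state=None):
        self.method = method
        self.with_replacement = with_replacement
        self.random_state = random_state

    def match(self, cohort: pd.DataFrame, seed=None) -> PairedDataset:
        if self.method not in (1, 2):
            raise ValueError("method must be 1 or 2")
        if seed is None:
            seed = self.random_state
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

        ids = cohort["id"].to_numpy()
        t_exp = cohort["t_exposure"].to_numpy(dtype=float)
        t_fin = cohort["t_final"].to_numpy(dtype=float)
        prof = profile_of(cohort).to_numpy()
        z = cohort[["z1", "z2", "z3"]].to_numpy()

        available = np.ones(len(cohort), dtype=bool)
        exposed_idx = np.flatnonzero(np.isfinite(t_exp) & (cohort["exposed"].to_numpy() == 1))
        # ascending exposure time, ties broken by subject id
        order = exposed_idx[np.lexsort((ids[exposed_idx], t_exp[exposed_idx]))]

        records: list[tuple] = []
        unmatched: list[int] = []
        never = ~np.isfinite(t_exp)
        for pair_id, jdx in enumerate(order):
            t_ej = t_exp[jdx]
            cand = (prof == prof[jdx]) & (t_fin >= t_ej)
            if self.method == 1:
                cand &= never
            else:
                cand &= t_exp > t_ej
            if not self.with_replacement:
                cand &= available
            cand[jdx] = False
            cand_idx = np.flatnonzero(cand)
            if cand_idx.size == 0:
                unmatched.append(int(ids[jdx]))
                continue
            cdx = cand_idx[rng.integers(cand_idx.size)]
            available[cdx] = False
            records.append(
                (
                    len(records),
                    int(ids[jdx]),
                    int(ids[cdx]),
                    float(t_ej),
                    bool(never[cdx]),
                    *map(int, z[jdx]),
                )
            )
        pairs = pd.DataFrame(records, columns=PAIR_COLUMNS)
        if pairs.empty:
            pairs = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                PAIR_COLUMNS, [int, int, int, float, bool, int, int, int])})
        return PairedDataset(
            pairs=pairs,
            method=self.method,
            cohort=cohort,
            unmatched_exposed=unmatched,
            seed=None if isinstance(seed, np.random.Generator) else seed,
        )


def match_cohort(cohort: pd.DataFrame, method: int, rng=None) -> PairedDataset:
    """Functional wrapper around :class:`RiskSetMatcher`."""
    return RiskSetMatcher(method=method).match(cohort, seed=rng)


def relative_pair_difference(paired1: PairedDataset, paired2: PairedDataset) -> float:
    """Relative difference in pair counts, (n2 - n1) / n1."""
    n1, n2 = paired1.n_pairs, paired2.n_pairs
    if n1 == 0:
        raise ValueError("relative pair difference undefined: Method-1 pair count is zero")
    return (n2 - n1) / n1
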