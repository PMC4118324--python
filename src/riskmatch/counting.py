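"""Counting-process (start-stop) tables for paired survival data.

Both members of a pair enter the risk set at the pair-formation time (the
exposed member's exposure time) — delayed entry.  The exposed member
carries exposure status 1 from entry, the control 0.  An imperfect control
(Method 2) is censored within her pair at her own exposure time.  Under the
stratified (pair-baseline) model the whole pair is additionally censored at
the first exit of either member; the marginal model follows each member to
her own censoring or event.

Rows are half-open intervals ``(start, stop]`` with the event indicator
attached to ``stop``.  When an interval grid is supplied, exposed
person-time is split at the grid boundaries and indicator columns
``e1 .. eL`` (exposure within interval ``I_l = [a_{l-1}, a_l)``) are added,
so interval-specific exposure effects are plain regression columns.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .matching import PairedDataset

__all__ = ["IntervalGrid", "build_counting_process", "exposure_columns"]


class IntervalGrid:
    """Strictly increasing time-axis partition ``a_0 = 0 < a_1 < ... < a_L``."""

    def __init__(self, boundaries):
        b = np.asarray(boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two boundaries")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        self.boundaries = b

    @property
    def L(self) -> int:
        return self.boundaries.size - 1

    @property
    def tmax(self) -> float:
        return float(self.boundaries[-1])

    def interval_index(self, t):
        """1-based index of the interval containing ``t`` (I_l closed on the left)."""
        idx = np.searchsorted(self.boundaries, np.asarray(t, dtype=float), side="right")
        return np.clip(idx, 1, self.L)

    @classmethod
    def from_event_quartiles(cls, event_times, tmax: float, L: int = 4) -> "IntervalGrid":
        """Boundaries at the empirical quantiles of pooled event times.

        ``L`` intervals with interior cut points at the ``1/L .. (L-1)/L``
        quantiles; degenerates gracefully to ``[0, tmax]`` when ``L == 1``.
        """
        times = np.asarray(event_times, dtype=float)
        times = times[np.isfinite(times)]
        if L == 1:
            return cls([0.0, tmax])
        if times.size < L:
            raise ValueError("not enough event times to place quantile boundaries")
        qs = np.quantile(times, np.arange(1, L) / L)
        b = np.concatenate([[0.0], qs, [tmax]])
        if np.any(np.diff(b) <= 0):
            raise ValueError("degenerate quantile boundaries; supply an explicit grid")
        return cls(b)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalGrid({np.round(self.boundaries, 3).tolist()})"


def exposure_columns(table: pd.DataFrame) -> list[str]:
    """Names of the interval exposure indicator columns, ``['e1', ...]``."""
    cols = sorted(
        (c for c in table.columns if re.fullmatch(r"e\d+", c)),
        key=lambda c: int(c[1:]),
    )
    return cols


def _split_exposed_rows(start, stop, event, cuts):
    """Split rows at interior grid cuts; returns expanded arrays + interval index."""
    lo = np.searchsorted(cuts, start, side="right")
    hi = np.searchsorted(cuts, stop, side="left")
    n_cuts = hi - lo
    n_seg = n_cuts + 1
    rep = np.repeat(np.arange(start.size), n_seg)
    seg = np.arange(rep.size) - np.repeat(np.cumsum(n_seg) - n_seg, n_seg)
    lo_r, n_r = lo[rep], n_cuts[rep]
    left = np.where(seg == 0, start[rep], cuts[np.minimum(lo_r + seg - 1, cuts.size - 1)])
    right = np.where(seg == n_r, stop[rep], cuts[np.minimum(lo_r + seg, cuts.size - 1)])
    ev = np.where(seg == n_r, event[rep], 0)
    return rep, left, right, ev


def build_counting_process(
    paired: PairedDataset,
    model_family: str = "lwa",
    grid: IntervalGrid | None = None,
    entry_at_origin: bool = False,
) -> pd.DataFrame:
    """Turn a paired dataset into a start-stop table ready for model fitting.

    Parameters
    ----------
    paired : PairedDataset
        Pairs plus their source cohort.
    model_family : {"lwa", "hp"}
        ``"hp"`` applies pair-level censoring (both members truncated at the
        earlier exit); ``"lwa"`` follows each member to her own exit.
    grid : IntervalGrid, optional
        When given, exposed person-time is split at the boundaries and
        ``e1..eL`` indicator columns are added.
    entry_at_origin : bool
        Enter both members at t = 0 instead of the formation time, with the
        same (time-fixed) exposure status.  Only meaningful for the
        stratified model on Method-1 pairs, where it provably leaves the
        partial likelihood unchanged; exposed for that equivalence check.

    Returns
    -------
    DataFrame with columns ``subject_id, pair_id, start, stop, event,
    exposed, z1, z2, z3`` and optionally ``e1..eL``.
    """
    if model_family not in ("lwa", "hp"):
        raise ValueError("model_family must be 'lwa' or 'hp'")
    pairs = paired.pairs
    cohort = paired.cohort.set_index("id")
    if pairs.empty:
        cols = ["subject_id", "pair_id", "start", "stop", "event", "exposed", "z1", "z2", "z3"]
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    tf = pairs["t_formation"].to_numpy(dtype=float)
    exp_id = pairs["exposed_id"].to_numpy()
    ctl_id = pairs["control_id"].to_numpy()

    exp_end = cohort.loc[exp_id, "t_final"].to_numpy(dtype=float)
    exp_event = cohort.loc[exp_id, "event"].to_numpy()
    ctl_final = cohort.loc[ctl_id, "t_final"].to_numpy(dtype=float)
    ctl_event = cohort.loc[ctl_id, "event"].to_numpy()
    ctl_texp = cohort.loc[ctl_id, "t_exposure"].to_numpy(dtype=float)

    # imperfect control: censored in this pair at her own (later) exposure
    imperfect = np.isfinite(ctl_texp)
    ctl_end = np.where(imperfect, np.minimum(ctl_texp, ctl_final), ctl_final)
    ctl_ev = np.where(imperfect & (ctl_texp < ctl_final), 0, ctl_event)

    if model_family == "hp":
        # pair censored when either member is censored or has the final event
        tau = np.minimum(exp_end, ctl_end)
        exp_ev = np.where(exp_end <= tau, exp_event, 0)
        ctl_ev = np.where(ctl_end <= tau, ctl_ev, 0)
        exp_stop = np.minimum(exp_end, tau)
        ctl_stop = np.minimum(ctl_end, tau)
    else:
        exp_ev = exp_event
        exp_stop = exp_end
        ctl_stop = ctl_end

    entry = np.zeros_like(tf) if entry_at_origin else tf
    z = pairs[["z1", "z2", "z3"]].to_numpy()
    pid = pairs["pair_id"].to_numpy()

    def member_frame(sid, start, stop, ev, exposed_flag):
        keep = stop > start
        return pd.DataFrame(
            {
                "subject_id": np.asarray(sid)[keep],
                "pair_id": pid[keep],
                "start": start[keep],
                "stop": stop[keep],
                "event": np.asarray(ev, dtype=np.int8)[keep],
                "exposed": np.int8(exposed_flag),
                "z1": z[keep, 0],
                "z2": z[keep, 1],
                "z3": z[keep, 2],
            }
        )

    table = pd.concat(
        [
            member_frame(exp_id, entry, exp_stop, exp_ev, 1),
            member_frame(ctl_id, entry, ctl_stop, ctl_ev, 0),
        ],
        ignore_index=True,
    )

    if grid is not None:
        if table["stop"].max() > grid.tmax + 1e-9:
            raise ValueError("interval grid does not cover the data range")
        table = _add_interval_indicators(table, grid)
    return table


def _add_interval_indicators(table: pd.DataFrame, grid: IntervalGrid) -> pd.DataFrame:
    """Split exposed rows at grid boundaries and add ``e1..eL`` columns."""
    cuts = grid.boundaries[1:-1]
    is_exp = table["exposed"].to_numpy() == 1
    unexp = table.loc[~is_exp].copy()
    exp = table.loc[is_exp]
    if len(exp) and cuts.size:
        rep, left, right, ev = _split_exposed_rows(
            exp["start"].to_numpy(dtype=float),
            exp["stop"].to_numpy(dtype=float),
            exp["event"].to_numpy(),
            cuts,
        )
        exp = exp.iloc[rep].copy()
        exp["start"] = left
        exp["stop"] = right
        exp["event"] = ev.astype(np.int8)
    out = pd.concat([exp, unexp], ignore_index=True)
    # membership by the left endpoint: the open segment (left, right] sits in
    # the interval whose half-open span [a_{l-1}, a_l) contains it
    lidx = out["exposed"].to_numpy() * grid.interval_index(out["start"].to_numpy())
    for l in range(1, grid.L + 1):
        out[f"e{l}"] = (lidx == l).astype(np.int8)
    return out.sort_values(["pair_id", "subject_id", "start"], ignore_index=True)
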