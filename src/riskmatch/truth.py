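"""Reference ("true") exposure effects for the illness-death scenario.

The parameter of interest is the ratio of the post-exposure to the
pre-exposure final-event intensity, HR(t) = lambda_23(t) / lambda_13(t).
Because a subject only enters the 2->3 transition once exposed (delayed
entry / left truncation) and because the 2->3 clock restarts at exposure,
the *population* post-exposure hazard at study time t is the hazard of the
convolution

    f_23(t) = integral_0^t f23_dur(t - u) f12(u) S13(u) du,

not the raw intensity.  This module discretizes the time axis into K tiny
steps, builds the left-truncated survival S23 as a product of one-step
conditional survival factors, reads off the implied per-step hazard, and
averages across covariate profiles with at-risk-mass weights:

    HRbar(t) = [sum_z N23z(t) lam23z(t) / sum_z N23z(t)]
             / [sum_z N13z(t) lam13z(t) / sum_z N13z(t)]

The per-profile ratio lam23z / lam13z is the theoretical profile-specific
effect HR_i(t).  The covariate-adjusted average HRbar_a(t) has no closed
form and is approximated empirically: one large cohort is simulated and a
proportional-hazards model with interval exposure indicators (adjusted for
the covariates) is fitted; exp(gamma_l) is the per-interval value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .counting import IntervalGrid
from .cox import _BreslowEngine, _newton
from .scenarios import PROFILES, ScenarioConfig

__all__ = [
    "TruthCurves",
    "profile_truth_curves",
    "s23_left_truncated",
    "risk_masses",
    "average_hr_unadjusted",
    "compute_truth",
    "empirical_hr_curves",
]


def _time_grid(tmax: float, K: int) -> np.ndarray:
    return np.linspace(0.0, tmax, K + 1)


def profile_truth_curves(config: ScenarioConfig, profile, t: np.ndarray) -> dict:
    """All per-profile ingredients on the discretization grid ``t``.

    Returns a dict with the raw transition functions, the left-truncated
    2->3 survival / hazard and the at-risk masses N13z, N23z.
    """
    dt = t[1] - t[0]
    s12 = config.spec12
    s13 = config.spec13
    s23 = config.spec23

    f12 = s12.density(t, profile)
    S12 = s12.survival(t, profile)
    S13 = s13.survival(t, profile)
    lam13 = s13.hazard(t, profile)
    f23dur = s23.density(t, profile)
    S23dur = s23.survival(t, profile)

    def conv(a, b):
        # trapezoid-weighted convolution integral on the uniform grid
        full = np.convolve(a, b)[: t.size]
        full -= 0.5 * (a[0] * b + a * b[0])
        return full * dt

    q = f12 * S13                  # density of (exposed at u, no direct event)
    f23conv = conv(q, f23dur)      # final-event density among the exposed
    Qconv = conv(q, S23dur)        # at-risk (exposed, event-free) mass

    # left-truncated survival: product of one-step conditional factors
    entered = cumulative_trapezoid(q, t, initial=0.0)
    deaths = f23conv * dt
    prev_deaths = np.cumsum(deaths) - deaths        # sum_{l < j} dt * f23(t_l)
    denom = entered - prev_deaths
    with np.errstate(divide="ignore", invalid="ignore"):
        dh = np.where(denom > 1e-12, f23conv * dt / denom, np.nan)
    dh[0] = np.nan
    bad = np.isfinite(dh) & (dh >= 1.0)
    if np.any(bad):
        raise ValueError(
            "discretization too coarse: one-step death probability reached 1; "
            "increase K"
        )
    one_minus = np.where(np.isfinite(dh), 1.0 - dh, 1.0)
    S23 = np.cumprod(one_minus)
    lam23 = -np.log(one_minus) / dt
    lam23[~np.isfinite(dh)] = np.nan

    gbar = config.censoring.survival(t)
    g = config.censoring.density(t)
    n0 = config.n_per_profile
    N13 = n0 * S13 * gbar * S12
    E23 = cumulative_trapezoid(gbar * q, t, initial=0.0)
    D23 = cumulative_trapezoid(gbar * f23conv, t, initial=0.0)
    C23 = cumulative_trapezoid(g * Qconv, t, initial=0.0)
    N23 = n0 * (E23 - D23 - C23)

    return {
        "t": t,
        "f12": f12,
        "S12": S12,
        "S13": S13,
        "lam13": lam13,
        "f23conv": f23conv,
        "S23": S23,
        "lam23": lam23,
        "N13": N13,
        "N23": N23,
        "E23": E23,
        "D23": D23,
        "C23": C23,
    }


def s23_left_truncated(config: ScenarioConfig, profile, K: int = 2000, tmax: float | None = None):
    """Left-truncated 2->3 survival and per-step hazard for one profile."""
    t = _time_grid(tmax or config.tmax, K)
    c = profile_truth_curves(config, profile, t)
    return t, c["S23"], c["lam23"]


def risk_masses(config: ScenarioConfig, profile, K: int = 2000, tmax: float | None = None):
    """At-risk masses N13z(t), N23z(t) for one profile."""
    t = _time_grid(tmax or config.tmax, K)
    c = profile_truth_curves(config, profile, t)
    return t, c["N13"], c["N23"]


@dataclass
class TruthCurves:
    """Reference effect curves on the discretization grid.

    ``hr_bar`` is the at-risk-weighted population average HR(t);
    ``hr_profile`` (8 x K+1) the per-profile ratio; diagnostics carry the
    weights and masses.
    """

    t: np.ndarray
    hr_bar: np.ndarray
    hr_profile: np.ndarray
    weights13: np.ndarray
    weights23: np.ndarray
    N13: np.ndarray
    N23: np.ndarray
    lam13: np.ndarray
    lam23: np.ndarray

    def interval_mean_log(self, grid: IntervalGrid, curve: np.ndarray, weights=None) -> np.ndarray:
        """Average of log(curve) over each grid interval (NaN-aware).

        With ``weights`` (a curve on the same grid) the average is
        weighted; used to weight by the expected exposed-event intensity,
        which is what an interval-indicator partial-likelihood fit targets
        — unweighted averages would be dominated by the earliest times,
        where almost nobody exposed is yet at risk.
        """
        out = np.full(grid.L, np.nan)
        idx = grid.interval_index(self.t)
        logc = np.log(curve)
        for l in range(1, grid.L + 1):
            m = (idx == l) & np.isfinite(logc)
            if weights is not None:
                m &= np.isfinite(weights) & (weights > 0)
            if m.any():
                out[l - 1] = np.average(logc[m], weights=None if weights is None else weights[m])
        return out

    def _event_weight(self, w: int | None = None) -> np.ndarray:
        """Expected exposed-event intensity N23 * lam23 (per profile or summed)."""
        contrib = np.where(np.isfinite(self.lam23), self.N23 * self.lam23, np.nan)
        return contrib[w] if w is not None else np.nansum(contrib, axis=0)

    def interval_log_hr_bar(self, grid: IntervalGrid, weighted: bool = True) -> np.ndarray:
        return self.interval_mean_log(
            grid, self.hr_bar, self._event_weight() if weighted else None
        )

    def interval_log_hr_profile(self, grid: IntervalGrid, weighted: bool = True) -> np.ndarray:
        """(8, L) per-profile interval-averaged log HR_i."""
        return np.vstack(
            [
                self.interval_mean_log(
                    grid, self.hr_profile[w], self._event_weight(w) if weighted else None
                )
                for w in range(8)
            ]
        )


def compute_truth(config: ScenarioConfig, K: int = 2000) -> TruthCurves:
    """Discretized reference curves for every profile and their average."""
    t = _time_grid(config.tmax, K)
    curves = [profile_truth_curves(config, p, t) for p in PROFILES]
    N13 = np.vstack([c["N13"] for c in curves])
    N23 = np.vstack([c["N23"] for c in curves])
    lam13 = np.vstack([c["lam13"] for c in curves])
    lam23 = np.vstack([c["lam23"] for c in curves])

    with np.errstate(invalid="ignore", divide="ignore"):
        w13 = N13 / N13.sum(axis=0)
        # mask profiles with undefined lam23 so weights renormalize over
        # profiles actually contributing a post-exposure hazard
        m23 = np.where(np.isfinite(lam23), N23, 0.0)
        w23 = m23 / m23.sum(axis=0)
        lam13_bar = (w13 * lam13).sum(axis=0)
        lam23_bar = np.nansum(w23 * lam23, axis=0)
        lam23_bar[m23.sum(axis=0) <= 0] = np.nan
        hr_bar = lam23_bar / lam13_bar
        hr_profile = lam23 / lam13
    return TruthCurves(
        t=t,
        hr_bar=hr_bar,
        hr_profile=hr_profile,
        weights13=w13,
        weights23=w23,
        N13=N13,
        N23=N23,
        lam13=lam13,
        lam23=lam23,
    )


def average_hr_unadjusted(config: ScenarioConfig, K: int = 2000):
    """Population-average HR(t) on the discretization grid."""
    tc = compute_truth(config, K=K)
    return tc.t, tc.hr_bar


# ---------------------------------------------------------------------------
# empirical (large-sample) approximation, including the adjusted average
# ---------------------------------------------------------------------------


def _cohort_counting_process(cohort: pd.DataFrame, grid: IntervalGrid):
    """Subject-level start-stop rows from t = 0 with interval exposure columns."""
    t_e = cohort["t_exposure"].to_numpy(dtype=float)
    t_i = cohort["t_final"].to_numpy(dtype=float)
    ev = cohort["event"].to_numpy()
    z = cohort[["z1", "z2", "z3"]].to_numpy(dtype=float)
    exposed = np.isfinite(t_e)

    bounds = grid.boundaries
    rows_start, rows_stop, rows_ev, rows_z, rows_el = [], [], [], [], []

    # pre-exposure (or whole follow-up) spell, no exposure indicators
    pre_stop = np.where(exposed, t_e, t_i)
    keep = pre_stop > 0
    rows_start.append(np.zeros(keep.sum()))
    rows_stop.append(pre_stop[keep])
    rows_ev.append(np.where(exposed[keep], 0, ev[keep]))
    rows_z.append(z[keep])
    rows_el.append(np.zeros((keep.sum(), grid.L)))

    # post-exposure person-time, split at grid boundaries
    eidx = np.flatnonzero(exposed & (t_i > t_e))
    if eidx.size:
        from .counting import _split_exposed_rows

        rep, left, right, ev_seg = _split_exposed_rows(
            t_e[eidx], t_i[eidx], ev[eidx], bounds[1:-1]
        )
        lidx = grid.interval_index(left)
        el = np.zeros((rep.size, grid.L))
        el[np.arange(rep.size), lidx - 1] = 1.0
        rows_start.append(left)
        rows_stop.append(right)
        rows_ev.append(ev_seg)
        rows_z.append(z[eidx][rep])
        rows_el.append(el)

    start = np.concatenate(rows_start)
    stop = np.concatenate(rows_stop)
    event = np.concatenate(rows_ev)
    Z = np.vstack(rows_z)
    EL = np.vstack(rows_el)
    return start, stop, event, Z, EL


def _fit_plain_cox(X, start, stop, event, gtol=1e-8, max_iter=50):
    engine = _BreslowEngine(X, start, stop, event)
    beta, ll, grad, H, n_iter, converged, diverged = _newton(engine, X.shape[1], gtol=gtol, max_iter=max_iter)
    return beta, converged and not diverged


def empirical_hr_curves(
    config: ScenarioConfig,
    n_large: int = 200_000,
    grid: IntervalGrid | None = None,
    seed: int | None = None,
) -> dict:
    """Large-sample empirical interval values of HRbar, HRbar_a and HR_i.

    One large cohort is simulated from the scenario (profile counts scaled
    to about ``n_large`` subjects) and three proportional-hazards fits with
    interval exposure indicators E_l(t) return exp of the interval
    coefficients: unadjusted (HRbar), covariate-adjusted (HRbar_a) and
    interaction (HR_i per profile).
    """
    if seed is None:
        raise ValueError("a seed is mandatory for the empirical truth curves")
    if grid is None:
        grid = IntervalGrid([0.0, config.tmax])
    from dataclasses import replace

    from .simulate import simulate_cohort

    n_pp = max(1, n_large // 8)
    big = replace(config, n_per_profile=n_pp)
    for attempt in range(2):
        cohort = simulate_cohort(big, seed=seed + attempt)
        start, stop, event, Z, EL = _cohort_counting_process(cohort, grid)

        out: dict[str, np.ndarray] = {"grid": grid.boundaries}
        ok = True
        g_u, conv = _fit_plain_cox(EL, start, stop, event)
        ok &= conv
        out["log_hr_bar"] = g_u
        g_a, conv = _fit_plain_cox(np.column_stack([EL, Z]), start, stop, event)
        ok &= conv
        out["log_hr_bar_adjusted"] = g_a[: grid.L]
        inter = np.column_stack([Z * EL[:, [l]] for l in range(grid.L)])
        g_i, conv = _fit_plain_cox(np.column_stack([EL, Z, inter]), start, stop, event)
        ok &= conv
        gam = g_i[: grid.L]
        alph = g_i[grid.L + 3 :].reshape(grid.L, 3)
        out["log_hr_profile"] = np.vstack(
            [gam + alph @ np.asarray(p, dtype=float) for p in PROFILES]
        )
        if ok:
            return out
    raise RuntimeError("empirical truth fits failed to converge at the requested n_large")
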