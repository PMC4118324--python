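"""Replication study: simulate, match, fit, and score against the truth.

For every replication ``s`` the cohort is simulated, pairs are formed by
both matching methods, and the requested models are fitted on the
counting-process tables.  Each Method x Model combination is scored
against its own reference:

* stratified (``hp``) and unadjusted marginal (``lwa_u``) fits against the
  population-average log HR(t);
* the covariate-adjusted marginal fit (``lwa_a``) against the empirically
  approximated adjusted average;
* the interaction fit (``lwa_i``) against the per-profile log HR_i(t).

Truth curves are averaged over each estimation interval to give the
per-interval reference.  Cell-level bias over S replications is

    b_lZ(w) = mean_s(gamma_sl + alpha_sl' Z) - (gamma_l + alpha_l' Z)

with the S-1-denominator empirical variance V and
RMSE_lZ(w) = sqrt(b^2 + V); aggregates average cells over intervals
(b_.Z), profiles (b_l.) or both (b_..), and likewise for the RMSE (the
aggregate RMSE is the mean of per-cell RMSEs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import IntervalGrid, build_counting_process
from .cox import ConvergenceError, MarginalPairCox, StratifiedPairCox
from .matching import RiskSetMatcher
from .scenarios import PROFILES, ScenarioConfig
from .simulate import IllnessDeathSimulator
from .truth import TruthCurves, compute_truth, empirical_hr_curves

__all__ = [
    "bias_rmse_cell",
    "aggregate_bias",
    "run_study",
    "StudyResult",
    "MODELS",
    "reference_scenario_metrics",
]

MODELS = ("hp", "lwa_u", "lwa_a", "lwa_i")


def bias_rmse_cell(estimates, truth: float):
    """Bias, empirical variance (S-1 denominator) and RMSE for one cell."""
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    if est.size < 2:
        raise ValueError("need at least 2 converged replications per cell")
    bias = est.mean() - truth
    var = est.var(ddof=1)
    return float(bias), float(var), float(np.sqrt(bias**2 + var))


def aggregate_bias(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell bias/RMSE over intervals and profiles.

    ``cells`` needs columns ``method, model, interval, profile, bias, var,
    rmse`` covering the full L x 8 grid per Method x Model; incomplete
    combinations are flagged with ``partial=True``.
    """
    out = []
    for (method, model), g in cells.groupby(["method", "model"]):
        L = g["interval"].nunique()
        partial = bool(g["bias"].isna().any()) or len(g) != L * 8
        b_dot_z = g.groupby("profile")["bias"].mean()          # b_.Z(w)
        rmse_dot_z = g.groupby("profile")["rmse"].mean()
        b_l_dot = g.groupby("interval")["bias"].mean()         # b_l.
        rmse_l_dot = g.groupby("interval")["rmse"].mean()
        out.append(
            {
                "method": method,
                "model": model,
                "b_dotdot": float(b_dot_z.mean()),
                "rmse_dotdot": float(rmse_dot_z.mean()),
                "b_dot_profile": b_dot_z.to_dict(),
                "rmse_dot_profile": rmse_dot_z.to_dict(),
                "b_interval": b_l_dot.to_dict(),
                "rmse_interval": rmse_l_dot.to_dict(),
                "partial": partial,
            }
        )
    return pd.DataFrame(out)


@dataclass
class StudyResult:
    """Everything the replication study produced."""

    archive: pd.DataFrame          # one row per rep x method x model x interval x profile
    cells: pd.DataFrame            # per-cell bias, variance, RMSE
    aggregates: pd.DataFrame       # per Method x Model summaries
    pair_stats: pd.DataFrame       # per rep x method x profile pair bookkeeping
    truth: TruthCurves
    grid: IntervalGrid
    n_failed_fits: int = 0
    seeds: dict = field(default_factory=dict)

    def aggregate(self, method: int, model: str) -> pd.Series:
        m = self.aggregates
        row = m[(m["method"] == method) & (m["model"] == model)]
        if row.empty:
            raise KeyError(f"no aggregate for method={method}, model={model}")
        return row.iloc[0]


def reference_scenario_metrics(result: StudyResult) -> dict:
    """Headline summaries of a study on the reference scenario.

    Pair-formation statistics for the best-prognosis profile (0,0,0) and
    the worst (1,1,1), plus the overall bias/RMSE aggregates per
    Method x Model that were fitted.
    """
    ps = result.pair_stats
    m1 = ps[(ps.method == 1) & (ps.profile == 0)]
    m2 = ps[(ps.method == 2) & (ps.profile == 0)]
    m2w = ps[(ps.method == 2) & (ps.profile == 7)]
    out = {
        "exposure_fraction_profile_000": float((m1.n_exposed / m1.n_subjects).mean()),
        "mean_pairs_method1_profile_000": float(m1.n_pairs.mean()),
        "mean_pairs_method2_profile_000": float(m2.n_pairs.mean()),
        "imperfect_fraction_profile_000": float(m2.n_imperfect.sum() / m2.n_pairs.sum()),
        "imperfect_fraction_profile_111": float(m2w.n_imperfect.sum() / m2w.n_pairs.sum()),
        "reps": int(ps.rep.nunique()),
    }
    for _, row in result.aggregates.iterrows():
        key = f"method{row.method}_{row.model}"
        out[f"bias_{key}"] = float(row.b_dotdot)
        out[f"rmse_{key}"] = float(row.rmse_dotdot)
    return out


def _default_grid(config: ScenarioConfig, L: int | None = None) -> IntervalGrid:
    """Default estimation grid: one interval for the constant-effect
    configuration, else L = 4 equal-width intervals of [0, tmax]."""
    if L is None:
        L = 1 if config.label == "constant" else 4
    return IntervalGrid(np.linspace(0.0, config.tmax, L + 1))


def _fit_one(model: str, paired, grid: IntervalGrid):
    """Fit one model on one paired dataset; returns (est_matrix, converged).

    ``est_matrix`` is (8, L): the estimated exposure log effect per profile
    and interval (rows identical when the model has no interaction).
    """
    if model == "hp":
        table = build_counting_process(paired, model_family="hp", grid=grid)
        fit = StratifiedPairCox(robust=False).fit(table)
        per_interval = fit.gamma_
        est = np.tile(per_interval, (8, 1))
    else:
        variant = {"lwa_u": "unadjusted", "lwa_a": "adjusted", "lwa_i": "interaction"}[model]
        table = build_counting_process(paired, model_family="lwa", grid=grid)
        fit = MarginalPairCox(variant=variant, robust=False).fit(table)
        if model == "lwa_i":
            est = np.vstack([fit.log_hr(p) for p in PROFILES])
        else:
            est = np.tile(fit.gamma_, (8, 1))
    return est, bool(fit.converged_)


def run_study(
    config: ScenarioConfig,
    methods=(1, 2),
    models=MODELS,
    reps: int = 200,
    seed: int = 0,
    grid: IntervalGrid | None = None,
    truth_K: int = 2000,
    n_large_adjusted: int = 200_000,
    max_failure_fraction: float = 0.2,
) -> StudyResult:
    """Run the full simulate -> match -> fit -> score pipeline.

    Deterministic given ``seed``: replication seeds are spawned from one
    root sequence, so any execution order yields the same archive.
    """
    models = tuple(models)
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    root = np.random.SeedSequence(seed)
    emp_ss, *rep_ss = root.spawn(reps + 1)

    if grid is None:
        grid = _default_grid(config)
    L = grid.L

    truth = compute_truth(config, K=truth_K)
    truth_bar = truth.interval_log_hr_bar(grid)              # (L,)
    truth_prof = truth.interval_log_hr_profile(grid)         # (8, L)
    truth_adj = None
    if "lwa_a" in models:
        emp_seed = int(emp_ss.generate_state(1)[0] % (2**31 - 1))
        emp = empirical_hr_curves(config, n_large=n_large_adjusted, grid=grid, seed=emp_seed)
        truth_adj = emp["log_hr_bar_adjusted"]               # (L,)

    sim = IllnessDeathSimulator(config)
    archive_rows = []
    pair_rows = []
    n_failed = 0
    n_fits = 0
    prof_idx = {p: w for w, p in enumerate(PROFILES)}

    for s, ss in enumerate(rep_ss):
        rng = np.random.default_rng(ss)
        cohort = sim.sample(rng)
        cprof = (cohort["z1"] * 4 + cohort["z2"] * 2 + cohort["z3"]).to_numpy()
        exposed = cohort["exposed"].to_numpy() == 1
        for method in methods:
            paired = RiskSetMatcher(method=method).match(cohort, seed=rng)
            pprof = (paired.pairs["z1"] * 4 + paired.pairs["z2"] * 2 + paired.pairs["z3"]).to_numpy()
            imperfect = ~paired.pairs["perfect"].to_numpy(dtype=bool)
            for p, w in prof_idx.items():
                sel = pprof == w
                pair_rows.append(
                    {
                        "rep": s,
                        "method": method,
                        "profile": w,
                        "n_subjects": int((cprof == w).sum()),
                        "n_exposed": int((exposed & (cprof == w)).sum()),
                        "n_pairs": int(sel.sum()),
                        "n_imperfect": int((sel & imperfect).sum()),
                    }
                )
            for model in models:
                n_fits += 1
                try:
                    est, converged = _fit_one(model, paired, grid)
                except (ConvergenceError, ValueError):
                    est, converged = np.full((8, L), np.nan), False
                if not converged:
                    n_failed += 1
                for w in range(8):
                    for l in range(L):
                        archive_rows.append(
                            {
                                "rep": s,
                                "method": method,
                                "model": model,
                                "interval": l + 1,
                                "profile": w,
                                "estimate": est[w, l],
                                "converged": converged,
                            }
                        )
        if n_fits and n_failed / n_fits > max_failure_fraction and s >= 10:
            raise RuntimeError(
                f"aborting: {n_failed}/{n_fits} model fits failed "
                f"(limit {max_failure_fraction:.0%})"
            )

    archive = pd.DataFrame(archive_rows)
    pair_stats = pd.DataFrame(pair_rows)

    def truth_for(model: str, w: int, l: int) -> float:
        if model in ("hp", "lwa_u"):
            return float(truth_bar[l])
        if model == "lwa_a":
            return float(truth_adj[l]) if truth_adj is not None else np.nan
        return float(truth_prof[w, l])

    cell_rows = []
    for (method, model), g in archive.groupby(["method", "model"]):
        ok = g[g["converged"]]
        for w in range(8):
            for l in range(L):
                vals = ok[(ok["profile"] == w) & (ok["interval"] == l + 1)]["estimate"]
                ref = truth_for(model, w, l)
                try:
                    bias, var, rmse = bias_rmse_cell(vals, ref)
                except ValueError:
                    bias = var = rmse = np.nan
                cell_rows.append(
                    {
                        "method": method,
                        "model": model,
                        "interval": l + 1,
                        "profile": w,
                        "truth": ref,
                        "bias": bias,
                        "var": var,
                        "rmse": rmse,
                        "n_used": len(vals),
                    }
                )
    cells = pd.DataFrame(cell_rows)
    aggregates = aggregate_bias(cells)
    return StudyResult(
        archive=archive,
        cells=cells,
        aggregates=aggregates,
        pair_stats=pair_stats,
        truth=truth,
        grid=grid,
        n_failed_fits=n_failed,
        seeds={"root": seed},
    )
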