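"""Delimited-text readers and writers for cohorts, pairs and fit results.

Cohort and pair tables are plain CSV with ``#``-prefixed metadata header
lines (scenario label, seed, method ...).  A never-exposed subject's
``t_exposure`` is stored as an empty field and read back as +inf.  Fit
results serialize to JSON with covariance matrices as nested lists.
"""

from __future__ import annotations

import io as _io
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .matching import PairedDataset

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_pairs",
    "read_pairs",
    "write_counting_process",
    "read_counting_process",
    "fit_result_to_dict",
    "write_fit_result",
]


def _write_with_meta(df: pd.DataFrame, path, meta: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in meta.items():
            if v is not None:
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_with_meta(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    lines = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)))
    return df, meta


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["t_exposure"] = out["t_exposure"].replace(math.inf, np.nan)
    meta = {"scenario": cohort.attrs.get("scenario"), "seed": cohort.attrs.get("seed")}
    _write_with_meta(out, path, meta)


def read_cohort(path) -> pd.DataFrame:
    df, meta = _read_with_meta(path)
    df["t_exposure"] = df["t_exposure"].fillna(math.inf)
    for col in ("id", "z1", "z2", "z3", "exposed", "event"):
        df[col] = df[col].astype(int)
    df.attrs["scenario"] = meta.get("scenario", "")
    if meta.get("seed") not in (None, "", "None"):
        df.attrs["seed"] = int(meta["seed"])
    return df


def write_pairs(paired: PairedDataset, path) -> None:
    meta = {
        "method": paired.method,
        "seed": paired.seed,
        "n_unmatched": len(paired.unmatched_exposed),
        "unmatched": ",".join(map(str, paired.unmatched_exposed)) or None,
    }
    _write_with_meta(paired.pairs, path, meta)


def read_pairs(path, cohort: pd.DataFrame) -> PairedDataset:
    df, meta = _read_with_meta(path)
    df["perfect"] = df["perfect"].astype(bool)
    unmatched = [int(x) for x in meta.get("unmatched", "").split(",") if x]
    seed = meta.get("seed")
    return PairedDataset(
        pairs=df,
        method=int(meta.get("method", 0)),
        cohort=cohort,
        unmatched_exposed=unmatched,
        seed=None if seed in (None, "", "None") else int(seed),
    )


def write_counting_process(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_counting_process(path) -> pd.DataFrame:
    return pd.read_csv(path)


def fit_result_to_dict(fit) -> dict:
    """JSON-ready summary of a fitted pair Cox model."""

    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    return {
        "model": type(fit).__name__,
        "variant": getattr(fit, "variant", None),
        "names": list(fit.names_),
        "coef": arr(fit.coef_),
        "gamma": arr(getattr(fit, "gamma_", None)),
        "beta": arr(getattr(fit, "beta_", None)),
        "alpha": arr(getattr(fit, "alpha_", None)),
        "vcov_naive": arr(fit.vcov_naive_),
        "vcov_robust": arr(fit.vcov_robust_),
        "loglik": fit.loglik_,
        "n_iter": fit.n_iter_,
        "converged": bool(fit.converged_),
        "diverged": bool(fit.diverged_),
        "n_events": int(fit.n_events_),
        "n_pairs": int(getattr(fit, "n_pairs_", 0)),
    }


def write_fit_result(fit, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2))
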