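"""Windowed univariate screening and mixed-effects feature analysis.

Two complementary views of per-feature association with POD:

* Spearman rank correlations between per-window feature summaries (mean
  value or missingness rate) and the binary outcome, with t-statistic
  p-values and Benjamini-Hochberg FDR applied separately per window;
* linear mixed-effects models (MLEM) per feature,
  ``value ~ target + time + target:time`` with nested random intercepts for
  patient and surgery-within-patient, fitted on min-max normalized
  responses over three consecutive begin-anchored 30-minute windows
  (time = 1, 2, 3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .preprocess import ObservationWindow, resample_to_grid

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "MlemResult",
    "fdr_correct",
    "fit_mlem",
    "mlem_windows",
    "spearman_pod",
    "window_summaries",
]


def mlem_windows() -> list[ObservationWindow]:
    """Three consecutive begin-anchored 30-minute windows (time = 1, 2, 3)."""
    return [
        ObservationWindow("from_begin", 30.0 * i, "from_begin", 30.0 * (i + 1))
        for i in range(3)
    ]


def window_summaries(
    events: pd.DataFrame,
    windows: list[ObservationWindow],
    interval_min: float,
    channels: list[str],
    surgery_ids: list,
    t_end: dict,
) -> pd.DataFrame:
    """Per surgery x feature x window mean and missingness rate.

    The mean is over observed grid bins; the missingness rate is the
    fraction of grid bins with no observation (rate 1 <=> mean missing).
    Surgeries whose intraoperative phase does not cover a window are
    skipped for that window.
    """
    rows = []
    for w_idx, window in enumerate(windows, start=1):
        covered = []
        for s in surgery_ids:
            try:
                from .preprocess import resolve_window

                start, end = resolve_window(window, t_end[s])
            except ValueError:
                continue
            if start >= 0 and end <= t_end[s] + 1e-9:
                covered.append(s)
        if not covered:
            logger.info("window %s covered by no surgery; skipped", window)
            continue
        tensor = resample_to_grid(events, window, interval_min, channels,
                                  covered, t_end)
        for j, name in enumerate(channels):
            vals = tensor.values[:, j, :]
            mask = tensor.mask[:, j, :]
            rate = mask.mean(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(vals, axis=1)
            for i, s in enumerate(covered):
                rows.append(
                    {
                        "surgery_id": s,
                        "feature": name,
                        "window": str(window),
                        "time": w_idx,
                        "mean": mean[i] if rate[i] < 1 else np.nan,
                        "miss_rate": float(rate[i]),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    feature: str
    window: str
    r_s: float  # absolute value; sign stored separately
    sign: int
    p: float
    q: float | None
    n_effective: int
    undefined: bool = False


def spearman_pod(values, labels, feature: str = "", window: str = "") -> CorrelationResult:
    """Average-rank Spearman correlation of a feature summary with the POD
    label; two-sided p from t = r*sqrt((n-2)/(1-r^2))."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    ok = ~np.isnan(values) & ~np.isnan(labels)
    v, y = values[ok], labels[ok]
    n = len(v)
    if n < 3 or np.unique(v).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(feature, window, np.nan, 0, np.nan, None, n,
                                 undefined=True)
    r, p = sps.spearmanr(v, y)
    return CorrelationResult(feature, window, abs(float(r)),
                             int(np.sign(r)), float(p), None, n)


def fdr_correct(
    results: list[CorrelationResult], alpha: float = 0.05
) -> list[CorrelationResult]:
    """Benjamini-Hochberg within each window group; undefined results are
    excluded from the correction and keep q=None."""
    by_window: dict[str, list[CorrelationResult]] = {}
    for res in results:
        if not res.undefined:
            by_window.setdefault(res.window, []).append(res)
    for group in by_window.values():
        pvals = np.array([r.p for r in group])
        _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for res, q in zip(group, qvals):
            res.q = float(q)
    return results


def fdr_rejections(pvals, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection mask for a flat p-value vector."""
    reject, _, _, _ = multipletests(np.asarray(pvals, dtype=float),
                                    alpha=alpha, method="fdr_bh")
    return reject


@dataclass
class MlemResult:
    feature: str
    dependent: str  # "value" or "missingness"
    c_target: float
    c_time: float
    c_interaction: float
    p_target: float
    p_time: float
    p_interaction: float
    converged: bool
    n_obs: int


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def fit_mlem(
    summaries: pd.DataFrame,
    labels: pd.DataFrame,
    feature: str,
    dependent: str = "value",
    normalize: bool = True,
    random_effects: bool = True,
) -> MlemResult:
    """Fit ``feature ~ target + time + target:time`` with random intercepts
    for patient and surgery-within-patient.

    ``summaries`` is the output of :func:`window_summaries`; ``labels`` maps
    surgery_id to patient_id and y.  Surgeries missing the dependent value
    in a window are dropped listwise from that window.  Non-convergence is
    flagged; callers should exclude flagged results.
    """
    col = "mean" if dependent == "value" else "miss_rate"
    df = summaries[summaries["feature"] == feature][
        ["surgery_id", "time", col]
    ].rename(columns={col: "dep"})
    df = df.merge(
        labels[["surgery_id", "patient_id", "y"]], on="surgery_id", how="inner"
    )
    df = df.dropna(subset=["dep"])
    if df.empty or df["y"].nunique() < 2 or df["time"].nunique() < 2:
        return MlemResult(feature, dependent, *[np.nan] * 6, False, len(df))
    dep = df["dep"].to_numpy(dtype=float)
    if normalize:
        dep = _minmax(dep)
    data = df.assign(dep=dep, target=df["y"].astype(float),
                     time=df["time"].astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if random_effects:
                # nested random intercepts: patient-level random intercept
                # plus a surgery-within-patient variance component
                model = MixedLM.from_formula(
                    "dep ~ target + time + target:time",
                    data=data,
                    groups="patient_id",
                    re_formula="1",
                    vc_formula={"surgery": "0 + C(surgery_id)"},
                )
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
                converged = bool(fit.converged)
            else:
                import statsmodels.formula.api as smf

                fit = smf.ols("dep ~ target + time + target:time", data=data).fit()
                converged = True
        params = fit.params
        pvals = fit.pvalues
        return MlemResult(
            feature,
            dependent,
            float(params["target"]),
            float(params["time"]),
            float(params["target:time"]),
            float(pvals["target"]),
            float(pvals["time"]),
            float(pvals["target:time"]),
            converged,
            len(df),
        )
    except Exception as e:  # noqa: BLE001 - any numerical failure flags the fit
        logger.warning("MLEM for %s (%s) failed: %s", feature, dependent, e)
        return MlemResult(feature, dependent, *[np.nan] * 6, False, len(df))
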