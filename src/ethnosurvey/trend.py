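"""Provenance trend: does garden origin become likelier as importance rises?

Each origin-known use report is paired with its species' overall importance
score (UV, CI or UD) and a binary outcome (1 = home-garden origin, 0 = wild
collected). The trend is summarised two ways: equal-count bins of the metric
with the observed garden fraction per bin, and a report-level logistic
regression

    logit P(garden) = b0 + b1 * metric

fitted by iteratively reweighted least squares (Fisher scoring with
step-halving, so the binomial log-likelihood is non-decreasing across
iterations). Standard errors come from the final Fisher information matrix.
The expected survey pattern is an increasing trend for UV and a flat one
for CI and UD.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import compute_metrics_table
from .model import SurveyDataset

__all__ = ["TrendFit", "report_level_frame", "fit_logistic_irls", "trend_report"]


@dataclass
class TrendFit:
    metric: str
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    converged: bool
    n_reports: int
    bins: list[dict] = field(default_factory=list)
    verdict: str = ""
    loglik_history: list[float] = field(default_factory=list)

    @property
    def slope_z(self) -> float:
        return self.slope / self.slope_se if self.slope_se > 0 else np.inf

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "intercept": self.intercept,
            "slope": self.slope,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "converged": self.converged,
            "n_reports": self.n_reports,
            "verdict": self.verdict,
            "bins": self.bins,
        }


def report_level_frame(
    dataset: SurveyDataset, metric: str = "uv", region: str | None = None
) -> pd.DataFrame:
    """One (metric value, garden outcome) pair per origin-known report.

    The metric is the species' overall-scope value by default; reports with
    unknown origin are excluded. Species of mixed provenance contribute
    their garden reports as 1 and their wild reports as 0.
    """
    if metric not in {"uv", "ci", "ud"}:
        raise ValueError(f"unknown metric {metric!r}")
    rep = dataset.origin_reports(region)
    if rep.empty:
        raise ValueError("no origin-known reports in scope")
    table = compute_metrics_table(dataset, region).set_index("species_id")
    out = pd.DataFrame(
        {
            "species_id": rep["species_id"].to_numpy(),
            "metric_value": table.loc[rep["species_id"], metric].to_numpy(),
            "garden": (rep["origin"] == "garden").astype(int).to_numpy(),
        }
    )
    return out


def _loglik(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    eta = np.clip(x @ beta, -30, 30)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def fit_logistic_irls(
    metric_values,
    outcomes,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> TrendFit:
    """Maximum-likelihood logistic fit of a binary outcome on one covariate.

    Fisher scoring (equivalently iteratively reweighted least squares) with
    step-halving whenever a step would decrease the log-likelihood. Under
    complete or quasi-complete separation the likelihood has no finite
    maximum; the fit then stops at ``max_iter`` with ``converged=False`` and
    a warning, as coefficient magnitudes diverge.
    """
    v = np.asarray(metric_values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("metric values and outcomes must be equal-length 1-d arrays")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if len(np.unique(v)) < 2:
        raise ValueError("metric is constant; slope unidentified")

    x = np.column_stack([np.ones_like(v), v])
    beta = np.zeros(2)
    ll = _loglik(beta, x, y)
    history = [ll]
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.clip(w, 1e-12, None)
        info = x.T @ (w[:, None] * x)
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the log-likelihood non-decreasing
        factor = 1.0
        for _half in range(30):
            new_beta = beta + factor * step
            new_ll = _loglik(new_beta, x, y)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        beta = new_beta
        history.append(new_ll)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if converged:
        mu_fit = 1.0 / (1.0 + np.exp(-np.clip(x @ beta, -30, 30)))
        if np.all(np.abs(y - mu_fit) < 1e-3):
            # perfect classification: separation, no finite likelihood maximiser
            converged = False
    if not converged:
        _warnings.warn(
            "IRLS did not converge (complete or quasi-separation likely); "
            "coefficient magnitudes diverge and estimates are the last iterate",
            stacklevel=2,
        )
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = x.T @ (w[:, None] * x)
    try:
        cov = np.linalg.inv(info)
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.array([np.inf, np.inf])
    return TrendFit(
        metric="",
        intercept=float(beta[0]),
        slope=float(beta[1]),
        intercept_se=float(ses[0]),
        slope_se=float(ses[1]),
        converged=converged,
        n_reports=len(y),
        loglik_history=history,
    )


def _equal_count_bins(v: np.ndarray, y: np.ndarray, n_bins: int) -> list[dict]:
    edges = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)))
    if len(edges) - 1 < n_bins:
        _warnings.warn(
            f"collapsed to {len(edges) - 1} bin(s); fewer distinct metric values "
            f"than requested bins ({n_bins})",
            stacklevel=3,
        )
    if len(edges) < 2:
        return [
            {
                "lo": float(v.min()),
                "hi": float(v.max()),
                "n": int(len(v)),
                "garden_fraction": float(y.mean()),
                "metric_mean": float(v.mean()),
            }
        ]
    idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)
    bins = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        bins.append(
            {
                "lo": float(edges[b]),
                "hi": float(edges[b + 1]),
                "n": int(mask.sum()),
                "garden_fraction": float(y[mask].mean()),
                "metric_mean": float(v[mask].mean()),
            }
        )
    return bins


def trend_report(
    dataset: SurveyDataset,
    metrics: tuple[str, ...] = ("uv", "ci", "ud"),
    n_bins: int = 10,
    alpha: float = 0.05,
) -> tuple[list[TrendFit], dict[str, str]]:
    """Logistic provenance trend per importance metric, with binned fractions.

    The verdict per metric is "increasing" (positive slope, Wald test
    significant at ``alpha``), "decreasing", or "flat". Metrics that cannot
    be fitted (zero variance, single outcome class) are skipped and the
    error recorded in the second return value.
    """
    from scipy.stats import norm

    fits: list[TrendFit] = []
    errors: dict[str, str] = {}
    for metric in metrics:
        try:
            frame = report_level_frame(dataset, metric)
            v = frame["metric_value"].to_numpy()
            y = frame["garden"].to_numpy()
            fit = fit_logistic_irls(v, y)
        except ValueError as exc:
            errors[metric] = str(exc)
            continue
        fit.metric = metric
        fit.bins = _equal_count_bins(v, y.astype(float), n_bins)
        if fit.slope_se > 0 and np.isfinite(fit.slope_se):
            p_wald = 2 * norm.sf(abs(fit.slope) / fit.slope_se)
        else:
            p_wald = 1.0
        if p_wald < alpha:
            fit.verdict = "increasing" if fit.slope > 0 else "decreasing"
        else:
            fit.verdict = "flat"
        fits.append(fit)
    return fits, errors
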