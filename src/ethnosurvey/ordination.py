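"""Informant ordination: dissimilarities, non-metric MDS, environmental fits.

Informants are embedded in a low-dimensional space from their Bray-Curtis
dissimilarities in plant-space (which species they report) or use-space
(which species-use pairs they report), by non-metric multidimensional
scaling minimising Kruskal's stress-1,

    stress = sqrt( sum_ij (dhat_ij - delta_ij)^2 / sum_ij delta_ij^2 ),

where delta are configuration distances and dhat is the isotonic
(pool-adjacent-violators) regression of delta onto the rank order of the
input dissimilarities. Informant covariates are then fitted post hoc onto
the ordination scores: continuous covariates as vectors (squared multiple
correlation of an OLS fit), categorical covariates as factors (between- vs
total sum of squares of score rows about level centroids), with
significance from whole-vector permutations of the covariate and the
add-one convention p = (1 + #{permuted >= observed}) / (1 + n_perm), whose
floor at 999 permutations is 0.001.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .model import IncidenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "EnvFitResult",
    "bray_curtis",
    "nmds_embed",
    "envfit_vector",
    "envfit_factor",
    "envfit_table",
]


@dataclass
class DissimilarityMatrix:
    ids: list
    values: np.ndarray  # symmetric, zero diagonal
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("dissimilarity matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix has a nonzero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    """NMDS configuration, centered and rotated to principal axes."""

    ids: list
    scores: np.ndarray  # n x k
    k: int
    stress: float
    n_restarts: int
    converged: bool
    seed: int | None
    stress_history: list[float] = field(default_factory=list)


@dataclass
class EnvFitResult:
    variable: str
    kind: str  # "vector" | "factor"
    r2: float
    p: float
    n_perm: int
    n_used: int
    direction: np.ndarray | None = None  # unit vector, vectors only
    centroids: dict | None = None  # per-level k-vectors, factors only
    degenerate: bool = False

    @property
    def significance_code(self) -> int:
        """Size encoding for plots: 3 for p<=0.001, 2 for <=0.01, 1 for <=0.05, 0 else."""
        for code, cut in ((3, 0.001), (2, 0.01), (1, 0.05)):
            if self.p <= cut:
                return code
        return 0


def bray_curtis(matrix: IncidenceMatrix) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between informant rows.

    d_ij = sum|x_i - x_j| / sum(x_i + x_j); on binary data this equals the
    Sorensen dissimilarity. All-zero rows make pairs undefined and must be
    excluded beforehand (see :meth:`IncidenceMatrix.drop_zero_rows`).
    """
    zero = matrix.zero_rows
    if len(zero) >= 2:
        raise ValueError(
            f"{len(zero)} all-zero informant rows ({zero[:5]}...); Bray-Curtis is "
            "undefined between empty inventories - exclude them with drop_zero_rows()"
        )
    d = squareform(pdist(matrix.values, metric="braycurtis"))
    return DissimilarityMatrix(ids=list(matrix.informant_ids), values=d, metric="braycurtis")


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical (metric) scaling used as the first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(dhat: np.ndarray, delta: np.ndarray) -> float:
    denom = float(np.sum(delta**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - delta) ** 2) / denom))


def _monotone_fit(delta: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Isotonic regression of configuration distances onto the rank order of d.

    Primary tie treatment: within blocks of tied dissimilarities the
    configuration distances are sorted ascending, so ties in d may be broken
    by delta without a stress penalty.
    """
    order = np.lexsort((delta, d))
    fit = isotonic_regression(delta[order], increasing=True).x
    dhat = np.empty_like(delta)
    dhat[order] = fit
    return dhat


def _smacof_run(
    d: np.ndarray, x: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    """One NMDS optimisation run: alternating isotonic fit and Guttman update."""
    n = x.shape[0]
    converged = False
    history: list[float] = []
    delta = pdist(x)
    dhat = _monotone_fit(delta, d)
    stress = _stress1(dhat, delta)
    history.append(stress)
    for _ in range(max_iter):
        # Guttman transform (majorisation step for the raw stress)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, dhat / delta, 0.0)
        b = squareform(-ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        delta = pdist(x)
        dhat = _monotone_fit(delta, d)
        new_stress = _stress1(dhat, delta)
        history.append(new_stress)
        if abs(stress - new_stress) < tol:
            stress = new_stress
            converged = True
            break
        stress = new_stress
    return x, stress, history, converged


def nmds_embed(
    d: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix, best of ``n_restarts`` runs.

    The first start is the classical (Torgerson) scaling of ``d``; the
    remaining starts are random Gaussian configurations. The returned
    configuration is centered and rotated to its principal axes; ``stress``
    is Kruskal's stress-1 of the best run and ``stress_history`` its
    per-iteration trace (non-increasing).
    """
    n = d.n
    if n < max(3, k + 1):
        raise ValueError(f"need at least {max(3, k + 1)} points for a {k}-dimensional NMDS")
    rng = np.random.default_rng(seed)
    dm = d.values
    dcond = d.condensed()

    best: tuple[np.ndarray, float, list[float], bool] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            x0 = _classical_scaling(dm, k)
        else:
            x0 = rng.standard_normal((n, k)) * np.std(dcond)
        x, stress, history, converged = _smacof_run(dcond, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, history, converged)
    assert best is not None
    x, stress, history, converged = best
    if not converged:
        _warnings.warn(
            f"NMDS did not converge in any of {n_restarts} restart(s) "
            f"(max_iter={max_iter}, tol={tol})",
            stacklevel=2,
        )

    # center and rotate to principal axes
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    return OrdinationResult(
        ids=list(d.ids),
        scores=x,
        k=k,
        stress=stress,
        n_restarts=n_restarts,
        converged=converged,
        seed=seed,
        stress_history=history,
    )


def _aligned(ord_result: OrdinationResult, values: pd.Series | dict | np.ndarray):
    """Align a per-informant covariate with the ordination rows."""
    if isinstance(values, (pd.Series, dict)):
        s = pd.Series(values)
        return np.asarray([s.get(i, np.nan) for i in ord_result.ids])
    arr = np.asarray(values)
    if len(arr) != len(ord_result.ids):
        raise ValueError("covariate length does not match ordination")
    return arr


def _perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    return (1 + int(np.sum(permuted >= observed - 1e-12))) / (1 + len(permuted))


def envfit_vector(
    ord_result: OrdinationResult,
    values,
    n_perm: int = 999,
    seed: int | None = None,
    name: str = "vector",
) -> EnvFitResult:
    """Fit a continuous covariate onto ordination scores.

    r^2 is the squared multiple correlation of an OLS regression of the
    centered covariate on the scores; the direction is the normalised
    coefficient vector. Significance comes from ``n_perm`` whole-vector
    shuffles of the covariate.
    """
    y = np.asarray(_aligned(ord_result, values), dtype=float)
    keep = np.isfinite(y)
    if not keep.all():
        _warnings.warn(
            f"{int((~keep).sum())} informant(s) dropped from '{name}' fit "
            "(missing covariate)",
            stacklevel=2,
        )
    y = y[keep]
    x = ord_result.scores[keep]
    if len(y) < ord_result.k + 2:
        raise ValueError(f"too few informants with '{name}' values to fit")
    if np.ptp(y) == 0:
        raise ValueError(f"covariate '{name}' is constant; r^2 undefined")

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    q, _ = np.linalg.qr(xc)
    sstot = float(yc @ yc)
    proj = q.T @ yc
    r2 = float(proj @ proj) / sstot
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    norm = np.linalg.norm(beta)
    direction = beta / norm if norm > 0 else beta

    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(yc)
        perms[i] = float((q.T @ yp) @ (q.T @ yp)) / sstot
    p = _perm_pvalue(r2, perms)
    return EnvFitResult(
        variable=name,
        kind="vector",
        r2=r2,
        p=p,
        n_perm=n_perm,
        n_used=len(y),
        direction=direction,
    )


def _factor_r2(x: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    grand = x.mean(axis=0)
    sstot = float(((x - grand) ** 2).sum())
    ssw = 0.0
    for lv in range(n_levels):
        rows = x[codes == lv]
        if len(rows):
            ssw += float(((rows - rows.mean(axis=0)) ** 2).sum())
    if sstot == 0:
        return 0.0
    return 1.0 - ssw / sstot


def envfit_factor(
    ord_result: OrdinationResult,
    levels,
    n_perm: int = 999,
    seed: int | None = None,
    name: str = "factor",
) -> EnvFitResult:
    """Fit a categorical covariate onto ordination scores.

    r^2 = 1 - SS_within / SS_total over score rows about level centroids;
    the permutation null shuffles level labels across informants.
    """
    raw = _aligned(ord_result, levels)
    lab = pd.Series(raw).astype(object)
    keep = lab.notna().to_numpy() & (lab.astype(str) != "").to_numpy()
    if not keep.all():
        _warnings.warn(
            f"{int((~keep).sum())} informant(s) dropped from '{name}' fit (missing level)",
            stacklevel=2,
        )
    lab = lab[keep]
    x = ord_result.scores[keep]
    cat = pd.Categorical(lab)
    present = [lv for i, lv in enumerate(cat.categories) if (cat.codes == i).sum() > 0]
    if len(present) < len(cat.categories):
        _warnings.warn(f"empty level(s) dropped from '{name}' fit", stacklevel=2)
        cat = pd.Categorical(lab, categories=present)
    if len(present) < 2:
        raise ValueError(f"factor '{name}' has fewer than 2 levels among ordinated informants")
    codes = np.asarray(cat.codes)
    counts = np.bincount(codes, minlength=len(present))
    degenerate = bool((counts == 1).all())

    r2 = _factor_r2(x, codes, len(present))
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for i in range(n_perm):
        perms[i] = _factor_r2(x, rng.permutation(codes), len(present))
    p = _perm_pvalue(r2, perms)
    centroids = {
        lv: x[codes == i].mean(axis=0) for i, lv in enumerate(present)
    }
    if degenerate:
        _warnings.warn(
            f"factor '{name}': every level has a single informant; r^2 is degenerate",
            stacklevel=2,
        )
    return EnvFitResult(
        variable=name,
        kind="factor",
        r2=r2,
        p=p,
        n_perm=n_perm,
        n_used=len(x),
        centroids=centroids,
        degenerate=degenerate,
    )


def envfit_table(
    ord_result: OrdinationResult,
    informants: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    age_coverage: float = 0.8,
) -> tuple[list[EnvFitResult], dict[str, str]]:
    """Fit the standard survey covariates onto an ordination.

    Elevation (and age, where coverage among ordinated informants reaches
    ``age_coverage``) are fitted as vectors; gender, community and — when
    more than one region is present — region are fitted as factors. Failed
    variables are reported in the second return value rather than raised.
    """
    info = informants.set_index("informant_id").loc[list(ord_result.ids)]
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    results: list[EnvFitResult] = []
    failures: dict[str, str] = {}

    jobs: list[tuple[str, str]] = [("elevation_m", "vector")]
    age = pd.to_numeric(info["age"], errors="coerce")
    if age.notna().mean() >= age_coverage:
        jobs.append(("age", "vector"))
    else:
        failures["age"] = (
            f"skipped: coverage {age.notna().mean():.2f} below threshold {age_coverage}"
        )
    jobs.append(("gender", "factor"))
    if info["region"].nunique() > 1:
        jobs.append(("region", "factor"))
    jobs.append(("community", "factor"))

    for (var, kind), child in zip(jobs, ss.spawn(len(jobs))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            if kind == "vector":
                vals = pd.to_numeric(info[var], errors="coerce")
                results.append(
                    envfit_vector(ord_result, vals, n_perm=n_perm, seed=sub_seed, name=var)
                )
            else:
                results.append(
                    envfit_factor(ord_result, info[var], n_perm=n_perm, seed=sub_seed, name=var)
                )
        except ValueError as exc:  # failed variables are reported, not fatal
            failures[var] = str(exc)
            logger.warning("envfit for %s failed: %s", var, exc)
    return results, failures


def envfit_frame(results: list[EnvFitResult]) -> pd.DataFrame:
    """Tabular view of envfit results (for export)."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "kind": r.kind,
                "r2": r.r2,
                "p": r.p,
                "n_perm": r.n_perm,
                "n_used": r.n_used,
                "significance_code": r.significance_code,
            }
            for r in results
        ]
    )
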