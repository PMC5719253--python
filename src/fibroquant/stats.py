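"""Cohort-level statistics: normality-gated tests, correlations, factor analysis.

Integrates the per-subject imaging and mechanics variables (SHG F/B ratios,
LOX/LOXL1/LOXL2 percent areas and densities, derived ratios) the way the
tissue cohorts are analysed:

* two-group comparisons gated on the D'Agostino-Pearson omnibus normality
  test (Student's t when both groups pass, Mann-Whitney U otherwise),
* Pearson correlations pooled across groups, reported as (r, R^2, p) with
  optional Benjamini-Hochberg adjustment across a family,
* principal-axis factoring (PAF) of the correlation matrix with promax
  (oblique) rotation, factor count from the Kaiser eigenvalue >= 1 rule,
* per-subject "relationship-group" scores: loading-weighted averages of
  z-scored variables, one score per factor, compared between groups.

The weighting convention for group scores -- absolute rotated pattern
loadings normalised to sum to one within each factor, applied to z-scored
variables -- is a stipulation; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoGroupResult",
    "FactorModel",
    "GroupScores",
    "two_group_test",
    "correlate",
    "bh_adjust",
    "paf",
    "varimax",
    "promax",
    "congruence",
    "scree_select",
    "fit_factor_model",
    "group_scores",
]

NORMALITY_MIN_N = 8      # the omnibus test is undefined below this
NORMALITY_ALPHA = 0.05
PAF_TOL = 1e-6
PAF_MAX_ITER = 1000
PAF_RIDGE_TOL = 1e-3     # accept a slowly drifting (under-identified) solution


# ---------------------------------------------------------------------------
# Two-group testing and correlation

@dataclass(frozen=True)
class TwoGroupResult:
    branch: str           # "t" or "mannwhitney"
    statistic: float
    p: float
    normality_p: tuple[float | None, float | None]

    def __str__(self) -> str:  # report form
        test = "Student's t-test" if self.branch == "t" else "Mann-Whitney U-test"
        return f"{test}: statistic={self.statistic:.4g}, two-tailed p={self.p:.4g}"


def _normal(x: np.ndarray) -> tuple[bool, float | None]:
    if len(x) < NORMALITY_MIN_N:
        return False, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.normaltest(x).pvalue)
    return p > NORMALITY_ALPHA, p


def two_group_test(x: np.ndarray, y: np.ndarray) -> TwoGroupResult:
    """Normality-gated two-group comparison.

    Both groups normal by the D'Agostino-Pearson omnibus test (and n >= 8
    each, the test's validity floor) -> unpaired two-tailed t-test; otherwise
    Mann-Whitney U.  Identical constant groups return p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    ok_x, p_x = _normal(x)
    ok_y, p_y = _normal(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return TwoGroupResult("t", 0.0, 1.0, (p_x, p_y))
    if ok_x and ok_y:
        stat, p = sps.ttest_ind(x, y)
        return TwoGroupResult("t", float(stat), float(p), (p_x, p_y))
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TwoGroupResult("mannwhitney", float(stat), float(p), (p_x, p_y))


def correlate(table: pd.DataFrame, var_a: str, var_b: str) -> tuple[float, float, float]:
    """Pearson correlation pooled across groups, pairwise-complete.

    Returns (r, R^2, two-tailed p).
    """
    sub = table[[var_a, var_b]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete pairs")
    a = sub[var_a].to_numpy(dtype=np.float64)
    b = sub[var_b].to_numpy(dtype=np.float64)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    res = sps.pearsonr(a, b)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a correlation family."""
    p = np.asarray(pvalues, dtype=np.float64)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Factor analysis: PAF extraction, varimax/promax rotation

@dataclass(frozen=True)
class FactorModel:
    """Fitted factor model on the correlation matrix of the cohort variables."""

    variables: tuple[str, ...]
    eigenvalues: np.ndarray          # of the full correlation matrix, descending
    n_factors: int
    pattern: np.ndarray              # variables x factors, promax-rotated
    communalities: np.ndarray
    factor_correlations: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.communalities < -1e-9) or np.any(self.communalities > 1 + 1e-9):
            raise ValueError("communalities outside [0, 1]")
        if self.n_factors < 1:
            raise ValueError("need at least one factor")


class FactorConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def paf(corr: np.ndarray, n_factors: int,
        tol: float = PAF_TOL, max_iter: int = PAF_MAX_ITER) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis factoring of a correlation matrix.

    Communalities start at squared multiple correlations, the reduced matrix
    (communalities on the diagonal) is eigen-decomposed, loadings of the top
    ``n_factors`` components give updated communalities, iterating to ``tol``.
    Heywood cases (communality > 1) are clipped with a warning.

    Under-identified models (negative degrees of freedom, e.g. two factors on
    four variables) have a flat ridge of equivalent solutions: the loading
    subspace stabilises quickly but communalities keep creeping along the
    ridge.  If ``max_iter`` is reached while the per-step communality change
    is already below ``PAF_RIDGE_TOL``, the current solution is returned with
    a warning; a genuinely diverging iteration raises
    :class:`FactorConvergenceError` with the change trace.

    Returns (unrotated loadings, communalities).
    """
    R = np.asarray(corr, dtype=np.float64)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    p = R.shape[0]
    if not 1 <= n_factors <= p:
        raise ValueError("n_factors must be between 1 and the number of variables")
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1.0 - 1.0 / np.diag(Rinv)  # squared multiple correlations
        h2 = np.clip(h2, 0.0, 1.0)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)

    trace: list[float] = []
    heywood = False
    for _ in range(max_iter):
        reduced = R.copy()
        np.fill_diagonal(reduced, h2)
        w, V = np.linalg.eigh(reduced)
        idx = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[idx], 0.0, None)
        L = V[:, idx] * np.sqrt(lam)
        h2_new = (L**2).sum(axis=1)
        if np.any(h2_new > 1.0):
            heywood = True
            h2_new = np.clip(h2_new, 0.0, 1.0)
        delta = float(np.max(np.abs(h2_new - h2)))
        trace.append(delta)
        h2 = h2_new
        if delta < tol:
            break
    else:
        if trace[-1] < PAF_RIDGE_TOL:
            warnings.warn(
                "PAF stopped at max_iter on a flat solution ridge "
                f"(last communality change {trace[-1]:.2e}); the loading "
                "subspace is stable but the model is weakly identified",
                stacklevel=2,
            )
        else:
            raise FactorConvergenceError(
                f"PAF did not converge in {max_iter} iterations "
                f"(last change {trace[-1]:.2e})", trace)
    if heywood:
        warnings.warn("Heywood case: communality > 1 clipped", stacklevel=2)

    # orient each factor so its largest-magnitude loading is positive
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    return L, h2


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser-normalised)."""
    L = np.asarray(loadings, dtype=np.float64).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    L /= h[:, None]
    Rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ Rot
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        Rot = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return (L @ Rot) * h[:, None]


def promax(loadings: np.ndarray, kappa: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation: varimax, then power-target transform.

    Returns (pattern matrix, factor correlation matrix).  kappa is the target
    power; 4 is the conventional default.
    """
    L = np.asarray(loadings, dtype=np.float64)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("promax needs at least 2 factors")
    if np.allclose(L, 0):
        raise ValueError("degenerate (all-zero) loadings")
    X = varimax(L)
    # element-wise power target preserving sign
    Y = np.sign(X) * np.abs(X) ** kappa
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    # scale columns so the implied factors have unit variance
    try:
        d = np.diag(np.linalg.inv(coef.T @ coef))
    except np.linalg.LinAlgError:
        d = np.diag(np.linalg.pinv(coef.T @ coef))
    coef = coef * np.sqrt(d)
    pattern = X @ coef
    coef_inv = np.linalg.inv(coef)
    phi = coef_inv @ coef_inv.T
    # orient factors with positive dominant loading
    for j in range(pattern.shape[1]):
        if pattern[np.argmax(np.abs(pattern[:, j])), j] < 0:
            pattern[:, j] = -pattern[:, j]
            phi[j, :] *= -1
            phi[:, j] *= -1
    return pattern, phi


def congruence(target: np.ndarray, estimate: np.ndarray) -> float:
    """Minimum Tucker congruence between matched factor columns.

    The estimate's columns are matched to the target's by the best
    permutation and sign assignment; the worst matched-column congruence is
    returned (1 = identical directions).
    """
    import itertools

    A = np.asarray(target, dtype=np.float64)
    B = np.asarray(estimate, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("target and estimate must have matching shapes")
    k = A.shape[1]
    best = -np.inf
    for perm in itertools.permutations(range(k)):
        cols = []
        for j in range(k):
            a, b = A[:, j], B[:, perm[j]]
            c = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            cols.append(c)
        best = max(best, min(cols))
    return float(best)


def scree_select(eigenvalues: np.ndarray) -> int:
    """Kaiser criterion: number of correlation-matrix eigenvalues >= 1."""
    lam = np.asarray(eigenvalues, dtype=np.float64)
    return int(np.sum(lam >= 1.0))


def fit_factor_model(table: pd.DataFrame, variables: list[str] | None = None,
                     n_factors: int | str = "auto", kappa: float = 4.0) -> FactorModel:
    """Listwise-complete PAF + promax on a cohort table.

    ``n_factors="auto"`` uses the Kaiser eigenvalue >= 1 rule on the
    correlation matrix.  With a single retained factor the unrotated solution
    is returned (rotation of one factor is a no-op).
    """
    if variables is None:
        variables = [c for c in table.columns if c not in ("subject", "group")]
    data = table[variables].dropna()  # listwise deletion
    R = np.corrcoef(data.to_numpy(dtype=np.float64), rowvar=False)
    lam = np.sort(np.linalg.eigvalsh(R))[::-1]
    k = scree_select(lam) if n_factors == "auto" else int(n_factors)
    k = max(k, 1)
    L, h2 = paf(R, k)
    if k >= 2:
        pattern, phi = promax(L, kappa=kappa)
    else:
        pattern, phi = L, np.eye(1)
    return FactorModel(
        variables=tuple(variables),
        eigenvalues=lam,
        n_factors=k,
        pattern=pattern,
        communalities=np.clip(h2, 0.0, 1.0),
        factor_correlations=phi,
    )


# ---------------------------------------------------------------------------
# Relationship-group scores

@dataclass(frozen=True)
class GroupScores:
    """Per-subject weighted-average scores per factor, plus group summaries."""

    scores: pd.DataFrame          # subject, group, factor_1..factor_k
    group_summary: pd.DataFrame   # group x factor means and s.d.
    excluded_subjects: tuple = ()


def group_scores(table: pd.DataFrame, model: FactorModel) -> GroupScores:
    """Loading-weighted average of z-scored variables, per subject and factor.

    Weights are |pattern loadings| normalised to sum to 1 within each factor.
    Subjects with any missing variable are excluded (listwise) and logged.
    """
    variables = list(model.variables)
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"table lacks model variables: {missing}")
    complete = table.dropna(subset=variables)
    excluded = tuple(table.loc[table[variables].isna().any(axis=1), "subject"])
    if excluded:
        warnings.warn(f"excluded subjects with missing data: {list(excluded)}", stacklevel=2)
    X = complete[variables].to_numpy(dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    W = np.abs(model.pattern)
    W = W / W.sum(axis=0, keepdims=True)
    S = Z @ W
    out = pd.DataFrame({"subject": complete["subject"].values,
                        "group": complete["group"].values})
    for j in range(model.n_factors):
        out[f"factor_{j + 1}"] = S[:, j]
    summary = out.groupby("group")[[f"factor_{j + 1}" for j in range(model.n_factors)]].agg(
        ["mean", "std"])
    return GroupScores(scores=out, group_summary=summary, excluded_subjects=excluded)
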