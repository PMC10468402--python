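"""Two-part (hurdle) regression engine with likelihood-ratio tests.

Single-cell expression of one gene is modelled in two parts: a logistic
regression of the detection indicator 1[y > 0] on the design (discrete part),
and a Gaussian linear regression of the log-normalized expression y on the same
design, restricted to cells where the gene is detected (continuous part).
Nested models are compared by summing the likelihood-ratio statistics of both
parts; the statistic is referred to a chi-square distribution with degrees of
freedom equal to the number of parameters dropped across the non-degenerate
parts.  This is the statistical engine behind the target and interaction tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DEFAULT_K_MIN = 3  # minimum detected cells for a continuous part
SEPARATION_RIDGE = 1e-6


@dataclass
class DesignSpec:
    """Covariate list + contrast for nested hurdle models.

    ``covariates`` is an ordered list of (name, kind) with kind in
    {"continuous", "categorical", "binary"}; an intercept is always included.
    ``contrast`` names the term(s) dropped in the reduced model.
    ``reference`` optionally pins the reference level per categorical.
    """

    covariates: list
    contrast: list
    reference: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.contrast, str):
            self.contrast = [self.contrast]
        names = {n for n, _ in self.covariates}
        unknown = set(self.contrast) - names
        if unknown:
            raise ValueError(f"contrast terms not among covariates: {sorted(unknown)}")

    def build(self, obs: pd.DataFrame):
        """Expand covariates against a cell table.

        Returns (X, contrast_cols): the full design matrix (with Intercept) and
        the design columns belonging to the contrast terms.
        """
        cols = {"Intercept": np.ones(len(obs))}
        contrast_cols: list = []
        for name, kind in self.covariates:
            v = obs[name]
            if kind == "categorical":
                levels = sorted(v.astype(str).unique())
                ref = self.reference.get(name, levels[0])
                for lev in levels:
                    if lev == ref:
                        continue
                    col = f"{name}[{lev}]"
                    cols[col] = (v.astype(str) == lev).to_numpy(dtype=float)
                    if name in self.contrast:
                        contrast_cols.append(col)
            else:
                cols[name] = v.to_numpy(dtype=float)
                if name in self.contrast:
                    contrast_cols.append(name)
        X = pd.DataFrame(cols, index=obs.index)
        return X, contrast_cols


@dataclass
class HurdleFit:
    """Fitted two-part model (either part may be degenerate)."""

    n: int
    n_detected: int
    # discrete (logistic) part
    disc_params: pd.Series | None = None
    disc_llf: float = 0.0
    disc_cols: list = field(default_factory=list)
    disc_degenerate: bool = True
    separated: bool = False
    # continuous (Gaussian) part
    cont_params: pd.Series | None = None
    cont_llf: float = 0.0
    cont_cols: list = field(default_factory=list)
    cont_degenerate: bool = True
    cont_mean: float = 0.0  # mean of detected y, used when continuous part degenerate
    converged: bool = True
    xbar: pd.Series | None = None  # column means of the full design

    @property
    def df_discrete(self) -> int:
        return 0 if self.disc_degenerate else len(self.disc_cols)

    @property
    def df_continuous(self) -> int:
        return 0 if self.cont_degenerate else len(self.cont_cols)

    @property
    def loglik(self) -> float:
        """Total two-part log-likelihood over the non-degenerate parts."""
        out = 0.0
        if not self.disc_degenerate:
            out += self.disc_llf
        if not self.cont_degenerate:
            out += self.cont_llf
        return out


@dataclass
class LRTResult:
    gene: str
    chisq: float
    df: int
    p: float
    log2fc: float
    status: str  # ok | degenerate | nonconverged
    fdr: float = np.nan


def _independent_columns(X: np.ndarray, cols: list, tol: float = 1e-9) -> list:
    """Greedy left-to-right selection of a full-rank column subset."""
    keep: list = []
    basis = np.empty((X.shape[0], 0))
    for j, name in enumerate(cols):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > basis.shape[1]:
            keep.append(name)
            basis = cand
    return keep


def _logistic_llf(z: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(z * np.log(p) + (1 - z) * np.log1p(-p)))


def _fit_logistic(z: np.ndarray, X: pd.DataFrame):
    """Logistic fit with an L2-penalized fallback on perfect separation.

    Returns (params, llf, separated, converged); llf is always the unpenalized
    log-likelihood evaluated at the returned coefficients.
    """
    Xv = X.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(z, Xv).fit(method="newton", disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
            if converged and np.all(np.isfinite(params)) and np.abs(params).max() < 30:
                return (pd.Series(params, index=X.columns),
                        _logistic_llf(z, Xv, params), False, True)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            pass
        # separation or unstable fit: small ridge keeps estimates finite
        res = sm.GLM(z, Xv, family=sm.families.Binomial()).fit_regularized(
            alpha=SEPARATION_RIDGE, L1_wt=0.0)
        params = np.asarray(res.params, dtype=float)
    return (pd.Series(params, index=X.columns),
            _logistic_llf(z, Xv, params), True, True)


def fit_hurdle(y, X: pd.DataFrame, k_min: int = DEFAULT_K_MIN) -> HurdleFit:
    """Fit the two-part hurdle model of one gene on a design matrix.

    The discrete part is marked degenerate when all cells (or none) are
    detected; the continuous part when fewer than ``k_min`` cells are detected,
    or when the detected values have no residual variance.  Design columns that
    are aliased (linearly dependent, possibly only within the detected subset)
    are dropped per part.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2:
        raise ValueError("need at least 2 cells")
    if len(y) != len(X):
        raise ValueError("y and design matrix disagree on cell count")
    z = (y > 0).astype(float)
    n_det = int(z.sum())
    fit = HurdleFit(n=len(y), n_detected=n_det, xbar=X.mean())

    # discrete part
    if 0 < n_det < len(y):
        cols = _independent_columns(X.to_numpy(dtype=float), list(X.columns))
        params, llf, separated, converged = _fit_logistic(z, X[cols])
        fit.disc_params, fit.disc_llf, fit.disc_cols = params, llf, cols
        fit.disc_degenerate = False
        fit.separated = separated
        fit.converged = fit.converged and converged

    # continuous part
    det = z > 0
    ypos = y[det]
    if n_det >= k_min:
        Xd = X[det]
        cols = _independent_columns(Xd.to_numpy(dtype=float), list(Xd.columns))
        if n_det > len(cols) and np.var(ypos) > 1e-12:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.OLS(ypos, Xd[cols].to_numpy(dtype=float)).fit()
            sigma2 = float(np.mean(res.resid ** 2))
            if sigma2 > 1e-12:
                fit.cont_params = pd.Series(np.asarray(res.params), index=cols)
                fit.cont_llf = float(res.llf)
                fit.cont_cols = cols
                fit.cont_degenerate = False
    fit.cont_mean = float(ypos.mean()) if n_det else 0.0
    return fit


def lrt(full: HurdleFit, reduced: HurdleFit, gene: str = "",
        log2fc: float = 0.0) -> LRTResult:
    """Likelihood-ratio test of nested hurdle fits.

    chisq = 2 * [(ll_full - ll_reduced) summed over parts that are
    non-degenerate in both fits], clipped at zero; df = number of parameters
    dropped, summed over those parts.  df == 0 yields status "degenerate" with
    p = 1.
    """
    stat, df = 0.0, 0
    if not full.disc_degenerate and not reduced.disc_degenerate:
        d = len(full.disc_cols) - len(reduced.disc_cols)
        if d > 0:
            stat += 2.0 * (full.disc_llf - reduced.disc_llf)
            df += d
    if not full.cont_degenerate and not reduced.cont_degenerate:
        d = len(full.cont_cols) - len(reduced.cont_cols)
        if d > 0:
            stat += 2.0 * (full.cont_llf - reduced.cont_llf)
            df += d
    stat = max(stat, 0.0)
    if df == 0:
        return LRTResult(gene, 0.0, 0, 1.0, log2fc, "degenerate")
    status = "ok" if (full.converged and reduced.converged) else "nonconverged"
    p = float(chi2.sf(stat, df))
    return LRTResult(gene, float(stat), df, p, log2fc, status)


def contrast_log2fc(fit: HurdleFit, contrast_col: str, mode: str = "combined") -> float:
    """Model-based log2 fold change for a binary contrast column.

    ``combined`` (default): difference in predicted expression
    P(detected) * E[y | detected] between contrast levels 1 and 0, all other
    covariates held at their means, converted from the natural-log expression
    scale to log2.  ``continuous``: the continuous-part coefficient alone.
    """
    if mode == "continuous":
        if fit.cont_params is not None and contrast_col in fit.cont_params.index:
            return float(fit.cont_params[contrast_col]) / LN2
        return 0.0
    if mode != "combined":
        raise ValueError(f"unknown log2fc mode {mode!r}")
    x1 = fit.xbar.copy()
    x0 = fit.xbar.copy()
    if contrast_col in x1.index:
        x1[contrast_col] = 1.0
        x0[contrast_col] = 0.0
    if fit.disc_degenerate:
        p1 = p0 = 1.0 if fit.n_detected == fit.n else 0.0
    else:
        p1 = float(expit(x1[fit.disc_cols] @ fit.disc_params))
        p0 = float(expit(x0[fit.disc_cols] @ fit.disc_params))
    if fit.cont_degenerate:
        m1 = m0 = fit.cont_mean
    else:
        m1 = float(x1[fit.cont_cols] @ fit.cont_params)
        m0 = float(x0[fit.cont_cols] @ fit.cont_params)
    return (p1 * m1 - p0 * m0) / LN2


def hurdle_lrt_table(Y, X: pd.DataFrame, contrast_cols: list, genes,
                     k_min: int = DEFAULT_K_MIN, lfc_mode: str = "combined",
                     fdr_method: str = "BH") -> pd.DataFrame:
    """Run the hurdle LRT for every gene column of Y against one design.

    Y is cells x genes (sparse or dense) of log-normalized expression; the
    reduced design drops ``contrast_cols``.  Returns a DataFrame with columns
    gene, chisq, df, p, log2fc, fdr, status; the BH family excludes genes whose
    test is degenerate in both parts.
    """
    if not contrast_cols:
        raise ValueError("contrast_cols must be non-empty")
    X = X.reset_index(drop=True)
    X_red = X.drop(columns=contrast_cols)
    dense = Y.toarray() if sp.issparse(Y) else np.asarray(Y)
    rows = []
    for j, gene in enumerate(genes):
        y = dense[:, j]
        full = fit_hurdle(y, X, k_min=k_min)
        red = fit_hurdle(y, X_red, k_min=k_min)
        lfc = contrast_log2fc(full, contrast_cols[0], mode=lfc_mode)
        rows.append(lrt(full, red, gene=str(gene), log2fc=lfc))
    out = pd.DataFrame(
        {"gene": [r.gene for r in rows], "chisq": [r.chisq for r in rows],
         "df": [r.df for r in rows], "p": [r.p for r in rows],
         "log2fc": [r.log2fc for r in rows], "status": [r.status for r in rows]}
    )
    p_for_fdr = out["p"].where(out["status"] != "degenerate", np.nan)
    out["fdr"] = adjust_pvalues(p_for_fdr.to_numpy(), method=fdr_method)
    return out


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment; missing entries are excluded and returned
    missing.  BH is step-up with monotonicity enforcement; Bonferroni is
    min(1, p * m) with m the number of non-missing tests."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must be in [0, 1]")
    if method == "BH":
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    elif method == "bonferroni":
        out[mask] = np.minimum(1.0, p[mask] * mask.sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return out
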