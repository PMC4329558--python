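"""Per-SNP case-control association under the additive genetic model.

The reported statistic for each SNP is the Wald test from an unconditional
logistic regression of case status on minor-allele dosage plus covariates,
with per-allele odds ratio and 95% CI. Observed-data fits are complete-case
and delegated to statsmodels (Newton/IRLS maximum likelihood).

For the permutation ensemble a Rao score test is used instead: the null
model (covariates only) is fitted once per relabeling and every SNP's score
statistic follows from one matrix product, which makes tens of thousands of
relabelings affordable. Missing dosages are mean-imputed inside this fast
path only. Score and Wald p-values are asymptotically equivalent; the
agreement is tolerance-tested.

Population stratification is adjusted by principal components of the
standardized genotype matrix, g -> (g - 2f) / sqrt(2 f (1 - f)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

#: z quantile for the 95% Wald confidence interval
Z_95 = 1.959964

FIT_OK = "ok"
FIT_MONOMORPHIC = "monomorphic"
FIT_ONE_CLASS = "one_class"
FIT_NOT_CONVERGED = "not_converged"


@dataclass
class CovariateDesign:
    """A full-rank design matrix (intercept first) with column labels."""

    matrix: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("design matrix shape does not match column labels")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient after encoding")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def build_design(
    covariate_frame: pd.DataFrame,
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
) -> CovariateDesign:
    """Build an intercept + covariates design from a sample metadata frame.

    Categorical covariates (study, sex, age stratum, ...) get reference-level
    indicator encoding; constant columns are silently dropped rather than
    breaking full rank.
    """
    n = len(covariate_frame)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for col in categorical or []:
        dummies = pd.get_dummies(
            covariate_frame[col].astype(str), prefix=col, drop_first=True
        )
        if dummies.shape[1]:
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns.tolist())
    for col in numeric or []:
        vals = covariate_frame[col].to_numpy(dtype=float)
        if np.nanstd(vals) > 0:
            blocks.append(vals[:, None])
            names.append(col)
    return CovariateDesign(np.hstack(blocks), names)


def intercept_only_design(n_samples: int) -> CovariateDesign:
    return CovariateDesign(np.ones((n_samples, 1)), ["intercept"])


# ---------------------------------------------------------------------------
# Stratification PCs
# ---------------------------------------------------------------------------

class GenotypePCA(BaseEstimator, TransformerMixin):
    """Principal components of standardized genotypes.

    Each dosage column is mean-imputed and standardized to
    ``(g - 2f) / sqrt(2 f (1 - f))`` with ``f`` the sample allele frequency;
    the transform returns the top ``n_components`` unit-norm sample
    eigenvectors of the resulting covariance, ordered by eigenvalue. These
    are the coordinates used as stratification covariates. Outlier-removal
    iterations and LD pruning are not performed.
    """

    def __init__(self, n_components: int = 2) -> None:
        self.n_components = n_components

    def fit(self, X, y=None):
        self._fit(np.asarray(X, dtype=float))
        return self

    def _fit(self, X: np.ndarray) -> np.ndarray:
        if X.ndim != 2:
            raise ValueError("X must be a samples x SNPs matrix")
        n = X.shape[0]
        if self.n_components >= n:
            raise ValueError(
                f"n_components={self.n_components} must be < n_samples={n}"
            )
        Z, mean, scale = _standardize_genotypes(X)
        self.mean_ = mean
        self.scale_ = scale
        if self.n_components == 0:
            self.components_ = np.empty((0, X.shape[1]))
            self.singular_values_ = np.empty(0)
            return np.empty((n, 0))
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        k = self.n_components
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
        # deterministic sign: largest-|.| loading of each component positive
        for i in range(k):
            j = np.argmax(np.abs(Vt[i]))
            if Vt[i, j] < 0:
                Vt[i] *= -1
                U[:, i] *= -1
        self.components_ = Vt
        self.singular_values_ = S
        return U

    def fit_transform(self, X, y=None):
        return self._fit(np.asarray(X, dtype=float))

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Z = np.where(np.isnan(X), self.mean_, X) - self.mean_
        Z = Z / self.scale_
        if self.n_components == 0:
            return np.empty((X.shape[0], 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            return Z @ self.components_.T / self.singular_values_


def _standardize_genotypes(X: np.ndarray):
    mean = np.nanmean(X, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    f = mean / 2.0
    var = 2.0 * f * (1.0 - f)
    scale = np.sqrt(np.where(var > 0, var, 1.0))
    Z = np.where(np.isnan(X), mean, X) - mean
    Z = Z / scale
    Z[:, var <= 0] = 0.0
    return Z, mean, scale


def compute_pcs(dosages: np.ndarray, k: int) -> np.ndarray:
    """Top-k stratification PCs of a dosage matrix (see :class:`GenotypePCA`)."""
    return GenotypePCA(n_components=k).fit_transform(dosages)


# ---------------------------------------------------------------------------
# Per-SNP Wald fits
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Additive-model logistic fit for one SNP."""

    snp_id: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    status: str = FIT_OK

    @property
    def ok(self) -> bool:
        return self.status == FIT_OK


def fit_snp_logistic(
    dosage_column: np.ndarray,
    status: np.ndarray,
    design: CovariateDesign | None = None,
    snp_id: str = "snp",
) -> AssociationResult:
    """Wald test for one SNP: logit P(case) = X beta + beta_g * dosage.

    Complete-case: samples with a missing call are dropped for this SNP.
    Degenerate inputs (monomorphic dosage, a single outcome class) and
    non-convergence/separation come back as flagged results, never raises.
    """
    g = np.asarray(dosage_column, dtype=float)
    y = np.asarray(status, dtype=float)
    X = design.matrix if design is not None else np.ones((len(y), 1))
    keep = ~np.isnan(g)
    g, y, X = g[keep], y[keep], X[keep]
    n_used = int(keep.sum())

    def flagged(code: str) -> AssociationResult:
        return AssociationResult(
            snp_id, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, n_used, code
        )

    if n_used == 0 or np.ptp(g) == 0:
        return flagged(FIT_MONOMORPHIC)
    if len(np.unique(y)) < 2:
        return flagged(FIT_ONE_CLASS)

    design_full = np.column_stack([X, g])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design_full).fit(
                method="newton", maxiter=25, tol=1e-10, disp=False
            )
        except Exception:
            return flagged(FIT_NOT_CONVERGED)
    if not fit.mle_retvals.get("converged", False):
        return flagged(FIT_NOT_CONVERGED)

    beta = float(fit.params[-1])
    se = float(fit.bse[-1])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        return flagged(FIT_NOT_CONVERGED)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        snp_id=snp_id,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p=max(p, np.finfo(float).tiny),
        n_used=n_used,
        status=FIT_OK,
    )


class SnpAssociation(BaseEstimator):
    """Per-SNP additive logistic association scan.

    ``fit(X, y)`` runs :func:`fit_snp_logistic` for every column of the
    dosage matrix against the binary status vector, optionally adjusting for
    a covariate design (pass ``design=`` to ``fit``). Results land in
    ``results_`` (a DataFrame, one row per SNP).
    """

    def __init__(self, ci_level: float = 0.95) -> None:
        self.ci_level = ci_level

    def fit(self, X, y, design: CovariateDesign | None = None, snp_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        snp_ids = list(snp_ids) if snp_ids is not None else [
            f"snp{j}" for j in range(X.shape[1])
        ]
        rows = []
        for j, sid in enumerate(snp_ids):
            r = fit_snp_logistic(X[:, j], y, design, snp_id=sid)
            rows.append(
                {
                    "snp_id": r.snp_id, "beta": r.beta, "se": r.se,
                    "or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "p": r.p, "n_used": r.n_used, "status": r.status,
                }
            )
        self.results_ = pd.DataFrame(rows).set_index("snp_id")
        return self


# ---------------------------------------------------------------------------
# Null-model IRLS and the Rao score test (permutation fast path)
# ---------------------------------------------------------------------------

def fit_null_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                      maxiter: int = 25) -> np.ndarray:
    """Fitted probabilities of the covariates-only logistic null model.

    Plain Newton/IRLS with step halving; converges when the largest absolute
    score component drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if not 0.0 < ybar < 1.0:
        raise ValueError("null model needs both outcome classes")
    if np.all(X[:, 0] == 1.0):
        beta[0] = np.log(ybar / (1.0 - ybar))
    for _ in range(maxiter):
        eta = X @ beta
        mu = _expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            return mu
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step halving against divergence (quasi-separation)
        ll = _loglik(y, mu)
        for _ in range(20):
            cand = beta + step
            mu_c = _expit(X @ cand)
            if _loglik(y, mu_c) >= ll - 1e-12:
                beta = cand
                break
            step *= 0.5
        else:
            break
    return _expit(X @ beta)


def _expit(eta: np.ndarray) -> np.ndarray:
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    return np.clip(mu, 1e-12, 1 - 1e-12)


def _loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def score_test_pvalues(
    dosage_matrix: np.ndarray,
    status: np.ndarray,
    design: CovariateDesign | None = None,
    mu: np.ndarray | None = None,
) -> np.ndarray:
    """Rao score test p-values for every SNP column against one null fit.

    With null fitted probabilities ``mu`` (fitted here if not supplied) the
    per-SNP statistic is U^2 / V with U = g'(y - mu) and V the efficient
    score variance after projecting out the covariates under weights
    mu(1 - mu); p comes from chi-square with 1 df. Missing dosages are
    mean-imputed. Degenerate columns (V ~ 0) report p = 1.
    """
    G = np.asarray(dosage_matrix, dtype=float)
    y = np.asarray(status, dtype=float)
    X = design.matrix if design is not None else np.ones((len(y), 1))
    if mu is None:
        mu = fit_null_logistic(X, y)
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    G = np.where(np.isnan(G), col_mean, G)

    w = mu * (1.0 - mu)
    U = G.T @ (y - mu)
    XtWX = X.T @ (X * w[:, None])
    XtWG = X.T @ (G * w[:, None])
    try:
        sol = np.linalg.solve(XtWX, XtWG)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(XtWX, XtWG, rcond=None)[0]
    V = np.einsum("ij,ij->j", G * w[:, None], G) - np.einsum(
        "ij,ij->j", XtWG, sol
    )
    stat = np.zeros(G.shape[1])
    good = V > 1e-12
    stat[good] = U[good] ** 2 / V[good]
    p = stats.chi2.sf(stat, df=1)
    return np.clip(p, np.finfo(float).tiny, 1.0)
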