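"""Per-cohort single-SNP association on residualized, standardized traits.

The analysis model follows the two-stage GWAS convention for DXA-derived
BMD: each trait is first regressed on anthropometric covariates (age,
sex and weight; height instead of weight for the skull), the residuals
are standardized, and each SNP's expected allelic dosage is then tested
by linear regression, optionally with ancestry principal components as
additional covariates.  Betas are therefore in adjusted SD per copy of
the effect allele.  Genomic control rescales test statistics by the
median association chi-square when it exceeds its null expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthgen import DosagePanel

#: chi2(1) median, the genomic-control denominator
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

COVARIATE_SETS = {"model0", "model1a"}


class MonomorphicError(ValueError):
    """Zero-variance dosage cannot be tested."""


@dataclass
class AssocRecord:
    """One SNP x trait association summary row."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    trait: str = ""
    cohort: str = ""

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def chi2(self) -> float:
        return self.z ** 2


@dataclass
class GcResult:
    lambda_gc: float
    corrected: bool


def _covariate_columns(covariate_set: str, trait: str) -> list[str]:
    if covariate_set == "model0":
        # skull BMD is adjusted for height instead of weight
        size = "HEIGHT" if trait == "SK" else "WEIGHT"
        return ["AGE", "SEX", size]
    if covariate_set == "model1a":
        return ["AGE", "SEX", "WEIGHT", "HEIGHT"]
    raise ValueError(f"unknown covariate set {covariate_set!r}; use one of {COVARIATE_SETS}")


def residualize_standardize(
    trait_values: np.ndarray,
    covariates: pd.DataFrame,
    covariate_set: str = "model0",
    trait: str = "",
) -> np.ndarray:
    """OLS residuals of trait on covariates, scaled to mean 0 / sd 1."""
    cols = _covariate_columns(covariate_set, trait)
    X = sm.add_constant(covariates[cols].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate design (constant covariate?)")
    resid = sm.OLS(np.asarray(trait_values, dtype=float), X).fit().resid
    return resid / resid.std(ddof=0)


def pc_covariates(panel: DosagePanel, k: int) -> np.ndarray:
    """Top-k principal-component scores of the standardized genotypes."""
    n = panel.n_individuals
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if k == 0:
        return np.empty((n, 0))
    z = panel.standardized().T  # (n, m), columns already centered/scaled
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :k] * s[:k]


def dosage_regression(
    y_std: np.ndarray,
    dosage: np.ndarray,
    extra_covariates: np.ndarray | None = None,
    snp_id: str = "",
    effect_allele: str = "",
    other_allele: str = "",
    trait: str = "",
    cohort: str = "",
    use_t: bool = False,
) -> AssocRecord:
    """OLS of the standardized trait on intercept + dosage + covariates.

    P-values use the normal (Wald) approximation by default, as the
    cohorts analysed here have thousands of individuals; ``use_t``
    switches to the exact t reference.
    """
    y = np.asarray(y_std, dtype=float)
    g = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    if extra_covariates is not None and extra_covariates.size:
        ok &= ~np.isnan(extra_covariates).any(axis=1)
    y, g = y[ok], g[ok]
    if g.std() == 0:
        raise MonomorphicError(f"SNP {snp_id or '<unnamed>'} has zero dosage variance")
    n = y.size
    cols = [np.ones(n), g]
    if extra_covariates is not None and extra_covariates.size:
        cols.extend(np.asarray(extra_covariates, dtype=float)[ok].T)
    X = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if use_t:
        p = 2.0 * stats.t.sf(abs(beta / se), dof)
    else:
        p = 2.0 * stats.norm.sf(abs(beta / se))
    return AssocRecord(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=float(np.mean(g) / 2.0),
        beta=beta,
        se=se,
        p=float(p),
        n=n,
        trait=trait,
        cohort=cohort,
    )


def run_gwas(
    panel: DosagePanel,
    y_std: np.ndarray,
    extra_covariates: np.ndarray | None = None,
    trait: str = "",
    cohort: str = "",
) -> pd.DataFrame:
    """Genome scan of one standardized trait over a panel.

    Vectorized Frisch-Waugh form of the same OLS as
    :func:`dosage_regression`: trait and dosages are projected off the
    nuisance design (intercept + covariates) and the per-SNP slope is
    computed on the residuals, with the degrees of freedom of the full
    joint regression.  Missing dosages are mean-imputed (panels here are
    complete after QC).
    """
    y = np.asarray(y_std, dtype=float)
    n = y.size
    if extra_covariates is not None and extra_covariates.size:
        nuis = np.column_stack([np.ones(n), extra_covariates])
    else:
        nuis = np.ones((n, 1))
    q, _ = np.linalg.qr(nuis)
    y_r = y - q @ (q.T @ y)
    x = panel.dosages.copy()
    mu = np.nanmean(x, axis=1, keepdims=True)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu[:, 0], inds[0])
    x_r = x - (x @ q) @ q.T
    sxx = np.einsum("ij,ij->i", x_r, x_r)
    monomorphic = sxx <= 0
    sxx_safe = np.where(monomorphic, 1.0, sxx)
    beta = (x_r @ y_r) / sxx_safe
    dof = n - nuis.shape[1] - 1
    rss = y_r @ y_r - beta ** 2 * sxx_safe
    se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx_safe)
    z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    df = pd.DataFrame(
        {
            "MarkerName": panel.snp_ids,
            "Allele1": panel.ea,
            "Allele2": panel.nea,
            "Freq1": x.mean(axis=1) / 2.0,
            "Effect": beta,
            "StdErr": se,
            "P": p,
            "N": n,
            "TRAIT": trait,
            "COHORT": cohort,
        }
    )
    return df[~monomorphic].reset_index(drop=True)


def lambda_gc(
    chi2: np.ndarray | None = None, p_values: np.ndarray | None = None
) -> GcResult:
    """Genomic-inflation factor: median association chi2 over 0.45494."""
    if chi2 is None:
        if p_values is None or len(p_values) == 0:
            raise ValueError("need chi-square statistics or P-values")
        chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), 1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty input")
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    return GcResult(lambda_gc=lam, corrected=lam > 1.0)


def gc_correct(records: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Rescale summary statistics for genomic inflation.

    Divides each chi-square by lambda (equivalently multiplies SE by
    sqrt(lambda)) only when lambda > 1; identity otherwise.
    """
    out = records.copy()
    if lam <= 1.0:
        return out
    out["StdErr"] = out["StdErr"] * np.sqrt(lam)
    z = out["Effect"] / out["StdErr"]
    out["P"] = 2.0 * stats.norm.sf(np.abs(z))
    return out
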