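"""Conditional association and locus-wise significance thresholds.

Secondary signals at a genome-wide significant locus are declared by
re-fitting the target SNP's regression with previously established
locus SNPs as covariates (individual-level conditioning), meta-analysing
the conditional estimates across cohorts, and comparing the conditional
meta P against a locus-specific threshold 0.05 / Meff, where Meff is the
effective number of independent tests from the eigenvalue dispersion of
the locus LD correlation matrix (Nyholt's spectral-decomposition
formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assoc import AssocRecord, MonomorphicError
from .metamod import MetaRecord, cochran_q, ivw_meta


class CollinearityError(ValueError):
    def __init__(self, snp_id: str):
        super().__init__(f"conditioning SNP {snp_id} is collinear with the target")
        self.snp_id = snp_id


def conditional_regression(
    y_std: np.ndarray,
    target: np.ndarray,
    conditioning: list[np.ndarray] | np.ndarray | None,
    snp_id: str = "",
    conditioning_ids: list[str] | None = None,
    **record_kwargs,
) -> AssocRecord:
    """Multiple OLS of y on intercept + target + conditioning dosages.

    The returned record carries the target coefficient; conditioning
    SNPs in near-perfect LD with the target (|r| >= 0.999) raise a
    collinearity error naming the offending SNP.
    """
    y = np.asarray(y_std, dtype=float)
    g = np.asarray(target, dtype=float)
    if conditioning is None:
        cond = np.empty((y.size, 0))
    else:
        cond = np.column_stack(conditioning) if isinstance(conditioning, list) else np.asarray(conditioning, dtype=float)
        if cond.ndim == 1:
            cond = cond[:, None]
    if g.std() == 0:
        raise MonomorphicError(f"target SNP {snp_id} has zero dosage variance")
    ids = conditioning_ids or [f"cond{i + 1}" for i in range(cond.shape[1])]
    for j in range(cond.shape[1]):
        if cond[:, j].std() == 0:
            continue
        r = np.corrcoef(g, cond[:, j])[0, 1]
        if abs(r) >= 0.999:
            raise CollinearityError(ids[j])
    n = y.size
    X = np.column_stack([np.ones(n), g, cond])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    se = float(np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1]))
    beta = float(coef[1])
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return AssocRecord(
        snp_id=snp_id,
        effect_allele=record_kwargs.get("effect_allele", ""),
        other_allele=record_kwargs.get("other_allele", ""),
        eaf=float(np.mean(g) / 2.0),
        beta=beta,
        se=se,
        p=p,
        n=n,
        trait=record_kwargs.get("trait", ""),
        cohort=record_kwargs.get("cohort", ""),
    )


def conditional_meta(records: list[AssocRecord]) -> MetaRecord:
    """Inverse-variance meta-analysis of per-cohort conditional records."""
    ests = [(r.beta, r.se) for r in records]
    beta, se, z, p = ivw_meta(ests)
    if len(ests) >= 2:
        q, df, p_het, i2 = cochran_q(ests, beta)
    else:
        q, df, p_het, i2 = 0.0, 0, 1.0, 0.0
    n_total = int(sum(r.n for r in records))
    eaf = float(sum(r.eaf * r.n for r in records) / n_total)
    return MetaRecord(
        snp_id=records[0].snp_id,
        effect_allele=records[0].effect_allele,
        eaf_pooled=eaf,
        beta_meta=beta,
        se_meta=se,
        z=z,
        p_meta=p,
        q=q,
        df_q=df,
        p_het=p_het,
        i2=i2,
        direction="".join("+" if r.beta >= 0 else "-" for r in records),
        n_total=n_total,
    )


@dataclass
class LocusThreshold:
    locus_id: str
    m_snps: int
    meff: float
    alpha_locus: float


def nyholt_meff(ld_corr: np.ndarray, locus_id: str = "", alpha: float = 0.05) -> LocusThreshold:
    """Effective number of independent tests from LD eigenvalue spread.

    Meff = 1 + (M-1) * (1 - Var(lambda)/M) with Var(lambda) =
    sum (lambda_i - 1)^2 / (M - 1); the locus alpha is 0.05 / Meff.
    Fully independent SNPs give Meff = M, perfect LD gives Meff = 1.
    """
    R = np.asarray(ld_corr, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("LD matrix must be square symmetric")
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-8:
        raise ValueError("LD matrix is not positive semi-definite")
    M = R.shape[0]
    if M == 1:
        meff = 1.0
    else:
        var_obs = float(np.sum((eig - 1.0) ** 2) / (M - 1))
        meff = 1.0 + (M - 1) * (1.0 - var_obs / M)
    return LocusThreshold(locus_id=locus_id, m_snps=M, meff=meff, alpha_locus=alpha / meff)


def ld_correlation(dosages: np.ndarray) -> np.ndarray:
    """Pairwise dosage correlation matrix of an (m, n) block of SNPs."""
    return np.corrcoef(np.asarray(dosages, dtype=float))


def declare_secondary(conditional: MetaRecord, threshold: LocusThreshold) -> bool:
    """Secondary signal iff conditional meta P <= the locus alpha."""
    return conditional.p_meta <= threshold.alpha_locus
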