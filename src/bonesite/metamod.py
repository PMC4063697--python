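"""Inverse-variance fixed-effects meta-analysis with heterogeneity.

Cohort summary statistics are harmonized to a common effect allele
(sign/frequency flips for swapped alleles, strand complementation,
ambiguous A/T and C/G SNPs dropped at high MAF), combined by
precision weighting, and screened for between-cohort heterogeneity
with Cochran's Q and the I^2 metric.  Genome-wide significance is the
conventional P < 5e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import chdtrc

GWS_ALPHA = 5e-8

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MetaRecord:
    snp_id: str
    effect_allele: str
    eaf_pooled: float
    beta_meta: float
    se_meta: float
    z: float
    p_meta: float
    q: float
    df_q: int
    p_het: float
    i2: float
    direction: str
    n_total: int

    @property
    def ci(self) -> tuple[float, float]:
        half = 1.96 * self.se_meta
        return (self.beta_meta - half, self.beta_meta + half)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize_alleles(
    record_a: dict, record_b: dict, ambiguous_maf: float = 0.40
) -> tuple[dict, dict] | tuple[None, str]:
    """Align cohort B's record to cohort A's effect allele.

    Swapped alleles negate beta and flip EAF; opposite-strand records
    are complemented first.  Strand-ambiguous (A/T, C/G) SNPs are
    dropped when the smaller cohort MAF exceeds ``ambiguous_maf``,
    since strand cannot then be resolved from frequency.  Returns the
    aligned pair, or (None, reason) for a drop.
    """
    a, b = dict(record_a), dict(record_b)
    ea_a, oa_a = a["Allele1"], a["Allele2"]
    ea_b, oa_b = b["Allele1"], b["Allele2"]

    if _is_ambiguous(ea_a, oa_a):
        maf = min(
            a["Freq1"], 1 - a["Freq1"], b["Freq1"], 1 - b["Freq1"]
        )
        if maf > ambiguous_maf:
            return None, "strand_ambiguous"

    if {ea_b, oa_b} != {ea_a, oa_a}:
        ea_b, oa_b = _COMPLEMENT.get(ea_b, "?"), _COMPLEMENT.get(oa_b, "?")
        if {ea_b, oa_b} != {ea_a, oa_a}:
            return None, "allele_mismatch"

    if (ea_b, oa_b) == (oa_a, ea_a):
        b["Effect"] = -b["Effect"]
        b["Freq1"] = 1.0 - b["Freq1"]
        ea_b, oa_b = oa_b, ea_b
    b["Allele1"], b["Allele2"] = ea_b, oa_b
    return a, b


def ivw_meta(estimates: list[tuple[float, float]]) -> tuple[float, float, float, float]:
    """Precision-weighted fixed-effects combination of (beta, se) pairs.

    Returns (beta_meta, se_meta, z, p); P is two-sided from the normal,
    evaluated through the log-space survival function so that values
    down to ~1e-300 are exact and smaller ones remain accurate.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    beta = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = se ** -2
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(np.sum(w) ** -0.5)
    z = beta_meta / se_meta
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p == 0.0:  # deep tail: use the log survival function
        p = float(2.0 * np.exp(stats.norm.logsf(abs(z))))
    return beta_meta, se_meta, float(z), p


def cochran_q(
    estimates: list[tuple[float, float]], beta_meta: float
) -> tuple[float, int, float, float]:
    """Cochran's Q, its df, heterogeneity P and the I^2 percentage."""
    if len(estimates) < 2:
        raise ValueError("heterogeneity needs at least two estimates")
    beta = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    w = se ** -2
    q = float(np.sum(w * (beta - beta_meta) ** 2))
    df = len(estimates) - 1
    p_het = float(chdtrc(df, q))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, p_het, i2


def gws_flag(p: float) -> bool:
    """Strict genome-wide significance: P < 5e-8."""
    return p < GWS_ALPHA


def meta_analyse(
    cohort_tables: list[pd.DataFrame], ambiguous_maf: float = 0.40
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine >=2 METAL-style cohort summary tables SNP by SNP.

    Returns the meta table (with Direction, HetQ, HetDf, HetISq,
    HetPVal columns) and a drop report.  Pooled EAF is sample-size
    weighted.
    """
    if len(cohort_tables) < 2:
        raise ValueError("need at least two cohorts")
    indexed = [t.set_index("MarkerName") for t in cohort_tables]
    common = indexed[0].index
    for t in indexed[1:]:
        common = common.intersection(t.index)
    rows, drops = [], []
    for snp in common:
        recs = [t.loc[snp].to_dict() for t in indexed]
        aligned = [recs[0]]
        reason = None
        for rec in recs[1:]:
            pair = harmonize_alleles(recs[0], rec, ambiguous_maf)
            if pair[0] is None:
                reason = pair[1]
                break
            aligned.append(pair[1])
        if reason is not None:
            drops.append({"MarkerName": snp, "reason": reason})
            continue
        ests = [(r["Effect"], r["StdErr"]) for r in aligned]
        beta, se, z, p = ivw_meta(ests)
        q, df, p_het, i2 = cochran_q(ests, beta)
        ns = np.array([r["N"] for r in aligned], dtype=float)
        eaf = float(np.sum([r["Freq1"] * r["N"] for r in aligned]) / ns.sum())
        rows.append(
            {
                "MarkerName": snp,
                "Allele1": aligned[0]["Allele1"],
                "Allele2": aligned[0]["Allele2"],
                "Freq1": eaf,
                "Effect": beta,
                "StdErr": se,
                "Zscore": z,
                "P": p,
                "Direction": "".join("+" if r["Effect"] >= 0 else "-" for r in aligned),
                "HetQ": q,
                "HetDf": df,
                "HetISq": i2,
                "HetPVal": p_het,
                "N": int(ns.sum()),
                "GWS": gws_flag(p),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(drops, columns=["MarkerName", "reason"])
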