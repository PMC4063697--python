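"""End-to-end driver: simulate -> QC -> GWAS -> meta -> conditional ->
site-specificity -> GREML, with a JSON manifest of every stage."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, condmod, greml, io, metamod, sitespec
from .config import PipelineConfig
from .synthgen import TRAITS, SpikedEffect, qc_filter, simulate_genotypes, simulate_phenotypes, spike_effect

log = logging.getLogger("bonesite")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _residual_matrix(pheno: pd.DataFrame, covariate_set: str, traits=TRAITS) -> dict[str, np.ndarray]:
    return {
        t: assoc.residualize_standardize(pheno[t].to_numpy(), pheno, covariate_set, trait=t)
        for t in traits
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    # --- simulate + QC ---------------------------------------------------
    panels, phenos = [], []
    for i, spec in enumerate(config.cohorts):
        panel = simulate_genotypes(spec)
        # shared effects_seed: both cohorts draw the same causal architecture
        sim = simulate_phenotypes(
            panel, config.arch, seed=config.seed + 100 + i, effects_seed=config.seed + 7
        )
        table = sim.table
        for spike in config.spikes:
            table = spike_effect(panel, table, SpikedEffect(spike["snp_id"], spike["per_trait_beta"]))
        panel, report = qc_filter(panel)
        log.info("cohort %s: %d SNPs pass QC (%d dropped)", spec.cohort_id, panel.n_snps, len(report))
        manifest["stages"].setdefault("qc", {})[spec.cohort_id] = {
            "n_snps_pass": int(panel.n_snps),
            "n_dropped": int(len(report)),
            "drop_reasons": report["reason"].value_counts().to_dict(),
        }
        io.write_dosage(panel, out / f"{spec.cohort_id}.dosage.tsv")
        io.write_phenotypes(table, out / f"{spec.cohort_id}.pheno.tsv")
        panels.append(panel)
        phenos.append(table)

    # --- per-cohort association + GC -------------------------------------
    cohort_stats: dict[str, dict[str, pd.DataFrame]] = {t: {} for t in TRAITS}
    residuals = []
    for i, (spec, panel, pheno) in enumerate(zip(config.cohorts, panels, phenos)):
        resid = _residual_matrix(pheno, config.covariate_set)
        residuals.append(resid)
        pcs = assoc.pc_covariates(panel, config.pcs[i]) if config.pcs[i] else None
        lambdas = {}
        for t in TRAITS:
            scan = assoc.run_gwas(panel, resid[t], pcs, trait=t, cohort=spec.cohort_id)
            gc = assoc.lambda_gc(chi2=(scan["Effect"] / scan["StdErr"]) ** 2)
            lambdas[t] = gc.lambda_gc
            if config.gc and gc.corrected:
                scan = assoc.gc_correct(scan, gc.lambda_gc)
            cohort_stats[t][spec.cohort_id] = scan
            io.write_summary_stats(scan, out / f"{spec.cohort_id}.{t}.assoc.tsv")
        log.info("cohort %s lambda_GC: %s", spec.cohort_id, lambdas)
        manifest["stages"].setdefault("assoc", {})[spec.cohort_id] = {
            "lambda_gc": lambdas,
            "n_snps": int(panel.n_snps),
        }

    # --- meta-analysis ----------------------------------------------------
    gws_hits: dict[str, list[str]] = {}
    meta_tables: dict[str, pd.DataFrame] = {}
    for t in TRAITS:
        meta, drops = metamod.meta_analyse(list(cohort_stats[t].values()))
        meta_tables[t] = meta
        hits = meta.loc[meta["P"] < config.gws_alpha, "MarkerName"].tolist()
        gws_hits[t] = hits
        io.write_summary_stats(meta, out / f"meta.{t}.tsv")
        manifest["stages"].setdefault("meta", {})[t] = {
            "n_meta": int(len(meta)),
            "n_dropped": int(len(drops)),
            "gws_hits": hits,
        }

    # --- conditional analysis --------------------------------------------
    if config.conditioning:
        cond = config.conditioning
        trait = cond.get("trait", "SK")
        records = []
        for spec, panel, resid in zip(config.cohorts, panels, residuals):
            conditioning = [panel.dosage(s) for s in cond["conditioning"] if s in panel.snp_ids]
            rec = condmod.conditional_regression(
                resid[trait], panel.dosage(cond["target"]), conditioning,
                snp_id=cond["target"], trait=trait, cohort=spec.cohort_id,
            )
            records.append(rec)
        cmeta = condmod.conditional_meta(records)
        block = panels[0].dosages[
            [panels[0].snp_index(s) for s in [cond["target"], *cond["conditioning"]] if s in panels[0].snp_ids]
        ]
        thr = condmod.nyholt_meff(condmod.ld_correlation(block), locus_id=cond["target"])
        manifest["stages"]["conditional"] = {
            "target": cond["target"],
            "beta_conditional": cmeta.beta_meta,
            "p_conditional": cmeta.p_meta,
            "meff": thr.meff,
            "alpha_locus": thr.alpha_locus,
            "secondary": condmod.declare_secondary(cmeta, thr),
        }

    # --- site-specificity test -------------------------------------------
    sitespec_rows = []
    for snp in config.sitespec_snps:
        cohort_data = []
        for panel, resid in zip(panels, residuals):
            if snp not in panel.snp_ids:
                continue
            Y = np.column_stack([resid[s] for s in sitespec.SITES])
            cohort_data.append((Y, panel.dosage(snp)))
        if not cohort_data:
            continue
        res = sitespec.site_specificity_test(cohort_data, snp_id=snp, alpha=config.sitespec_alpha)
        row = {
            "SNP": snp, "FreeSite": res.free_site,
            "FisherX": res.fisher_x, "FisherDf": res.fisher_df,
            "FisherP": res.fisher_p, "Significant": res.significant,
        }
        for i, (chi, p) in enumerate(res.per_cohort, start=1):
            row[f"Chi_c{i}"], row[f"P_c{i}"] = chi, p
        sitespec_rows.append(row)
    if sitespec_rows:
        df = pd.DataFrame(sitespec_rows)
        df.to_csv(out / "sitespec.tsv", sep="\t", index=False)
        manifest["stages"]["sitespec"] = df.to_dict(orient="records")

    # --- GREML ------------------------------------------------------------
    if config.run_greml:
        panel, resid = panels[0], residuals[0]
        n_keep = min(config.greml_max_n or panel.n_individuals, panel.n_individuals)
        sel = np.arange(n_keep)
        from .synthgen import DosagePanel

        sub_panel = DosagePanel(
            snp_ids=panel.snp_ids, chrom=panel.chrom, pos=panel.pos,
            ea=panel.ea, nea=panel.nea,
            dosages=panel.dosages[:, sel], iids=panel.iids[sel],
        )
        grm = greml.compute_grm(sub_panel)
        retained = greml.prune_related(grm, config.relatedness_cutoff)
        keep = np.isin(grm.ids, retained)
        grm_pruned = greml.Grm(matrix=grm.matrix[np.ix_(keep, keep)], ids=grm.ids[keep], m_snps=grm.m_snps)
        uni = {}
        for t in TRAITS:
            est = greml.reml_univariate(resid[t][sel][keep], grm_pruned)
            uni[t] = {"v_g": est.v_g, "se": est.se_vg, "p": est.p_lrt}
        t1, t2 = config.greml_pair
        Y = np.column_stack([resid[t1][sel][keep], resid[t2][sel][keep]])
        biv = greml.reml_bivariate(Y, grm_pruned)
        r_p, se_rp = greml.phenotypic_correlation(Y[:, 0], Y[:, 1])
        manifest["stages"]["greml"] = {
            "n_grm": int(keep.sum()),
            "n_removed_related": int((~keep).sum()),
            "univariate": uni,
            "bivariate": {
                "pair": [t1, t2], "r_g": biv.r_g, "se_rg": biv.se_rg,
                "r_e": biv.r_e, "se_re": biv.se_re, "p_rg0": biv.p_rg0,
            },
            "phenotypic_correlation": {"r_p": r_p, "se": se_rp},
        }

    for f in sorted(out.glob("*.tsv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
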