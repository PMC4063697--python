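#!/usr/bin/env python
"""Per-cohort GWAS on residualized BMD traits, then fixed-effects meta.

Reads the cohorts written by 01_simulate_cohorts.py, residualizes each
trait (age/sex/weight; height for the skull), scans every SNP, applies
genomic control per cohort, and combines the cohorts by inverse-variance
weighting.  Full meta tables go to scratch/meta/ (bulky); a compact
per-trait summary with lambda_GC and the genome-wide significant hits
is written to results/meta/.
"""

from pathlib import Path

import pandas as pd

from bonesite import assoc, io, metamod
from bonesite.synthgen import TRAITS

IN = Path("scratch/cohorts")
OUT = Path("scratch/meta")
SUMMARY = Path("results/meta")
OUT.mkdir(parents=True, exist_ok=True)
SUMMARY.mkdir(parents=True, exist_ok=True)

cohorts = sorted(p.name.split(".")[0] for p in IN.glob("*.dosage.tsv"))
if not cohorts:
    raise SystemExit("run 01_simulate_cohorts.py first")

scans: dict[str, list] = {t: [] for t in TRAITS}
lambdas = []
for cohort in cohorts:
    panel = io.read_dosage(IN / f"{cohort}.dosage.tsv")
    pheno = io.read_phenotypes(IN / f"{cohort}.pheno.tsv")
    for t in TRAITS:
        y = assoc.residualize_standardize(pheno[t].to_numpy(), pheno, "model0", trait=t)
        scan = assoc.run_gwas(panel, y, trait=t, cohort=cohort)
        gc = assoc.lambda_gc(chi2=(scan["Effect"] / scan["StdErr"]) ** 2)
        if gc.corrected:
            scan = assoc.gc_correct(scan, gc.lambda_gc)
        print(f"{cohort} {t}: lambda_GC = {gc.lambda_gc:.3f}")
        lambdas.append({"cohort": cohort, "trait": t, "lambda_gc": gc.lambda_gc})
        scans[t].append(scan)

hit_rows = []
for t in TRAITS:
    meta, drops = metamod.meta_analyse(scans[t])
    io.write_summary_stats(meta, OUT / f"meta.{t}.tsv")
    hits = meta[meta["GWS"]]
    hit_rows.append(hits.assign(TRAIT=t))
    print(f"{t}: {len(meta)} SNPs combined, {len(drops)} dropped, "
          f"{len(hits)} genome-wide significant")
    for _, row in hits.iterrows():
        print(f"  {row.MarkerName}: beta={row.Effect:.3f} SE={row.StdErr:.3f} "
              f"P={row.P:.2e} I2={row.HetISq:.0f}")

pd.DataFrame(lambdas).to_csv(SUMMARY / "lambda_gc.tsv", sep="\t", index=False)
pd.concat(hit_rows).to_csv(SUMMARY / "gws_hits.tsv", sep="\t", index=False)
print(f"\nsummaries in {SUMMARY}/, full tables in {OUT}/")
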