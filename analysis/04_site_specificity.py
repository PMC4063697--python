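#!/usr/bin/env python
"""Site-specificity of SNP effects across skull, upper and lower limb.

Two demonstrations: (i) the analytic Fisher-combination tail evaluated
at the published chi-square statistics reproduces the published
combined P-values; (ii) the full two-cohort likelihood-ratio pipeline
flags a synthetic SNP spiked with the published skull/upper-limb
pattern (strong UL and SK effects, negligible LL effect) while an
equal-effect SNP stays null.  Writes results/sitespec/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import chdtrc

from bonesite import sitespec
from bonesite.datasets import load_site_specificity_reference

OUT = Path("results/sitespec")
OUT.mkdir(parents=True, exist_ok=True)

ref = load_site_specificity_reference()
ref["P_RECOMPUTED"] = [float(chdtrc(4, c)) for c in ref.CHI]
ref.to_csv(OUT / "reference_recomputed.tsv", sep="\t", index=False)
print("Fisher tail at printed Chi (df = 4):")
for _, row in ref[ref.CHI >= 15].iterrows():
    print(f"  {row.RSID} ({row.GENE}): chi={row.CHI:.2f} printed P={row.FISHER_P:.2e} "
          f"recomputed P={row.P_RECOMPUTED:.2e}")

SIGMA = np.array([[1.0, 0.64, 0.31], [0.64, 1.0, 0.40], [0.31, 0.40, 1.0]])


def spiked_cohorts(beta, seed):
    out = []
    for n, s in zip((5330, 4086), (seed, seed + 1)):
        rng = np.random.default_rng(s)
        g = rng.binomial(2, 0.35, n).astype(float)
        z = (g - g.mean()) / g.std()
        Y = rng.multivariate_normal(np.zeros(3), SIGMA, n) + np.outer(z, beta)
        out.append((Y, g))
    return out


rows = []
for name, beta in (
    ("cped1_like", np.array([0.020, 0.187, 0.169])),
    ("equal_effects", np.array([0.12, 0.12, 0.12])),
):
    res = sitespec.site_specificity_test(spiked_cohorts(beta, 1234), snp_id=name)
    rows.append(
        {"snp": name, "free_site": res.free_site, "fisher_x": res.fisher_x,
         "fisher_df": res.fisher_df, "fisher_p": res.fisher_p,
         "significant": res.significant}
    )
df = pd.DataFrame(rows)
df.to_csv(OUT / "spiked_patterns.tsv", sep="\t", index=False)
print("\ntwo-cohort LRT + Fisher on spiked synthetic SNPs:")
print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
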