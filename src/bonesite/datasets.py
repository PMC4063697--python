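"""Packaged reference tables.

Small TSVs of printed summary statistics from a published two-cohort
paediatric total-body DXA BMD genome-wide meta-analysis: the top
genome-wide significant associations per skeletal site with per-cohort
and combined estimates, and the cross-site effect comparison with its
per-SNP Fisher combination.  They serve as inputs for recomputation and
as regression fixtures; individual-level study data are access
controlled and never shipped.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_top_hits() -> pd.DataFrame:
    """Top per-site association rows: cohort A/B and combined (meta).

    Columns ``*_A``/``*_B`` are the two cohort estimates (EAF, beta in
    adjusted SD per allele copy, SE, P) and ``*_M`` the published
    inverse-variance combination, with I^2 and heterogeneity P.
    """
    return _load("gwas_top_hits.tsv")


def load_site_specificity_reference() -> pd.DataFrame:
    """Cross-site effect-size comparison for all genome-wide hits.

    Per SNP: LL/UL/SK betas with 95% CIs and P, plus the Fisher
    combination (CHI on 4 df and its tail P) of the two per-cohort
    site-specificity likelihood-ratio tests.
    """
    return _load("site_specificity_reference.tsv")
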