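"""Pipeline configuration: a YAML-loadable bundle of stage parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .metamod import GWS_ALPHA
from .sitespec import SITESPEC_ALPHA
from .synthgen import DEFAULT_H2, DEFAULT_RE, DEFAULT_RG, TRAITS, CohortSpec, TraitArchitecture


@dataclass
class PipelineConfig:
    """Everything the end-to-end driver needs; seeds flow from ``seed``."""

    cohorts: list[CohortSpec]
    arch: TraitArchitecture
    spikes: list[dict] = field(default_factory=list)  # {snp_id, per_trait_beta}
    covariate_set: str = "model0"
    pcs: list[int] = field(default_factory=lambda: [0, 20])
    gc: bool = True
    gws_alpha: float = GWS_ALPHA
    sitespec_alpha: float = SITESPEC_ALPHA
    sitespec_snps: list[str] = field(default_factory=list)
    conditioning: dict | None = None  # {target, conditioning: [snp ids], trait}
    relatedness_cutoff: float = 0.025
    run_greml: bool = True
    greml_pair: tuple[str, str] = ("LL", "UL")
    greml_max_n: int | None = 1500  # cap GREML cohort size at desk scale
    seed: int = 0
    out_dir: Path = Path("results/pipeline")

    def validate(self) -> None:
        if not (0 < self.gws_alpha < 1 and 0 < self.sitespec_alpha < 1):
            raise ValueError("significance levels must lie in (0, 1)")
        if len(self.pcs) != len(self.cohorts):
            raise ValueError("one PC count per cohort required")
        for spec in self.cohorts:
            spec.validate()
        self.arch.validate(min(c.n_snps for c in self.cohorts))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        seed = int(raw.get("seed", 0))
        cohorts = [
            CohortSpec(
                cohort_id=c["cohort_id"],
                n_individuals=int(c["n_individuals"]),
                n_snps=int(c["n_snps"]),
                maf_range=tuple(c.get("maf_range", (0.05, 0.5))),
                dosage_noise_sd=float(c.get("dosage_noise_sd", 0.0)),
                seed=int(c.get("seed", seed + i)),
            )
            for i, c in enumerate(raw["cohorts"])
        ]
        arch_raw = raw.get("architecture", {})
        arch = TraitArchitecture(
            h2=dict(arch_raw.get("h2", DEFAULT_H2)),
            Rg=np.array(arch_raw.get("Rg", DEFAULT_RG), dtype=float),
            Re=np.array(arch_raw.get("Re", DEFAULT_RE), dtype=float),
            n_causal=arch_raw.get("n_causal"),
            covariate_loadings=arch_raw.get("covariate_loadings"),
        )
        cfg = cls(
            cohorts=cohorts,
            arch=arch,
            spikes=list(raw.get("spikes", [])),
            covariate_set=raw.get("covariate_set", "model0"),
            pcs=list(raw.get("pcs", [0, 20][: len(cohorts)] or [0])),
            gc=bool(raw.get("gc", True)),
            gws_alpha=float(raw.get("gws_alpha", GWS_ALPHA)),
            sitespec_alpha=float(raw.get("sitespec_alpha", SITESPEC_ALPHA)),
            sitespec_snps=list(raw.get("sitespec_snps", [])),
            conditioning=raw.get("conditioning"),
            relatedness_cutoff=float(raw.get("relatedness_cutoff", 0.025)),
            run_greml=bool(raw.get("run_greml", True)),
            greml_pair=tuple(raw.get("greml_pair", ("LL", "UL"))),
            greml_max_n=raw.get("greml_max_n", 1500),
            seed=seed,
            out_dir=Path(raw.get("out_dir", "results/pipeline")),
        )
        cfg.validate()
        return cfg


def demo_config(out_dir: str | Path = "results/pipeline", seed: int = 0) -> PipelineConfig:
    """Small two-cohort demo: n = 1,000 + 800, m = 2,000 SNPs.

    Spikes one SNP with a skull/upper-limb-specific effect pattern so
    every downstream stage has signal to find.
    """
    cohorts = [
        CohortSpec("COHORT_A", 1000, 2000, seed=seed + 11),
        CohortSpec("COHORT_B", 800, 2000, seed=seed + 12),
    ]
    # sparse causal background (20 of 2,000 SNPs, 1%) keeps the median
    # test statistic near its null value (lambda_GC ~ 1.01-1.03), the
    # inflation regime of a well-controlled polygenic GWAS
    arch = TraitArchitecture(covariate_loadings=None, n_causal=20)
    spike = {
        "snp_id": "snp000100",
        "per_trait_beta": {t: b for t, b in zip(TRAITS, (0.12, 0.02, 0.19, 0.17))},
    }
    cfg = PipelineConfig(
        cohorts=cohorts,
        arch=arch,
        spikes=[spike],
        pcs=[0, 2],
        sitespec_snps=["snp000100"],
        conditioning={
            "target": "snp000100",
            "conditioning": ["snp000101"],
            "trait": "SK",
        },
        greml_max_n=800,
        seed=seed,
        out_dir=Path(out_dir),
    )
    cfg.validate()
    return cfg
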