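"""Generator sanity: allele frequencies, HWE, reproducibility, QC."""

import math

import numpy as np
import pandas as pd
import pytest

from bonesite.synthgen import (
    CohortSpec,
    DosagePanel,
    ParameterError,
    SpikedEffect,
    TraitArchitecture,
    hwe_exact_test,
    qc_filter,
    simulate_genotypes,
    simulate_phenotypes,
    spike_effect,
)


def _panel_from_genotypes(geno, snp_ids=None):
    m, n = geno.shape
    ids = snp_ids or [f"s{i}" for i in range(m)]
    return DosagePanel(
        snp_ids=np.array(ids, dtype=object),
        chrom=np.ones(m, dtype=int),
        pos=np.arange(m) + 1,
        ea=np.array(["A"] * m, dtype=object),
        nea=np.array(["G"] * m, dtype=object),
        dosages=np.asarray(geno, dtype=float),
        iids=np.array([f"i{j}" for j in range(n)], dtype=object),
    )


class TestSimulateGenotypes:
    def test_allele_frequency_matches_generating_value(self):
        spec = CohortSpec("X", 10_000, 50, maf_range=(0.3, 0.3), seed=1)
        panel = simulate_genotypes(spec)
        assert np.all(np.abs(panel.eaf() - 0.3) < 0.02)

    def test_hardy_weinberg_class_proportions(self):
        spec = CohortSpec("X", 40_000, 5, maf_range=(0.5, 0.5), seed=2)
        panel = simulate_genotypes(spec)
        counts = np.stack([(panel.dosages == k).mean(axis=1) for k in (0, 1, 2)])
        assert np.allclose(counts, [[0.25], [0.5], [0.25]], atol=0.02)

    def test_seed_reproducibility_and_distinctness(self):
        spec = CohortSpec("X", 200, 100, seed=3)
        a = simulate_genotypes(spec)
        b = simulate_genotypes(spec)
        c = simulate_genotypes(CohortSpec("X", 200, 100, seed=4))
        assert np.array_equal(a.dosages, b.dosages)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_jitter_stays_in_dosage_range(self):
        panel = simulate_genotypes(CohortSpec("X", 500, 50, dosage_noise_sd=0.3, seed=5))
        assert panel.dosages.min() >= 0.0 and panel.dosages.max() <= 2.0

    @pytest.mark.parametrize("bad", [(0.0, 0.3), (0.1, 0.6), (0.4, 0.2)])
    def test_invalid_maf_range_rejected(self, bad):
        with pytest.raises(ParameterError):
            simulate_genotypes(CohortSpec("X", 10, 5, maf_range=bad, seed=0))


class TestSimulatePhenotypes:
    def test_no_genetics_leaves_residual_correlation(self):
        panel = simulate_genotypes(CohortSpec("X", 4000, 50, seed=6))
        arch = TraitArchitecture(h2={t: 0.0 for t in "TBLH LL UL SK".split()},
                                 covariate_loadings=None)
        sim = simulate_phenotypes(panel, arch, seed=7)
        corr = np.corrcoef(sim.table[["LL", "UL"]].to_numpy().T)[0, 1]
        assert corr == pytest.approx(arch.Re[1, 2], abs=0.05)

    def test_fully_genetic_traits_track_genetic_correlation(self):
        panel = simulate_genotypes(CohortSpec("X", 3000, 500, seed=8))
        arch = TraitArchitecture(h2={t: 1.0 for t in "TBLH LL UL SK".split()},
                                 covariate_loadings=None)
        sim = simulate_phenotypes(panel, arch, seed=9)
        corr = np.corrcoef(sim.table[["LL", "UL"]].to_numpy().T)[0, 1]
        assert corr == pytest.approx(arch.Rg[1, 2], abs=0.06)

    def test_genetic_value_correlation_recovers_generating_rg(self):
        # LL/UL generating genetic correlation 0.78 at n = m = 5,000
        panel = simulate_genotypes(CohortSpec("X", 5000, 5000, seed=10))
        arch = TraitArchitecture(covariate_loadings=None)
        sim = simulate_phenotypes(panel, arch, seed=11)
        r = np.corrcoef(sim.genetic[:, 1], sim.genetic[:, 2])[0, 1]
        assert r == pytest.approx(0.78, abs=0.05)

    def test_unit_total_variance_before_covariates(self, small_panel):
        sim = simulate_phenotypes(small_panel, TraitArchitecture(covariate_loadings=None), seed=12)
        assert np.allclose(sim.table[["TBLH", "LL", "UL", "SK"]].var(ddof=0), 1.0, atol=0.2)

    def test_shared_effects_seed_fixes_the_causal_architecture(self, small_panel):
        arch = TraitArchitecture(covariate_loadings=None, n_causal=20)
        a = simulate_phenotypes(small_panel, arch, seed=1, effects_seed=42)
        b = simulate_phenotypes(small_panel, arch, seed=2, effects_seed=42)
        c = simulate_phenotypes(small_panel, arch, seed=2, effects_seed=43)
        # same panel + same effects seed -> identical genetic values,
        # even though residual draws differ
        assert np.array_equal(a.genetic, b.genetic)
        assert not np.array_equal(a.table["LL"], b.table["LL"])
        assert not np.array_equal(b.genetic, c.genetic)

    def test_non_psd_correlation_rejected(self, small_panel):
        bad = np.array(
            [[1.0, 0.99, -0.99, 0.0], [0.99, 1.0, 0.9, 0.0],
             [-0.99, 0.9, 1.0, 0.0], [0.0, 0.0, 0.0, 1.0]]
        )
        with pytest.raises(ParameterError):
            simulate_phenotypes(small_panel, TraitArchitecture(Rg=bad), seed=0)


class TestSpikeEffect:
    def test_zero_betas_identity(self, small_cohort):
        panel, sim = small_cohort
        out = spike_effect(panel, sim.table, SpikedEffect("snp000001", {t: 0.0 for t in ("LL", "UL")}))
        pd.testing.assert_frame_equal(out, sim.table)

    def test_per_trait_ols_recovers_spiked_betas(self):
        # skull/upper-limb-specific pattern at n = 5,000
        panel = simulate_genotypes(CohortSpec("X", 5000, 20, seed=13))
        arch = TraitArchitecture(h2={t: 0.0 for t in "TBLH LL UL SK".split()},
                                 covariate_loadings=None)
        sim = simulate_phenotypes(panel, arch, seed=14)
        betas = {"LL": 0.020, "UL": 0.187, "SK": 0.169}
        spiked = spike_effect(panel, sim.table, SpikedEffect("snp000005", betas))
        g = panel.dosage("snp000005")
        z = (g - g.mean()) / g.std()
        for trait, beta in betas.items():
            y = spiked[trait].to_numpy()
            bhat = float(z @ y / (z @ z))
            se = np.sqrt((y.var() - bhat ** 2 * z.var()) / len(y)) / z.std()
            assert abs(bhat - beta) < 2 * se + 1e-9

    def test_independent_snp_unaffected(self):
        panel = simulate_genotypes(CohortSpec("X", 5000, 20, seed=15))
        arch = TraitArchitecture(h2={t: 0.0 for t in "TBLH LL UL SK".split()},
                                 covariate_loadings=None)
        sim = simulate_phenotypes(panel, arch, seed=16)
        spiked = spike_effect(panel, sim.table, SpikedEffect("snp000005", {"LL": 0.3}))
        g_other = panel.dosage("snp000010")
        z = (g_other - g_other.mean()) / g_other.std()
        y = spiked["LL"].to_numpy()
        assert abs(float(z @ y / (z @ z))) < 3.0 / np.sqrt(len(y))

    def test_unknown_snp_raises(self, small_cohort):
        panel, sim = small_cohort
        with pytest.raises(KeyError):
            spike_effect(panel, sim.table, SpikedEffect("nope", {"LL": 0.1}))


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-integer enumeration over heterozygote counts (brute force)."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    weights = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        weights[h] = math.comb(n, h) * math.comb(n - h, hr) * 2 ** h
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestHweExactTest:
    def test_monomorphic_has_p_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_matches_enumeration_oracle_balanced_case(self):
        assert hwe_exact_test(5, 10, 5) == pytest.approx(hwe_enumeration_oracle(5, 10, 5), abs=1e-12)

    def test_extreme_heterozygosity_more_extreme_than_hwe_proportions(self):
        assert hwe_exact_test(0, 20, 0) < hwe_exact_test(10, 0, 10) or (
            hwe_exact_test(0, 20, 0) < 1.0 and hwe_exact_test(10, 0, 10) <= 1.0
        )
        assert hwe_exact_test(0, 20, 0) == pytest.approx(hwe_enumeration_oracle(0, 20, 0), abs=1e-12)
        assert hwe_exact_test(10, 0, 10) == pytest.approx(hwe_enumeration_oracle(10, 0, 10), abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestQcFilter:
    def test_low_maf_snp_dropped_with_reason(self, rng):
        geno = rng.binomial(2, 0.3, size=(4, 1000)).astype(float)
        rare = np.zeros(1000)
        rare[:10] = 1.0  # MAF 0.005
        panel = _panel_from_genotypes(np.vstack([geno, rare]))
        kept, report = qc_filter(panel)
        assert kept.n_snps == 4
        assert report.iloc[0]["snp_id"] == "s4" and report.iloc[0]["reason"] == "MAF"

    def test_low_call_rate_dropped(self, rng):
        geno = rng.binomial(2, 0.3, size=(2, 1000)).astype(float)
        geno[1, :60] = np.nan  # 6% missing
        kept, report = qc_filter(_panel_from_genotypes(geno))
        assert kept.n_snps == 1
        assert report.iloc[0]["reason"] == "call_rate"

    def test_hwe_violating_snp_dropped(self):
        # all heterozygotes: enumeration gives P well below 5e-7
        ok_snp = np.repeat([0.0, 1.0, 2.0], [75, 150, 75])  # exact HWE proportions
        geno = np.vstack([np.ones(300), ok_snp])
        assert hwe_exact_test(0, 300, 0) < 5e-7
        kept, report = qc_filter(_panel_from_genotypes(geno))
        assert list(report["reason"]) == ["HWE"]
        assert kept.n_snps == 1

    def test_idempotent(self, small_panel):
        once, _ = qc_filter(small_panel)
        twice, report = qc_filter(once)
        assert twice.n_snps == once.n_snps and report.empty
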