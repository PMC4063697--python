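"""GRM construction, relatedness pruning and REML variance components."""

import itertools

import numpy as np
import pytest

from bonesite import greml
from bonesite.synthgen import (
    CohortSpec,
    DosagePanel,
    TraitArchitecture,
    simulate_genotypes,
    simulate_phenotypes,
)


def _panel(geno):
    m, n = geno.shape
    return DosagePanel(
        snp_ids=np.array([f"s{i}" for i in range(m)], dtype=object),
        chrom=np.ones(m, int), pos=np.arange(m) + 1,
        ea=np.array(["A"] * m, dtype=object), nea=np.array(["G"] * m, dtype=object),
        dosages=np.asarray(geno, dtype=float),
        iids=np.array([f"i{j}" for j in range(n)], dtype=object),
    )


def _grm_hand_formula(geno):
    m, n = geno.shape
    p = geno.mean(axis=1) / 2
    a = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            a[j, k] = np.mean(
                [(geno[i, j] - 2 * p[i]) * (geno[i, k] - 2 * p[i]) / (2 * p[i] * (1 - p[i]))
                 for i in range(m)]
            )
    return a


class TestComputeGrm:
    def test_matches_hand_formula_on_toy_panel(self):
        geno = np.array([[0, 1, 2, 1, 0], [1, 1, 0, 2, 1], [2, 0, 1, 1, 2]], dtype=float)
        grm = greml.compute_grm(_panel(geno))
        assert np.allclose(grm.matrix, _grm_hand_formula(geno), atol=1e-12)
        assert grm.m_snps == 3

    def test_mean_dosage_individual_contributes_zero(self, rng):
        geno = rng.binomial(2, 0.3, size=(200, 50)).astype(float)
        # appending the frequency-matched individual leaves 2p unchanged
        mean_col = geno.mean(axis=1, keepdims=True)
        grm = greml.compute_grm(_panel(np.hstack([geno, mean_col])))
        assert np.allclose(grm.matrix[-1, :], 0.0, atol=1e-12)

    def test_duplicated_individual_identity_by_state(self, rng):
        geno = rng.binomial(2, rng.uniform(0.1, 0.5, 500)[:, None], size=(500, 60)).astype(float)
        geno[:, -1] = geno[:, 0]
        grm = greml.compute_grm(_panel(geno))
        assert grm.matrix[0, -1] == pytest.approx(grm.matrix[0, 0], abs=1e-12)
        assert abs(grm.matrix[0, -1] - 1.0) < 5 / np.sqrt(500)

    def test_offdiagonal_mean_near_zero_for_unrelated_panel(self):
        panel = simulate_genotypes(CohortSpec("U", 200, 1000, seed=41))
        grm = greml.compute_grm(panel)
        n = grm.matrix.shape[0]
        off = grm.matrix[np.triu_indices(n, 1)]
        assert abs(off.mean()) < 3 / np.sqrt(n * 1000)

    def test_monomorphic_snp_asserts(self):
        geno = np.vstack([np.full(10, 2.0), np.random.default_rng(0).binomial(2, 0.4, 10)])
        with pytest.raises(AssertionError):
            greml.compute_grm(_panel(geno.astype(float)))


def _max_independent_set_size(adj):
    n = adj.shape[0]
    best = 0
    for mask in range(1 << n):
        nodes = [i for i in range(n) if mask >> i & 1]
        if len(nodes) <= best:
            continue
        if all(not adj[a, b] for a, b in itertools.combinations(nodes, 2)):
            best = len(nodes)
    return best


class TestPruneRelated:
    def _grm_from_matrix(self, a):
        n = a.shape[0]
        return greml.Grm(matrix=a, ids=np.array([f"i{j}" for j in range(n)], dtype=object), m_snps=100)

    def test_unrelated_set_fully_retained(self, rng):
        a = np.eye(20) + rng.normal(0, 0.005, (20, 20))
        a = (a + a.T) / 2
        grm = self._grm_from_matrix(a)
        assert len(greml.prune_related(grm, 0.025)) == 20

    def test_duplicate_pair_loses_exactly_one(self, rng):
        a = np.eye(10) * 1.0
        a[2, 7] = a[7, 2] = 0.98
        retained = greml.prune_related(self._grm_from_matrix(a), 0.025)
        assert len(retained) == 9 and ("i2" in retained) != ("i7" in retained)

    def test_retained_set_has_no_pair_over_cutoff_and_near_optimal_size(self, rng):
        n = 16
        a = np.eye(n)
        adj = np.zeros((n, n), dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.2:
                a[i, j] = a[j, i] = 0.05
                adj[i, j] = adj[j, i] = True
        grm = self._grm_from_matrix(a)
        retained = greml.prune_related(grm, 0.025)
        idx = [int(s[1:]) for s in retained]
        sub = a[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0)
        assert np.abs(sub).max() <= 0.025
        assert len(retained) >= _max_independent_set_size(adj) - 2


@pytest.fixture(scope="module")
def grm_and_traits():
    """One simulated cohort with two moderately heritable traits."""
    n, m = 1200, 1500
    panel = simulate_genotypes(CohortSpec("G", n, m, seed=50))
    arch = TraitArchitecture(
        trait_names=("LL", "UL"), h2={"LL": 0.4, "UL": 0.4},
        Rg=np.array([[1.0, 0.78], [0.78, 1.0]]),
        Re=np.array([[1.0, 0.55], [0.55, 1.0]]),
        covariate_loadings=None,
    )
    sim = simulate_phenotypes(panel, arch, seed=51)
    return greml.compute_grm(panel), sim.table[["LL", "UL"]].to_numpy()


class TestRemlUnivariate:
    def test_null_trait_estimates_near_zero(self):
        hits = 0
        for seed in range(10):
            panel = simulate_genotypes(CohortSpec("N", 800, 400, seed=60 + seed))
            grm = greml.compute_grm(panel)
            y = np.random.default_rng(160 + seed).normal(size=800)
            est = greml.reml_univariate((y - y.mean()) / y.std(), grm)
            hits += est.v_g < 0.05
        assert hits >= 9

    def test_optimum_beats_grid_search(self, grm_and_traits):
        grm, Y = grm_and_traits
        y = Y[:, 0]
        y = (y - y.mean()) / y.std()
        est = greml.reml_univariate(y, grm)
        d, u = grm.eigen()
        yt, xt = u.T @ y, u.T @ np.ones_like(y)
        grid = [
            -greml._uni_profile_negloglik(h, d, yt, xt)
            for h in np.linspace(1e-6, 1 - 1e-6, 100)
        ]
        opt = -greml._uni_profile_negloglik(est.v_g, d, yt, xt)
        assert opt >= max(grid) - 1e-6

    def test_heritable_trait_recovered_with_sensible_se(self, grm_and_traits):
        grm, Y = grm_and_traits
        y = Y[:, 0]
        est = greml.reml_univariate((y - y.mean()) / y.std(), grm)
        assert abs(est.v_g - 0.4) < 3 * est.se_vg
        assert 0.02 < est.se_vg < 0.3
        assert est.p_lrt < 0.01

    def test_matches_haseman_elston_across_seeds(self):
        diffs = []
        for seed in range(12):
            panel = simulate_genotypes(CohortSpec("HE", 700, 400, seed=80 + seed))
            arch = TraitArchitecture(trait_names=("LL",), h2={"LL": 0.4},
                                     Rg=np.eye(1), Re=np.eye(1), covariate_loadings=None)
            sim = simulate_phenotypes(panel, arch, seed=180 + seed)
            grm = greml.compute_grm(panel)
            y = sim.table["LL"].to_numpy()
            y = (y - y.mean()) / y.std()
            diffs.append(greml.reml_univariate(y, grm).sigma2_g - greml.haseman_elston(y, grm))
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * mc_se + 1e-3


class TestRemlBivariate:
    def test_recovers_generating_correlations(self, grm_and_traits):
        grm, Y = grm_and_traits
        est = greml.reml_bivariate(Y, grm)
        assert est.r_g == pytest.approx(0.78, abs=3 * est.se_rg)
        assert est.r_e == pytest.approx(0.55, abs=3 * est.se_re)
        assert est.p_rg0 < 1e-3
        assert np.all(np.diff(est.trace) >= -1e-9)

    def test_null_correlations_near_zero(self):
        rgs = []
        for seed in range(3):
            panel = simulate_genotypes(CohortSpec("Z", 1500, 1000, seed=70 + seed))
            arch = TraitArchitecture(trait_names=("LL", "UL"), h2={"LL": 0.4, "UL": 0.4},
                                     Rg=np.eye(2), Re=np.eye(2), covariate_loadings=None)
            sim = simulate_phenotypes(panel, arch, seed=170 + seed)
            grm = greml.compute_grm(panel)
            est = greml.reml_bivariate(sim.table[["LL", "UL"]].to_numpy(), grm)
            rgs.append(est.r_g)
        assert abs(np.mean(rgs)) < 0.1

    def test_marginals_match_univariate_when_covariances_fixed_zero(self, grm_and_traits):
        grm, Y = grm_and_traits
        ws = greml._BivarWorkspace(Y, grm)
        v1, v2 = Y[:, 0].var(ddof=1), Y[:, 1].var(ddof=1)
        theta0 = np.array([0.5 * v1, 0.5 * v2, 0.0, 0.5 * v1, 0.5 * v2, 0.0])
        theta, _, _, _ = greml._fit_bivar(ws, theta0, [0, 1, 3, 4])
        for col, (ig, ie) in enumerate([(0, 3), (1, 4)]):
            uni = greml.reml_univariate(Y[:, col], grm)
            assert theta[ig] == pytest.approx(uni.sigma2_g, abs=1e-3 * max(1.0, v1))
            assert theta[ie] == pytest.approx(uni.sigma2_e, abs=1e-3 * max(1.0, v1))

    def test_duplicated_trait_drives_correlations_to_one(self, grm_and_traits):
        grm, Y = grm_and_traits
        y = Y[:, 0]
        est = greml.reml_bivariate(np.column_stack([y, y]), grm)
        assert est.r_g > 0.99 and est.r_e > 0.99


class TestPhenotypicCorrelation:
    def test_identical_vectors_give_unit_correlation(self, rng):
        y = rng.normal(size=100)
        r, se = greml.phenotypic_correlation(y, y)
        assert r == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        r, _ = greml.phenotypic_correlation(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.03

    def test_variance_decomposition_identity_for_standardized_traits(self):
        # r_p = h2 * r_g + (1 - h2) * r_e = 0.4*0.78 + 0.6*0.55 = 0.642
        panel = simulate_genotypes(CohortSpec("P", 5000, 2000, seed=90))
        arch = TraitArchitecture(trait_names=("LL", "UL"), h2={"LL": 0.4, "UL": 0.4},
                                 Rg=np.array([[1, 0.78], [0.78, 1]]),
                                 Re=np.array([[1, 0.55], [0.55, 1]]),
                                 covariate_loadings=None)
        sim = simulate_phenotypes(panel, arch, seed=91)
        r, _ = greml.phenotypic_correlation(sim.table["LL"], sim.table["UL"])
        assert r == pytest.approx(0.64, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            greml.phenotypic_correlation(np.ones(10), np.arange(10.0))
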