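import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import block_expression
from coexnet import (
    bh_fdr,
    build_network,
    correlate_with_trait,
    hypergeometric_overlap,
    membership_significance_validation,
    moderated_t_test,
    permutation_module_validation,
)
from coexnet.errors import (
    ConfigurationError,
    DegenerateInputError,
    UndefinedCorrelationError,
)
from coexnet.stats import pearson_with_p


class TestTraitCorrelation:
    def test_identical_profile_gives_r_one(self):
        trait = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        r, p, n = pearson_with_p(np.array([1.0, 2.0, 3.0, 4.0, 9.9]), trait)
        assert r == 1.0 and p == 0.0 and n == 4

    def test_drinker_only_convention_uses_treated_count(self, small_study):
        cfg, (expr_a, _, info_a, _, _) = small_study
        result = correlate_with_trait(expr_a.head(5), info_a, "ethanol_intake")
        assert (result["n_used"] == cfg.n_treated_a).all()

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, p, n = pearson_with_p(x, y)
            r_ref = np.corrcoef(x, y)[0, 1]
            t_ref = r_ref * math.sqrt((n - 2) / (1 - r_ref ** 2))
            p_ref = 2 * sps.t.sf(abs(t_ref), df=n - 2)
            assert r == pytest.approx(r_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_too_few_usable_samples_is_an_error(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p(np.array([1.0, 2.0, np.nan]), np.array([1.0, 2.0, 3.0]))


class TestModeratedT:
    @pytest.fixture()
    def two_group(self, rng):
        info = pd.DataFrame(
            {"group": ["treated"] * 6 + ["control"] * 6},
            index=[f"s{i}" for i in range(12)],
        )
        expr = pd.DataFrame(
            rng.normal(size=(80, 12)) * np.exp(rng.normal(scale=0.4, size=(80, 1))),
            index=[f"g{i}" for i in range(80)],
            columns=info.index,
        )
        return expr, info

    def test_zero_prior_df_recovers_ordinary_t(self, two_group):
        expr, info = two_group
        de = moderated_t_test(expr, info, prior_df=0)
        treated = info.index[info["group"] == "treated"]
        control = info.index[info["group"] == "control"]
        ref = sps.ttest_ind(expr[treated], expr[control], axis=1)
        assert np.abs(de["t"].to_numpy() - ref.statistic).max() < 1e-10
        assert np.abs(de["p"].to_numpy() - ref.pvalue).max() < 1e-10

    def test_infinite_prior_df_pins_variance_at_prior(self, two_group):
        expr, info = two_group
        de = moderated_t_test(expr, info, prior_df=np.inf)
        # constant denominator: |t| proportional to |log_ratio|
        ratio = np.abs(de["t"] / de["log_ratio"])
        assert ratio.std() / ratio.mean() < 1e-12

    def test_group_too_small_is_degenerate(self, two_group):
        expr, info = two_group
        with pytest.raises(DegenerateInputError):
            moderated_t_test(expr, info.iloc[[0, 1, 2, 6]])

    def test_agrees_with_limma_oracle(self, tmp_path):
        """Independent cross-check against the reference empirical-Bayes
        implementation (limma, run through Rscript) on one fixture."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        x = rng.normal(size=(200, 16)) * np.exp(rng.normal(scale=0.4, size=(200, 1)))
        x[:30, :8] += 1.0
        expr = pd.DataFrame(
            x, index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(16)],
        )
        info = pd.DataFrame(
            {"group": ["treated"] * 8 + ["control"] * 8}, index=expr.columns
        )
        expr_path = tmp_path / "expr.tsv"
        expr.to_csv(expr_path, sep="\t")
        out_path = tmp_path / "limma.csv"
        script = tmp_path / "run.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'x <- as.matrix(read.delim("{expr_path}", row.names=1))\n'
            "design <- cbind(Intercept=1, Treated=c(rep(1,8), rep(0,8)))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            'out <- data.frame(t=fit$t[,"Treated"], p=fit$p.value[,"Treated"])\n'
            f'write.csv(out, "{out_path}")\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[:200]}")
        ref = pd.read_csv(out_path, index_col=0)
        de = moderated_t_test(expr, info)
        assert np.abs(de["t"].to_numpy() - ref["t"].to_numpy()).max() < 1e-6
        assert np.abs(de["p"].to_numpy() - ref["p"].to_numpy()).max() < 1e-8


class TestBHFDR:
    def test_hand_examples(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        assert np.allclose(q[perm], q_perm)


class TestHypergeometricOverlap:
    def test_exact_hand_example(self):
        universe = list(range(10))
        result = hypergeometric_overlap(universe[:4], [0, 1, 2, 4, 5], universe)
        assert result.n_overlap == 3
        assert result.p == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_when_minimum_achievable_is_p_one(self):
        universe = list(range(10))
        result = hypergeometric_overlap([0, 1], [5, 6], universe)
        assert result.p == pytest.approx(1.0)

    def test_full_universe_overlap_is_certain(self):
        universe = list(range(6))
        result = hypergeometric_overlap(universe, universe, universe)
        assert result.n_overlap == 6 and result.p == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            hypergeometric_overlap([1, 99], [1], list(range(10)))

    def test_matches_enumeration_on_small_universes(self):
        """Exhaustive subset enumeration oracle for a spread of shapes."""
        for n_universe, k_a, k_b in [(5, 2, 3), (7, 4, 4), (9, 3, 6), (6, 6, 2)]:
            universe = list(range(n_universe))
            set_a = set(universe[:k_a])
            for overlap in range(max(0, k_a + k_b - n_universe), min(k_a, k_b) + 1):
                total = hits = 0
                for combo in itertools.combinations(universe, k_b):
                    total += 1
                    hits += len(set_a & set(combo)) >= overlap
                set_b = set(universe[:overlap]) | set(
                    universe[k_a : k_a + k_b - overlap]
                )
                result = hypergeometric_overlap(set_a, set_b, universe)
                assert result.n_overlap == overlap
                assert result.p == pytest.approx(hits / total, abs=1e-12)


class TestPermutationValidation:
    def test_whole_universe_module_has_p_one(self, rng):
        expr, _ = block_expression(rng, (30,), loading=2.0)
        net = build_network(expr, power=6)
        assign = pd.Series(1, index=expr.index)
        report = permutation_module_validation(net, assign, n_perm=100, seed=0)
        assert report["empirical_p"].iloc[0] == pytest.approx(1.0)
        assert report["observed_mean_tom"].iloc[0] == pytest.approx(
            report["null_mean_tom"].iloc[0]
        )

    def test_planted_module_minimal_p(self, small_network, small_study):
        _, (expr_a, _, _, _, truth) = small_study
        assign = truth.module_of_gene[expr_a.index]
        report = permutation_module_validation(
            small_network, assign, n_perm=100, seed=1
        )
        assert report["empirical_p"].tolist() == pytest.approx([1 / 101] * 3)

    def test_random_module_p_is_calibrated(self, rng):
        """A 'module' drawn uniformly at random has a uniform p: the fraction
        with p <= 0.05 over 200 repeats stays in the 99% binomial band."""
        expr, _ = block_expression(rng, (40,), loading=2.0, n_background=160)
        net = build_network(expr, power=6)
        hits = 0
        n_rep = 200
        gen = np.random.default_rng(11)
        for _ in range(n_rep):
            members = gen.choice(net.n_genes, size=25, replace=False)
            labels = np.zeros(net.n_genes, dtype=int)
            labels[members] = 1
            assign = pd.Series(labels, index=expr.index)
            report = permutation_module_validation(net, assign, n_perm=99, seed=gen)
            hits += report["empirical_p"].iloc[0] <= 0.05
        band = 2.576 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) <= band

    def test_never_zero_p(self, small_network, small_study):
        _, (expr_a, _, _, _, truth) = small_study
        assign = truth.module_of_gene[expr_a.index]
        report = permutation_module_validation(small_network, assign, n_perm=5, seed=2)
        assert (report["empirical_p"] > 0).all()

    def test_tiny_module_rejected(self, small_network, small_study):
        _, (expr_a, *_rest) = small_study
        assign = pd.Series(0, index=expr_a.index)
        assign.iloc[0] = 1
        with pytest.raises(DegenerateInputError):
            permutation_module_validation(small_network, assign, n_perm=10, seed=0)


@pytest.fixture(scope="module")
def membership_fixture():
    """A trait-coupled module with a wide loading spread: genes that track
    the module summary most strongly also carry the most trait signal."""
    from coexnet import (
        SimConfig,
        compute_membership_and_connectivity,
        generate_study,
    )

    cfg = SimConfig(
        seed=13, n_genes_per_species=250, module_sizes=(60,),
        shared_module_flags=(True,), trait_loading=(0.9,), de_effect=(0.0,),
        within_module_loading_range=(0.3, 1.0), noise_sd=0.6,
    )
    expr_a, _, info_a, _, truth = generate_study(cfg)
    net = build_network(expr_a, power=6)
    assign = truth.module_of_gene[expr_a.index]
    kme, _, _ = compute_membership_and_connectivity(expr_a, net, assign)
    members = assign.index[assign == 1]
    gene_r = correlate_with_trait(
        expr_a.loc[members], info_a, "ethanol_intake"
    ).set_index("entity_id")["r"]
    return kme.loc[members, 1], gene_r


class TestMembershipSignificance:
    def test_planted_signal_module_shows_positive_coupling(
        self, membership_fixture
    ):
        membership, gene_r = membership_fixture
        r, p = membership_significance_validation(membership, gene_r)
        assert r > 0 and p <= 0.01

    def test_shuffled_membership_is_calibrated(self, membership_fixture):
        membership, gene_r = membership_fixture
        members = membership.index
        kme_col = membership
        gen = np.random.default_rng(4)
        hits = 0
        for _ in range(100):
            shuffled = pd.Series(
                gen.permutation(kme_col.to_numpy()), index=members
            )
            _, p = membership_significance_validation(shuffled, gene_r)
            hits += p <= 0.05
        assert hits <= 12  # 99.9% binomial bound at nominal 5%

    def test_two_gene_module_is_an_error(self):
        s = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(DegenerateInputError):
            membership_significance_validation(s, s)
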