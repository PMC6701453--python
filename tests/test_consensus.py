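import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from conftest import random_symmetric_adjacency
from coexnet import (
    ConsensusModuleDetector,
    SimConfig,
    collapse_to_genes,
    consensus_tom,
    cross_tabulate,
    detect_meta_modules,
    generate_study,
    scale_tom,
)
from coexnet.errors import ConfigurationError, EmptyResultError


@pytest.fixture(scope="module")
def consensus_study():
    cfg = SimConfig(
        seed=11, n_genes_per_species=900,
        module_sizes=(60, 60, 60, 60, 60),
        shared_module_flags=(True, True, True, False, False),
        trait_loading=(0.8, 0, 0, 0, 0), de_effect=(0, 1.5, 0, 0, 0),
        within_module_loading_range=(0.8, 1.0), noise_sd=0.6,
        homolog_fraction=700 / 900,
    )
    return cfg, generate_study(cfg)


class TestCollapse:
    def test_highest_mean_probeset_kept_and_single_passthrough(self):
        expr = pd.DataFrame(
            {"s1": [5.0, 7.0, 3.0], "s2": [5.0, 7.0, 3.0]},
            index=["p1", "p2", "p3"],
        )
        annot = pd.DataFrame(
            {"symbol": ["GA", "GA", "GB"], "is_control_probe": [False] * 3},
            index=expr.index,
        )
        collapsed = collapse_to_genes(expr, annot)
        assert collapsed.loc["GA", "s1"] == 7.0  # the mean-7.0 probeset wins
        assert collapsed.loc["GB", "s1"] == 3.0  # single probeset passes through
        assert len(collapsed) == annot["symbol"].nunique()

    def test_tie_broken_by_probeset_id(self):
        expr = pd.DataFrame(
            {"s1": [4.0, 4.0], "s2": [4.0, 4.0]}, index=["pB", "pA"]
        )
        annot = pd.DataFrame(
            {"symbol": ["G", "G"], "is_control_probe": [False, False]},
            index=expr.index,
        )
        collapsed = collapse_to_genes(expr, annot)
        assert len(collapsed) == 1  # deterministically keeps pA (lexicographic)


class TestScaleTom:
    def test_identity_when_already_matched(self, rng):
        tom = random_symmetric_adjacency(rng, 30) * 0.8
        np.fill_diagonal(tom, 1.0)
        assert np.allclose(scale_tom(tom, tom), tom)

    def test_quantile_matched_after_scaling(self, rng):
        t_target = random_symmetric_adjacency(rng, 40) * 0.5
        t_ref = random_symmetric_adjacency(rng, 40) * 0.9
        np.fill_diagonal(t_target, 1.0)
        np.fill_diagonal(t_ref, 1.0)
        scaled = scale_tom(t_target, t_ref, quantile=0.95)
        iu = np.triu_indices(40, k=1)
        assert np.quantile(scaled[iu], 0.95, method="lower") == pytest.approx(
            np.quantile(t_ref[iu], 0.95, method="lower"), abs=1e-8
        )

    def test_scaling_preserves_elementwise_order(self, rng):
        t_target = random_symmetric_adjacency(rng, 25) * 0.4 + 0.01
        t_ref = random_symmetric_adjacency(rng, 25) * 0.9
        np.fill_diagonal(t_target, 1.0)
        np.fill_diagonal(t_ref, 1.0)
        scaled = scale_tom(t_target, t_ref)
        iu = np.triu_indices(25, k=1)
        order = np.argsort(t_target[iu])
        assert (np.diff(scaled[iu][order]) >= -1e-14).all()

    def test_degenerate_quantile_rejected(self, rng):
        tom = random_symmetric_adjacency(rng, 10)
        with pytest.raises(ConfigurationError):
            scale_tom(tom, tom, quantile=1.0)
        flat = np.ones((10, 10))
        with pytest.raises(ConfigurationError):
            scale_tom(flat, tom)


class TestConsensusTom:
    def test_identical_inputs_pass_through(self, rng):
        tom = random_symmetric_adjacency(rng, 15)
        assert np.array_equal(consensus_tom(tom, tom), tom)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 10_000))
    def test_consensus_never_exceeds_either_input(self, n, seed):
        gen = np.random.default_rng(seed)
        a = random_symmetric_adjacency(gen, n)
        b = random_symmetric_adjacency(gen, n)
        cons = consensus_tom(a, b)
        assert (cons <= a).all() and (cons <= b).all()
        # when one input dominates elementwise the other is returned
        assert np.array_equal(consensus_tom(a, np.minimum(a, b)), np.minimum(a, b))

    def test_misaligned_shapes_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            consensus_tom(np.ones((3, 3)), np.ones((4, 4)))


class TestMetaModules:
    def test_shared_modules_recovered_private_suppressed(self, consensus_study):
        cfg, (expr_a, expr_b, info_a, info_b, truth) = consensus_study
        result = detect_meta_modules(
            expr_a, expr_b, truth.homolog_pairs, info_a=info_a, info_b=info_b
        )
        planted = truth.module_of_gene[result.pairs["species_a"]].to_numpy()
        assign = result.assignment.to_numpy()
        shared = np.isin(planted, [1, 2, 3])
        assert adjusted_rand_score(planted[shared], assign[shared]) >= 0.8
        # species-private planted modules leave no meta-module: no meta label
        # captures even half of a private module's genes
        for private in (4, 5):
            members = assign[planted == private]
            members = members[members != 0]
            if len(members):
                top_share = pd.Series(members).value_counts().iloc[0] / (
                    planted == private
                ).sum()
                assert top_share < 0.5

    def test_per_species_trait_correlation_respects_treated_counts(
        self, consensus_study
    ):
        cfg, (expr_a, expr_b, info_a, info_b, truth) = consensus_study
        result = detect_meta_modules(
            expr_a, expr_b, truth.homolog_pairs, info_a=info_a, info_b=info_b
        )
        assert (result.trait_correlations["a"]["n_used"] == cfg.n_treated_a).all()
        assert (result.trait_correlations["b"]["n_used"] == cfg.n_treated_b).all()

    def test_empty_homolog_overlap_is_an_error(self, consensus_study):
        _, (expr_a, expr_b, *_rest) = consensus_study
        empty_map = pd.DataFrame({"species_a": ["zz"], "species_b": ["yy"]})
        with pytest.raises(EmptyResultError):
            detect_meta_modules(expr_a, expr_b, empty_map)

    def test_estimator_wrapper_exposes_fitted_attributes(self, consensus_study):
        _, (expr_a, expr_b, _, _, truth) = consensus_study
        det = ConsensusModuleDetector(power=8).fit(expr_a, expr_b, truth.homolog_pairs)
        assert det.n_modules_ >= 3
        assert len(det.labels_) == len(det.result_.pairs)


class TestCrossTabulate:
    def test_identical_assignments_minimal_diagonal_p(self, rng):
        genes = [f"g{i}" for i in range(120)]
        labels = pd.Series([1] * 40 + [2] * 40 + [0] * 40, index=genes)
        grid = cross_tabulate(labels, labels)
        for m in (1, 2):
            row = grid[grid["meta_module"] == m]
            best = row.loc[row["p"].idxmin(), "species_module"]
            assert best == m
            assert row["p"].min() < 1e-10

    def test_shared_modules_give_row_minimum_at_their_counterpart(
        self, consensus_study
    ):
        cfg, (expr_a, expr_b, _, _, truth) = consensus_study
        result = detect_meta_modules(expr_a, expr_b, truth.homolog_pairs)
        meta = result.assignment_for_species("a")
        planted = truth.module_of_gene[meta.index]
        grid = cross_tabulate(meta, planted)
        for m in sorted(meta[meta != 0].unique()):
            row = grid[grid["meta_module"] == m]
            best = int(row.loc[row["p"].idxmin(), "species_module"])
            assert best in (1, 2, 3)  # a shared planted module

    def test_independent_random_assignments_calibrated(self):
        gen = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        hits = total = 0
        for _ in range(40):
            a = pd.Series(gen.integers(1, 5, size=200), index=genes)
            b = pd.Series(gen.integers(1, 5, size=200), index=genes)
            grid = cross_tabulate(a, b)
            hits += (grid["p"] <= 0.05).sum()
            total += len(grid)
        frac = hits / total
        assert 0.01 <= frac <= 0.1  # near the nominal 5%
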