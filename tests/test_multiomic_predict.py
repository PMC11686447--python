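"""Tests for the multiblock sparse PLS-DA workflow."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from glygolgi.multiomic_predict import (
    OmicsBlockSet,
    build_design,
    cross_validate,
    filter_gene_panel,
    fit_block_splsda,
    predict_classes,
    roc_auc,
    spls_pair,
    stability_select,
    tune_model,
)
from glygolgi.synthetic_data import make_dataset, project_a_spec, project_b_spec


@pytest.fixture(scope="module")
def dataset_a():
    return make_dataset(project_a_spec(seed=3))


@pytest.fixture(scope="module")
def dataset_b():
    return make_dataset(project_b_spec(seed=3))


def separable_blockset(n=40, p=30, seed=0) -> OmicsBlockSet:
    """Two widely separated classes in a single expression block."""
    rng = np.random.default_rng(seed)
    labels = pd.Series(
        ["hi"] * (n // 2) + ["lo"] * (n // 2),
        index=[f"s{i}" for i in range(n)],
    )
    base = rng.uniform(4, 8, size=p)
    counts = rng.poisson(2.0 ** (base + rng.normal(0, 0.2, size=(n, p))))
    counts[: n // 2, :5] = rng.poisson(
        2.0 ** (base[:5] + 3.0 + rng.normal(0, 0.2, size=(n // 2, 5)))
    )
    block = pd.DataFrame(counts, index=labels.index, columns=[f"g{j}" for j in range(p)])
    return OmicsBlockSet(blocks={"day0": block}, labels=labels)


class TestFilterGenePanel:
    def test_full_panel_kept_in_order(self, dataset_a):
        block = dataset_a.blocks.blocks["day0"]
        panel = dataset_a.blocks.gene_panel
        out = filter_gene_panel(block, panel)
        assert list(out.columns) == panel
        assert len(panel) == 76

    def test_missing_gene_warned_not_dropped_silently(self, dataset_a):
        block = dataset_a.blocks.blocks["day0"].drop(columns=["Alg5"])
        panel = dataset_a.blocks.gene_panel
        with pytest.warns(UserWarning, match="Alg5"):
            out = filter_gene_panel(block, panel)
        assert out.shape[1] == 75

    def test_empty_panel_rejected(self, dataset_a):
        with pytest.raises(ValueError):
            filter_gene_panel(dataset_a.blocks.blocks["day0"], [])

    def test_zero_overlap_rejected(self, dataset_a):
        with pytest.raises(ValueError):
            filter_gene_panel(dataset_a.blocks.blocks["day0"], ["NotAGene"])


class TestSplsPair:
    def test_identical_blocks_perfect_correlation(self, rng):
        x = rng.normal(size=(30, 8))
        fit = spls_pair(x, x.copy(), n_components=1)
        r = np.corrcoef(fit["scores_x"][:, 0], fit["scores_y"][:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_shared_latent_factor_recovered(self, rng):
        z = rng.normal(size=50)
        x = np.outer(z, rng.normal(size=12)) + 0.3 * rng.normal(size=(50, 12))
        y = np.outer(z, rng.normal(size=9)) + 0.3 * rng.normal(size=(50, 9))
        fit = spls_pair(x, y, n_components=1, keep_x=6, keep_y=5)
        r = abs(np.corrcoef(fit["scores_x"][:, 0], fit["scores_y"][:, 0])[0, 1])
        assert r >= 0.9

    def test_keepx_one_single_nonzero(self, rng):
        x = rng.normal(size=(20, 10))
        y = rng.normal(size=(20, 6))
        fit = spls_pair(x, y, n_components=1, keep_x=1)
        assert np.count_nonzero(fit["loadings_x"][:, 0]) == 1

    def test_loading_unit_norm(self, rng):
        x = rng.normal(size=(25, 10))
        y = rng.normal(size=(25, 7))
        fit = spls_pair(x, y, n_components=2, keep_x=4, keep_y=3)
        for h in range(2):
            assert np.linalg.norm(fit["loadings_x"][:, h]) == pytest.approx(1.0)


class TestBuildDesign:
    def test_duplicated_block_strongly_connected(self, dataset_a):
        b = dataset_a.blocks.blocks["day0"]
        bs = OmicsBlockSet(
            blocks={"x": b, "y": b.copy()},
            labels=dataset_a.blocks.labels,
            gene_panel=dataset_a.blocks.gene_panel,
        )
        design = build_design(bs)
        assert design.loc["x", "y"] == 1.0

    def test_independent_noise_blocks_weakly_connected(self, dataset_a):
        design = build_design(dataset_a.blocks)
        off_diag = design.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(off_diag == 0.1)

    def test_symmetric_zero_diagonal(self, dataset_a):
        d = build_design(dataset_a.blocks).to_numpy()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)


class TestBlockSplsda:
    def test_separable_training_error_zero(self):
        bs = separable_blockset()
        model = fit_block_splsda(bs, n_components=1, keep_x=5)
        out = predict_classes(model, bs)
        assert (out["predicted"] == bs.labels).all()

    def test_sparsity_honors_keepx(self, dataset_b):
        model = fit_block_splsda(dataset_b.blocks, n_components=2, keep_x=6)
        for block in model.block_names:
            nz = np.count_nonzero(model.loadings[block], axis=0)
            assert list(nz) == [6, 6]

    def test_loadings_unit_norm(self, dataset_b):
        model = fit_block_splsda(dataset_b.blocks, n_components=2, keep_x=6)
        for block in model.block_names:
            norms = np.linalg.norm(model.loadings[block], axis=0)
            np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_keepx_exceeding_width_capped(self, dataset_b):
        model = fit_block_splsda(dataset_b.blocks, n_components=1, keep_x=10_000)
        assert model.keep_x["day0"] == [76]

    def test_missing_feature_error(self):
        bs = separable_blockset()
        model = fit_block_splsda(bs, n_components=1, keep_x=5)
        broken = {"day0": bs.blocks["day0"].drop(columns=["g0"])}
        with pytest.raises(ValueError, match="g0"):
            predict_classes(model, broken)

    def test_scores_finite(self, dataset_b):
        model = fit_block_splsda(dataset_b.blocks, n_components=2, keep_x=6)
        out = predict_classes(model, dataset_b.blocks)
        assert np.isfinite(out["class_scores"].to_numpy()).all()


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], ["n", "n", "p", "p"], "p") == 1.0

    def test_all_ties_half(self):
        assert roc_auc([1.0] * 6, ["p", "n"] * 3, "p") == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], ["p", "p", "p"], "p")

    def test_matches_sklearn_trapezoidal(self, rng):
        """Rank-based AUC equals trapezoidal ROC integration (with ties)."""
        for _ in range(100):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            ours = roc_auc(scores, labels, 1)
            theirs = roc_auc_score(labels, scores)
            assert abs(ours - theirs) < 1e-9


class TestCrossValidation:
    def test_fold_determinism(self, dataset_b):
        design = build_design(dataset_b.blocks)
        a = cross_validate(dataset_b.blocks, design, n_components=2, keep_x=6, seed=9)
        b = cross_validate(dataset_b.blocks, design, n_components=2, keep_x=6, seed=9)
        assert a.fold_selections == b.fold_selections
        pd.testing.assert_frame_equal(a.fold_aucs, b.fold_aucs)

    def test_replicate_groups_not_split(self, dataset_b):
        bs = dataset_b.blocks
        rep = cross_validate(bs, None, n_components=2, keep_x=4, seed=1)
        groups = bs.groups
        for fold in rep.folds:
            fold_groups = set(groups.iloc[fold])
            other = set(groups.iloc[[i for i in range(len(groups)) if i not in fold]])
            # a group in the test fold never also appears in training
            assert not (fold_groups & other)

    def test_selection_frequency_range(self, dataset_b):
        rep = cross_validate(dataset_b.blocks, None, n_components=2, keep_x=6, seed=2)
        f = rep.selection_frequency
        assert ((f["frequency"] >= 0) & (f["frequency"] <= 1)).all()
        assert (f["count"] <= rep.n_folds).all()


class TestStabilitySelection:
    def test_threshold_boundary(self):
        freq = pd.DataFrame(
            {
                "block": ["day0"] * 3,
                "gene": ["a", "b", "c"],
                "count": [10, 7, 6],
                "frequency": [1.0, 0.7, 0.6],
                "screen_count": [10, 10, 10],
            }
        )
        gene_class = pd.DataFrame(
            {"block": ["day0"] * 3, "gene": ["a", "b", "c"], "class": ["x", "x", "y"]}
        )
        report = _report_stub(freq, gene_class)
        stable = stability_select(report, min_folds=7)
        assert sorted(stable["gene"]) == ["a", "b"]

    def test_markers_recovered_at_day0(self, dataset_b):
        """On one fixture: most planted day-0 markers become stable and
        false positives stay within budget (the seed-ensemble sensitivity
        bound lives in the acceptance suite)."""
        design = build_design(dataset_b.blocks)
        rep = cross_validate(dataset_b.blocks, design, n_components=2, keep_x=6, seed=53)
        stable = stability_select(rep)
        day0 = set(stable[stable["block"] == "day0"]["gene"])
        markers = {m.gene for m in dataset_b.true_markers if m.day == "day0"}
        assert len(day0 & markers) / len(markers) >= 0.5
        assert len(day0 - markers) <= 2

    def test_marker_class_annotation(self, dataset_b):
        design = build_design(dataset_b.blocks)
        rep = cross_validate(dataset_b.blocks, design, n_components=2, keep_x=6, seed=53)
        stable = stability_select(rep)
        by_gene = dict(zip(stable["gene"], stable["class"]))
        for m in dataset_b.true_markers:
            if m.gene in by_gene:
                assert by_gene[m.gene] == m.cluster


def _report_stub(freq, gene_class):
    from glygolgi.multiomic_predict import CvReport

    empty = pd.DataFrame()
    return CvReport(
        fold_selections=[],
        fold_aucs=empty,
        selection_frequency=freq,
        gene_class=gene_class,
        pooled_scores=empty,
        pooled_block_scores={},
        labels=pd.Series(dtype=object),
        predicted=pd.Series(dtype=object),
        n_folds=10,
    )


class TestTuning:
    def test_single_point_grid_returned(self, dataset_b):
        out = tune_model(
            dataset_b.blocks,
            None,
            n_components_grid=[2],
            keep_x_grid=[6],
            seed=4,
        )
        assert (out["n_components"], out["keep_x"]) == (2, 6)

    def test_planted_signal_prefers_sparse(self, dataset_b):
        out = tune_model(
            dataset_b.blocks,
            None,
            keep_x_grid=[2, 8, 20, 76],
            seed=4,
        )
        assert out["keep_x"] <= 20

    def test_deterministic(self, dataset_b):
        kw = dict(n_components_grid=[2], keep_x_grid=[2, 8], seed=11)
        a = tune_model(dataset_b.blocks, None, **kw)
        b = tune_model(dataset_b.blocks, None, **kw)
        assert (a["n_components"], a["keep_x"]) == (b["n_components"], b["keep_x"])
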