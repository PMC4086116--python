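"""Decoy-spiking machinery: ROC/AUC identities, determinism, LOOCV design,
category ablation and planted-signal recovery."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mirprio.fixtures import make_bundle
from mirprio.validation import (
    SpikeDesign,
    ablation,
    loocv_targets,
    roc_auc,
    spike_run,
)


class TestRocAuc:
    def test_always_first_gives_auc_one(self):
        assert roc_auc([1] * 10, 20).auc == 1.0

    def test_always_last_gives_auc_zero(self):
        assert roc_auc([20] * 10, 20).auc == 0.0

    def test_uniform_ranks_give_half(self):
        rng = np.random.default_rng(0)
        ranks = rng.integers(1, 21, size=10_000)
        assert roc_auc(ranks.tolist(), 20).auc == pytest.approx(0.5, abs=0.02)

    def test_rank_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        L = 50
        ranks = rng.integers(1, L + 1, size=200)
        fwd = roc_auc(ranks.tolist(), L).auc
        rev = roc_auc((L + 1 - ranks).tolist(), L).auc
        assert fwd + rev == pytest.approx(1.0, abs=1e-12)

    def test_curve_endpoints(self):
        r = roc_auc([3, 7], 10)
        assert r.curve[0][0] == 0.0
        assert r.curve[-1] == (1.0, 1.0)

    def test_out_of_range_rank_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            roc_auc([0], 10)
        with pytest.raises(ValueError, match="out of range"):
            roc_auc([11], 10)


@pytest.fixture(scope="module")
def spiked(small_spec):
    bundle = make_bundle(dataclasses.replace(small_spec, signal_strength=1.0))
    target_mir = bundle.truth.planted_mirs[0]
    target_gene = sorted(bundle.truth.signal_module)[0]
    design = SpikeDesign(n_decoy_mirs=5, n_decoy_genes=29, n_runs=10, rng_seed=13)
    kwargs = dict(
        decoy_mir_pool=sorted(set(bundle.compendium.mirs) - {target_mir}),
        decoy_gene_pool=bundle.genes,
        design=design,
        corpus=bundle.corpus,
        compendium=bundle.compendium,
        training=bundle.training,
        ppi_edges=bundle.ppi_edges,
    )
    return bundle, target_mir, target_gene, design, kwargs


class TestSpikeRun:
    def test_same_seed_is_bit_identical(self, spiked):
        _, tm, tg, _, kwargs = spiked
        a = spike_run(tm, tg, **kwargs)
        b = spike_run(tm, tg, **kwargs)
        assert a == b

    def test_pool_smaller_than_design_raises(self, spiked):
        _, tm, tg, design, kwargs = spiked
        bad = dict(kwargs, decoy_mir_pool=kwargs["decoy_mir_pool"][:3])
        with pytest.raises(ValueError, match="pool"):
            spike_run(tm, tg, **bad)

    def test_dominant_planted_mir_always_ranks_first(self, spiked):
        _, tm, tg, _, kwargs = spiked
        mir_roc, _ = spike_run(tm, tg, **kwargs)
        # strength 1.0: every planted target in the training module
        assert all(r == 1 for r in mir_roc.ranks)

    def test_planted_outranks_decoys_by_rank_sum(self, spiked):
        _, tm, tg, design, kwargs = spiked
        mir_roc, _ = spike_run(tm, tg, **kwargs)
        n = design.n_decoy_mirs + 1
        # each run contributes 1 planted rank; decoys occupy the rest
        decoy_ranks = [
            r for planted in mir_roc.ranks for r in range(1, n + 1) if r != planted
        ]
        stat = mannwhitneyu(mir_roc.ranks, decoy_ranks, alternative="less")
        assert stat.pvalue < 1e-3


class TestLoocv:
    def test_paper_scale_experiment_count(self, small_spec):
        # 4 held-out targets here; the full-scale design (20 per miR x 6 miRs)
        # gives the 120-experiment layout the same way
        bundle = make_bundle(dataclasses.replace(small_spec, signal_strength=1.0))
        mir = bundle.truth.planted_mirs[0]
        targets = sorted(bundle.compendium.genes_of(mir))[:4]
        design = SpikeDesign(n_decoy_mirs=5, n_decoy_genes=20, n_runs=1, rng_seed=3)
        summary = loocv_targets(
            targets, bundle.genes, mir,
            sorted(bundle.compendium.mirs), design,
            bundle.corpus, bundle.compendium, ppi_edges=bundle.ppi_edges,
        )
        assert summary.n_experiments == len(targets)
        assert len(summary.gene_roc.ranks) == len(targets)
        assert 0.0 <= summary.mir_top10_fraction <= summary.mir_top20_fraction <= 1.0

    def test_training_list_of_one_raises(self, small_bundle):
        mir = small_bundle.truth.planted_mirs[0]
        with pytest.raises(ValueError, match="at least 2"):
            loocv_targets(
                ["G0001"], small_bundle.genes, mir,
                sorted(small_bundle.compendium.mirs),
                SpikeDesign(n_decoy_mirs=5, n_decoy_genes=20, rng_seed=0),
                small_bundle.corpus, small_bundle.compendium,
            )


class TestAblation:
    def test_unknown_category_raises(self, spiked):
        _, tm, tg, design, kwargs = spiked
        with pytest.raises(KeyError, match="unknown"):
            ablation([["NotACategory"]], tm, tg, **kwargs)

    def test_empty_subset_raises(self, spiked):
        _, tm, tg, design, kwargs = spiked
        with pytest.raises(ValueError, match="empty"):
            ablation([[]], tm, tg, **kwargs)

    def test_single_category_subsets_give_one_curve_each(self, spiked):
        bundle, tm, tg, design, kwargs = spiked
        subsets = [[c] for c in bundle.corpus.categories]
        out = ablation(subsets, tm, tg, **kwargs)
        assert len(out) == len(subsets)
        for mir_roc, gene_roc in out.values():
            assert len(mir_roc.ranks) == design.n_runs

    def test_inert_categories_do_not_change_aucs(self, spiked):
        # restricting to all categories == no restriction
        bundle, tm, tg, _, kwargs = spiked
        full = spike_run(tm, tg, **kwargs)
        via_ablation = ablation(
            [list(bundle.corpus.categories)], tm, tg, **kwargs
        )[tuple(bundle.corpus.categories)]
        assert via_ablation == full
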