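import itertools
import math

import numpy as np
import pytest

from conftest import random_dna
from wdsvr import baselines, evalmetrics, seqdata, tworound
from wdsvr.seqdata import AffinityDataset
from wdsvr.synthetic import LandscapeSpec, PlantedAnchor, generate_landscape
from wdsvr.wdkernel import SelectedAnchor
from wdsvr.importance import KmerSelection


@pytest.fixture(scope="module")
def landscape():
    spec = LandscapeSpec(
        n=80, L=10, planted_anchors=(PlantedAnchor("GACGT", 3, -1.0, 0.5),),
        baseline=4.0, noise_sd=0.2, affinity_range=(1.0, 1e4), seed=11,
    )
    ds, _ = generate_landscape(spec)
    return ds


def _small_cfg(**kw):
    defaults = dict(
        round1_grid=((2, 0, 0),), round2_grid=((2, 0),),
        n_per_side=3, cv_folds=3, seed=0,
    )
    defaults.update(kw)
    return tworound.PipelineConfig(**defaults)


class TestFitRound1:
    def test_selection_counts_and_determinism(self, landscape):
        train = landscape.subset(range(30))
        m_a, sel_a = tworound.fit_round1(train, d=2, s=0, m=0, n_per_side=5)
        m_b, sel_b = tworound.fit_round1(train, d=2, s=0, m=0, n_per_side=5)
        for k in (1, 2):
            assert len(sel_a.high_affinity(k)) == 5
            assert len(sel_a.low_affinity(k)) == 5
        assert sel_a.per_k == sel_b.per_k
        np.testing.assert_array_equal(m_a.dual_coef, m_b.dual_coef)

    def test_planted_anchor_recovered(self, landscape):
        _m, sel = tworound.fit_round1(landscape, d=5, s=1, m=1)
        assert ("GACGT", 3) in [(kmer, pos) for kmer, pos, _ in sel.high_affinity(5)]

    def test_empty_dataset_rejected(self):
        empty = AffinityDataset(records=(), length=10)
        with pytest.raises(ValueError):
            tworound.fit_round1(empty, 2, 0, 0)


class TestFitRound2:
    def test_vacuous_restriction_equals_plain_wdsvr(self, rng):
        seqs = [random_dna(rng, 8) for _ in range(25)]
        affs = np.exp(np.random.default_rng(1).normal(2.0, 0.4, size=25))
        ds = AffinityDataset.from_arrays(seqs, affs)
        full = KmerSelection(per_k={
            k: {"high_affinity": [], "low_affinity": []} for k in (1, 2)
        })
        for k in (1, 2):
            anchors = [
                ("".join(t), i + 1, 0.0)
                for t in itertools.product("ACGT", repeat=k)
                for i in range(8 - k + 1)
            ]
            full.per_k[k]["high_affinity"] = anchors
        m2 = tworound.fit_round2(ds, full, d=2, s=0, normalize=False)
        m1, _ = tworound.fit_round1(ds, d=2, s=0, m=0, normalize=False)
        test_seqs = [random_dna(rng, 8) for _ in range(10)]
        np.testing.assert_allclose(
            tworound.predict_model(m2, test_seqs),
            tworound.predict_model(m1, test_seqs),
            atol=1e-8,
        )

    def test_empty_selection_rejected(self, landscape):
        with pytest.raises(ValueError, match="empty"):
            tworound.fit_round2(landscape, KmerSelection(), d=2, s=0)

    def test_single_anchor_selection_fits(self, landscape):
        sel = KmerSelection(per_k={5: {
            "high_affinity": [("GACGT", 3, -1.0)], "low_affinity": [],
        }})
        m2 = tworound.fit_round2(landscape, sel, d=5, s=0)
        pred = tworound.predict_model(m2, landscape.sequences[:10])
        assert np.all(np.isfinite(pred))


class TestGridSearch:
    def test_singleton_grid_returned_directly(self, landscape):
        cfg = _small_cfg(round1_grid=((3, 1, 0),))
        assert tworound.grid_search(landscape, cfg, "round1") == (3, 1, 0)

    def test_choice_is_inside_grid(self, landscape):
        grid = ((2, 0, 0), (3, 0, 0), (3, 1, 1))
        cfg = _small_cfg(round1_grid=grid)
        assert tworound.grid_search(landscape, cfg, "round1") in grid

    def test_round2_needs_round1_params(self, landscape):
        cfg = _small_cfg(round2_grid=((2, 0), (3, 0)))
        with pytest.raises(ValueError, match="round1_params"):
            tworound.grid_search(landscape, cfg, "round2")

    def test_degree_recovery_on_planted_5mer(self):
        """CV grid search prefers degrees that can represent the planted
        5-mer (d >= 5) in at least 8 of 10 seeds."""
        wins = 0
        for seed in range(10):
            spec = LandscapeSpec(
                n=120, L=12, planted_anchors=(PlantedAnchor("GACGT", 4, -1.0, 0.5),),
                baseline=4.0, noise_sd=0.2, affinity_range=(1.0, 1e4), seed=seed,
            )
            ds, _ = generate_landscape(spec)
            cfg = _small_cfg(
                round1_grid=tuple((d, 0, 0) for d in range(2, 8)), seed=seed
            )
            d, s, m = tworound.grid_search(ds, cfg, "round1")
            wins += d >= 5
        assert wins >= 8


@pytest.fixture(scope="module")
def result(landscape):
    cfg = _small_cfg(
        round1_grid=((5, 1, 1),), round2_grid=((5, 0),), n_per_side=5, seed=4
    )
    return tworound.fit(landscape, cfg), cfg


class TestEndToEnd:

    def test_chosen_configs_and_counts(self, result):
        res, _cfg = result
        assert res.chosen_configs == {"round1": [5, 1, 1], "round2": [5, 0]}
        assert res.round2_model.kernel_config.restriction == res.selection.anchors(max_k=5)
        assert res.selection.total() == 2 * 5 * 5

    def test_cv_report_has_both_rounds_all_metrics(self, result):
        res, cfg = result
        assert len(res.cv_report["folds"]) == cfg.cv_folds
        for fold in res.cv_report["folds"]:
            for stage in ("round1", "round2"):
                assert set(fold[stage]) == {"rmse", "rmsre", "pearson", "spearman", "n"}

    def test_no_fold_leaks_test_into_selection(self, result):
        res, _cfg = result
        for fold in res.cv_report["folds"]:
            assert fold["selection_input_fingerprint"] == fold["train_fingerprint"]
            assert fold["train_fingerprint"] != fold["test_fingerprint"]

    def test_bit_reproducible(self, landscape, result):
        res, cfg = result
        res2 = tworound.fit(landscape, cfg)
        probe = landscape.sequences[:10]
        np.testing.assert_array_equal(
            tworound.predict(res, probe), tworound.predict(res2, probe)
        )
        assert res.cv_report == res2.cv_report

    def test_serialization_round_trip(self, result, tmp_path):
        res, _cfg = result
        p = tmp_path / "fit.json"
        res.save(p)
        res2 = tworound.FitResult.load(p)
        probe = res.round2_model.training_sequences[:8]
        np.testing.assert_array_equal(
            tworound.predict(res, probe), tworound.predict(res2, probe)
        )

    def test_predict_permutation_equivariant(self, result, landscape):
        res, _cfg = result
        probe = landscape.sequences[:12]
        perm = list(reversed(range(12)))
        p = tworound.predict(res, probe)
        pp = tworound.predict(res, [probe[i] for i in perm])
        np.testing.assert_allclose(pp, p[perm], atol=1e-12)

    def test_training_set_predictions_match_fitted(self, result):
        res, _cfg = result
        seqs = res.round2_model.training_sequences
        np.testing.assert_allclose(
            tworound.predict(res, seqs), res.round2_model.fitted_values, atol=1e-8
        )

    def test_length_mismatch_rejected(self, result):
        res, _cfg = result
        with pytest.raises(ValueError, match="length"):
            tworound.predict(res, ["ACGT"])


class TestZeroNoiseRecovery:
    def test_held_out_spearman_on_noiseless_landscape(self):
        """With no measurement noise and a continuous landscape (small mono
        effects + planted motif), held-out rank correlation of the final
        Round-2 predictor is high (fixed-seed regression check)."""
        W = np.random.default_rng(100).normal(0, 0.08, size=(12, 4))
        spec = LandscapeSpec(
            n=400, L=12,
            planted_anchors=(
                PlantedAnchor("TGACTCA", 3, -1.0, 0.55),
                PlantedAnchor("TATGACTCAT", None, -0.5, 0.10),
            ),
            mono_weights=W, baseline=math.log(150.0), noise_sd=0.0,
            affinity_range=(8.0, 1000.0), seed=0,
        )
        ds, _ = generate_landscape(spec)
        tr, te = seqdata.kfold_split(len(ds), 5, seed=0)[0]
        train, test = ds.subset(tr), ds.subset(te)
        _m1, sel = tworound.fit_round1(train, 7, 1, 1)
        m2 = tworound.fit_round2(train, sel, 7, 0)
        pred = tworound.predict_model(m2, test.sequences)
        assert evalmetrics.spearman(pred, test.affinities) >= 0.9
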