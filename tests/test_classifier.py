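import numpy as np
import pytest

from taglessppi.classifier import (
    GoldStandard,
    LogisticModel,
    cross_validate_scores,
    fdr_at_threshold,
    fit_logistic,
    one_operon_out_folds,
    select_high_confidence,
    threshold_for_fdr,
)
from taglessppi.features import PairFeatures
from taglessppi.iodata import PairKey


def make_features(rows):
    """rows: (a, b, cc_sec, cc_hic, dice, pep, minprot[, n, c, f])"""
    out = []
    for r in rows:
        a, b, *vals = r
        vals = list(vals) + [0.0] * (8 - len(vals))
        out.append(PairFeatures(PairKey(a, b), *vals[:5], *vals[5:8]))
    return out


def separable_gold(n=40, seed=0, spread=3.0):
    """Synthetic feature rows where positives outscore negatives."""
    rng = np.random.default_rng(seed)
    feats, pos, neg = [], set(), set()
    operons = {}
    for i in range(n):
        label = i % 2
        a, b = f"p{2 * i}", f"p{2 * i + 1}"
        pk = PairKey(a, b)
        base = spread if label else -spread
        cc = np.tanh(base + rng.normal(0, 1.0))
        feats.append(
            PairFeatures(pk, cc, np.tanh(base + rng.normal(0, 1.0)),
                         0.25 + 0.2 * label + rng.normal(0, 0.02),
                         min(1.0, 0.5 + 0.3 * label + rng.uniform(0, 0.1)),
                         10 - 5 * label)
        )
        (pos if label else neg).add(pk)
        operons[a] = operons[b] = f"op{i // 4}"  # 4 pairs per operon
    return feats, GoldStandard(frozenset(pos), frozenset(neg), operons)


class TestFolds:
    def test_disjoint_operons_give_disjoint_validation(self):
        operons = {"a1": "O1", "a2": "O1", "b1": "O2", "b2": "O2", "c1": "O3", "c2": "O3"}
        pairs = {PairKey("a1", "a2"), PairKey("b1", "b2"), PairKey("c1", "c2")}
        gold = GoldStandard(frozenset({PairKey("a1", "a2")}),
                            frozenset({PairKey("b1", "b2")}), operons)
        folds = one_operon_out_folds(gold, pairs)
        assert len(folds) == 3
        seen_proteins = []
        for f in folds:
            prots = {p for pk in f.validation_pairs for p in pk}
            seen_proteins.append(prots)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (seen_proteins[i] & seen_proteins[j])

    def test_operon_spanning_pair_validated_twice_trained_never(self):
        operons = {"a": "O1", "b": "O2", "x": "O3", "y": "O3"}
        span = PairKey("a", "b")
        other = PairKey("x", "y")
        gold = GoldStandard(frozenset({span}), frozenset({other}), operons)
        folds = {f.operon_id: f for f in one_operon_out_folds(gold, {span, other})}
        assert span in folds["O1"].validation_pairs
        assert span in folds["O2"].validation_pairs
        assert span not in folds["O1"].train_pairs
        assert span not in folds["O2"].train_pairs
        assert span in folds["O3"].train_pairs

    @pytest.mark.parametrize("seed", range(5))
    def test_no_training_pair_touches_heldout_operon(self, seed):
        rng = np.random.default_rng(seed)
        prots = [f"p{i}" for i in range(30)]
        operons = {p: f"O{rng.integers(8)}" for p in prots}
        def rand_pairs(k):
            out = set()
            while len(out) < k:
                a, b = rng.choice(prots, 2, replace=False)
                out.add(PairKey(str(a), str(b)))
            return frozenset(out)
        pos = rand_pairs(15)
        gold = GoldStandard(pos, rand_pairs(20) - pos, operons)
        cands = rand_pairs(40)
        for fold in one_operon_out_folds(gold, cands):
            members = {p for p, o in operons.items() if o == fold.operon_id}
            for pk in fold.train_pairs:
                assert not pk.touches(members)
            for pk in fold.validation_pairs:
                assert pk.touches(members)

    def test_singletons_form_one_protein_operons(self):
        gold = GoldStandard(frozenset({PairKey("a", "b")}),
                            frozenset({PairKey("c", "d")}), {})
        folds = one_operon_out_folds(gold, {PairKey("a", "b"), PairKey("c", "d")})
        assert {f.operon_id for f in folds} == {"a", "b", "c", "d"}


class TestFitLogistic:
    def test_separable_features_rank_positives_first(self):
        feats, gold = separable_gold(seed=1)
        scores, _ = cross_validate_scores(feats, gold, "MS_ONLY")
        pos_scores = [scores[pk] for pk in gold.positives]
        neg_scores = [scores[pk] for pk in gold.negatives]
        assert min(pos_scores) > max(neg_scores)

    def test_single_class_training_raises(self):
        feats, gold = separable_gold()
        only_pos = GoldStandard(gold.positives, frozenset(), gold.operon_map)
        with pytest.raises(ValueError):
            fit_logistic(feats, only_pos, "MS_ONLY")

    def test_label_permutation_destroys_ranking(self):
        # over >= 20 shuffles the held-out AUC should center near 0.5
        # (leave-operon-out CV is mildly pessimistic at finite n, so the
        # tolerance is one-sided-generous below 0.5 and tight above)
        feats, gold = separable_gold(n=100, seed=2)
        rng = np.random.default_rng(0)
        all_pairs = sorted(gold.positives | gold.negatives)
        aucs = []
        for _ in range(20):
            labels = np.array([1] * len(gold.positives) + [0] * len(gold.negatives))
            rng.shuffle(labels)
            pos = frozenset(pk for pk, y in zip(all_pairs, labels) if y)
            neg = frozenset(pk for pk, y in zip(all_pairs, labels) if not y)
            shuffled = GoldStandard(pos, neg, gold.operon_map)
            scores, _ = cross_validate_scores(feats, shuffled, "MS_ONLY")
            from sklearn.metrics import roc_auc_score

            y = [1 if pk in pos else 0 for pk in all_pairs]
            s = [scores[pk] for pk in all_pairs]
            aucs.append(roc_auc_score(y, s))
        assert 0.35 < np.mean(aucs) < 0.6

    def test_feature_rescaling_preserves_ranking(self):
        feats, gold = separable_gold(seed=3)
        scaled = [
            PairFeatures(f.pair, f.cc_sec * 5.0, f.cc_hic, f.dice, f.peptide_ratio,
                         f.min_proteins, f.string_neighborhood,
                         f.string_cooccurrence, f.string_fusion)
            for f in feats
        ]
        m1 = fit_logistic(feats, gold, "MS_ONLY")
        m2 = fit_logistic(scaled, gold, "MS_ONLY")
        pairs = sorted(gold.positives | gold.negatives)
        fmap1 = {f.pair: f for f in feats}
        fmap2 = {f.pair: f for f in scaled}
        s1 = m1.score(np.array([fmap1[pk].as_tuple(m1.feature_names) for pk in pairs]))
        s2 = m2.score(np.array([fmap2[pk].as_tuple(m2.feature_names) for pk in pairs]))
        assert list(np.argsort(s1)) == list(np.argsort(s2))

    def test_model_save_load_round_trip(self, tmp_path):
        feats, gold = separable_gold(seed=4)
        model = fit_logistic(feats, gold, "MS_ONLY")
        model.save(tmp_path / "model.txt")
        back = LogisticModel.load(tmp_path / "model.txt")
        X = np.array([f.as_tuple(model.feature_names) for f in feats])
        np.testing.assert_array_equal(model.score(X), back.score(X))


class TestCrossValidationConsistency:
    def test_fast_path_equals_explicit_folds(self):
        feats, gold = separable_gold(n=16, seed=5)
        fmap = {f.pair: f for f in feats}
        fast_scores, fast_folds = cross_validate_scores(feats, gold, "MS_ONLY")
        # explicit reference: average held-out score over usable folds
        sums, counts = {}, {}
        for fold in one_operon_out_folds(gold, fmap.keys()):
            try:
                model = fit_logistic(fmap, gold, "MS_ONLY",
                                     train_pairs=fold.train_pairs)
            except ValueError:
                continue
            for pk in fold.validation_pairs:
                s = float(model.score(np.array([fmap[pk].as_tuple(model.feature_names)]))[0])
                sums[pk] = sums.get(pk, 0.0) + s
                counts[pk] = counts.get(pk, 0) + 1
        ref = {pk: sums[pk] / counts[pk] for pk in sums}
        assert set(ref) == set(fast_scores)
        for pk in ref:
            assert fast_scores[pk] == pytest.approx(ref[pk], abs=1e-9)


class TestFdrMachinery:
    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(11)
        pairs = [PairKey(f"a{i}", f"b{i}") for i in range(30)]
        scores = {pk: float(rng.uniform()) for pk in pairs}
        pos = frozenset(pairs[:10])
        neg = frozenset(pairs[10:25])
        gold = GoldStandard(pos, neg, {})
        for t in sorted(scores.values()):
            npos = sum(scores[pk] >= t for pk in pos)
            nneg = sum(scores[pk] >= t for pk in neg)
            expected = nneg / (npos + nneg) if npos + nneg else None
            assert fdr_at_threshold(scores, gold, t) == expected

    def test_clean_threshold_gives_zero_fdr(self):
        gold = GoldStandard(frozenset({PairKey("a", "b")}),
                            frozenset({PairKey("c", "d")}), {})
        scores = {PairKey("a", "b"): 0.9, PairKey("c", "d"): 0.1}
        assert fdr_at_threshold(scores, gold, 0.5) == 0.0

    def test_not_estimable_above_all_gold(self):
        gold = GoldStandard(frozenset({PairKey("a", "b")}),
                            frozenset({PairKey("c", "d")}), {})
        assert fdr_at_threshold({PairKey("a", "b"): 0.2}, gold, 0.9) is None

    def test_toy_threshold_selection(self):
        gold = GoldStandard(
            frozenset({PairKey("p1", "p2"), PairKey("p3", "p4")}),
            frozenset({PairKey("n1", "n2")}), {},
        )
        scores = {PairKey("p1", "p2"): 0.9, PairKey("p3", "p4"): 0.8,
                  PairKey("n1", "n2"): 0.1}
        pred = threshold_for_fdr(scores, gold, target=0.2)
        assert pred.threshold <= 0.8
        assert set(pred.predicted) >= gold.positives
        assert pred.fdr_estimate == 0.0

    def test_vacuous_target_predicts_everything(self):
        gold = GoldStandard(frozenset({PairKey("p1", "p2")}),
                            frozenset({PairKey("n1", "n2")}), {})
        scores = {PairKey("p1", "p2"): 0.9, PairKey("n1", "n2"): 0.1,
                  PairKey("x", "y"): 0.5}
        pred = threshold_for_fdr(scores, gold, target=1.0)
        assert len(pred.predicted) == len(scores)

    def test_unreachable_target_returns_empty_with_warning(self, caplog):
        gold = GoldStandard(frozenset({PairKey("p1", "p2")}),
                            frozenset({PairKey("n1", "n2")}), {})
        scores = {PairKey("p1", "p2"): 0.1, PairKey("n1", "n2"): 0.9}
        with caplog.at_level("WARNING"):
            pred = threshold_for_fdr(scores, gold, target=0.2)
        assert pred.predicted == []
        assert pred.fdr_estimate is None
        assert any("unreachable" in r.message for r in caplog.records)

    def test_staircase_property_lowest_admissible_threshold(self):
        rng = np.random.default_rng(5)
        pairs = [PairKey(f"a{i}", f"b{i}") for i in range(40)]
        scores = {pk: float(rng.normal()) for pk in pairs}
        gold = GoldStandard(frozenset(pairs[:15]), frozenset(pairs[15:30]), {})
        pred = threshold_for_fdr(scores, gold, target=0.3)
        assert fdr_at_threshold(scores, gold, pred.threshold) <= 0.3
        lower = [s for s in set(scores.values()) if s < pred.threshold]
        for t in lower:
            fdr = fdr_at_threshold(scores, gold, t)
            assert fdr is None or fdr > 0.3


class TestSelectHighConfidence:
    def _pred(self):
        scores = {PairKey(f"a{i}", f"b{i}"): i / 10 for i in range(1, 6)}
        gold = GoldStandard(frozenset([PairKey("a5", "b5")]),
                            frozenset([PairKey("a1", "b1")]), {})
        return threshold_for_fdr(scores, gold, target=1.0)

    def test_cut_below_all_scores_is_identity(self):
        pred = self._pred()
        kept, _ = select_high_confidence(pred, None, score_cut=0.0)
        assert kept == pred.predicted

    def test_cut_above_all_scores_is_empty(self):
        pred = self._pred()
        kept, _ = select_high_confidence(pred, None, score_cut=2.0)
        assert kept == []

    def test_reports_metrics_for_both_portions(self):
        pred = self._pred()
        provider = lambda pairs: {"n": float(len(pairs))}
        kept, report = select_high_confidence(pred, provider, score_cut=0.35)
        assert report["kept"]["n"] == len(kept)
        assert report["kept"]["n"] + report["discarded"]["n"] == len(pred.predicted)
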