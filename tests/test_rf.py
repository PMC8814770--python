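"""Composition random forest: features, class scheme, evaluation, scaling."""

import numpy as np
import pandas as pd
import pytest

from capsidarch.g2t import ELONGATED
from capsidarch.rf import (
    AMINO_ACIDS,
    FEATURE_NAMES,
    LogAccuracyModel,
    RFHyperparams,
    accuracy_vs_size,
    build_class_scheme,
    clade_feature_profile,
    compute_features,
    evaluate_classifier,
    feature_analysis,
    featurize_library,
    fit_log_accuracy,
    isoelectric_point,
    load_pka_table,
    train_classifier,
)
from capsidarch.simulate import (
    MCPClassProfile,
    default_class_profiles,
    simulate_mcp_classes,
)


class TestFeatures:
    def test_homopolymer(self):
        fv = compute_features("GGGG")
        assert fv.length == 4
        assert fv.aa_freq["G"] == 1.0
        assert sum(v for aa, v in fv.aa_freq.items() if aa != "G") == 0.0

    def test_uniform_composition(self):
        fv = compute_features(AMINO_ACIDS)
        assert all(v == pytest.approx(0.05) for v in fv.aa_freq.values())
        assert abs(sum(fv.aa_freq.values()) - 1.0) < 1e-9

    def test_ambiguity_codes_excluded(self):
        fv = compute_features("GGXGG")
        assert fv.length == 4
        assert fv.aa_freq["G"] == 1.0

    def test_feature_vector_order_and_size(self):
        arr = compute_features(AMINO_ACIDS).to_array()
        assert arr.shape == (22,)
        assert len(FEATURE_NAMES) == 22
        assert arr[0] == 20  # length first, pI second

    def test_pure_function(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        assert np.array_equal(
            compute_features(seq).to_array(), compute_features(seq).to_array()
        )

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            compute_features("XXXX")


class TestIsoelectricPoint:
    def test_acidic_sequence_below_7(self):
        assert isoelectric_point("DEDEDEDE") < 7

    def test_basic_sequence_above_7(self):
        assert isoelectric_point("KRKRKRKR") > 7

    def test_matches_brute_force_grid_scan(self):
        seq = AMINO_ACIDS
        pka = load_pka_table()
        from capsidarch.rf import _net_charge

        counts = {aa: seq.count(aa) for aa in "KRHDECY"}
        grid = np.arange(0.0, 14.0, 1e-5)
        charges = np.array([_net_charge(ph, counts, pka) for ph in grid])
        brute = grid[np.argmin(np.abs(charges))]
        assert isoelectric_point(seq) == pytest.approx(brute, abs=1e-3)


class TestClassScheme:
    def test_overlapping_ranges_merge(self, scheme):
        # 9 and 9.33 differ by 3.6% -> ranges overlap under a 9% margin
        assert scheme.class_for(9.0) == scheme.class_for(9.33)

    def test_disjoint_ts_stay_separate(self, scheme):
        assert scheme.class_for(4.0) != scheme.class_for(7.0)

    def test_jumbo_grouping(self, scheme):
        classes = {scheme.class_for(t) for t in (25.33, 27.0, 28.0, 31.0, 52.0)}
        assert classes == {scheme.jumbo_class}

    def test_elongated_class_present(self, scheme):
        assert scheme.class_for(ELONGATED) == scheme.elongated_class

    def test_every_label_maps_to_one_class(self, scheme, architectures):
        for arch in architectures:
            if arch.t_float >= 1:
                scheme.class_for(arch.t_float)  # no KeyError

    def test_correctness_margin(self, scheme):
        cls7 = scheme.class_for(7.0)
        assert scheme.is_correct(cls7, 7.0)
        assert scheme.is_correct(cls7, 7.5)  # within 9% of 7.5 is 6.83..8.18
        assert not scheme.is_correct(cls7, 19.0)
        assert not scheme.is_correct(scheme.elongated_class, 7.0)
        assert scheme.is_correct(scheme.elongated_class, ELONGATED)


class TestTraining:
    def test_separable_classes_perfect_training_accuracy(self, sep_library, sep_features):
        y = [str(e.t_label) for e in sep_library]
        model = train_classifier(sep_features, y, seed=0)
        assert (model.predict(sep_features) == np.array(y)).mean() == 1.0

    def test_deterministic_given_seed(self, sep_library, sep_features):
        y = [str(e.t_label) for e in sep_library]
        p1 = train_classifier(sep_features, y, seed=42).predict(sep_features)
        p2 = train_classifier(sep_features, y, seed=42).predict(sep_features)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, sep_features):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(sep_features[:10], ["T=7"] * 10, seed=0)

    def test_label_permutation_gives_chance_accuracy(self, sep_library, sep_features):
        rng = np.random.default_rng(3)
        y = np.array([str(e.t_label) for e in sep_library])
        y_perm = rng.permutation(y)
        n = len(y)
        train = rng.permutation(n)[: int(0.8 * n)]
        test = np.setdiff1d(np.arange(n), train)
        model = train_classifier(sep_features[train], y_perm[train], seed=0)
        acc = (model.predict(sep_features[test]) == y_perm[test]).mean()
        assert abs(acc - 1 / 3) < 0.2  # chance level for 3 balanced classes


class TestEvaluation:
    def test_separable_library_high_accuracy(self, sep_library, scheme, sep_features):
        res = evaluate_classifier(
            sep_library, scheme, n_splits=3, seed=1, features=sep_features
        )
        assert res["overall_accuracy"] > 0.95

    def test_reproducible_given_seed(self, sep_library, scheme, sep_features):
        r1 = evaluate_classifier(sep_library, scheme, n_splits=2, seed=5, features=sep_features)
        r2 = evaluate_classifier(sep_library, scheme, n_splits=2, seed=5, features=sep_features)
        assert r1 == r2

    def test_singleton_class_counted_incorrect_not_crashed(self, g2t_fit, scheme):
        profiles = default_class_profiles()
        library = simulate_mcp_classes(profiles, 30, seed=7, fit=g2t_fit)
        lone = MCPClassProfile(
            "T=13", 13.0, length_mean=450, length_sd=10,
            aa_weights=tuple([1 / 20] * 20),
        )
        library = library + simulate_mcp_classes([lone, profiles[0]], 1, seed=8, fit=g2t_fit)[:1]
        res = evaluate_classifier(
            library, scheme, n_splits=2, seed=2, max_resample=1
        )
        assert 0 <= res["overall_accuracy"] <= 1

    def test_morphology_confusion_with_elongated(self, g2t_fit, scheme):
        profiles = default_class_profiles() + [
            MCPClassProfile(
                ELONGATED, ELONGATED, length_mean=600, length_sd=10,
                aa_weights=tuple(np.full(20, 1 / 20)),
            )
        ]
        library = simulate_mcp_classes(profiles, 40, seed=9, fit=g2t_fit)
        res = evaluate_classifier(library, scheme, n_splits=2, seed=3)
        morph = res["morphology_confusion_mean"]
        assert morph["icosahedral_as_icosahedral"] + morph[
            "icosahedral_as_elongated"
        ] == pytest.approx(100.0)
        assert morph["elongated_as_elongated"] > 50.0


class TestAccuracyScaling:
    def test_noiseless_log_model_recovered(self):
        n = np.array([50, 100, 200, 400, 800])
        table = pd.DataFrame({"n": n, "mean_accuracy": 0.2 * np.log10(n) + 0.3})
        res = fit_log_accuracy(table)
        assert res.g == pytest.approx(0.2, abs=1e-8)
        assert res.h == pytest.approx(0.3, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_n_for_inverts_the_fit(self):
        table = pd.DataFrame(
            {"n": [50, 100, 200], "mean_accuracy": [0.5, 0.56, 0.62]}
        )
        res = fit_log_accuracy(table)
        for target in (0.6, 0.9):
            assert res.predict(res.n_for(target)) == pytest.approx(target, abs=1e-9)
        assert res.n_for(res.h) == pytest.approx(1.0)

    def test_learnable_library_has_positive_slope(self, sep_library, scheme, sep_features):
        table = accuracy_vs_size(
            sep_library, scheme, n_splits_per_size=2, seed=4,
            sizes=[20, 60, 140], features=sep_features,
        )
        res = fit_log_accuracy(table)
        assert res.g > 0

    def test_bootstrap_ci_contains_estimate(self):
        rng = np.random.default_rng(0)
        n = np.array([50, 100, 200, 400, 800, 1600])
        acc = 0.15 * np.log10(n) + 0.35 + rng.normal(0, 0.005, n.size)
        res = LogAccuracyModel(n, acc).fit().bootstrap_ci(n_boot=300, seed=1)
        assert res.ci_g[0] <= res.g <= res.ci_g[1]
        assert res.ci_h[0] <= res.h <= res.ci_h[1]


class TestFeatureAnalysis:
    @pytest.fixture(scope="class")
    def split(self, sep_library, sep_features):
        y = np.array([str(e.t_label) for e in sep_library])
        rng = np.random.default_rng(11)
        n = len(y)
        train = rng.permutation(n)[: int(0.8 * n)]
        test = np.setdiff1d(np.arange(n), train)
        model = train_classifier(sep_features[train], y[train], seed=0)
        return model, sep_features[train], y[train], sep_features[test], y[test]

    def test_all_22_features_reported(self, split):
        model, Xtr, ytr, Xte, yte = split
        table = feature_analysis(model, Xtr, ytr, Xte, yte, mode="permutation", seed=0)
        assert list(table["feature"]) == FEATURE_NAMES

    def test_constant_feature_has_no_effect(self, split):
        model, Xtr, ytr, Xte, yte = split
        # pI is nearly constant across i.i.d. composition classes compared
        # to the determining frequencies; permute a truly constant column
        Xte_const = Xte.copy()
        Xte_const[:, 1] = 7.0
        model2 = train_classifier(
            np.column_stack([Xtr[:, 0:1], np.full((len(ytr), 1), 7.0), Xtr[:, 2:]]),
            ytr, seed=0,
        )
        table = feature_analysis(model2, Xtr, ytr, Xte_const, yte, mode="permutation", seed=0)
        assert abs(table.set_index("feature").loc["pI", "delta"]) < 1e-9

    def test_determining_feature_has_maximal_permutation_delta(self):
        # class label is a deterministic function of one feature column
        rng = np.random.default_rng(2)
        n = 300
        X = rng.normal(size=(n, 22))
        y = np.where(X[:, 5] > 0, "hi", "lo")
        model = train_classifier(X[:200], y[:200], RFHyperparams(min_samples_split=2), seed=0)
        table = feature_analysis(
            model, X[:200], y[:200], X[200:], y[200:], mode="permutation", seed=1
        )
        assert table["delta"].idxmax() == 5

    def test_dropout_mode_retrains_without_feature(self, split):
        model, Xtr, ytr, Xte, yte = split
        table = feature_analysis(
            model, Xtr, ytr, Xte, yte, mode="dropout",
            hyperparams=RFHyperparams(), seed=0,
        )
        assert len(table) == 22
        assert table.attrs["mode"] == "dropout"


class TestCladeProfile:
    def test_whole_library_clade_has_no_significant_features(self, sep_library, sep_features):
        table = clade_feature_profile(
            sep_library, [e.id for e in sep_library], features=sep_features
        )
        assert not table["significant"].any()

    def test_shifted_glycine_flagged(self, g2t_fit):
        base = default_class_profiles(separation=0.0)
        shifted = MCPClassProfile(
            "T=19", 19.0, length_mean=400, length_sd=15,
            aa_weights=tuple(
                np.array(base[0].aa_weights) * 0
                + np.asarray(
                    [(0.3 if aa == "G" else 0.7 / 19) for aa in AMINO_ACIDS]
                )
            ),
        )
        library = simulate_mcp_classes([base[0], base[1], shifted], 40, seed=13, fit=g2t_fit)
        clade_ids = [e.id for e in library if e.t_label == 19.0]
        table = clade_feature_profile(library, clade_ids).set_index("feature")
        assert table.loc["freq_G", "significant"]

    def test_single_mean_entry_not_flagged(self, sep_library, sep_features):
        # an entry sitting exactly at the library mean deviates by 0 < 1 SD
        from capsidarch.library import MCPEntry

        mean_entry = MCPEntry(
            id="at_mean", phage_name="at_mean", sequence="M", genome_kbp=40.0
        )
        library = list(sep_library) + [mean_entry]
        features = np.vstack([sep_features, sep_features.mean(axis=0)])
        table = clade_feature_profile(library, ["at_mean"], features=features)
        assert not table["significant"].any()

    def test_empty_clade_rejected(self, sep_library):
        with pytest.raises(ValueError):
            clade_feature_profile(sep_library, [])
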