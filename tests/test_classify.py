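import numpy as np
import pandas as pd
import pytest

from methylclf import synthetic as syn
from methylclf.classify import (
    LoocvReport,
    loocv_evaluate,
    nsc_discriminant,
    predict_nsc,
    rank_dmp_recurrence,
    roc_auc,
    train_nsc,
)


def _random_instance(n=8, p=5, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(n, p)),
        index=[f"S{i}" for i in range(n)],
        columns=[f"cg{i}" for i in range(p)],
    )
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0])[:n]
    return X, y


def _hand_nsc(X, y, delta):
    """Direct scalar evaluation of the shrunken-centroid formulas."""
    V = X.to_numpy()
    n, p = V.shape
    classes = np.unique(y)
    out = {}
    overall = V.mean(axis=0)
    cents = {}
    s = np.zeros(p)
    for c in classes:
        cents[c] = V[y == c].mean(axis=0)
    for i in range(p):
        ss = 0.0
        for c in classes:
            for row in V[y == c]:
                ss += (row[i] - cents[c][i]) ** 2
        s[i] = np.sqrt(ss / (n - len(classes)))
    s0 = np.median(s)
    d, dp, shrunk = {}, {}, {}
    for c in classes:
        n_k = (y == c).sum()
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
        d[c] = np.array(
            [(cents[c][i] - overall[i]) / (m_k * (s[i] + s0)) for i in range(p)]
        )
        dp[c] = np.sign(d[c]) * np.maximum(np.abs(d[c]) - delta, 0.0)
        shrunk[c] = np.array(
            [overall[i] + m_k * (s[i] + s0) * dp[c][i] for i in range(p)]
        )
    return overall, s, s0, d, dp, shrunk


class TestTrainNsc:
    def test_delta_zero_gives_class_means(self):
        X, y = _random_instance(seed=1)
        model = train_nsc(X, y, delta=0.0)
        for j, c in enumerate(model.classes):
            np.testing.assert_allclose(
                model.class_centroids[:, j], X.to_numpy()[y == c].mean(axis=0), atol=1e-12
            )

    def test_total_shrinkage_collapses_to_overall(self):
        X, y = _random_instance(seed=2)
        big = np.abs(train_nsc(X, y, delta=0.0).d_ik).max() + 1.0
        model = train_nsc(X, y, delta=big)
        for j in range(2):
            np.testing.assert_allclose(
                model.class_centroids[:, j], model.overall_centroid, atol=1e-12
            )
        # posteriors then equal the priors for any input
        _, score = predict_nsc(model, X)
        prior_sev = float(model.priors[model.classes == 1][0])
        np.testing.assert_allclose(score, np.full(len(X), prior_sev), atol=1e-12)

    def test_matches_hand_evaluation(self):
        X, y = _random_instance(n=8, p=5, seed=3)
        delta = 0.7
        model = train_nsc(X, y, delta=delta)
        overall, s, s0, d, dp, shrunk = _hand_nsc(X, y, delta)
        np.testing.assert_allclose(model.overall_centroid, overall, atol=1e-12)
        np.testing.assert_allclose(model.s, s, atol=1e-12)
        assert model.s0 == pytest.approx(s0, abs=1e-12)
        for j, c in enumerate(model.classes):
            np.testing.assert_allclose(model.d_ik[:, j], d[c], atol=1e-12)
            np.testing.assert_allclose(model.d_prime[:, j], dp[c], atol=1e-12)
            np.testing.assert_allclose(model.class_centroids[:, j], shrunk[c], atol=1e-12)

    def test_shrunken_differences_never_grow(self):
        X, y = _random_instance(seed=4)
        model = train_nsc(X, y, delta=0.5)
        assert (np.abs(model.d_prime) <= np.abs(model.d_ik) + 1e-15).all()

    def test_single_class_refused(self):
        X, _ = _random_instance(seed=5)
        with pytest.raises(ValueError, match="single class"):
            train_nsc(X, np.zeros(len(X), dtype=int))

    def test_delta_zero_equals_scaled_nearest_centroid(self):
        # with Δ=0 and equal priors, prediction is nearest centroid in
        # (s_i + s0)-scaled space
        X, y = _random_instance(n=8, p=6, seed=6)
        model = train_nsc(X, y, delta=0.0, priors=np.array([0.5, 0.5]))
        rng = np.random.default_rng(7)
        Xnew = pd.DataFrame(rng.uniform(0, 1, size=(10, 6)), columns=X.columns)
        pred, _ = predict_nsc(model, Xnew)
        scale = model.s + model.s0
        cents = {c: X.to_numpy()[y == c].mean(axis=0) for c in model.classes}
        for i in range(10):
            v = Xnew.iloc[i].to_numpy()
            dists = {c: (((v - cents[c]) / scale) ** 2).sum() for c in model.classes}
            assert pred[i] == min(dists, key=dists.get)


class TestPredictNsc:
    def test_centroid_predicted_as_its_class(self):
        # equal priors so the zero-distance class wins outright
        X, y = _random_instance(seed=8)
        model = train_nsc(X, y, delta=0.2, priors=np.array([0.5, 0.5]))
        x = pd.DataFrame(model.class_centroids[:, 1][None, :], columns=X.columns)
        pred, score = predict_nsc(model, x)
        assert pred[0] == model.classes[1]

    def test_prior_tiebreak(self):
        X, y = _random_instance(seed=9)
        big = np.abs(train_nsc(X, y, delta=0.0).d_ik).max() + 1.0
        model = train_nsc(X, y, delta=big, priors=np.array([0.9, 0.1]))
        # total shrinkage: every input equidistant -> majority (high-prior) class
        pred, _ = predict_nsc(model, X)
        assert (pred == model.classes[0]).all()

    def test_scores_match_bruteforce_discriminant(self):
        X, y = _random_instance(n=8, p=5, seed=10)
        model = train_nsc(X, y, delta=0.3)
        rng = np.random.default_rng(11)
        Xnew = pd.DataFrame(rng.uniform(0, 1, size=(5, 5)), columns=X.columns)
        deltas = nsc_discriminant(model, Xnew)
        for i in range(5):
            v = Xnew.iloc[i].to_numpy()
            for j in range(2):
                expect = (
                    ((v - model.class_centroids[:, j]) ** 2) / (model.s + model.s0) ** 2
                ).sum() - 2 * np.log(model.priors[j])
                assert deltas[i, j] == pytest.approx(expect, abs=1e-12)

    def test_missing_probes_refused(self):
        X, y = _random_instance(seed=12)
        model = train_nsc(X, y)
        with pytest.raises(ValueError, match="missing probe"):
            predict_nsc(model, X.iloc[:, :3])


def _brute_force_auc(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert auc == 1.0

    def test_interleaved(self):
        _, auc, _ = roc_auc([0.9, 0.4, 0.8, 0.3], [1, 0, 1, 0])
        assert auc == pytest.approx(_brute_force_auc([0.9, 0.4, 0.8, 0.3], [1, 0, 1, 0]))

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 1, 0
            _, auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(14)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        _, auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        _, a1, _ = roc_auc(scores, labels)
        _, a2, _ = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_refused(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_delong_ci_contains_auc(self):
        rng = np.random.default_rng(16)
        scores = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 30)]
        labels = np.r_[np.ones(20, int), np.zeros(30, int)]
        _, auc, (lo, hi) = roc_auc(scores, labels)
        assert 0.0 <= lo <= auc <= hi <= 1.0
        assert hi - lo > 0


class TestLoocv:
    def test_separable_cohort_auc_one(self):
        cfg = syn.CohortConfig(
            n_samples=24, n_severe=6, n_probes=800, n_planted_dmps=10,
            delta_beta_range=(0.3, 0.3), noise_sd=0.01, n_batches=1,
            batch_shift_sd=0.0, n_discriminating=100, seed=30,
        )
        beta, sheet, annot, qc, ref, truth = syn.simulate_cohort(cfg)
        report = loocv_evaluate(beta, sheet)
        assert report.auc == 1.0

    def test_label_permuted_null_auc(self):
        aucs = []
        for seed in range(10):
            cfg = syn.CohortConfig(
                n_samples=24, n_severe=6, n_probes=800, n_planted_dmps=10,
                delta_beta_range=(0.3, 0.3), noise_sd=0.01, n_batches=1,
                batch_shift_sd=0.0, n_discriminating=100, seed=40 + seed,
            )
            beta, sheet, annot, qc, ref, truth = syn.simulate_cohort(cfg)
            rng = np.random.default_rng(seed)
            sheet = sheet.copy()
            sheet["group"] = rng.permutation(sheet["group"].to_numpy())
            aucs.append(loocv_evaluate(beta, sheet).auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_recurrence_bounds_and_huge_effect_probe(self):
        cfg = syn.CohortConfig(
            n_samples=20, n_severe=5, n_probes=600, n_planted_dmps=3,
            delta_beta_range=(0.4, 0.4), noise_sd=0.005, n_batches=1,
            batch_shift_sd=0.0, n_discriminating=100, seed=50,
        )
        beta, sheet, annot, qc, ref, truth = syn.simulate_cohort(cfg)
        report = loocv_evaluate(beta, sheet)
        assert (report.recurrence <= report.n_iterations).all()
        # a huge planted effect is selected in every iteration
        assert report.recurrence.loc[list(truth.planted_dmps.index)].eq(
            report.n_iterations
        ).all()

    def test_no_leakage_vs_leaky_selection(self):
        # pure-noise cohort: nested selection stays null while selecting the
        # top probes once on all data demonstrably inflates the AUC
        rng = np.random.default_rng(60)
        n, p = 40, 2000
        sheet = pd.DataFrame(
            {
                "group": ["severe"] * 8 + ["no/mild"] * 32,
                "sex": rng.choice(["M", "F"], n),
                "age_years": rng.uniform(20, 70, n).round(1),
            },
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
        beta = pd.DataFrame(
            rng.normal(0.5, 0.05, size=(p, n)),
            index=[f"cg{i}" for i in range(p)],
            columns=sheet.index,
        )
        nested = loocv_evaluate(beta, sheet)
        assert 0.2 <= nested.auc <= 0.8  # wide per-seed band around 0.5

        # leaky variant: pick top-20 probes by p on the full data first
        from methylclf import dmp as dmp_mod

        table, _ = dmp_mod.run_dmp_analysis(beta, sheet, None, alpha=1.1, min_abs_delta=0.0)
        top = table.sort_values("p").head(20).index
        y = (sheet["group"] == "severe").astype(int)
        scores = []
        for sid in beta.columns:
            train = [s for s in beta.columns if s != sid]
            model = train_nsc(beta.loc[top, train].T, y.loc[train].to_numpy(), delta=0.0)
            _, sc = predict_nsc(model, beta.loc[top, [sid]].T)
            scores.append(sc[0])
        _, leaky_auc, _ = roc_auc(scores, y.to_numpy())
        assert leaky_auc > nested.auc + 0.1
        assert leaky_auc > 0.8

    def test_zero_dmp_folds_scored_at_prior(self):
        rng = np.random.default_rng(61)
        n, p = 20, 300
        sheet = pd.DataFrame(
            {"group": ["severe"] * 4 + ["no/mild"] * 16},
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
        )
        beta = pd.DataFrame(
            rng.normal(0.5, 0.01, size=(p, n)),
            index=[f"cg{i}" for i in range(p)],
            columns=sheet.index,
        )
        report = loocv_evaluate(beta, sheet)
        assert len(report.zero_dmp_folds) == n
        assert (report.records["score"] == 0.2).all()
        assert report.auc == 0.5  # all tied, counted half


class TestRankRecurrence:
    def _report(self, recurrence):
        return LoocvReport(
            records=pd.DataFrame(), roc=pd.DataFrame(), auc=1.0, auc_ci=(1, 1),
            recurrence=pd.Series(recurrence), n_iterations=85,
        )

    def test_recurrence_then_abs_delta(self):
        dmps = pd.DataFrame(
            {"delta_beta": [-0.180, -0.162, -0.129], "p_bonferroni": [0.001, 0.002, 0.005]},
            index=["cgA", "cgB", "cgC"],
        )
        report = self._report({"cgA": 85, "cgB": 85, "cgC": 82})
        ranked = rank_dmp_recurrence(report, dmps)
        assert list(ranked.index) == ["cgA", "cgB", "cgC"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_all_ties_order_by_abs_delta(self):
        dmps = pd.DataFrame(
            {"delta_beta": [0.05, -0.2, 0.1]}, index=["a", "b", "c"]
        )
        report = self._report({"a": 10, "b": 10, "c": 10})
        ranked = rank_dmp_recurrence(report, dmps)
        assert list(ranked.index) == ["b", "c", "a"]

    def test_empty(self):
        ranked = rank_dmp_recurrence(self._report({}), pd.DataFrame())
        assert ranked.empty

    def test_absent_probe_recurrence_zero(self):
        dmps = pd.DataFrame({"delta_beta": [0.1]}, index=["zzz"])
        ranked = rank_dmp_recurrence(self._report({"other": 5}), dmps)
        assert ranked["recurrence"].iloc[0] == 0
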