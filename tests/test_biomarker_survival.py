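"""ROC / Youden threshold / Kaplan-Meier / log-rank biomarker evaluation."""
import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

import pancmetab as pm
from pancmetab.biomarker_survival import (
    kaplan_meier,
    log_rank_test,
    roc_curve,
    youden_threshold,
)


def auc_pair_oracle(values, labels):
    """All-pairs count with ties half-weighted (Mann-Whitney identity)."""
    pos = values[labels.astype(bool)]
    neg = values[~labels.astype(bool)]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def logrank_oracle(ta, ea, tb, eb):
    """Step-by-step hypergeometric risk-table log-rank."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    obs = exp = var = 0.0
    for t in times:
        na, nb = (ta >= t).sum(), (tb >= t).sum()
        n = na + nb
        da = ((ta == t) & ea).sum()
        db = ((tb == t) & eb).sum()
        d = da + db
        obs += da
        exp += d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = (obs - exp) ** 2 / var if var > 0 else 0.0
    return chi2, float(chi2_dist.sf(chi2, 1))


class TestRoc:
    def test_auc_equals_pair_count_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(3, 25, size=2)
            values = np.round(rng.normal(0, 1, n1 + n2), 1)  # induce ties
            labels = np.array([1] * n1 + [0] * n2)
            rng.shuffle(labels)
            roc = roc_curve(values, labels)
            assert roc.auc == pytest.approx(
                auc_pair_oracle(values, labels), abs=1e-12
            )

    def test_perfect_separation(self):
        roc = roc_curve(np.array([1, 2, 3, 10, 11, 12]),
                        np.array([0, 0, 0, 1, 1, 1]))
        assert roc.auc == 1.0

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, 30)
        a = roc_curve(values, labels).auc
        b = roc_curve(values, 1 - labels).auc
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        roc = roc_curve(rng.normal(0, 1, 40), rng.integers(0, 2, 40))
        assert (roc.tpr[0], roc.fpr[0]) == (0.0, 0.0)
        assert (roc.tpr[-1], roc.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.arange(5.0), np.ones(5))


class TestYouden:
    def test_printed_confusion_structure(self):
        # 9 positives (7 above the optimal cut), 8 negatives (6 below):
        # sensitivity 7/9 = 77.78 %, specificity 6/8 = 75.00 %
        pos = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 0.1, 0.2]
        neg = [0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 1.55, 1.65]
        values = np.array(pos + neg)
        labels = np.array([1] * 9 + [0] * 8)
        rep = youden_threshold(roc_curve(values, labels), values=values)
        assert rep.sensitivity == pytest.approx(0.7778, abs=1e-4)
        assert rep.specificity == pytest.approx(0.7500, abs=1e-4)
        assert rep.youden_j == pytest.approx(rep.sensitivity + rep.specificity - 1)
        assert 0.55 < rep.threshold < 1.0  # midpoint between adjacent values

    def test_perfect_separation(self):
        values = np.array([1, 2, 3, 10, 11, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        rep = youden_threshold(roc_curve(values, labels), values=values)
        assert rep.sensitivity == rep.specificity == 1.0
        assert rep.youden_j == 1.0

    def test_no_discrimination(self):
        values = np.full(10, 3.0)
        labels = np.array([0, 1] * 5)
        rep = youden_threshold(roc_curve(values, labels), values=values)
        assert rep.youden_j == 0.0


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(10, 25), 1)
        km = kaplan_meier(t, np.ones(25, dtype=bool))
        for tt in km.event_times:
            assert km.survival_at(tt) == pytest.approx((t > tt).mean(), abs=1e-12)

    def test_all_censored(self):
        km = kaplan_meier([3.0, 5.0, 8.0], [False, False, False])
        assert np.all(km.survival == 1.0)

    def test_single_subject(self):
        km = kaplan_meier([5.0], [True])
        assert km.survival_at(4.999) == 1.0
        assert km.survival_at(5.0) == 0.0

    def test_order_invariance(self):
        t = np.array([4.0, 1.0, 9.0, 2.0, 7.0])
        e = np.array([1, 0, 1, 1, 0], dtype=bool)
        a = kaplan_meier(t, e)
        perm = [2, 0, 4, 1, 3]
        b = kaplan_meier(t[perm], e[perm])
        np.testing.assert_allclose(a.survival, b.survival)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [True, True])


class TestLogRank:
    def test_identical_groups(self):
        t = [2.0, 4.0, 6.0]
        e = [True, True, False]
        res = log_rank_test(t, e, t, e)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle_on_tiny_cases(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            na, nb = rng.integers(2, 6, size=2)
            ta = rng.integers(1, 15, na).astype(float)
            tb = rng.integers(1, 15, nb).astype(float)
            ea = rng.integers(0, 2, na).astype(bool)
            eb = rng.integers(0, 2, nb).astype(bool)
            if not (ea.any() or eb.any()):
                continue
            chi2_o, p_o = logrank_oracle(ta, ea, tb, eb)
            res = log_rank_test(ta, ea, tb, eb)
            assert res["chi2"] == pytest.approx(chi2_o, abs=1e-10)
            assert res["p"] == pytest.approx(p_o, abs=1e-10)

    def test_group_swap_invariance(self):
        ta, ea = [2.0, 5.0, 9.0], [True, True, False]
        tb, eb = [1.0, 3.0, 4.0, 8.0], [True, False, True, True]
        a = log_rank_test(ta, ea, tb, eb)
        b = log_rank_test(tb, eb, ta, ea)
        assert a["chi2"] == pytest.approx(b["chi2"], rel=1e-12)

    def test_no_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            res = log_rank_test([1.0, 2.0], [False, False], [3.0], [False])
        assert res == {"chi2": 0.0, "p": 1.0}


class TestEvaluateBiomarker:
    def _survivor_cohort(self, assignments, seed, ethanolamine_gap_sd=0.0):
        base = pm.load_design("table2").groups[0].stats
        sd = base["ethanolamine"][1]
        lo = dict(base)
        hi = dict(base)
        lo["ethanolamine"] = (
            max(base["ethanolamine"][0] - ethanolamine_gap_sd / 2 * sd, 0.05), sd
        )
        hi["ethanolamine"] = (
            base["ethanolamine"][0] + ethanolamine_gap_sd / 2 * sd, sd
        )
        design = pm.CohortDesign(groups=(
            pm.GroupSpec("long", 8, lo, tissue="PA", survival_group="long"),
            pm.GroupSpec("short", 9, hi, tissue="PA", survival_group="short"),
        ))
        quant, meta = pm.simulate_concentrations(design, seed=seed, assignments=assignments)
        meta = pm.simulate_survival(meta, seed=seed)
        return quant, meta

    def test_signal_cohort_produces_expected_report(self, assignments):
        quant, meta = self._survivor_cohort(assignments, seed=0, ethanolamine_gap_sd=2)
        rep = pm.evaluate_biomarker(quant, meta, "ethanolamine")
        assert rep.roc.auc > 0.5
        assert rep.threshold.youden_j == pytest.approx(
            rep.threshold.sensitivity + rep.threshold.specificity - 1
        )
        assert rep.n_low + rep.n_high == 17
        d = rep.to_dict()
        assert d["metabolite"] == "ethanolamine"

    def test_null_cohort_auc_near_chance(self, assignments):
        # at 8 vs 9 the null AUC has SD ~ sqrt((n+1)/(12 n1 n2)) ~ 0.14, so
        # |AUC - 0.5| < 0.2 holds for ~84 % of cohorts in expectation
        ok = 0
        aucs = []
        for seed in range(60):
            quant, meta = self._survivor_cohort(assignments, seed=seed)
            rep = pm.evaluate_biomarker(quant, meta, "ethanolamine")
            aucs.append(rep.roc.auc)
            ok += abs(rep.roc.auc - 0.5) < 0.2
        assert ok >= 0.72 * 60
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_missing_metabolite_lists_available(self, assignments):
        quant, meta = self._survivor_cohort(assignments, seed=1)
        with pytest.raises(KeyError, match="lactate"):
            pm.evaluate_biomarker(quant, meta, "notathing")

    def test_degenerate_stratum_reports_without_logrank(self, assignments):
        quant, meta = self._survivor_cohort(assignments, seed=2, ethanolamine_gap_sd=2)
        # push every value above any plausible cut except one sample
        quant["ethanolamine"] = 5.0
        quant.iloc[0, quant.columns.get_loc("ethanolamine")] = 0.1
        rep = pm.evaluate_biomarker(quant, meta, "ethanolamine")
        assert rep.logrank is None
        assert rep.warnings
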