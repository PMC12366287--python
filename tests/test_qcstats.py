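"""ΔpH QC windows, encapsulation statistics, crosstalk and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scoph import qcstats, synthgen
from scoph.config import SynthParams
from scoph.qcstats import QCThresholds


THR = QCThresholds()  # printed glucose-rich windows: 0.28 / 1.02 / 0.37


def summaries(rows):
    return pd.DataFrame(rows, columns=["position", "occ_class", "delta_ph"])


class TestApplyQC:
    def test_single_inside_window_kept(self):
        _, out = qcstats.apply_qc(summaries([(0, "SINGLE", 0.50)]), THR)
        assert out.qc_action.tolist() == ["kept"]
        assert out.qc_class.tolist() == ["SINGLE"]

    def test_single_above_window_reclassified_multi(self):
        _, out = qcstats.apply_qc(summaries([(0, "SINGLE", 1.20)]), THR)
        assert out.qc_action.tolist() == ["reclassified_multi"]
        assert out.qc_class.tolist() == ["MULTI"]

    def test_single_below_window_is_debris(self):
        _, out = qcstats.apply_qc(summaries([(0, "SINGLE", 0.10)]), THR)
        assert out.qc_action.tolist() == ["reclassified_empty_debris"]
        assert out.qc_class.tolist() == ["EMPTY"]

    def test_acidifying_empty_is_hidden_cell_error(self):
        _, out = qcstats.apply_qc(summaries([(0, "EMPTY", 0.50)]), THR)
        assert out.qc_action.tolist() == ["error_hidden_cell"]

    def test_missing_trace_excluded(self):
        report, out = qcstats.apply_qc(summaries([(0, "SINGLE", np.nan)]), THR)
        assert out.qc_action.tolist() == ["excluded_no_trace"]
        assert report.counts["SINGLE"]["excluded"] == 1

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["EMPTY", "SINGLE", "MULTI"]),
                st.one_of(st.just(float("nan")), st.floats(0, 2)),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_partition_is_exhaustive_and_exclusive(self, rows):
        df = summaries([(0, c, d) for c, d in rows])
        report, out = qcstats.apply_qc(df, THR)
        for cls, c in report.counts.items():
            n_cls = (df.occ_class == cls).sum()
            assert c["kept"] + c["excluded"] + c["reclassified"] == n_cls
        assert report.n_input == len(df)

    def test_qc_strictly_reduces_classification_error(self):
        # image classes with injected confusions: hidden cells look EMPTY,
        # debris looks SINGLE; ΔpH separates them under the low preset
        rng = np.random.default_rng(5)
        params = SynthParams(seed=0)
        rows, truth = [], []
        for _ in range(150):
            n = rng.poisson(1.0)
            emulsion = "HG" if rng.random() < 0.5 else "UT"
            dph = float(synthgen.sample_delta_ph(1, emulsion, n, params, rng)[0]) if n else params.dph_empty
            true_cls = "EMPTY" if n == 0 else "SINGLE" if n == 1 else "MULTI"
            obs = true_cls
            if true_cls == "SINGLE" and rng.random() < 0.15:
                obs = "EMPTY"  # weakly fluorescent cell missed
            elif true_cls == "EMPTY" and rng.random() < 0.15:
                obs = "SINGLE"  # debris mistaken for a cell
            rows.append((0, obs, dph))
            truth.append(true_cls)
        df = summaries(rows)
        _, out = qcstats.apply_qc(df, QCThresholds.low_acidification())
        before = (df.occ_class != np.array(truth)).sum()
        kept = out.qc_class != "EXCLUDED"
        after = (out.qc_class[kept] != np.array(truth)[kept.to_numpy()]).sum()
        assert after < before


class TestRates:
    def test_basic_efficiency(self):
        rows = [(0, "SINGLE", 0.5)] * 22 + [(0, "EMPTY", 0.1)] * 78
        _, out = qcstats.apply_qc(summaries(rows), THR)
        rates = qcstats.rates(out)
        pooled = rates[rates.position == "pooled"].iloc[0]
        assert pooled.encapsulation_efficiency == pytest.approx(0.22)
        assert pooled.single_error_rate == 0.0

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(11)
        rows = [
            (int(rng.integers(0, 3)), rng.choice(["EMPTY", "SINGLE", "MULTI"]), float(rng.uniform(0, 1.5)))
            for _ in range(500)
        ]
        _, out = qcstats.apply_qc(summaries(rows), THR)
        rates = qcstats.rates(out)
        err_actions = {"reclassified_empty_debris", "reclassified_multi", "error_hidden_cell"}
        for _, r in rates.iterrows():
            sel = out if r.position == "pooled" else out[out.position == r.position]
            singles = sel[sel.occ_class == "SINGLE"]
            expected = sum(a in err_actions for a in singles.qc_action) / len(singles)
            assert r.single_error_rate == pytest.approx(expected)
            kept_singles = ((sel.occ_class == "SINGLE") & (sel.qc_action == "kept")).sum()
            assert r.encapsulation_efficiency == pytest.approx(kept_singles / len(sel))


class TestCrosstalk:
    times = np.arange(0, 181, 5.0)

    def test_identical_populations_ratio_one(self):
        traces = np.full((5, len(self.times)), 800.0)
        res = qcstats.crosstalk_ratio(traces, traces, self.times, seed=0)
        assert np.allclose(res.ratio, 1.0)
        assert res.stable

    def test_retained_probe_is_stable_over_3h(self):
        rng = np.random.default_rng(3)
        pos = 1000.0 + rng.normal(0, 10, (8, len(self.times)))
        neg = 100.0 + rng.normal(0, 2, (8, len(self.times)))
        res = qcstats.crosstalk_ratio(pos, neg, self.times, seed=1)
        assert res.stable
        assert res.n_sample == 3

    def test_leakage_detected_as_drift(self):
        # exponential equilibration of probe between droplet populations
        eq = np.exp(-self.times / 60.0)
        pos = np.tile(100.0 + 900.0 * eq, (5, 1))
        neg = np.tile(1000.0 - 900.0 * eq, (5, 1))
        res = qcstats.crosstalk_ratio(pos, neg, self.times, seed=2)
        assert not res.stable

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            qcstats.crosstalk_ratio(np.empty((0, 5)), np.ones((3, 5)), np.arange(5))


class TestDesignNumbers:
    def test_zero_lambda(self):
        d = qcstats.poisson_design(0.0, 143.0)
        assert d.lam == 0 and d.p_empty == 1.0 and d.p_single == 0.0

    def test_paper_design_point(self):
        # 1.2×10⁷ cells/mL × 143 pL → λ = 1.716; 18% empty, ~31% single, ~52% multi
        d = qcstats.poisson_design(1.2e7, 143.0)
        assert d.lam == pytest.approx(1.716, abs=1e-9)
        assert d.p_empty == pytest.approx(0.180, abs=0.0005)
        assert d.p_single == pytest.approx(0.3085, abs=0.0005)
        assert d.p_multi == pytest.approx(0.512, abs=0.0005)

    @given(st.floats(0, 10))
    def test_probabilities_sum_to_one(self, lam):
        d = qcstats.poisson_design(lam * 1e9, 1.0)
        assert d.p_empty + d.p_single + d.p_multi == pytest.approx(1.0, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            qcstats.poisson_design(-1.0, 143.0)
        with pytest.raises(ValueError):
            qcstats.poisson_design(1.0, 0.0)


class TestGeometry:
    def test_sphere_volume_printed_values(self):
        assert qcstats.droplet_volume(60.0) == pytest.approx(113.1, abs=0.05)
        assert qcstats.droplet_volume(65.0) == pytest.approx(143.8, abs=0.05)

    def test_cubic_scaling(self):
        assert qcstats.droplet_volume(120.0) == pytest.approx(8 * qcstats.droplet_volume(60.0))

    def test_polydispersity_printed_value(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=400)
        d = (d - d.mean()) / d.std(ddof=1)  # exact mean 0, SD 1
        sample = 59.9 + 2.4 * d
        assert qcstats.polydispersity(sample) == pytest.approx(4.0, abs=0.05)

    def test_constant_diameters_zero(self):
        assert qcstats.polydispersity([60.0] * 5) == 0.0

    def test_shift_reduces_cv(self):
        d = np.array([58.0, 60.0, 62.0])
        assert qcstats.polydispersity(d + 10) < qcstats.polydispersity(d)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            qcstats.polydispersity([60.0])
        with pytest.raises(ValueError):
            qcstats.polydispersity([1.0, -1.0])


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        t, p, symbol = qcstats.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and symbol == "ns"

    @pytest.mark.parametrize(
        "p,symbol",
        [(0.2, "ns"), (0.05, "*"), (0.01, "**"), (0.0005, "***")],
    )
    def test_symbol_legend(self, p, symbol):
        assert qcstats.significance_symbol(p) == symbol

    def test_matches_pooled_t_formula(self):
        # closed-form pooled-variance Student's t as the independent oracle
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 30))
            b = rng.normal(0.5, 1.3, rng.integers(3, 30))
            t, p, _ = qcstats.compare_groups(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            from scipy import stats as sps

            p_manual = 2 * sps.t.sf(abs(t_manual), na + nb - 2)
            assert t == pytest.approx(t_manual, abs=1e-10)
            assert p == pytest.approx(p_manual, abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            qcstats.compare_groups([1.0], [1.0, 2.0])


def test_simulated_default_experiment_separates_populations():
    """At λ = 1.716 over 3 windows (507 droplets), kept HG single-cell droplets
    acidify significantly more than UT singles (two-tailed t-test, ***)."""
    rng = np.random.default_rng(123)
    params = SynthParams(seed=0)
    n = 507
    counts = synthgen.sample_occupancy(params.lambda_cells, n, rng)
    emulsions = synthgen.sample_emulsions(n, params.frac_hg, rng)
    rows = []
    for c, e in zip(counts, emulsions):
        dph = params.dph_empty + synthgen.sample_cell_rates(int(c), e, params, rng).sum()
        cls = "EMPTY" if c == 0 else "SINGLE" if c == 1 else "MULTI"
        rows.append({"position": 0, "occ_class": cls, "emulsion": e, "delta_ph": dph})
    df = pd.DataFrame(rows)
    _, out = qcstats.apply_qc(df, QCThresholds.low_acidification())
    kept = out[(out.qc_action == "kept") & (out.qc_class == "SINGLE")]
    hg = kept[kept.emulsion == "HG"].delta_ph
    ut = kept[kept.emulsion == "UT"].delta_ph
    assert len(hg) >= 10 and len(ut) >= 10
    t, p, symbol = qcstats.compare_groups(hg, ut)
    assert hg.mean() > ut.mean()
    assert symbol == "***" and p <= 0.001
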