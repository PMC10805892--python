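"""Copy-state expectation model, ROH_H statistic, DOC ratios and event calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import allokaryo as ak
from allokaryo.karyotype import (
    CopyState,
    KaryotypeConfig,
    classify_state,
    state_grid,
)

from conftest import brute_force_roh


class TestExpectationModel:
    @pytest.mark.parametrize(
        "state,f",
        [((4, 0), 1.0), ((3, 1), 0.75), ((2, 2), 0.5), ((1, 3), 0.25), ((0, 2), 0.0)],
    )
    def test_frequency_grid(self, state, f):
        assert ak.expected_frequency(*state) == f

    @pytest.mark.parametrize("copies,doc", [(4, 2.0), (3, 1.5), (2, 1.0), (0, 0.0), (1, 0.5)])
    def test_doc_grid(self, copies, doc):
        assert ak.expected_doc(copies) == doc

    def test_balanced_states_all_give_half(self):
        for c in (1, 2):
            assert CopyState(c, c).expected_frequency() == 0.5

    def test_frequency_strictly_increasing_in_c_ref_at_fixed_total(self):
        for total in range(1, 6):
            fs = [
                CopyState(c, total - c).expected_frequency()
                for c in range(0, min(total, 4) + 1)
                if total - c <= 4
            ]
            assert all(x < y for x, y in zip(fs, fs[1:]))

    def test_doc_linear_in_copy_number(self):
        for ca, cb in state_grid():
            assert CopyState(ca, cb).expected_doc() == (ca / 2, cb / 2)

    def test_frequency_undefined_at_zero_total(self):
        with pytest.raises(ValueError):
            CopyState(0, 0).expected_frequency()


class TestHomoeologousFrequency:
    def test_balanced_sites(self):
        assert ak.homoeologous_frequency([10, 10, 10], [10, 10, 10]) == 0.5

    def test_exchange_signature(self):
        assert ak.homoeologous_frequency([30] * 5, [10] * 5) == 0.75

    def test_single_site_arithmetic(self):
        assert ak.homoeologous_frequency([7], [3]) == pytest.approx(0.7)

    def test_zero_depth_flagged_missing(self):
        assert np.isnan(ak.homoeologous_frequency([0, 0], [0, 0]))


class TestRohH:
    def test_perfect_balance_is_zero(self):
        chi2, df = ak.roh_h_statistic([5, 9, 2], [5, 9, 2])
        assert chi2 == 0.0 and df == 3

    def test_hand_computed_single_site(self):
        chi2, df = ak.roh_h_statistic([30], [10])
        assert chi2 == pytest.approx(10.0) and df == 1

    def test_zero_depth_sites_do_not_contribute(self):
        chi2, df = ak.roh_h_statistic([3, 0], [1, 0])
        assert chi2 == pytest.approx(1.0) and df == 1

    def test_empty_window_undefined(self):
        with pytest.raises(ValueError):
            ak.roh_h_statistic([], [])
        with pytest.raises(ValueError):
            ak.roh_h_statistic([0], [0])

    @settings(max_examples=500, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)),
            min_size=1,
            max_size=10,
        )
    )
    def test_matches_brute_force_oracle(self, depths):
        a = [d[0] for d in depths]
        b = [d[1] for d in depths]
        if all(x + y == 0 for x, y in depths):
            return
        chi2, df = ak.roh_h_statistic(a, b)
        chi2_o, df_o = brute_force_roh(a, b)
        assert chi2 == pytest.approx(chi2_o) and df == df_o

    def test_null_mean_is_degrees_of_freedom(self):
        # under balanced (2,2) binomial sampling E[chi2] = df
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(50):
            depth = rng.poisson(40, size=500)
            depth = np.maximum(depth, 1)
            a = rng.binomial(depth, 0.5)
            chi2, df = ak.roh_h_statistic(a, depth - a)
            ratios.append(chi2 / df)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)


def _cov_frame(depths_a, depths_b, width=100_000):
    rows = []
    for i, (da, db) in enumerate(zip(depths_a, depths_b)):
        rows.append(("chr1", i * width, (i + 1) * width, "A", da))
        rows.append(("chr1", i * width, (i + 1) * width, "B", db))
    return pd.DataFrame(rows, columns=["pair", "start", "end", "subgenome", "depth"])


class TestDocRatio:
    def test_self_comparison_is_unity(self):
        cov = _cov_frame([4, 5, 4, 6], [4, 4, 5, 4])
        out = ak.doc_ratio(cov, cov)
        assert np.allclose(out["doc_A"], 1.0) and np.allclose(out["doc_B"], 1.0)

    def test_median_normalisation_cancels_library_size(self):
        # accession sequenced twice as deep: ratios still 1
        ref = _cov_frame([4, 5, 4, 6, 5], [4, 4, 5, 4, 5])
        acc = ref.copy()
        acc["depth"] *= 2
        out = ak.doc_ratio(acc, ref)
        assert np.allclose(out["doc_A"], 1.0) and np.allclose(out["doc_B"], 1.0)

    def test_local_gain_scores_above_one(self):
        ref = _cov_frame([4] * 10, [4] * 10)
        acc = _cov_frame([4] * 8 + [6, 6], [4] * 10)
        out = ak.doc_ratio(acc, ref).sort_values("start")
        assert np.allclose(out["doc_A"].iloc[-2:], 1.5)
        assert np.allclose(out["doc_A"].iloc[:8], 1.0)

    def test_zero_reference_window_flagged_missing(self):
        ref = _cov_frame([0, 4, 4], [4, 4, 4])
        acc = _cov_frame([4, 4, 4], [4, 4, 4])
        out = ak.doc_ratio(acc, ref).sort_values("start")
        assert np.isnan(out["doc_A"].iloc[0])

    def test_mismatched_window_sets_refused(self):
        with pytest.raises(ValueError):
            ak.doc_ratio(_cov_frame([1, 2], [1, 2]), _cov_frame([1], [1]))


class TestCatalogDerivation:
    def test_balanced_site_retained_skewed_dropped(self):
        sd = pd.DataFrame(
            {
                "pair": ["chr1"] * 3,
                "pos": [10, 20, 30],
                "a_depth": [20, 39, 3],
                "b_depth": [20, 1, 2],
            }
        )
        out = ak.derive_homoeologous_catalog(sd)
        assert list(out["pos"]) == [10]  # 39/1 skewed; 3/2 under-covered

    def test_empty_input_empty_catalog(self):
        sd = pd.DataFrame(columns=["pair", "pos", "a_depth", "b_depth"])
        assert len(ak.derive_homoeologous_catalog(sd)) == 0

    def test_euploid_simulation_retains_most_true_sites(self):
        params = ak.SimulationParams(
            n_chromosome_pairs=1,
            chromosome_length=500_000,
            homoeologous_site_density=0.02,
            repeat_fraction_profile=0.0,
            coverage_per_copy=20.0,
            sequencing_error=0.0,
            seed=8,
        )
        ref = ak.simulate_reference(params)
        truth = ak.inject_karyotype(ref, [], accessions=["ref_acc"])
        obs = ak.simulate_observables(ref, truth, params)
        sd = obs.accession_site_depth("ref_acc")
        kept = ak.derive_homoeologous_catalog(sd)
        assert len(kept) / len(sd) >= 0.95


class TestFitCopyState:
    def test_heterozygous_exchange_signature(self):
        fit = ak.fit_copy_state(0.75, 1.5, 0.5)
        assert fit.state == (3, 1) and fit.m == 1.0 and not fit.mosaic

    def test_euploid(self):
        fit = ak.fit_copy_state(0.5, 1.0, 1.0)
        assert fit.state == (2, 2) and not fit.mosaic and fit.residual == 0.0

    def test_halfway_mixture_detected_as_mosaic(self):
        fit = ak.fit_copy_state(0.625, 1.25, 0.75)
        assert fit.mosaic and fit.state == (3, 1)
        assert fit.m == pytest.approx(0.5, abs=0.01)

    def test_all_grid_states_recover_exactly(self):
        for ca, cb in state_grid():
            cs = CopyState(ca, cb)
            da, db = cs.expected_doc()
            fit = ak.fit_copy_state(cs.expected_frequency(), da, db)
            assert fit.state == (ca, cb), (ca, cb)
            assert not fit.mosaic

    def test_tie_broken_toward_euploid(self):
        # doc-only observation equidistant between (2,2) and, e.g., (3,1)
        fit = ak.fit_copy_state(np.nan, 1.25, 0.75)
        assert fit.state == (2, 2) or fit.mosaic is True

    def test_doc_only_fit_without_frequency(self):
        fit = ak.fit_copy_state(np.nan, 1.5, 1.0)
        assert fit.state == (3, 2)

    def test_all_missing_refused(self):
        with pytest.raises(ValueError):
            ak.fit_copy_state(np.nan, np.nan, np.nan)


class TestClassification:
    @pytest.mark.parametrize(
        "state,whole,expected",
        [
            ((3, 1), False, ("homoeologous_exchange", "heterozygous")),
            ((1, 3), False, ("homoeologous_exchange", "heterozygous")),
            ((4, 0), False, ("homoeologous_exchange", "homozygous")),
            ((0, 4), False, ("homoeologous_exchange", "homozygous")),
            ((1, 2), False, ("deletion", "heterozygous")),
            ((0, 2), False, ("deletion", "homozygous")),
            ((3, 2), False, ("duplication", "heterozygous")),
            ((3, 2), True, ("aneuploidy_gain", "heterozygous")),
            ((1, 2), True, ("aneuploidy_loss", "heterozygous")),
        ],
    )
    def test_event_taxonomy(self, state, whole, expected):
        assert classify_state(*state, mosaic=False, whole_chromosome=whole) == expected

    def test_mosaic_zygosity_propagates(self):
        assert classify_state(3, 1, mosaic=True, whole_chromosome=False)[1] == "mosaic"

    def test_whole_chromosome_exchange_stays_exchange(self):
        etype, _ = classify_state(4, 0, mosaic=False, whole_chromosome=True)
        assert etype == "homoeologous_exchange"


def _run_scan(events, seed, params=None, config=None):
    params = params or ak.SimulationParams(
        n_chromosome_pairs=4,
        chromosome_length=1_500_000,
        homoeologous_site_density=0.02,
        coverage_per_copy=5.0,
        seed=seed,
    )
    ref = ak.simulate_reference(params)
    truth = ak.inject_karyotype(ref, events, accessions=["reference", "acc"])
    obs = ak.simulate_observables(ref, truth, params)
    model = ak.KaryotypeModel.from_observables(obs, "acc", "reference", ref, config)
    return ref, model.fit()


class TestSegmentEvents:
    def test_heterozygous_exchange_recovered(self):
        ref, res = _run_scan(
            [ak.exchange("acc", "chr1", 500_000, 1_500_000, toward="A")], seed=21
        )
        evs = [e for e in res.events if e.pair == "chr1"]
        assert len(evs) == 1
        e = evs[0]
        assert e.type == "homoeologous_exchange" and e.zygosity == "heterozygous"
        assert (e.c_ref, e.c_other) == (3, 1)
        # boundary within one genomic window of the truth
        win = res.window_fits[res.window_fits["pair"] == "chr1"]
        spans = (win["end"] - win["start"]).to_numpy()
        assert abs(e.start - 500_000) <= spans.max()
        assert e.end == 1_500_000

    def test_exchange_conserves_total_doc(self):
        ref, res = _run_scan(
            [ak.exchange("acc", "chr1", 500_000, 1_500_000)], seed=22
        )
        e = next(ev for ev in res.events if ev.type == "homoeologous_exchange")
        win = res.window_fits
        inside = win[
            (win["pair"] == "chr1") & (win["start"] >= e.start) & (win["end"] <= e.end)
        ]
        assert np.allclose(inside["doc_A"] + inside["doc_B"], 2.0, atol=0.1)

    def test_deletion_breaks_total_doc(self):
        ref, res = _run_scan(
            [ak.deletion("acc", "chr2", 0, 800_000, "A")], seed=23
        )
        e = next(ev for ev in res.events if ev.type == "deletion")
        win = res.window_fits
        inside = win[
            (win["pair"] == "chr2") & (win["start"] >= e.start) & (win["end"] <= e.end)
        ]
        assert (inside["doc_A"] + inside["doc_B"]).mean() < 1.8

    def test_whole_chromosome_trisomy_is_aneuploidy_gain(self):
        ref, res = _run_scan(
            [ak.TruthEvent("acc", "chr3", 0, 1_500_000, 3, 2)], seed=24
        )
        evs = [e for e in res.events if e.pair == "chr3"]
        assert len(evs) == 1
        assert evs[0].type == "aneuploidy_gain"
        assert evs[0].span >= 0.95 * 1_500_000

    def test_euploid_yields_no_events(self):
        ref, res = _run_scan([], seed=25)
        assert res.events == []

    def test_events_below_minimum_size_dropped(self):
        cfg = KaryotypeConfig(min_event_size=2_000_000)
        ref, res = _run_scan(
            [ak.exchange("acc", "chr1", 500_000, 1_500_000)], seed=26, config=cfg
        )
        assert res.events == []

    def test_plot_chromosome_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        ref, res = _run_scan(
            [ak.exchange("acc", "chr1", 500_000, 1_500_000)], seed=28
        )
        axes = res.plot_chromosome("chr1")
        assert len(axes) == 2
        import matplotlib.pyplot as plt

        plt.close("all")

    def test_summary_and_report_roundtrip(self, tmp_path):
        from allokaryo.report import events_from_bed, write_reports

        ref, res = _run_scan(
            [ak.exchange("acc", "chr1", 500_000, 1_500_000)], seed=27
        )
        assert "homoeologous_exchange" in res.summary()
        write_reports(res, tmp_path)
        bed = events_from_bed(tmp_path / "acc.events.bed")
        assert len(bed) == len(res.events)
        e = res.events[0]
        row = bed.iloc[0]
        assert (row["chrom"], row["start"], row["end"]) == (e.pair, e.start, e.end)
        assert (row["type"], row["zygosity"]) == (e.type, e.zygosity)
        assert (row["c_ref"], row["c_other"]) == (e.c_ref, e.c_other)
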