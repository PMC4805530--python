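"""Read-count histograms, EM mixture fitting, and threshold calibration."""

import numpy as np
import pandas as pd
import pytest

from l1audit import readcount_model as rcm
from l1audit import synthetic
from l1audit.records import GoldStandardSet, Locus, ValidationError
from l1audit.synthetic import KnrMixture


def _gold(loci, ind="ind1"):
    return {
        ind: GoldStandardSet(
            ind, "rcseq", frozenset(loci),
            pd.DataFrame({"included": [True] * len(loci)}),
        )
    }


def _calls(rows, ind="ind1", cls="knr_call"):
    """rows: (sample_id, contig, start, read_count)"""
    return pd.DataFrame(
        {
            "sample_id": [r[0] for r in rows],
            "individual_id": [ind] * len(rows),
            "material": ["single_cell"] * len(rows),
            "cell_type": ["hippocampal_neuron"] * len(rows),
            "contig": [r[1] for r in rows],
            "start": [r[2] for r in rows],
            "end": [r[2] + 1 for r in rows],
            "read_count": [r[3] for r in rows],
            "junctions": ["both"] * len(rows),
            "prior_study": [True] * len(rows),
            "prior_rcseq_only": [False] * len(rows),
            "candidate_class": [cls] * len(rows),
            "score": [np.nan] * len(rows),
        }
    )


class TestHistogram:
    def test_per_sample_counting(self):
        gold = _gold([Locus("chr1", 100, 101)])
        calls = _calls([("A", "chr1", 100, 5), ("B", "chr1", 100, 1)])
        hist = rcm.per_sample_histogram(calls, gold, "knr_single_cell")
        assert hist.counts == {1: 1, 5: 1}
        assert hist.n_total == 2

    def test_dropout_contributes_nothing(self):
        gold = _gold([Locus("chr1", 100, 101), Locus("chr2", 5, 6)])
        calls = _calls([("A", "chr1", 100, 5)])  # chr2 locus dropped out
        hist = rcm.per_sample_histogram(calls, gold, "knr_single_cell")
        assert hist.n_total == 1

    def test_population_reference_mismatch(self, tiny_call_frame):
        with pytest.raises(ValidationError, match="gold"):
            rcm.per_sample_histogram(tiny_call_frame, None, "knr_single_cell")
        with pytest.raises(ValidationError, match="somatic"):
            rcm.per_sample_histogram(
                tiny_call_frame, _gold([]), "somatic_single_cell"
            )

    def test_simulated_histogram_matches_truth_oracle(self, cohort, gold_sets):
        calls, _, truth = cohort
        hist = rcm.per_sample_histogram(calls, gold_sets, "knr_single_cell")
        # oracle: walk raw rows with truth labels and gold membership
        gold_keys = {
            (ind, l.contig, l.start, l.end)
            for ind, gs in gold_sets.items() for l in gs.loci
        }
        expected: dict[int, int] = {}
        for idx, row in calls.iterrows():
            if row["material"] != "single_cell":
                continue
            if truth.labels[idx] != "knr_true":
                continue
            key = (row["individual_id"], row["contig"], row["start"],
                   row["end"])
            if key in gold_keys:
                expected[row["read_count"]] = expected.get(
                    row["read_count"], 0) + 1
        assert hist.counts == expected

    def test_counting_conserves_calls(self, cohort, gold_sets):
        calls, _, _ = cohort
        knr = rcm.per_sample_histogram(calls, gold_sets, "knr_single_cell")
        som = rcm.per_sample_histogram(calls, None, "somatic_single_cell")
        sc = calls[calls["material"] == "single_cell"]
        n_som = (sc["candidate_class"] == "somatic_candidate").sum()
        assert som.n_total == n_som
        assert knr.n_total <= (sc["candidate_class"] == "knr_call").sum()


class TestMixtureFit:
    def test_pure_low_component_recovered(self):
        rng = np.random.default_rng(0)
        counts = rng.geometric(0.6, size=2000)
        hist = rcm.ReadCountHistogram(
            counts=dict(zip(*np.unique(counts, return_counts=True))),
            population="knr_single_cell",
        )
        fit = rcm.fit_two_component_mixture(hist)
        assert fit.weight_low >= 0.99

    def test_loglik_monotone_nondecreasing(self, cohort, gold_sets):
        calls, _, _ = cohort
        hist = rcm.per_sample_histogram(calls, gold_sets, "knr_single_cell")
        fit = rcm.fit_two_component_mixture(hist)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-7 * np.abs(trace[:-1])).all()
        assert fit.converged

    def test_small_sample_refused(self):
        hist = rcm.ReadCountHistogram(
            counts={1: 10, 40: 5}, population="knr_single_cell"
        )
        with pytest.raises(ValidationError, match="50"):
            rcm.fit_two_component_mixture(hist)

    def test_degenerate_single_count_falls_back(self):
        hist = rcm.ReadCountHistogram(
            counts={2: 100}, population="knr_single_cell"
        )
        fit = rcm.fit_two_component_mixture(hist)
        assert fit.fallback
        assert fit.weight_high in (0.0, 1.0)

    @pytest.mark.parametrize("w_high", [0.25, 1 / 3, 0.5])
    def test_weight_recovery(self, w_high):
        """EM recovers the high-component weight at n=4000 (a few seeds; the
        20-seed grid runs in the acceptance suite)."""
        mix = KnrMixture(weight_low=1 - w_high)
        for seed in range(3):
            rng = synthetic.stream_rng(seed, "knr")
            counts = synthetic._mixture_counts(rng, mix, 4000)
            hist = rcm.ReadCountHistogram(
                counts=dict(zip(*np.unique(counts, return_counts=True))),
                population="knr_single_cell",
            )
            fit = rcm.fit_two_component_mixture(hist)
            assert abs(fit.weight_high - w_high) < 0.05


@pytest.fixture(scope="module")
def gold_fit():
    mix = KnrMixture()
    rng = synthetic.stream_rng(123, "knr")
    counts = synthetic._mixture_counts(rng, mix, 4000)
    hist = rcm.ReadCountHistogram(
        counts=dict(zip(*np.unique(counts, return_counts=True))),
        population="knr_single_cell",
    )
    return rcm.fit_two_component_mixture(hist)


class TestTrueFraction:

    def test_pure_signal_gives_high_fraction(self, gold_fit):
        rng = synthetic.stream_rng(5, "somatic")
        counts = synthetic._zt_nbinom(rng, 55.0, 1.5, 3000)
        hist = rcm.ReadCountHistogram(
            counts=dict(zip(*np.unique(counts, return_counts=True))),
            population="somatic_single_cell",
        )
        est = rcm.estimate_true_fraction(hist, gold_fit, n_boot=0)
        assert est.fraction >= 0.9

    def test_spike_in_recovery(self, gold_fit):
        rng = synthetic.stream_rng(6, "somatic")
        n, frac = 5000, 0.10
        n_true = int(n * frac)
        counts = np.concatenate([
            synthetic.ChimeraCountModel().sample(rng, n - n_true),
            synthetic._zt_nbinom(rng, 55.0, 1.5, n_true),
        ])
        hist = rcm.ReadCountHistogram(
            counts=dict(zip(*np.unique(counts, return_counts=True))),
            population="somatic_single_cell",
        )
        est = rcm.estimate_true_fraction(hist, gold_fit, n_boot=100, seed=1)
        assert abs(est.fraction - frac) < 0.04
        assert est.ci_low <= frac <= est.ci_high

    def test_nonconverged_gold_fit_refused(self, gold_fit):
        import dataclasses

        bad = dataclasses.replace(gold_fit, converged=False)
        hist = rcm.ReadCountHistogram(
            counts={1: 50}, population="somatic_single_cell"
        )
        with pytest.raises(ValidationError, match="converge"):
            rcm.estimate_true_fraction(hist, bad)


class TestThresholdTable:
    def test_min_reads_one_retains_everything(self, cohort, gold_sets):
        calls, samples, _ = cohort
        tab = rcm.threshold_table(calls, samples, gold_sets)
        first = tab[tab["min_reads"] == 1].iloc[0]
        assert first["call_sensitivity"] == 1.0
        assert first["fp_retained"] == 1.0

    def test_columns_non_increasing(self, cohort, gold_sets):
        calls, samples, _ = cohort
        tab = rcm.threshold_table(calls, samples, gold_sets)
        for col in ("call_sensitivity", "fp_retained",
                    "mean_per_cell_sensitivity"):
            assert (np.diff(tab[col].to_numpy()) <= 1e-12).all()


class TestChooseThreshold:
    def test_hand_computed_knee(self):
        tab = pd.DataFrame({
            "min_reads": [1, 2, 3, 4],
            "call_sensitivity": [1.0, 0.7, 0.55, 0.45],
            "mean_per_cell_sensitivity": [0.5, 0.35, 0.27, 0.22],
            "fp_retained": [1.0, 0.03, 0.005, 0.003],
        })
        assert rcm.choose_threshold(tab) == 3

    def test_all_signal_keeps_threshold_one(self):
        tab = pd.DataFrame({
            "min_reads": [1, 2, 3],
            "call_sensitivity": [1.0, 0.7, 0.5],
            "mean_per_cell_sensitivity": [0.5, 0.35, 0.25],
            "fp_retained": [0.0, 0.0, 0.0],
        })
        assert rcm.choose_threshold(tab) == 1

    def test_invalid_knee_rejected(self):
        tab = pd.DataFrame({
            "min_reads": [1], "call_sensitivity": [1.0],
            "mean_per_cell_sensitivity": [0.5], "fp_retained": [1.0],
        })
        with pytest.raises(ValidationError, match="knee"):
            rcm.choose_threshold(tab, knee=0.0)
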