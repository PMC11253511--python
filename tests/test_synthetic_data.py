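"""Generator correctness: seeded determinism, planted truth, forward models."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit

from dsbquant.proteomics_io import build_design
from dsbquant.synthetic_data import (
    RepairTruth,
    ResectionTruth,
    SpikeDesign,
    gen_foci_counts,
    gen_lfq_table,
    gen_repair_blot,
    gen_resection_cq,
    protein_id,
)


class TestGenLfqTable:
    def test_seeded_determinism(self):
        d = SpikeDesign(n_proteins=100, spike_ids=(protein_id(0),), seed=11)
        t1, tr1 = gen_lfq_table(d)
        t2, tr2 = gen_lfq_table(d)
        pd.testing.assert_frame_equal(t1.lfq, t2.lfq)
        assert tr1 == tr2

    def test_row_counts_and_decoy_flags(self):
        d = SpikeDesign(n_proteins=50, decoy_rows=7, seed=0)
        t, _ = gen_lfq_table(d)
        assert t.n_proteins == 57
        assert int(t.flags.any(axis=1).sum()) == 7

    def test_empty_spike_set_gives_empty_truth(self):
        t, truth = gen_lfq_table(SpikeDesign(n_proteins=20, seed=0))
        assert truth["spiked"] == {}

    def test_spike_shifts_designated_cells_only(self):
        pid = protein_id(3)
        d = SpikeDesign(
            n_proteins=200,
            spike_ids=(pid,),
            spike_log2fc=5.0,
            between_replicate_sd=0.1,
            dropout_midpoint=0.0,  # no dropout: clean mean comparison
            seed=4,
        )
        t, _ = gen_lfq_table(d)
        log2 = np.log2(t.lfq)
        spiked_cols = d.groups.samples_for("lateM", "HO") + d.groups.samples_for(
            "lateM", "phleo"
        )
        other_cols = [s for s in t.samples if s not in spiked_cols]
        assert (
            log2.loc[pid, spiked_cols].mean() - log2.loc[pid, other_cols].mean()
            == pytest.approx(5.0, abs=0.3)
        )

    def test_no_dropout_when_midpoint_far_below(self):
        d = SpikeDesign(n_proteins=300, dropout_midpoint=-100.0, seed=2)
        t, _ = gen_lfq_table(d)
        assert not t.lfq.iloc[:300].isna().any().any()

    def test_empirical_missingness_matches_logistic_expectation(self):
        # midpoint at the protein mean: the marginal intensity is normal with
        # sd sqrt(protein_sd^2 + replicate_sd^2); expected missingness is the
        # integral of the logistic against that density.
        d = SpikeDesign(
            n_proteins=20000,
            base_mean_log2=25.0,
            between_protein_sd=1.0,
            between_replicate_sd=0.3,
            dropout_midpoint=25.0,
            dropout_slope=3.0,
            decoy_rows=0,
            seed=8,
        )
        t, _ = gen_lfq_table(d)
        sd = np.hypot(1.0, 0.3)
        expected, _ = integrate.quad(
            lambda x: expit((25.0 - x) * 3.0)
            * np.exp(-((x - 25.0) ** 2) / (2 * sd**2))
            / (sd * np.sqrt(2 * np.pi)),
            20,
            30,
        )
        empirical = float(t.lfq.isna().mean().mean())
        n = t.lfq.size
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert abs(empirical - expected) < 5 * mc_se

    def test_missingness_non_increasing_in_intensity(self):
        # MNAR structure: binned missingness must fall with the protein mean
        d = SpikeDesign(n_proteins=30000, decoy_rows=0, seed=5)
        t, _ = gen_lfq_table(d)
        log2 = np.log2(t.lfq)
        means = log2.mean(axis=1).to_numpy()  # measured-mean abundance proxy
        miss = t.lfq.isna().mean(axis=1).to_numpy()
        keep = np.isfinite(means)
        means, miss = means[keep], miss[keep]
        order = np.argsort(means)
        bins = np.array_split(miss[order], 20)
        rates = np.array([b.mean() for b in bins])
        # allow tiny non-monotonic jitter in the all-but-flat high bins
        assert np.all(np.diff(rates) <= 0.01)


class TestGenResectionCq:
    def _truth(self, f, r, E_rs=2.0, **kw):
        return ResectionTruth(
            f_by_time={0: 0.0, 120: f},
            r_by_amplicon_time={("RS", 120): r},
            efficiency={"ADH1": 2.0, "HOcs": 2.0, "RS": E_rs},
            cq_noise_sd=0.0,
            n_replicates=1,
            **kw,
        )

    def _cq(self, table, amplicon, aliquot, time):
        sel = table[
            (table["amplicon"] == amplicon)
            & (table["aliquot"] == aliquot)
            & (table["time_min"] == time)
        ]
        return float(sel["cq"].iloc[0])

    def test_full_protection_gives_zero_delta_cq(self):
        cq = gen_resection_cq(self._truth(1.0, 1.0))
        assert self._cq(cq, "RS", "digest", 120) == pytest.approx(
            self._cq(cq, "RS", "mock", 120)
        )

    def test_unresected_digest_hits_sentinel(self):
        truth = self._truth(0.8, 0.0)
        cq = gen_resection_cq(truth)
        assert self._cq(cq, "RS", "digest", 120) == truth.max_cq

    def test_partial_resection_delta_cq_closed_form(self):
        # f=0.8, r=0.5: mock signal 2-0.4=1.6, digest 0.4; dCq = log2(4) = 2
        cq = gen_resection_cq(self._truth(0.8, 0.5))
        dcq = self._cq(cq, "RS", "digest", 120) - self._cq(cq, "RS", "mock", 120)
        assert dcq == pytest.approx(2.0, abs=1e-12)

    def test_seeded_determinism_with_noise(self):
        truth = ResectionTruth(cq_noise_sd=0.2, seed=9)
        pd.testing.assert_frame_equal(
            gen_resection_cq(truth), gen_resection_cq(truth)
        )

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            ResectionTruth(efficiency={"ADH1": 1.0, "HOcs": 2.0})


class TestGenRepairBlot:
    def test_all_bands_non_negative_and_determinism(self):
        truth = RepairTruth(lane_scale_sd=0.5, band_noise_cv=0.2, seed=3)
        lanes = gen_repair_blot(truth)
        assert (lanes["intensity"] >= 0).all()
        pd.testing.assert_frame_equal(lanes, gen_repair_blot(truth))

    def test_zero_switch_gives_zero_product_bands(self):
        truth = RepairTruth(
            switch_fraction_by_time={60: 0.0, 90: 0.0},
            lane_scale_sd=0.0,
            band_noise_cv=0.0,
        )
        lanes = gen_repair_blot(truth)
        assert (lanes.loc[lanes["band"] == "MATalpha", "intensity"] == 0).all()

    def test_missing_reference_time_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            RepairTruth(switch_fraction_by_time={90: 0.4}, reference_time=60)


class TestGenFociCounts:
    def test_counts_conserve_n_cells(self):
        counts = gen_foci_counts(
            {"no_focus": 0.75, "focus": 0.15, "foci": 0.10}, 100, 5, seed=1
        )
        assert (counts.drop(columns="replicate").sum(axis=1) == 100).all()

    def test_degenerate_proportions(self):
        counts = gen_foci_counts({"no_focus": 1.0, "focus": 0.0}, 50, 3, seed=0)
        assert (counts["no_focus"] == 50).all()
        assert (counts["focus"] == 0).all()

    def test_seeded_determinism(self):
        a = gen_foci_counts({"a": 0.5, "b": 0.5}, 10, 2, seed=7)
        b = gen_foci_counts({"a": 0.5, "b": 0.5}, 10, 2, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_means_within_binomial_error(self):
        props = {"no_focus": 0.75, "focus": 0.15, "foci": 0.10}
        counts = gen_foci_counts(props, 100, 200, seed=6)
        for cat, p in props.items():
            se = np.sqrt(p * (1 - p) * 100) / np.sqrt(200)
            assert abs(counts[cat].mean() - 100 * p) < 4 * se

    def test_negative_proportion_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gen_foci_counts({"a": -0.1, "b": 1.1}, 10, 1)
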