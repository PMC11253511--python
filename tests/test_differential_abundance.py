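"""Log2 transform, low-tail beta imputation, Welch testing, curve calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dsbquant import differential_abundance as da
from dsbquant.differential_abundance import (
    CurveParams,
    ImputationParams,
    compare,
    impute_replicate,
    log2_transform,
    significance_curve,
)
from dsbquant.proteomics_io import Comparison, ProteinGroupsTable, filter_decoys, filter_min_valid
from dsbquant.stats_core import welch_t
from dsbquant.synthetic_data import SpikeDesign, gen_lfq_table, protein_id


def _table(matrix, samples):
    ids = pd.Index([f"p{i}" for i in range(len(matrix))], name="protein_group_id")
    return ProteinGroupsTable(
        lfq=pd.DataFrame(matrix, index=ids, columns=samples, dtype=float),
        gene_names=pd.Series("", index=ids),
        flags=pd.DataFrame(
            False, index=ids, columns=["contaminant", "reverse", "only_by_site"]
        ),
    )


class TestLog2Transform:
    def test_values_and_missing(self):
        t = _table([[1024.0, np.nan]], ["a", "b"])
        out = log2_transform(t)
        assert out.lfq.iloc[0, 0] == 10.0
        assert np.isnan(out.lfq.iloc[0, 1])

    def test_matches_elementwise_oracle(self, rng):
        vals = rng.uniform(1, 1e9, size=(20, 3))
        t = _table(vals, ["a", "b", "c"])
        np.testing.assert_allclose(log2_transform(t).lfq.to_numpy(), np.log2(vals))

    def test_nonpositive_rejected(self):
        t = _table([[0.5, -1.0]], ["a", "b"])
        t.lfq.iloc[0, 1] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            log2_transform(t)


class TestImputeReplicate:
    def test_identity_without_missing(self, rng):
        col = rng.normal(size=100)
        out = impute_replicate(col, ImputationParams(), rng)
        np.testing.assert_array_equal(out, col)

    def test_measured_untouched_and_containment(self, rng):
        col = rng.normal(size=2000)
        col[rng.random(2000) < 0.3] = np.nan
        measured = col[np.isfinite(col)]
        p = ImputationParams()
        out = impute_replicate(col, p, rng)
        np.testing.assert_array_equal(out[np.isfinite(col)], measured)
        lo, hi = np.quantile(measured, [p.q_low, p.q_high])
        imputed = out[~np.isfinite(col)]
        assert imputed.min() >= lo and imputed.max() <= hi
        assert imputed.max() <= np.quantile(measured, 0.05)

    def test_imputed_mean_matches_beta_midpoint(self, rng):
        # Beta(2,2) has mean 1/2: imputed values center on the band midpoint
        n_missing = 100_000
        measured = rng.normal(size=50_000)
        col = np.concatenate([measured, np.full(n_missing, np.nan)])
        p = ImputationParams()
        out = impute_replicate(col, p, np.random.default_rng(0))
        lo, hi = np.quantile(measured, [p.q_low, p.q_high])
        imputed = out[50_000:]
        mc_se = (hi - lo) * np.sqrt(1 / 20) / np.sqrt(n_missing)
        assert abs(imputed.mean() - (lo + hi) / 2) < 3 * mc_se

    def test_too_few_measured_rejected(self, rng):
        with pytest.raises(ValueError, match="2 measured"):
            impute_replicate(np.array([1.0, np.nan, np.nan]), ImputationParams(), rng)


class TestSignificanceCurve:
    def test_fold_change_below_offset_never_passes(self):
        assert not significance_curve(0.5, 1e-10)
        assert not significance_curve(-1.0, 1e-10)

    def test_p_above_floor_never_passes(self):
        assert not significance_curve(5.0, 0.2)

    def test_cutoff_at_fc_two_matches_closed_form(self):
        # threshold at |fc|=2 is -log10(0.05) + 0.5/1 = 1.80103
        assert significance_curve(2.0, 0.01)
        assert not significance_curve(2.0, 0.02)
        assert significance_curve(-2.0, 0.01)

    @given(
        fc_a=st.floats(1.05, 8),
        fc_extra=st.floats(0, 4),
        p_a=st.floats(1e-12, 1.0, exclude_min=False),
        p_ratio=st.floats(0.01, 1.0),
    )
    def test_monotone_in_both_axes(self, fc_a, fc_extra, p_a, p_ratio):
        # anything with larger |fc| and smaller p than a significant point
        # is itself significant
        if significance_curve(fc_a, p_a):
            assert significance_curve(fc_a + fc_extra, p_a * p_ratio)


class TestCompare:
    def test_identical_groups_give_null_row(self, design44):
        samples = design44.samples_for("lateM", "HO") + design44.samples_for(
            "lateM", "mock"
        )
        t = _table([[20.0, 21.0, 22.0, 23.0, 20.0, 21.0, 22.0, 23.0]], samples)
        res = compare(t, design44, Comparison("lateM", "HO"))
        assert res.loc["p0", "log2fc"] == 0.0
        assert res.loc["p0", "direction"] == "none"

    def test_result_covers_input_rows_exactly(self, design44):
        table, _ = gen_lfq_table(SpikeDesign(n_proteins=80, seed=3))
        comp = Comparison("lateM", "phleo")
        filtered = filter_min_valid(filter_decoys(table), design44, comp)
        res = compare(log2_transform(filtered), design44, comp)
        assert list(res.index) == list(filtered.ids)

    def test_seeded_determinism(self, design44):
        table, _ = gen_lfq_table(SpikeDesign(n_proteins=120, seed=6))
        comp = Comparison("G2M", "HO")
        filtered = log2_transform(filter_min_valid(filter_decoys(table), design44, comp))
        r1 = compare(filtered, design44, comp, ImputationParams(seed=42))
        r2 = compare(filtered, design44, comp, ImputationParams(seed=42))
        pd.testing.assert_frame_equal(r1, r2)

    def test_spiked_proteins_recovered(self, design44):
        spikes = tuple(protein_id(i) for i in range(20))
        table, _ = gen_lfq_table(
            SpikeDesign(n_proteins=800, spike_ids=spikes, spike_log2fc=2.0, seed=9)
        )
        comp = Comparison("lateM", "HO")
        filtered = filter_min_valid(filter_decoys(table), design44, comp)
        res = compare(log2_transform(filtered), design44, comp, ImputationParams(seed=9))
        enriched = set(res.index[res["direction"] == "enriched"])
        assert len(enriched & set(spikes)) >= 18  # >=90% sensitivity
        nulls = set(res.index) - set(spikes)
        assert len(enriched & nulls) <= len(nulls) * 0.01

    def test_neg_log10_consistency_and_direction_invariants(self, design44):
        table, _ = gen_lfq_table(SpikeDesign(n_proteins=150, seed=13))
        comp = Comparison("lateM", "HO")
        filtered = filter_min_valid(filter_decoys(table), design44, comp)
        res = compare(log2_transform(filtered), design44, comp)
        ok = res["p_value"] > 0
        np.testing.assert_allclose(
            res.loc[ok, "neg_log10_p"], -np.log10(res.loc[ok, "p_value"])
        )
        sig = res["significant"]
        assert (res.loc[sig, "log2fc"].abs() > 1.0).all()
        enriched = res["direction"] == "enriched"
        assert (res.loc[enriched, "log2fc"] > 0).all()
        assert sig[enriched].all()
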