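"""Contamination estimation, exclusion thresholds and linear unmixing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netkit import contamination, io
from netkit.markers import MarkerSet
from netkit.simulate import (
    SampleSpec,
    SimulationConfig,
    contamination_recovery,
    generate_contaminated_cohort,
    marker_sets_from_truth,
)

from conftest import tiny_matrix, tiny_meta


def make_marker_set(genes, target="TU", contaminant="TAM"):
    return MarkerSet(target=target, contaminant=contaminant,
                     genes=tuple(genes), scores=(np.nan,) * len(genes))


class TestChooseReference:
    def setup_method(self):
        genes = [f"m{i}" for i in range(5)] + ["filler"]
        pure = np.array([0.0] * 5 + [1000.0])
        contam_profile = np.array([200.0] * 5 + [800.0])
        mixed = 0.9 * pure + 0.1 * contam_profile
        self.matrix = tiny_matrix(
            np.column_stack([pure, mixed, contam_profile]),
            genes=genes, samples=["pure", "mixed", "tam0"])
        self.meta = tiny_meta([
            ("pure", "TU", "omentum", "P1", False),
            ("mixed", "TU", "omentum", "P2", False),
            ("tam0", "TAM", "omentum", "P1", False),
        ])
        self.ms = make_marker_set([f"m{i}" for i in range(5)])

    def test_pure_sample_wins(self):
        chosen = contamination.choose_reference_sample(
            self.matrix, self.meta, "TU", [self.ms])
        assert chosen == "pure"

    def test_single_sample_degenerate(self):
        chosen = contamination.choose_reference_sample(
            self.matrix, self.meta, "TAM", [])
        assert chosen == "tam0"

    def test_pinned_flag_overrides(self):
        meta = self.meta.copy()
        meta.loc["mixed", "is_reference"] = True
        chosen = contamination.choose_reference_sample(
            self.matrix, meta, "TU", [self.ms])
        assert chosen == "mixed"


class TestEstimate:
    def test_self_reference_is_floor(self):
        genes = ["m0", "m1", "m2"]
        ref = pd.Series([0.0, 0.0, 0.0], index=genes)
        cref = pd.Series([1000.0, 1000.0, 1000.0], index=genes)
        ms = make_marker_set(genes)
        pct, floored = contamination.estimate_contamination(ref, ref, cref, ms,
                                                            floor_percent=1.5)
        assert pct == 1.5 and floored

    def test_linear_mixture_is_exact(self):
        genes = [f"m{i}" for i in range(25)]
        tref = pd.Series(0.0, index=genes)
        cref = pd.Series(1000.0, index=genes)
        sample = 0.9 * tref + 0.1 * cref
        ms = make_marker_set(genes)
        pct, floored = contamination.estimate_contamination(sample, tref, cref, ms)
        assert pct == pytest.approx(10.0) and not floored

    def test_zero_reference_markers_dropped(self):
        genes = ["m0", "m1"]
        tref = pd.Series([0.0, 0.0], index=genes)
        cref = pd.Series([0.0, 1000.0], index=genes)
        sample = pd.Series([5.0, 50.0], index=genes)
        with pytest.warns(UserWarning, match="m0"):
            pct, _ = contamination.estimate_contamination(
                sample, tref, cref, make_marker_set(genes))
        assert pct == pytest.approx(5.0)
        with pytest.raises(ValueError):
            contamination.estimate_contamination(
                sample, tref, 0.0 * cref, make_marker_set(genes))

    def test_noisy_recovery_at_five_percent(self):
        """Monte-Carlo: sigma=0.2 noise, 25 markers, truth 5% -> within 1pp."""
        config = SimulationConfig(seed=42, n_genes=400, n_markers_per_type=25)
        est = contamination_recovery(config, 0.05, n_replicates=200)
        assert np.mean(np.abs(est - 5.0) <= 1.0) >= 0.95

    def test_monotone_in_true_fraction(self):
        config = SimulationConfig(seed=5, n_genes=400, noise_sigma=0.0)
        fracs = [0.0, 0.01, 0.03, 0.08, 0.15]
        estimates = [contamination_recovery(config, f, n_replicates=1)[0]
                     for f in fracs]
        assert estimates == sorted(estimates)
        assert np.allclose(estimates, [100 * f for f in fracs], atol=1e-9)


class TestExclusion:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "cell_type", "contaminant",
                           "estimated_percent", "floored"])

    def test_threshold_is_inclusive(self):
        table = self.make_table([("s1", "TU", "TAM", 4.0, False)])
        kept, excluded = contamination.apply_exclusion(
            table, contamination.AdjustmentConfig({"TU": ("TAM",)}))
        assert excluded == ["s1"] and kept == []

    def test_adi_below_six_percent_kept(self):
        table = self.make_table([
            ("a1", "ADI", "TU", 5.9, False),
            ("a1", "ADI", "TAM", 5.9, False),
        ])
        kept, excluded = contamination.apply_exclusion(
            table, contamination.AdjustmentConfig({"ADI": ("TU", "TAM")}))
        assert kept == ["a1"] and excluded == []

    def test_caf_never_excluded_by_default(self):
        table = self.make_table([("c1", "CAF", "TU", 50.0, False)])
        config = contamination.AdjustmentConfig({"CAF": ("TU",)})
        kept, excluded = contamination.apply_exclusion(table, config)
        assert kept == ["c1"]
        strict = contamination.AdjustmentConfig(
            {"CAF": ("TU",)}, exclusion_threshold={"CAF": 10.0})
        kept, excluded = contamination.apply_exclusion(table, strict)
        assert excluded == ["c1"]


class TestAdjustSample:
    def test_zero_fraction_is_identity(self):
        col = pd.Series([10.0, 20.0], index=["a", "b"])
        out = contamination.adjust_sample(col, {"TAM": 0.0},
                                          {"TAM": pd.Series([5.0, 5.0], index=["a", "b"])})
        assert (out == col).all()

    def test_linear_model_arithmetic(self):
        col = pd.Series([90.0], index=["g"])
        profile = pd.Series([500.0], index=["g"])
        out = contamination.adjust_sample(col, {"TAM": 0.10}, {"TAM": profile})
        assert out["g"] == pytest.approx((90.0 - 50.0) / 0.9)

    def test_negative_clamped_to_zero(self):
        col = pd.Series([10.0], index=["g"])
        profile = pd.Series([500.0], index=["g"])
        out = contamination.adjust_sample(col, {"TAM": 0.10}, {"TAM": profile})
        assert out["g"] == 0.0

    def test_fraction_at_one_errors(self):
        col = pd.Series([10.0], index=["g"])
        with pytest.raises(ValueError):
            contamination.adjust_sample(col, {"TAM": 1.0},
                                        {"TAM": pd.Series([1.0], index=["g"])})

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.95))
    def test_single_contaminant_inversion(self, seed, frac):
        """adjust((1-f)T + fC, f, C) == T up to floating point."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        t = pd.Series(rng.uniform(0.0, 1000.0, 20), index=genes)
        c = pd.Series(rng.uniform(0.0, 1000.0, 20), index=genes)
        mixed = (1 - frac) * t + frac * c
        out = contamination.adjust_sample(mixed, {"X": frac}, {"X": c})
        assert np.allclose(out, t, rtol=1e-9, atol=1e-6)


class TestRunAdjustment:
    def test_noisefree_recovery(self, noisefree_cohort):
        """Known-fraction mixtures invert to pure profiles after renormalisation."""
        matrix, meta, truth, markers, profiles = noisefree_cohort
        targets = {t: tuple(c for c in profiles.columns if c != t)
                   for t in profiles.columns}
        msets = marker_sets_from_truth(markers, targets)
        config = contamination.AdjustmentConfig(contaminants_by_target=targets)
        result = contamination.run_adjustment(matrix, meta, msets, config)
        # TU_05 carries 5% TAM -> >= 4% threshold -> excluded
        assert result.excluded_samples == ["TU_05"]
        for sample in result.adjusted.columns:
            pure = profiles[meta.loc[sample, "cell_type"]]
            mask = pure > 1.0
            rel = np.abs(result.adjusted[sample][mask] - pure[mask]) / pure[mask]
            assert rel.max() < 1e-6, sample

    def test_estimates_match_truth_exactly(self, noisefree_cohort):
        matrix, meta, truth, markers, profiles = noisefree_cohort
        targets = {t: tuple(c for c in profiles.columns if c != t)
                   for t in profiles.columns}
        msets = marker_sets_from_truth(markers, targets)
        config = contamination.AdjustmentConfig(contaminants_by_target=targets)
        table, _ = contamination.estimate_cohort(matrix, meta, msets, config)
        merged = table.merge(truth, how="left",
                             on=["sample_id", "contaminant"]).fillna({"true_frac": 0.0})
        err = (merged["estimated_percent"] - 100 * merged["true_frac"]).abs()
        assert err.max() < 1e-9

    def test_marker_suppression(self, noisefree_cohort):
        """Adjustment can only decrease contaminant-marker signal in targets."""
        matrix, meta, truth, markers, profiles = noisefree_cohort
        targets = {"TU": ("TAM",)}
        msets = marker_sets_from_truth(markers, targets)
        config = contamination.AdjustmentConfig(contaminants_by_target=targets)
        result = contamination.run_adjustment(matrix, meta, msets, config)
        tam_markers = list(markers["TAM"])
        for sample in ("TU_04",):  # the kept contaminated sample
            before = matrix.loc[tam_markers, sample]
            after = result.adjusted.loc[tam_markers, sample]
            assert (after <= before + 1e-9).all()

    def test_adjusted_matrix_contract(self, noisefree_cohort):
        matrix, meta, truth, markers, profiles = noisefree_cohort
        targets = {"TU": ("TAM",)}
        msets = marker_sets_from_truth(markers, targets)
        config = contamination.AdjustmentConfig(contaminants_by_target=targets)
        result = contamination.run_adjustment(matrix, meta, msets, config)
        assert (result.adjusted.to_numpy() >= 0).all()
        assert np.allclose(result.adjusted.sum(axis=0), io.TPM_TOTAL, rtol=1e-9)

    def test_deterministic_rerun(self, noisefree_cohort):
        matrix, meta, truth, markers, profiles = noisefree_cohort
        targets = {"TU": ("TAM",)}
        msets = marker_sets_from_truth(markers, targets)
        config = contamination.AdjustmentConfig(contaminants_by_target=targets)
        r1 = contamination.run_adjustment(matrix, meta, msets, config)
        r2 = contamination.run_adjustment(matrix, meta, msets, config)
        pd.testing.assert_frame_equal(r1.adjusted, r2.adjusted)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_patient_matched_profile_source(self, noisefree_cohort):
        matrix, meta, truth, markers, profiles = noisefree_cohort
        targets = {"TU": ("TAM",)}
        msets = marker_sets_from_truth(markers, targets)
        config = contamination.AdjustmentConfig(
            contaminants_by_target=targets,
            contaminant_profile_source="patient_matched_if_available")
        result = contamination.run_adjustment(matrix, meta, msets, config)
        # sample TU_04 (patient P04) should use TAM_04 from the same patient
        assert result.profiles_used["TU_04"]["TAM"] == "patient_matched:TAM_04"
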