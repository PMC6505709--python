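import numpy as np
import pandas as pd
import pytest

from adascreen import (
    ADAConfig,
    ValidationError,
    absolute_amplitude,
    amplitude_profile,
    column_center,
    compute_thresholds,
    criterion_candidates,
    estimate_sigma,
    overall_deviation,
    run_ada,
    signed_amplitude,
    stage_deviation_profile,
    strict_3sigma_candidates,
)
from adascreen.core import CRITERION_DOWN, CRITERION_UP, STRICT

from conftest import build_matrix, random_matrix

STAGES = ("control", "incipient", "moderate", "severe")
DISEASE = STAGES[1:]


def make_profile(rows, genes=None):
    """Deviation profile DataFrame from per-gene (D_ctrl, D_inc, D_mod, D_sev)."""
    rows = np.asarray(rows, float)
    genes = genes or [f"g{k}" for k in range(1, len(rows) + 1)]
    return pd.DataFrame(rows, index=genes, columns=list(STAGES))


class TestColumnCenter:
    def test_toy_hand_computation(self, toy_control_block):
        dev = column_center(toy_control_block, "control")
        expected = np.array([[-1.0, -1.0], [0.0, 0.0], [1.0, 1.0]])
        np.testing.assert_allclose(dev.values.to_numpy(), expected)

    def test_constant_column_centers_to_zero(self):
        m = build_matrix(np.full((4, 8), 7.25), (2, 2, 2, 2))
        for stage in STAGES:
            dev = column_center(m, stage)
            assert (dev.values.to_numpy() == 0).all()

    def test_columns_sum_to_zero(self, small_four_stage):
        for stage in STAGES:
            dev = column_center(small_four_stage, stage)
            np.testing.assert_allclose(
                dev.values.sum(axis=0), 0.0, atol=1e-9 * 6
            )

    def test_matches_scalar_loop_oracle(self, small_four_stage):
        m = small_four_stage
        block = m.stage_slice("incipient")
        dev = column_center(m, "incipient").values
        for j, s in enumerate(block.columns):
            col = [block.iat[i, j] for i in range(block.shape[0])]
            mean = sum(col) / len(col)
            for i in range(block.shape[0]):
                assert dev.iat[i, j] == pytest.approx(
                    col[i] - mean, abs=1e-12
                )

    def test_absent_stage_errors(self):
        m = build_matrix(np.ones((2, 4)), (2, 2, 0, 0))
        with pytest.raises(ValidationError, match="moderate"):
            column_center(m, "moderate")


class TestOverallDeviation:
    def test_toy_continuation(self, toy_control_block):
        dev = column_center(toy_control_block, "control")
        d = overall_deviation(dev)
        np.testing.assert_allclose(d.to_numpy(), [-1.0, 0.0, 1.0])

    def test_matches_scalar_loop_oracle(self, small_four_stage):
        dev = column_center(small_four_stage, "severe")
        d = overall_deviation(dev)
        for i in range(dev.values.shape[0]):
            row = [dev.values.iat[i, j] for j in range(dev.values.shape[1])]
            assert d.iloc[i] == pytest.approx(
                sum(row) / len(row), abs=1e-12
            )


class TestAmplitudes:
    def test_hand_computed_signed_and_absolute(self):
        profile = make_profile([[0.5, 1.0, 2.0, 2.5]])
        a = signed_amplitude(profile)
        np.testing.assert_allclose(
            a.loc["g1", list(DISEASE)].to_numpy(), [0.5, 1.5, 2.0]
        )
        np.testing.assert_allclose(
            absolute_amplitude(profile).loc["g1"].to_numpy(),
            [0.5, 1.5, 2.0],
        )

    def test_identical_stages_give_zero_amplitudes(self):
        profile = make_profile([[0.3, 0.3, 0.3, 0.3]])
        assert (signed_amplitude(profile).to_numpy() == 0).all()

    def test_negative_amplitudes_fold_to_magnitudes(self):
        profile = make_profile([[0.0, -0.5, -1.5, -2.0]])
        np.testing.assert_allclose(
            absolute_amplitude(profile).loc["g1"].to_numpy(),
            [0.5, 1.5, 2.0],
        )

    def test_absolute_equals_magnitude_of_signed(self):
        rng = np.random.default_rng(3)
        profile = make_profile(rng.normal(size=(30, 4)))
        amps = amplitude_profile(profile)
        np.testing.assert_array_equal(
            amps.absolute.to_numpy(), np.abs(amps.signed.to_numpy())
        )

    def test_swapping_control_with_disease_stage_flips_sign(self):
        profile = make_profile([[0.2, 1.1, 0.4, 0.9]])
        swapped = profile.rename(
            columns={"control": "incipient", "incipient": "control"}
        )
        a = signed_amplitude(profile)["incipient"]
        a_swapped = signed_amplitude(swapped)["incipient"]
        np.testing.assert_allclose(
            a_swapped.to_numpy(), -a.to_numpy()
        )

    def test_missing_stage_errors(self):
        profile = make_profile([[0.0, 1.0, 2.0, 3.0]]).drop(
            columns=["moderate"]
        )
        with pytest.raises(ValidationError, match="moderate"):
            signed_amplitude(profile)


class TestEstimateSigma:
    def test_constant_vector(self):
        assert estimate_sigma([1.0, 1.0, 1.0]) == (1.0, 0.0)

    def test_hand_computed_moments(self):
        mean, sigma = estimate_sigma([0.0, 0.0, 0.0, 4.0])
        assert mean == pytest.approx(1.0)
        assert sigma == pytest.approx(np.sqrt(3.0))

    def test_sample_convention_uses_n_minus_one(self):
        x = [0.0, 0.0, 0.0, 4.0]
        _, s = estimate_sigma(x, ddof=1)
        assert s == pytest.approx(2.0)

    def test_empty_vector_errors(self):
        with pytest.raises(ValidationError):
            estimate_sigma([])


class TestStrictRule:
    def _setup(self, rng, n=100):
        # 99 null genes with tiny amplitudes, one planted outlier
        base = rng.normal(0.0, 0.1, size=(n, 3))
        d_ctrl = rng.normal(0.0, 0.05, size=n)
        profile = np.column_stack([d_ctrl, base + d_ctrl[:, None]])
        # null rows get non-monotone D by construction noise; planted row:
        sigma0 = base.std(axis=0)
        profile[0] = [0.0, 10 * sigma0[0], 12 * sigma0[1], 15 * sigma0[2]]
        return make_profile(profile)

    def test_single_planted_outlier_is_the_only_call(self):
        profile = self._setup(np.random.default_rng(11))
        amps = amplitude_profile(profile)
        thr = compute_thresholds(amps)
        calls = strict_3sigma_candidates(profile, amps, thr)

        # brute-force check over every gene
        expected = []
        for g in profile.index:
            d = profile.loc[g].to_numpy()
            ok = all(
                abs(amps.signed.at[g, t] - thr.mean_signed[t])
                > thr.cutoff_strict[t]
                for t in DISEASE
            )
            if ok and (np.diff(d) > 0).all():
                expected.append((g, "up"))
            elif ok and (np.diff(d) < 0).all():
                expected.append((g, "down"))
        assert [(c.gene_id, c.direction) for c in calls] == sorted(expected)
        assert ("g1", "up") in expected
        assert all(c.criterion == STRICT for c in calls)

    def test_zero_amplitude_gene_never_called(self):
        profile = self._setup(np.random.default_rng(5))
        profile.loc["g2"] = [0.1, 0.1, 0.1, 0.1]
        amps = amplitude_profile(profile)
        thr = compute_thresholds(amps)
        calls = strict_3sigma_candidates(profile, amps, thr)
        assert "g2" not in {c.gene_id for c in calls}

    def test_all_stage_conjunction_required(self):
        # severe stage has a wide null spread, so a gene can be extreme in
        # incipient and moderate, monotone in D, yet inside 3 sigma in severe
        rng = np.random.default_rng(9)
        amps_null = np.column_stack([
            rng.normal(0.0, 0.1, 99),
            rng.normal(0.0, 0.1, 99),
            rng.normal(0.0, 0.5, 99),
        ])
        profile_arr = np.column_stack([np.zeros(99), amps_null])
        profile = make_profile(
            np.vstack([profile_arr, [0.0, 0.5, 0.6, 0.65]])
        )
        amps = amplitude_profile(profile)
        thr = compute_thresholds(amps)
        target = profile.index[-1]
        for t in ("incipient", "moderate"):
            assert (
                abs(amps.signed.at[target, t] - thr.mean_signed[t])
                > thr.cutoff_strict[t]
            )
        assert (
            abs(amps.signed.at[target, "severe"] - thr.mean_signed["severe"])
            <= thr.cutoff_strict["severe"]
        )
        d = profile.loc[target].to_numpy()
        assert (np.diff(d) > 0).all()
        calls = strict_3sigma_candidates(profile, amps, thr)
        assert target not in {c.gene_id for c in calls}


class TestCriterionRule:
    def test_directions_are_mutually_exclusive(self):
        rng = np.random.default_rng(2)
        profile = make_profile(rng.normal(size=(200, 4)))
        amps = amplitude_profile(profile)
        thr = compute_thresholds(amps)
        calls = criterion_candidates(profile, amps, thr)
        genes = [c.gene_id for c in calls]
        assert len(genes) == len(set(genes))
        for c in calls:
            assert (c.criterion, c.direction) in {
                (CRITERION_UP, "up"), (CRITERION_DOWN, "down"),
            }

    def test_planted_monotone_genes_recovered_with_direction(self):
        from adascreen import SyntheticDesign, generate

        matrix, truth = generate(
            SyntheticDesign(n_genes=200, n_up=3, n_down=3, seed=13)
        )
        res = run_ada(matrix, method="relaxed")
        by_gene = {c.gene_id: c.direction for c in res.candidates}
        assert set(by_gene) == truth.planted
        for g in truth.genes_with("up"):
            assert by_gene[g] == "up"
        for g in truth.genes_with("down"):
            assert by_gene[g] == "down"

    def test_strict_calls_also_pass_relaxed_amplitude_test(
        self, seeded_synthetic
    ):
        matrix, _ = seeded_synthetic
        res = run_ada(matrix, method="both")
        thr = res.thresholds
        for t in DISEASE:
            assert thr.sigma_absolute[t] <= thr.sigma_signed[t]
        relaxed = {
            (c.gene_id, c.direction)
            for c in res.candidates
            if c.criterion != STRICT
        }
        for c in res.candidates:
            if c.criterion == STRICT:
                assert (c.gene_id, c.direction) in relaxed


class TestRunAda:
    def test_offset_only_matrix_yields_no_candidates(self):
        # exact dyadic values so centering cancels offsets bit-exactly
        baseline = np.array([4.0, 5.25, 6.5, 8.75])
        offsets = np.array([0.5, -0.25, 1.0, 0.0, -0.5, 0.75, 0.25, -1.0])
        arr = baseline[:, None] + offsets[None, :]
        m = build_matrix(arr, (2, 2, 2, 2))
        res = run_ada(m, method="both")
        assert (res.amplitudes.signed.to_numpy() == 0).all()
        assert res.candidates == []

    def test_seeded_fixture_matches_truth_table(self, seeded_synthetic):
        matrix, truth = seeded_synthetic
        res = run_ada(matrix, method="relaxed")
        assert {c.gene_id for c in res.candidates} == truth.planted

    def test_both_methods_kept_separate(self, seeded_synthetic):
        matrix, _ = seeded_synthetic
        res = run_ada(matrix, method="both")
        criteria = {c.criterion for c in res.candidates}
        assert STRICT in criteria
        assert criteria <= {STRICT, CRITERION_UP, CRITERION_DOWN}
        n_strict = len(res.calls_for(STRICT))
        n_relaxed = len(res.candidates) - n_strict
        assert n_strict > 0 and n_relaxed > 0

    def test_missing_stage_errors_with_name(self):
        m = build_matrix(np.ones((3, 6)), (2, 2, 2, 0))
        with pytest.raises(ValidationError, match="severe"):
            run_ada(m)

    def test_invalid_method_rejected(self, small_four_stage):
        with pytest.raises(ValidationError, match="method"):
            run_ada(small_four_stage, method="fuzzy")


class TestConfig:
    def test_sigma_convention_changes_thresholds(self, small_four_stage):
        pop = run_ada(small_four_stage, config=ADAConfig()).thresholds
        samp = run_ada(
            small_four_stage, config=ADAConfig(variance="sample")
        ).thresholds
        for t in DISEASE:
            assert samp.sigma_signed[t] > pop.sigma_signed[t]

    def test_signed_relaxed_definition_never_calls_down_genes(self):
        from adascreen import SyntheticDesign, generate

        matrix, truth = generate(
            SyntheticDesign(n_genes=300, n_up=4, n_down=4, seed=21)
        )
        res = run_ada(
            matrix,
            method="relaxed",
            config=ADAConfig(relaxed_amplitude="signed"),
        )
        directions = {c.direction for c in res.candidates}
        assert "down" not in directions

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ADAConfig(multiplier=0.0)
        with pytest.raises(ValidationError):
            ADAConfig(variance="bootstrap")


def test_stage_deviation_profile_shape(small_four_stage):
    profile = stage_deviation_profile(small_four_stage)
    assert list(profile.columns) == list(STAGES)
    assert list(profile.index) == small_four_stage.gene_ids


def test_centering_idempotent(small_four_stage):
    dev = column_center(small_four_stage, "control")
    again = dev.values - dev.values.mean(axis=0)
    np.testing.assert_allclose(
        again.to_numpy(), dev.values.to_numpy(), atol=1e-12
    )
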