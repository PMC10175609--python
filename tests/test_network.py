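"""Compass network: mask geometry, targets, optimization, bump readout."""

import numpy as np
import pytest

from cxcompass import (
    DegenerateStateError,
    build_mask,
    bump_position,
    label_to_index,
    make_targets,
    optimize_feedforward,
    step,
)
from cxcompass.network import (
    N_COLUMNS,
    bump_index,
    init_template,
    load_model,
    maintenance_fit_loss,
    quadrant_rotated,
    save_model,
)


class TestMask:
    def test_cl1a_to_cl2_is_same_column_identity(self):
        mask = build_mask("default").matrix
        block = mask[16:, :16]
        assert block.sum() == 16
        assert np.array_equal(block, np.eye(16, dtype=bool))

    def test_same_type_blocks_are_tridiagonal_without_wrap(self):
        mask = build_mask("default").matrix
        for block in (mask[:16, :16], mask[16:, 16:]):
            i, j = np.where(block)
            assert np.all(np.abs(i - j) <= 1)
            assert not block[0, 15] and not block[15, 0]  # open bridge ends

    def test_cl2_to_cl1a_band_around_column_and_mirror(self):
        # CL2 in column L1 (position 8, index 7) may reach CL1a within
        # +-2 of L1 and within +-2 of its mirror column R1
        mask = build_mask("default").matrix
        j = label_to_index("L1")
        allowed = np.where(mask[:16, 16 + j])[0]
        near_l1 = set(range(j - 2, j + 3))
        near_r1 = set(range(label_to_index("R1") - 2, label_to_index("R1") + 3))
        assert set(allowed) == (near_l1 | near_r1) & set(range(16))

    def test_noduli_variant_couples_same_hemisphere_cl2_only(self):
        mask = build_mask("noduli").matrix
        cl2 = mask[16:, 16:]
        assert cl2[label_to_index("L7"), label_to_index("L3")]      # same hemisphere
        assert not cl2[label_to_index("R7"), label_to_index("L3")]  # across midline

    def test_noduli_mask_strictly_contains_default(self):
        d = build_mask("default").matrix
        n = build_mask("noduli").matrix
        assert np.all(n[d])
        assert n.sum() > d.sum()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_mask("ring")


class TestTargets:
    def test_each_target_peaks_at_its_column(self, targets):
        for c in range(N_COLUMNS):
            x = targets.target(c)
            assert np.argmax(x[:16]) == c

    def test_cl1a_and_cl2_subvectors_equal(self, targets):
        assert np.array_equal(targets.matrix[:16], targets.matrix[16:])

    def test_full_period_cosine_sums_to_zero(self, targets):
        np.testing.assert_allclose(targets.matrix.sum(axis=0), 0.0, atol=1e-12)

    def test_targets_are_cyclic_shifts(self, targets):
        shifted = targets.shifted(3)
        for c in range(N_COLUMNS):
            np.testing.assert_allclose(shifted[:, c],
                                       targets.target((c + 3) % N_COLUMNS))

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            make_targets(3)


class TestStep:
    def test_identity_and_zero(self):
        x = np.arange(32, dtype=float)
        np.testing.assert_array_equal(step(np.eye(32), x), x)
        np.testing.assert_array_equal(step(np.eye(32), np.zeros(32)), 0.0)

    def test_linearity(self, default_model):
        rng = np.random.default_rng(2)
        x = rng.normal(size=32)
        np.testing.assert_allclose(step(default_model, 3.0 * x),
                                   3.0 * step(default_model, x), rtol=1e-12)

    def test_dimension_mismatch(self, default_model):
        with pytest.raises(ValueError, match="dimension mismatch"):
            step(default_model, np.zeros(16))


class TestMaintenance:
    def test_targets_become_fixed_points(self, default_model, noduli_model, targets):
        X = targets.matrix
        for model in (default_model, noduli_model):
            M = model.weights
            assert np.abs(M @ X - X).max() <= 1e-3
            assert np.abs(M @ M @ X - X).max() <= 2e-3  # two-step criterion

    def test_masked_entries_stay_exactly_zero(self, default_model):
        off = ~default_model.mask.matrix
        assert np.all(default_model.weights[off] == 0.0)

    def test_sign_template_initialization(self):
        mask = build_mask("default")
        m0 = init_template(mask)
        assert np.all(m0[16:, :16][mask.matrix[16:, :16]] == 0.5)   # CL1a -> CL2
        assert np.all(m0[:16, 16:][mask.matrix[:16, 16:]] == -0.5)  # CL2 -> CL1a
        assert np.all(m0[:16, :16][mask.matrix[:16, :16]] == 0.5)   # same-type
        assert np.all(m0[~mask.matrix] == 0.0)

    def test_emergent_sign_structure_is_reported(self, default_model):
        # the excitatory/inhibitory layout is an optimization outcome;
        # it is recorded (not enforced) in the model metadata
        report = default_model.metadata["sign_structure"]
        assert set(report) == {"cl1a_to_cl2_all_excitatory",
                               "cl2_to_cl1a_main_band_excitatory",
                               "cl2_to_cl1a_mirror_band_inhibitory"}
        assert report["cl1a_to_cl2_all_excitatory"] is True

    def test_deterministic_refit(self, default_model, targets):
        from cxcompass import optimize_maintenance
        again = optimize_maintenance(build_mask("default"), targets)
        np.testing.assert_array_equal(again.weights, default_model.weights)


class TestShift:
    @pytest.mark.parametrize("direction, delta", [("left", +1), ("right", -1)])
    def test_every_target_moves_one_column(self, default_model,
                                           default_modulations, targets,
                                           direction, delta):
        mod = getattr(default_modulations, direction)
        eff = default_model.weights + mod.delta
        for c in range(N_COLUMNS):
            y = eff @ targets.target(c)
            expected = (c + delta) % N_COLUMNS
            assert bump_index(y, "CL1a")[0] == expected
            assert bump_index(y, "CL2")[0] == expected

    def test_modulation_respects_mask(self, default_model, default_modulations):
        off = ~default_model.mask.matrix
        assert np.all(default_modulations.left.delta[off] == 0.0)
        assert np.all(default_modulations.right.delta[off] == 0.0)

    def test_wrap_examples(self, default_model, default_modulations, targets):
        left = default_model.weights + default_modulations.left.delta
        right = default_model.weights + default_modulations.right.delta
        # left turn: bump at R1 moves to R2 (toward higher index)
        assert bump_position(left @ targets.target("R1")) == "R2"
        # right turn: bump at L8 wraps to R8
        assert bump_position(right @ targets.target("L8")) == "R8"

    def test_left_right_modulations_are_quadrant_rotations(self, default_modulations):
        dl = default_modulations.left.delta
        dr = default_modulations.right.delta
        rel = np.linalg.norm(dr - quadrant_rotated(dl)) / np.linalg.norm(dr)
        assert rel < 1e-4

    def test_invalid_direction_rejected(self, default_model, targets):
        from cxcompass import optimize_shift
        with pytest.raises(ValueError, match="direction"):
            optimize_shift(default_model, targets, "up")


class TestFeedforwardControl:
    def test_zero_input_recovers_baseline_loss(self, default_model, targets):
        ff = optimize_feedforward(default_model, targets, "left")
        X = targets.matrix
        M = default_model.weights
        expected = float((((M @ X - targets.shifted(1)) ** 2).sum()
                          + ((M @ M @ X - targets.shifted(2)) ** 2).sum())
                         / (2 * X.size))
        assert ff.baseline_loss == pytest.approx(expected, rel=1e-12)

    def test_loss_symmetric_under_turn_relabeling(self, default_model, targets):
        left = optimize_feedforward(default_model, targets, "left")
        right = optimize_feedforward(default_model, targets, "right")
        assert left.fit_loss == pytest.approx(right.fit_loss, rel=1e-6)


class TestBumpReadout:
    def test_one_hot_maps_to_column_label(self):
        x = np.zeros(32)
        x[4] = 1.0   # 1-based position 5
        assert bump_position(x, "CL1a") == "L4"

    def test_targets_read_back_their_column(self, targets):
        from cxcompass.columns import PB_LABELS
        for c, label in enumerate(PB_LABELS):
            assert bump_position(targets.target(c), "CL1a") == label
            assert bump_position(targets.target(c), "CL2") == label

    def test_scale_invariance(self, targets):
        x = targets.target("R3")
        assert bump_position(2.0 * x) == bump_position(x)

    def test_degenerate_state_raises(self):
        with pytest.raises(DegenerateStateError):
            bump_position(np.ones(32))

    def test_tie_flag(self):
        x = np.zeros(32)
        x[3] = x[7] = 1.0
        idx, degenerate = bump_index(x, "CL1a")
        assert idx == 3 and degenerate


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, default_model, default_modulations):
        save_model(tmp_path / "m", default_model, default_modulations)
        model, mods = load_model(tmp_path / "m")
        np.testing.assert_allclose(model.weights, default_model.weights,
                                   rtol=0, atol=1e-12)
        assert model.variant == "default"
        assert mods is not None
        np.testing.assert_allclose(mods.left.delta, default_modulations.left.delta,
                                   rtol=0, atol=1e-12)
        # losses survive the round trip
        assert mods.left.fit_loss == pytest.approx(
            default_modulations.left.fit_loss, rel=1e-6, abs=1e-18)
        # reloaded weights still honor the mask exactly
        assert np.all(model.weights[~model.mask.matrix] == 0.0)

    def test_lambda_robustness_of_fit(self, targets):
        # the final maintenance fit is insensitive to the structure-
        # phase regularization anywhere in its working range
        from cxcompass import optimize_maintenance
        losses = {}
        for lam in (0.1, 0.2):
            m = optimize_maintenance(build_mask("default"), targets, lam=lam)
            losses[lam] = maintenance_fit_loss(m.weights, targets)
        assert all(v < 1e-12 for v in losses.values())
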