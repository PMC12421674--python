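"""Frame geometry, global elasticity, persistence lengths, threading."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rigidbase.constants import KBT, KBT_PN_ANGSTROM
from rigidbase import mechanics as mech
from rigidbase.core import vector_index
from rigidbase.predictor import (
    effective_stiffness_for_subset,
    model_stiffness,
    predict_mean_vector,
)


def rod_steps(rng, n_snap, n_steps, sd_tilt=0.0, sd_roll=0.0, sd_twist=0.0,
              rise=3.3, twist=34.0):
    """Homogeneous-rod step ensemble with Gaussian angle noise (rad)."""
    steps = np.zeros((n_snap, n_steps, 6))
    steps[..., 2] = rise
    steps[..., 3] = np.rad2deg(rng.normal(0, sd_tilt, (n_snap, n_steps)))
    steps[..., 4] = np.rad2deg(rng.normal(0, sd_roll, (n_snap, n_steps)))
    steps[..., 5] = twist + np.rad2deg(rng.normal(0, sd_twist, (n_snap, n_steps)))
    return steps


def rod_equilibrium(n_steps, rise=3.3, twist=34.0):
    eq = np.zeros((n_steps, 6))
    eq[:, 2] = rise
    eq[:, 5] = twist
    return eq


class TestStepGeometry:
    def test_pure_twist(self):
        h_rise, h_twist = mech.step_to_helical(np.array([0, 0, 3.3, 0, 0, 34.0]))
        assert h_rise == pytest.approx(3.3)
        assert h_twist == pytest.approx(34.0)

    def test_zero_rotation_limit(self):
        h_rise, h_twist = mech.step_to_helical(np.array([0, 0, 3.3, 0, 0, 0.0]))
        assert h_rise == pytest.approx(3.3)
        assert h_twist == 0.0

    def test_against_rotation_matrix_oracle(self, rng):
        steps = np.column_stack([
            rng.uniform(-1, 1, 8), rng.uniform(-1, 1, 8), rng.uniform(2.8, 3.6, 8),
            rng.uniform(-8, 8, 8), rng.uniform(-10, 10, 8), rng.uniform(20, 40, 8)])
        rot, disp = mech.step_rotation_displacement(steps)
        h_rise, h_twist = mech.step_to_helical(steps)
        for i in range(8):
            rv = Rotation.from_matrix(rot[i]).as_rotvec()
            ang = np.linalg.norm(rv)
            ax = rv / ang
            if ax[2] < 0:
                ax, ang = -ax, -ang
            assert h_twist[i] == pytest.approx(np.rad2deg(ang), abs=1e-8)
            assert h_rise[i] == pytest.approx(disp[i] @ ax, abs=1e-8)

    def test_frames_round_trip(self, rng):
        steps = rod_steps(rng, 3, 10, 0.05, 0.05, 0.06)
        steps[..., 0] = rng.uniform(-0.5, 0.5, (3, 10))
        steps[..., 1] = rng.uniform(-0.5, 0.5, (3, 10))
        fs = mech.build_frames(steps)
        rec = mech.extract_steps(fs.frames, fs.origins)
        np.testing.assert_allclose(rec, steps, atol=1e-8)

    def test_straight_rod_normals_collinear(self):
        steps = rod_equilibrium(10, twist=34.0)
        fs = mech.build_frames(steps)
        np.testing.assert_allclose(
            np.einsum("pi,i->p", fs.normals[0], fs.normals[0, 0]), 1.0,
            atol=1e-12)

    def test_roll_circle_closes(self):
        n = 12
        steps = np.tile([0, 0, 3.3, 0, 360.0 / n, 0], (n, 1))
        fs = mech.build_frames(steps)
        assert fs.normals[0, -1] @ fs.normals[0, 0] == pytest.approx(1.0, abs=1e-9)


class TestGlobalCoordinates:
    def test_sum_arithmetic(self):
        h_rise = np.full((1, 25), 3.3)
        h_twist = np.full((1, 25), 34.0)
        l, w = mech.global_length_twist(h_rise, h_twist)
        assert l == pytest.approx(82.5)
        assert w == pytest.approx(25 * 34 * np.pi / 180)

    def test_material_constants_arithmetic(self, rng):
        # construct samples with known variance/covariance structure
        l = 82.5 + np.sqrt(2.1) * rng.standard_normal(400000)
        w = 14.8 + np.sqrt(0.069) * rng.standard_normal(400000)
        rec = mech.material_constants(l, w, l0=82.5)
        assert rec.stretch_modulus_pn == pytest.approx(
            KBT_PN_ANGSTROM * 82.5 / 2.1, rel=0.02)
        assert rec.twist_stiffness_nm == pytest.approx(82.5 / 0.069 / 10, rel=0.02)
        # independent l, w -> no twist-stretch coupling
        assert abs(rec.twist_stretch_nm_per_turn) < 0.05

    def test_twist_stretch_sign_convention(self, rng):
        """Positive coupling: overtwisting lengthens."""
        w = 0.1 * rng.standard_normal(200000)
        l = 100.0 + 2.0 * w + 0.01 * rng.standard_normal(200000)
        rec = mech.material_constants(l, w + 14.8)
        assert rec.twist_stretch_nm_per_turn > 0
        assert rec.twist_stretch_nm_per_turn == pytest.approx(
            2.0 * np.pi / 5, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mech.material_constants(np.full(10, 5.0), np.linspace(1, 2, 10))


class TestSampling:
    def test_mean_and_covariance_recovery(self, rng):
        k = np.array([[2.0, 0.3], [0.3, 1.0]])
        w_hat = np.array([1.0, -2.0])
        s = mech.sample_ensemble(w_hat, k, 100000, seed=9)
        np.testing.assert_allclose(s.mean(axis=0), w_hat, atol=0.01)
        np.testing.assert_allclose(np.cov(s.T), KBT * np.linalg.inv(k),
                                   rtol=0.05, atol=0.002)

    def test_deterministic(self):
        k = np.eye(3)
        a = mech.sample_ensemble(np.zeros(3), k, 100, seed=4)
        b = mech.sample_ensemble(np.zeros(3), k, 100, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_non_spd_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            mech.sample_ensemble(np.zeros(2), -np.eye(2), 10)


class TestPersistence:
    def test_homogeneous_rod_closed_form(self, rng):
        """lp = 2h/<theta^2> for an isotropic rod; alpha ~ 1."""
        sd = 0.05
        steps = rod_steps(rng, 30000, 25, sd_tilt=sd, sd_roll=sd)
        fs = mech.build_frames(steps, equilibrium_steps=rod_equilibrium(25))
        fit = mech.bending_persistence(fs)
        expected_nm = 2 * 3.3 / (2 * sd ** 2) / 10
        assert fit.persistence_nm == pytest.approx(expected_nm, rel=0.05)
        assert fit.alpha == pytest.approx(1.0, abs=0.02)

    def test_zero_fluctuations_unbounded(self):
        steps = np.tile(rod_equilibrium(10)[None], (5, 1, 1))
        fs = mech.build_frames(steps, equilibrium_steps=rod_equilibrium(10))
        fit = mech.bending_persistence(fs)
        assert fit.unbounded

    def test_intrinsically_bent_fluctuation_free(self):
        """Static structure is factored out: a bent but rigid duplex has
        ratio identically 1."""
        eq = rod_equilibrium(12)
        eq[:, 4] = 8.0  # constant roll: intrinsic bend
        steps = np.tile(eq[None], (4, 1, 1))
        fs = mech.build_frames(steps, equilibrium_steps=eq)
        fit = mech.bending_persistence(fs)
        np.testing.assert_allclose(fit.ratio, 1.0, atol=1e-12)
        assert fit.unbounded

    def test_twist_persistence_closed_form_and_c_ltw_half(self, rng):
        sd = 0.06
        steps = rod_steps(rng, 30000, 25, sd_twist=sd)
        steps[..., 2] += 0.02 * rng.standard_normal((30000, 25))
        fs = mech.build_frames(steps, equilibrium_steps=rod_equilibrium(25))
        fit = mech.twist_persistence(fs)
        expected_nm = 2 * 3.3 / sd ** 2 / 10
        assert fit.persistence_nm == pytest.approx(expected_nm, rel=0.05)
        l, w = mech.global_length_twist(fs.h_rise, fs.h_twist)
        rec = mech.material_constants(l, w)
        assert rec.twist_stiffness_nm == pytest.approx(
            fit.persistence_nm / 2, rel=0.05)


class TestStaticDisorder:
    def test_identical_records_no_disorder(self, dna_params):
        """If every hexamer maps to the same record there is no sequence
        disorder and both static persistence lengths are unbounded."""
        rec = dna_params.hexamer("AAAAAA").copy()
        bend, twist = mech.static_persistence(
            _UniformParams(rec), n_seq=20, seq_len=40, seed=0)
        assert bend.unbounded
        assert twist.unbounded

    def test_seed_reproducible(self, dna_params):
        a = mech.static_persistence(dna_params, n_seq=30, seq_len=40, seed=3)
        b = mech.static_persistence(dna_params, n_seq=30, seq_len=40, seed=3)
        assert a[0].persistence_nm == b[0].persistence_nm
        assert a[1].persistence_nm == b[1].persistence_nm

    def test_disorder_scale_matches_closed_form(self):
        """Static bending p.l. ~ 2h/(var_tilt+var_roll) when context
        values are independent across hexamers (flat anchors, so no
        letter-sharing correlation between neighboring steps)."""
        from rigidbase.parameter_io import (
            DNA_DIMER_ANCHORS,
            generate_synthetic_parameters,
        )

        flat = {d: (0.0, 0.0, 3.3, 0.0, 0.0, 34.0) for d in DNA_DIMER_ANCHORS}
        ps = generate_synthetic_parameters(7, dimer_anchor_table=flat,
                                           with_blocks=False)
        bend, _ = mech.static_persistence(ps, n_seq=300, seq_len=80, seed=2)
        rng = np.random.default_rng(0)
        letters = np.array(list("ACGT"))
        vals = []
        for _ in range(500):
            h = "".join(rng.choice(letters, 6))
            vals.append(ps.hexamer(h).central_step[3:5])
        vals = np.deg2rad(np.array(vals))
        var = vals[:, 0].var() + vals[:, 1].var()
        expected_nm = 2 * 3.3 / var / 10
        assert bend.persistence_nm == pytest.approx(expected_nm, rel=0.2)


class _UniformParams:
    """Parameter-set stand-in where every hexamer maps to one record
    (emulates zero sequence disorder)."""

    def __init__(self, rec):
        self._rec = rec
        self.na_type = rec.na_type

    def hexamer(self, seq):
        return self._rec

    def heptamer(self, seq):
        from rigidbase.core import heptamer_from_hexamers

        return heptamer_from_hexamers(self._rec, self._rec)


class TestLengthProfile:
    def test_flat_for_uncorrelated_rod(self, rng):
        h_rise = 3.3 + 0.05 * rng.standard_normal((20000, 10))
        h_twist = 34.0 + 2.0 * rng.standard_normal((20000, 10))
        prof = mech.length_profile(h_rise, h_twist)
        ys = [row["Y_pn"] for row in prof]
        assert max(ys) / min(ys) < 1.1  # flat within MC error
        assert prof[0]["length"] == 2
        # full-length entry equals the whole-duplex constants
        l, w = mech.global_length_twist(h_rise, h_twist)
        rec = mech.material_constants(l, w)
        assert prof[-1]["Y_pn"] == pytest.approx(rec.stretch_modulus_pn)
        assert prof[-1]["C_nm"] == pytest.approx(rec.twist_stiffness_nm)


class TestThreading:
    def test_zero_energy_at_own_means(self, dna_params):
        seq = "GCATTACGGATCCAGTT"
        w = predict_mean_vector(seq, dna_params)
        m = 4
        # template = the model's own predicted roll/twist/slide at offset 0
        tmpl = np.empty((m, 3))
        for t in range(m):
            pos = t + 3
            tmpl[t] = [w[vector_index(len(seq), "step", pos, c)]
                       for c in ("roll", "twist", "slide")]
        prof = mech.thread_template_energy(seq, tmpl, dna_params,
                                           step_subset=("roll", "twist", "slide"))
        assert prof[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(prof[1:] > 0)

    def test_block_diagonal_independent_sum(self, dna_params):
        """With a diagonal stiffness the threading energy is the simple
        per-coordinate harmonic sum."""
        seq = "GCATTACGGA"
        n = len(seq)
        w_hat = predict_mean_vector(seq, dna_params)
        tmpl = np.array([[5.0, 34.0], [2.0, 30.0]])
        subset = ("roll", "twist")
        idx = [vector_index(n, "step", t + 3, c)
               for t in range(2) for c in subset]
        kdiag = np.full(12 * n - 6, 2.0)
        from rigidbase.predictor import StiffnessMatrix

        K = StiffnessMatrix(np.diag(kdiag), n)
        k_eff = effective_stiffness_for_subset(K, np.array(idx))
        delta = tmpl.reshape(-1) - w_hat[idx]
        expected = float(0.5 * delta @ k_eff @ delta)
        brute = 0.5 * np.sum(2.0 * delta ** 2)
        assert expected == pytest.approx(brute)

    def test_template_too_long_rejected(self, dna_params):
        with pytest.raises(ValueError):
            mech.thread_template_energy("GCATTACG", np.zeros((10, 3)), dna_params)
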