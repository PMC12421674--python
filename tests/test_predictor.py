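"""Sliding-window prediction, block assembly, cutoff repair, energies."""

import numpy as np
import pytest

from rigidbase.constants import LAMBDA_C
from rigidbase.core import (
    block_slice,
    complement_stiffness_block,
    complement_vector,
    reverse_complement,
    vector_index,
    vector_length,
)
from rigidbase.predictor import (
    StiffnessMatrix,
    apply_eigenvalue_cutoff,
    assemble_stiffness_matrix,
    band_mask,
    deformation_energy,
    effective_stiffness_for_subset,
    model_stiffness,
    nondimensionalize,
    predict_mean_vector,
    predict_profile,
    redimensionalize,
    trim_to_band,
)


class TestProfile:
    def test_coverage_counts_25bp(self, dna_params):
        seq = "GCGCATATCGCGATCCGATGCATGC"
        prof = predict_profile(seq, dna_params)
        assert len(prof.covered_steps) == 20   # steps 3..22
        assert len(prof.covered_pairs) == 19   # pairs 4..22
        assert prof.covered_steps[0] == 3
        assert prof.covered_pairs[0] == 4
        # three pairs at each end not covered
        assert np.isnan(prof.pair_coords[:3]).all()
        assert np.isnan(prof.pair_coords[-3:]).all()

    def test_constant_window_poly_g(self, dna_params):
        rec = dna_params.hexamer("GGGGGG")
        prof = predict_profile("G" * 12, dna_params)
        for j in prof.covered_steps:
            np.testing.assert_allclose(prof.step_coords[j - 1], rec.central_step)
            assert prof.major_groove[j - 1] == rec.major_groove_width

    def test_too_short_rejected(self, dna_params):
        with pytest.raises(ValueError):
            predict_profile("CATGAC", dna_params)

    def test_complement_symmetry(self, dna_params):
        """The profile of the reverse complement is the parity-transformed
        reversal of the original profile."""
        seq = "GCATTACGGATCCA"
        a = predict_profile(seq, dna_params)
        b = predict_profile(reverse_complement(seq), dna_params)
        n = len(seq)
        # step j of the complement corresponds to step n-j of the original
        for j in b.covered_steps:
            orig = a.step_coords[n - j - 1].copy()
            orig[[0, 3]] *= -1.0  # shift, tilt
            np.testing.assert_allclose(b.step_coords[j - 1], orig, atol=1e-12)
            assert b.major_groove[j - 1] == pytest.approx(
                a.major_groove[n - j - 1])
        for j in b.covered_pairs:
            orig = a.pair_coords[n - j].copy()
            orig[[0, 3]] *= -1.0  # shear, buckle
            np.testing.assert_allclose(b.pair_coords[j - 1], orig, atol=1e-12)


class TestAssembly:
    def test_single_hexamer_equals_block(self, dna_params):
        K = assemble_stiffness_matrix("CATGAC", dna_params)
        np.testing.assert_allclose(K.matrix,
                                   dna_params.hexamer("CATGAC").stiffness_block)

    def test_two_block_overlap_average(self, dna_params):
        seq = "CATGACT"
        K = assemble_stiffness_matrix(seq, dna_params)
        b1 = dna_params.hexamer("CATGAC").stiffness_block
        b2 = dna_params.hexamer("ATGACT").stiffness_block
        # overlap: coordinates 12..65 of block 1 == 0..53 of block 2
        np.testing.assert_allclose(K.matrix[12:66, 12:66],
                                   0.5 * (b1[12:, 12:] + b2[:54, :54]))
        # non-overlapping corners are single-block
        np.testing.assert_allclose(K.matrix[:12, :12], b1[:12, :12])
        np.testing.assert_allclose(K.matrix[66:, 66:], b2[54:, 54:])
        # no coupling outside the hexameric band
        assert np.all(K.matrix[:6, 72:] == 0)

    def test_reassembly_from_extracted_blocks_exact(self, dna_params):
        from rigidbase.ensemble import extract_hexamer_blocks

        seq = "CATGACTTCAGG"
        K = assemble_stiffness_matrix(seq, dna_params)
        blocks, _ = extract_hexamer_blocks(K, seq)
        ps2_records = {}
        for canon, b in blocks.items():
            rec = dna_params.hexamer(canon).copy()
            rec.stiffness_block = b
            ps2_records[canon] = rec
        from rigidbase.parameter_io import ParameterSet

        ps2 = ParameterSet("DNA", ps2_records)
        K2 = assemble_stiffness_matrix(seq, ps2)
        np.testing.assert_allclose(K2.matrix, K.matrix, atol=1e-10)

    def test_complement_covariance(self, dna_params):
        """assemble(revcomp(seq)) equals the signed-permutation transform
        of assemble(seq), exactly."""
        seq = "GCATTACGG"
        K = assemble_stiffness_matrix(seq, dna_params)
        Kc = assemble_stiffness_matrix(reverse_complement(seq), dna_params)
        np.testing.assert_allclose(
            Kc.matrix, complement_stiffness_block(K.matrix, len(seq)),
            atol=1e-10)


class TestUnitsAndCutoff:
    def test_nondimensionalize_translation_unchanged(self):
        m = np.zeros((66, 66))
        i = vector_index(6, "pair", 1, "shear")
        m[i, i] = 2.0
        K = StiffnessMatrix(m, 6)
        assert nondimensionalize(K).matrix[i, i] == 2.0

    def test_nondimensionalize_rotation_121(self):
        m = np.zeros((66, 66))
        i = vector_index(6, "step", 3, "twist")
        m[i, i] = 0.05
        K = StiffnessMatrix(m, 6)
        assert nondimensionalize(K).matrix[i, i] == pytest.approx(6.05)

    def test_round_trip_exact(self, dna_params):
        K = assemble_stiffness_matrix("CATGACT", dna_params)
        back = redimensionalize(nondimensionalize(K))
        np.testing.assert_allclose(back.matrix, K.matrix)

    def test_cutoff_raises_small_eigenvalues(self, rng):
        vecs6, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        vals6 = np.array([-0.10, 0.20, 0.48, 1.0, 5.0, 7.0])
        m6 = (vecs6 * vals6) @ vecs6.T
        K6 = StiffnessMatrix(0.5 * (m6 + m6.T), 1, dimensionless=True)
        out = apply_eigenvalue_cutoff(K6, 0.48)
        got = np.sort(np.linalg.eigvalsh(out.matrix))
        np.testing.assert_allclose(got, [0.48, 0.48, 0.48, 1.0, 5.0, 7.0],
                                   atol=1e-10)
        # eigenvectors of unmodified modes unchanged
        for v in vals6[3:]:
            orig = vecs6[:, np.where(vals6 == v)[0][0]]
            proj = out.matrix @ orig
            np.testing.assert_allclose(proj, v * orig, atol=1e-9)

    def test_cutoff_noop_when_spectrum_above(self, rng):
        m = np.eye(6) * 2.0
        K = StiffnessMatrix(m, 1, dimensionless=True)
        out = apply_eigenvalue_cutoff(K, 0.48)
        np.testing.assert_allclose(out.matrix, m)

    def test_cutoff_requires_nondimensional(self, dna_params):
        K = assemble_stiffness_matrix("CATGAC", dna_params)
        with pytest.raises(ValueError):
            apply_eigenvalue_cutoff(K, 0.48)

    def test_default_cutoffs(self):
        assert LAMBDA_C["DNA"] == 0.48
        assert LAMBDA_C["RNA"] == 0.44

    def test_model_stiffness_min_eigenvalue_above_cutoff(self, dna_params):
        K = model_stiffness("GCATTACGGAT", dna_params, trim=False)
        knd = nondimensionalize(K)
        assert np.linalg.eigvalsh(knd.matrix)[0] >= 0.48 - 1e-8


class TestBandTrim:
    def test_banded_unchanged(self, dna_params):
        K = assemble_stiffness_matrix("CATGACTT", dna_params)
        out = trim_to_band(K)
        np.testing.assert_allclose(out.matrix, K.matrix)

    def test_dense_trim_frobenius(self, rng):
        n_bp = 8
        dim = vector_length(n_bp)
        a = rng.standard_normal((dim, dim + 10))
        m = a @ a.T / dim
        K = StiffnessMatrix(m, n_bp, banded=False)
        out = trim_to_band(K)
        mask = band_mask(n_bp)
        off = np.where(mask, 0.0, m)
        assert np.linalg.norm(m - out.matrix) == pytest.approx(
            np.linalg.norm(off))

    def test_band_pattern(self):
        mask = band_mask(7)
        i = vector_index(7, "pair", 1, "shear")
        j = vector_index(7, "pair", 7, "shear")
        assert not mask[i, j]  # pairs 1 and 7 share no hexamer
        j6 = vector_index(7, "pair", 6, "shear")
        assert mask[i, j6]

    def test_narrow_band_can_break_definiteness(self, rng):
        """Truncating interactions to a too-narrow band can produce an
        indefinite matrix even though the full matrix is SPD."""
        found = False
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 30
            # SPD matrix with strong long-range structure
            u = r.standard_normal((n, 3))
            m = u @ u.T + 0.05 * np.eye(n)
            narrow = np.triu(np.tril(np.ones((n, n)), 2), -2)  # bandwidth 2
            trunc = np.where(narrow > 0, m, 0.0)
            if np.linalg.eigvalsh(trunc)[0] < 0:
                found = True
                break
        assert found


class TestEnergiesAndReduction:
    def test_zero_at_equilibrium(self, dna_params):
        K = model_stiffness("CATGACT", dna_params)
        w = predict_mean_vector("CATGACT", dna_params)
        assert deformation_energy(w, w, K) == 0.0

    def test_single_coordinate_arithmetic(self):
        K = np.array([[0.05]])
        assert deformation_energy([5.0], [0.0], K) == pytest.approx(0.625)

    def test_quadratic_scaling(self, dna_params):
        K = model_stiffness("CATGACT", dna_params)
        w_hat = predict_mean_vector("CATGACT", dna_params)
        d = np.full_like(w_hat, 0.1)
        e1 = deformation_energy(w_hat + d, w_hat, K)
        e2 = deformation_energy(w_hat + 2 * d, w_hat, K)
        assert e2 == pytest.approx(4 * e1)
        assert e1 > 0

    def test_schur_complement_hand_case(self):
        K = np.array([[3.0, 1.0], [1.0, 2.0]])
        red = effective_stiffness_for_subset(K, np.array([0]))
        assert red[0, 0] == pytest.approx(2.5)
        # oracle: brute-force minimization over the free coordinate
        xs = np.linspace(-5, 5, 20001)
        e = 0.5 * (K[0, 0] * 1.0 + 2 * K[0, 1] * xs + K[1, 1] * xs ** 2)
        assert 2 * e.min() == pytest.approx(2.5, abs=1e-6)

    def test_block_diagonal_reduction(self, rng):
        a = rng.uniform(1, 3, 3)
        K = np.diag(np.concatenate([a, rng.uniform(1, 3, 3)]))
        red = effective_stiffness_for_subset(K, np.arange(3))
        np.testing.assert_allclose(red, np.diag(a))

    def test_full_subset_is_identity_operation(self, rng):
        m = np.eye(4) + 0.1 * rng.standard_normal((4, 4))
        m = 0.5 * (m + m.T)
        red = effective_stiffness_for_subset(m, np.arange(4))
        np.testing.assert_allclose(red, m)
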