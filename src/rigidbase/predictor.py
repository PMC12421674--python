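"""Sequence -> shape, groove, coordinate-stiffness, and stiffness-matrix
prediction by hexameric/heptameric sliding windows.

Each base-pair step takes the central-step parameters of the hexamer
centered on it, each base pair the central-pair parameters of its
heptamer (the mean of two overlapping hexamers); the major groove width
is carried by the hexamer's central step and the minor groove width by
the heptamer's central pair. Because a window must fit inside the
sequence, three pairs at each end are not covered.

The nonlocal stiffness matrix is assembled by placing every hexamer's
66x66 block at its position along the diagonal and arithmetically
averaging entries where blocks overlap (an interior entry is covered by
up to six windows). The assembled matrix is exactly zero outside the
hexameric band. Because assembly can leave a handful of near-zero or
negative eigenvalues, a spectral cutoff repair replaces all
nondimensionalized eigenvalues below λc with λc (default 0.48 for DNA,
0.44 for RNA), leaving the eigenvectors untouched; trimming the
repaired matrix back to the band is a small perturbation and is applied
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .constants import ANGLE_SCALE, LAMBDA_C, LENGTH_SCALE
from .core import DuplexSequence, block_slice, vector_length
from .parameter_io import ParameterSet

__all__ = [
    "ShapeProfile",
    "StiffnessMatrix",
    "predict_profile",
    "predict_mean_vector",
    "assemble_stiffness_matrix",
    "unit_scale_vector",
    "nondimensionalize",
    "redimensionalize",
    "apply_eigenvalue_cutoff",
    "trim_to_band",
    "band_mask",
    "deformation_energy",
    "effective_stiffness_for_subset",
]


@dataclass
class ShapeProfile:
    """Per-position predicted shape and coordinate stiffness.

    Arrays are indexed by 1-based position minus one; uncovered end
    positions (three pairs on each side) hold NaN and are listed by the
    coverage masks rather than silently filled.
    """

    sequence: str
    na_type: str
    pair_coords: np.ndarray        # (N, 6), NaN where uncovered
    step_coords: np.ndarray        # (N-1, 6)
    minor_groove: np.ndarray       # (N,) per covered pair
    major_groove: np.ndarray       # (N-1,) per covered step
    pair_stiffness: np.ndarray     # (N, 6)
    step_stiffness: np.ndarray     # (N-1, 6)
    minor_groove_stiffness: np.ndarray
    major_groove_stiffness: np.ndarray

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def covered_steps(self) -> np.ndarray:
        """1-based indices of steps with a full hexameric context."""
        return np.where(~np.isnan(self.step_coords[:, 0]))[0] + 1

    @property
    def covered_pairs(self) -> np.ndarray:
        return np.where(~np.isnan(self.pair_coords[:, 0]))[0] + 1


@dataclass
class StiffnessMatrix:
    """Symmetric stiffness matrix over the duplex coordinate vector."""

    matrix: np.ndarray
    n_bp: int
    banded: bool = True
    dimensionless: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = vector_length(self.n_bp)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n},{n})")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


def _window_records(seq: DuplexSequence, ps: ParameterSet):
    for start in range(len(seq) - 5):
        yield start + 1, ps.hexamer(seq.letters[start:start + 6])


def predict_profile(seq: DuplexSequence | str, ps: ParameterSet) -> ShapeProfile:
    """Sliding-window prediction of shape, grooves, and kx profiles.

    Step j (1-based) takes the central-step values of the hexamer at
    pairs j-2..j+3 (covered for 3 <= j <= N-3); pair j takes the
    central-pair values of the heptamer at pairs j-3..j+3 (covered for
    4 <= j <= N-3). Requires at least 7 bp.
    """
    if isinstance(seq, str):
        seq = DuplexSequence(seq, ps.na_type)
    n = len(seq)
    if n < 7:
        raise ValueError("sequence must have at least 7 bp for pair-level output")
    prof = ShapeProfile(
        seq.letters, ps.na_type,
        np.full((n, 6), np.nan), np.full((n - 1, 6), np.nan),
        np.full(n, np.nan), np.full(n - 1, np.nan),
        np.full((n, 6), np.nan), np.full((n - 1, 6), np.nan),
        np.full(n, np.nan), np.full(n - 1, np.nan),
    )
    for j in range(3, n - 2):          # steps 3..N-3
        rec = ps.hexamer(seq.letters[j - 3:j + 3])
        prof.step_coords[j - 1] = rec.central_step
        prof.step_stiffness[j - 1] = rec.step_stiffness[2]
        prof.major_groove[j - 1] = rec.major_groove_width
        prof.major_groove_stiffness[j - 1] = rec.major_groove_stiffness
    for j in range(4, n - 2):          # pairs 4..N-3
        rec = ps.heptamer(seq.letters[j - 4:j + 3])
        prof.pair_coords[j - 1] = rec.central_pair
        prof.pair_stiffness[j - 1] = rec.pair_stiffness
        prof.minor_groove[j - 1] = rec.minor_groove_width
        prof.minor_groove_stiffness[j - 1] = rec.minor_groove_stiffness
    return prof


def predict_mean_vector(seq: DuplexSequence | str, ps: ParameterSet,
                        fill_ends: bool = True) -> np.ndarray:
    """Equilibrium coordinate vector ŵ of the duplex.

    End positions not covered by the sliding windows are filled with
    the values of the nearest covered window (needed for energies and
    frame reconstruction over the full vector); pass
    ``fill_ends=False`` to keep NaN there.
    """
    if isinstance(seq, str):
        seq = DuplexSequence(seq, ps.na_type)
    n = len(seq)
    if n < 6:
        raise ValueError("sequence must have at least 6 bp")
    w = np.full(vector_length(n), np.nan)
    pair_rows = np.full((n, 6), np.nan)
    step_rows = np.full((n - 1, 6), np.nan)
    if n >= 7:
        prof = predict_profile(seq, ps)
        pair_rows = prof.pair_coords.copy()
        step_rows = prof.step_coords.copy()
    else:
        rec = ps.hexamer(seq.letters)
        pair_rows = rec.pair_coords.copy()
        step_rows = rec.step_coords.copy()
    if fill_ends:
        # hexamer windows at the very ends supply the missing values
        first = ps.hexamer(seq.letters[:6])
        last = ps.hexamer(seq.letters[-6:])
        for j in range(n):
            if np.isnan(pair_rows[j, 0]):
                pair_rows[j] = first.pair_coords[j] if j < 3 \
                    else last.pair_coords[j - (n - 6)]
        for j in range(n - 1):
            if np.isnan(step_rows[j, 0]):
                step_rows[j] = first.step_coords[j] if j < 3 \
                    else last.step_coords[j - (n - 6)]
    for p in range(n):
        w[p * 12:p * 12 + 6] = pair_rows[p]
        if p < n - 1:
            w[p * 12 + 6:p * 12 + 12] = step_rows[p]
    return w


def assemble_stiffness_matrix(seq: DuplexSequence | str,
                              ps: ParameterSet) -> StiffnessMatrix:
    """Assemble the banded stiffness matrix from hexameric blocks.

    Each hexamer window contributes its 66x66 block at its slice of
    the coordinate vector; entries covered by several windows are
    arithmetic means of the contributing blocks.
    """
    if isinstance(seq, str):
        seq = DuplexSequence(seq, ps.na_type)
    n = len(seq)
    if n < 6:
        raise ValueError("sequence must have at least 6 bp")
    dim = vector_length(n)
    acc = np.zeros((dim, dim))
    cnt = np.zeros((dim, dim))
    for start, rec in _window_records(seq, ps):
        if rec.stiffness_block is None:
            raise ValueError(f"hexamer {rec.sequence} has no stiffness block")
        sl = block_slice(start, n)
        acc[sl, sl] += rec.stiffness_block
        cnt[sl, sl] += 1.0
    with np.errstate(invalid="ignore"):
        mat = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1.0), 0.0)
    mat = 0.5 * (mat + mat.T)
    return StiffnessMatrix(mat, n, banded=True, dimensionless=False,
                           meta={"sequence": seq.letters, "na_type": ps.na_type})


def unit_scale_vector(n_bp: int) -> np.ndarray:
    """Per-coordinate nondimensionalization scales (1 Å / 11 deg)."""
    scales = np.array([LENGTH_SCALE] * 3 + [ANGLE_SCALE] * 3)
    parts = []
    for p in range(n_bp):
        parts.append(scales)
        if p < n_bp - 1:
            parts.append(scales)
    return np.concatenate(parts)


def nondimensionalize(K: StiffnessMatrix) -> StiffnessMatrix:
    """Make all entries kcal/mol via K_nd[i,j] = K[i,j]*s_i*s_j."""
    if K.dimensionless:
        return K
    s = unit_scale_vector(K.n_bp)
    return StiffnessMatrix(K.matrix * np.outer(s, s), K.n_bp,
                           banded=K.banded, dimensionless=True, meta=dict(K.meta))


def redimensionalize(K: StiffnessMatrix) -> StiffnessMatrix:
    """Exact inverse of :func:`nondimensionalize`."""
    if not K.dimensionless:
        return K
    s = unit_scale_vector(K.n_bp)
    return StiffnessMatrix(K.matrix / np.outer(s, s), K.n_bp,
                           banded=K.banded, dimensionless=False, meta=dict(K.meta))


def apply_eigenvalue_cutoff(K: StiffnessMatrix,
                            lambda_c: float | None = None) -> StiffnessMatrix:
    """Replace eigenvalues below λc by λc (spectral repair).

    Operates on the nondimensionalized matrix: K = P D P^T with D the
    eigenvalues; entries of D below the cutoff are raised to the
    cutoff and the matrix reassembled, leaving eigenvectors unchanged.
    This is the minimal perturbation making the smallest eigenvalue
    >= λc.
    """
    if not K.dimensionless:
        raise ValueError("eigenvalue cutoff must be applied to the "
                         "nondimensionalized matrix")
    if lambda_c is None:
        lambda_c = LAMBDA_C[K.meta.get("na_type", "DNA")]
    m = K.matrix
    if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(m)
    if vals[0] >= lambda_c:
        out = StiffnessMatrix(m.copy(), K.n_bp, banded=K.banded,
                              dimensionless=True, meta=dict(K.meta))
        out.meta["lambda_c"] = lambda_c
        return out
    clipped = np.maximum(vals, lambda_c)
    mat = (vecs * clipped) @ vecs.T
    mat = 0.5 * (mat + mat.T)
    out = StiffnessMatrix(mat, K.n_bp, banded=False, dimensionless=True,
                          meta=dict(K.meta))
    out.meta["lambda_c"] = lambda_c
    return out


def band_mask(n_bp: int) -> np.ndarray:
    """Boolean mask of entries inside the union of hexameric blocks."""
    dim = vector_length(n_bp)
    mask = np.zeros((dim, dim), dtype=bool)
    if n_bp <= 6:
        mask[:] = True
        return mask
    for start in range(1, n_bp - 4):
        sl = block_slice(start, n_bp)
        mask[sl, sl] = True
    return mask


def trim_to_band(K: StiffnessMatrix) -> StiffnessMatrix:
    """Zero all entries outside the hexameric band.

    Reports (in ``meta``) whether the trimmed matrix is still positive
    definite — truncating interactions to too narrow a band can break
    definiteness.
    """
    mask = band_mask(K.n_bp)
    mat = np.where(mask, K.matrix, 0.0)
    out = StiffnessMatrix(mat, K.n_bp, banded=True,
                          dimensionless=K.dimensionless, meta=dict(K.meta))
    out.meta["positive_definite_after_trim"] = bool(
        np.linalg.eigvalsh(mat)[0] > 0)
    return out


def model_stiffness(seq: DuplexSequence | str, ps: ParameterSet,
                    lambda_c: float | None = None,
                    cutoff: bool = True, trim: bool = True) -> StiffnessMatrix:
    """Assembled stiffness with the default repair pipeline applied.

    Assembly -> nondimensionalize -> eigenvalue cutoff -> band trim ->
    redimensionalize. ``cutoff=False`` skips the spectral repair,
    ``trim=False`` keeps the repaired (generally dense) matrix.
    """
    K = assemble_stiffness_matrix(seq, ps)
    if not cutoff:
        return K
    K = apply_eigenvalue_cutoff(nondimensionalize(K), lambda_c)
    if trim:
        K = trim_to_band(K)
    return redimensionalize(K)


def deformation_energy(w: np.ndarray, w_hat: np.ndarray,
                       K: StiffnessMatrix | np.ndarray) -> float:
    """Quadratic deformation energy E = 1/2 (w-ŵ)ᵀ K (w-ŵ), kcal/mol.

    Units must be consistent: a dimensional K with raw coordinates, or
    a nondimensional K with scaled coordinates.
    """
    mat = K.matrix if isinstance(K, StiffnessMatrix) else np.asarray(K, float)
    d = np.asarray(w, float) - np.asarray(w_hat, float)
    if d.shape[-1] != mat.shape[0]:
        raise ValueError("dimension mismatch between coordinates and stiffness")
    return float(0.5 * d @ mat @ d)


def effective_stiffness_for_subset(K: StiffnessMatrix | np.ndarray,
                                   constrained: np.ndarray) -> np.ndarray:
    """Effective stiffness of a coordinate subset, all others relaxed.

    With the free coordinates minimized out, the energy of the
    constrained subset c is governed by the Schur complement
    K_cc - K_cf K_ff^{-1} K_fc.
    """
    mat = K.matrix if isinstance(K, StiffnessMatrix) else np.asarray(K, float)
    n = mat.shape[0]
    constrained = np.asarray(constrained, dtype=np.intp)
    if constrained.size == 0:
        raise ValueError("constrained subset must be non-empty")
    free = np.setdiff1d(np.arange(n), constrained)
    if free.size == 0:
        return mat.copy()
    kcc = mat[np.ix_(constrained, constrained)]
    kcf = mat[np.ix_(constrained, free)]
    kff = mat[np.ix_(free, free)]
    try:
        sol = np.linalg.solve(kff, kcf.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("free-coordinate block is singular") from exc
    red = kcc - kcf @ sol
    return 0.5 * (red + red.T)
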