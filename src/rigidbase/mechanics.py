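"""Elastic-rod analysis of duplex ensembles: 3D reconstruction, global
length and twist, material constants, persistence lengths, static
disorder, length-dependence profiles, and template threading energies.

Base-pair frames are reconstructed from step coordinates with the
mid-step triad composition used by 3DNA: the step rotation is
Rz(Ω/2-φ)·Ry(Γ)·Rz(Ω/2+φ) with bend Γ = sqrt(tilt²+roll²) and phase
φ = atan2(tilt, roll), and the displacement (shift, slide, rise) is
expressed in the mid-step frame. The helical rise and twist of a step
are the projection of the displacement on the step's rotation axis and
the step's rotation angle.

Global length l = Σ h-rise and twist ω = Σ h-twist (rad) fluctuate in
thermal equilibrium; their variances give the stretch modulus
Y = kBT·l0/var(l) (pN), the torsionally relaxed twist stiffness
C = l0/var(ω) (length units), and the twist-stretch coupling
k = cov(l,ω)/var(ω) (reported in nm/turn via the factor π/5). Bending
and twist persistence lengths come from semilog fits of the normal and
twist correlation decays with the equilibrium (static) structure
factored out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KBT, KBT_PN_ANGSTROM
from .core import DuplexSequence, vector_index
from .parameter_io import ParameterSet
from .predictor import (
    StiffnessMatrix,
    effective_stiffness_for_subset,
    model_stiffness,
    predict_mean_vector,
)

__all__ = [
    "FrameSeries",
    "GlobalElasticRecord",
    "PersistenceFit",
    "sample_ensemble",
    "step_to_helical",
    "build_frames",
    "global_length_twist",
    "material_constants",
    "bending_persistence",
    "twist_persistence",
    "static_persistence",
    "length_profile",
    "thread_template_energy",
]


# ---------------------------------------------------------------------------
# Gaussian sampling
# ---------------------------------------------------------------------------

def sample_ensemble(w_hat: np.ndarray, K: StiffnessMatrix | np.ndarray,
                    n: int, seed: int = 0) -> np.ndarray:
    """Draw n samples from the Gaussian N(ŵ, kBT·K⁻¹).

    K must be symmetric positive definite (post-cutoff). Sampling uses
    the Cholesky factor of K: w = ŵ + sqrt(kBT)·L^{-T} z.
    """
    mat = K.matrix if isinstance(K, StiffnessMatrix) else np.asarray(K, float)
    w_hat = np.asarray(w_hat, float)
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        chol = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "stiffness matrix is not positive definite; apply the "
            "eigenvalue cutoff first") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, mat.shape[0]))
    # solve L^T x = z  =>  cov(x) = (L L^T)^{-1} = K^{-1}
    x = np.linalg.solve(chol.T, z.T).T
    return w_hat + np.sqrt(KBT) * x


# ---------------------------------------------------------------------------
# Step geometry (mid-step triad convention)
# ---------------------------------------------------------------------------

def _rz(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _ry(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    out[..., 1, 1] = 1.0
    return out


def step_rotation_displacement(step: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step rotation matrix and displacement in the preceding frame.

    ``step`` has trailing dimension 6: (shift, slide, rise, tilt, roll,
    twist), angles in degrees. Vectorized over leading dimensions.
    """
    step = np.asarray(step, float)
    shift, slide, rise = step[..., 0], step[..., 1], step[..., 2]
    tilt = np.deg2rad(step[..., 3])
    roll = np.deg2rad(step[..., 4])
    twist = np.deg2rad(step[..., 5])
    gamma = np.hypot(tilt, roll)
    phi = np.arctan2(tilt, roll)
    rot = _rz(twist / 2 - phi) @ _ry(gamma) @ _rz(twist / 2 + phi)
    mst = _rz(twist / 2 - phi) @ _ry(gamma / 2) @ _rz(phi)
    disp = (mst @ np.stack([shift, slide, rise], axis=-1)[..., None])[..., 0]
    return rot, disp


def step_to_helical(step: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Helical rise and twist of one or many steps.

    h-twist is the rotation angle of the full step rotation (signed
    about the axis closer to the mid-step z), h-rise the displacement
    projected on that axis. In the near-zero-rotation limit the axis is
    undefined and the convention h-rise = |displacement·ẑ|, h-twist = 0
    is used. Returns (h_rise Å, h_twist deg) arrays.
    """
    rot, disp = step_rotation_displacement(step)
    # rotation vector from the skew part; angle from trace
    tr = np.clip((np.trace(rot, axis1=-2, axis2=-1) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(tr)
    axis = np.stack([
        rot[..., 2, 1] - rot[..., 1, 2],
        rot[..., 0, 2] - rot[..., 2, 0],
        rot[..., 1, 0] - rot[..., 0, 1],
    ], axis=-1)
    norm = np.linalg.norm(axis, axis=-1, keepdims=True)
    small = norm[..., 0] < 1e-12
    safe = np.where(norm > 1e-12, norm, 1.0)
    axis = axis / safe
    # sign convention: axis with positive z-component, signed angle
    flip = axis[..., 2] < 0
    axis = np.where(flip[..., None], -axis, axis)
    h_twist = np.where(flip, -angle, angle)
    h_rise = np.einsum("...i,...i->...", disp, axis)
    h_rise = np.where(small, np.abs(disp[..., 2]), h_rise)
    h_twist = np.where(small, 0.0, h_twist)
    return h_rise, np.rad2deg(h_twist)


@dataclass
class FrameSeries:
    """Orthonormal base-pair frames and origins per snapshot.

    ``frames`` has shape (n_snapshots, n_pairs, 3, 3) with the pair
    normal in the last column; ``origins`` (n_snapshots, n_pairs, 3).
    ``equilibrium`` optionally holds the FrameSeries of the model's
    equilibrium structure (one snapshot).
    """

    frames: np.ndarray
    origins: np.ndarray
    h_rise: np.ndarray    # (n_snapshots, n_steps) Å
    h_twist: np.ndarray   # (n_snapshots, n_steps) deg
    equilibrium: "FrameSeries | None" = None

    @property
    def normals(self) -> np.ndarray:
        return self.frames[..., :, 2]

    @property
    def n_steps(self) -> int:
        return self.h_rise.shape[-1]


def build_frames(steps: np.ndarray,
                 equilibrium_steps: np.ndarray | None = None) -> FrameSeries:
    """Reconstruct 3D frames from per-step coordinate series.

    ``steps`` has shape (n_snapshots, n_steps, 6) (a single snapshot
    may omit the leading axis). Frames are composed step by step with
    the mid-step triad convention, starting from the identity frame at
    the origin.
    """
    steps = np.asarray(steps, float)
    single = steps.ndim == 2
    if single:
        steps = steps[None]
    n_snap, n_steps, _ = steps.shape
    rot, disp = step_rotation_displacement(steps)
    frames = np.empty((n_snap, n_steps + 1, 3, 3))
    origins = np.empty((n_snap, n_steps + 1, 3))
    frames[:, 0] = np.eye(3)
    origins[:, 0] = 0.0
    for s in range(n_steps):
        origins[:, s + 1] = origins[:, s] + \
            np.einsum("nij,nj->ni", frames[:, s], disp[:, s])
        frames[:, s + 1] = frames[:, s] @ rot[:, s]
    h_rise, h_twist = step_to_helical(steps)
    eq = None
    if equilibrium_steps is not None:
        eq = build_frames(equilibrium_steps)
    return FrameSeries(frames, origins, h_rise, h_twist, equilibrium=eq)


def extract_steps(frames: np.ndarray, origins: np.ndarray) -> np.ndarray:
    """Inverse of :func:`build_frames`: recover step coordinates.

    Accepts (n_pairs, 3, 3)/(n_pairs, 3) or batched arrays; returns
    step coordinates with angles in degrees.
    """
    frames = np.asarray(frames, float)
    origins = np.asarray(origins, float)
    single = frames.ndim == 3
    if single:
        frames, origins = frames[None], origins[None]
    rel = np.swapaxes(frames[:, :-1], -1, -2) @ frames[:, 1:]
    d_lab = origins[:, 1:] - origins[:, :-1]
    d_loc = np.einsum("nsij,nsj->nsi", np.swapaxes(frames[:, :-1], -1, -2), d_lab)
    # invert rel = Rz(a) Ry(g) Rz(b) with a = t/2 - phi, b = t/2 + phi:
    # rel e_z = (sin g cos a, sin g sin a, cos g) fixes g and a, the
    # residual Ry(g)^T Rz(a)^T rel = Rz(b) fixes b.
    zcol = rel[..., :, 2]
    gamma = np.arccos(np.clip(zcol[..., 2], -1, 1))
    a = np.arctan2(zcol[..., 1], zcol[..., 0])
    rest = np.swapaxes(_ry(gamma), -1, -2) @ np.swapaxes(_rz(a), -1, -2) @ rel
    b = np.arctan2(rest[..., 1, 0], rest[..., 0, 0])
    twist = a + b
    # atan2 branch cuts can shift a (and hence twist) by 2*pi and phi by
    # pi; wrap the twist into (-pi, pi] and restore the matching phi
    k = np.round(twist / (2 * np.pi))
    twist = twist - 2 * np.pi * k
    phi = (b - a) / 2 + np.pi * k
    tilt = gamma * np.sin(phi)
    roll = gamma * np.cos(phi)
    mst = _rz(twist / 2 - phi) @ _ry(gamma / 2) @ _rz(phi)
    loc = np.einsum("nsij,nsi->nsj", mst, d_loc)  # mst^T d_loc
    out = np.stack([loc[..., 0], loc[..., 1], loc[..., 2],
                    np.rad2deg(tilt), np.rad2deg(roll), np.rad2deg(twist)],
                   axis=-1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Global elasticity
# ---------------------------------------------------------------------------

def global_length_twist(h_rise: np.ndarray,
                        h_twist_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global length (Å) and twist (rad): sums over steps."""
    h_rise = np.atleast_2d(np.asarray(h_rise, float))
    h_twist = np.atleast_2d(np.asarray(h_twist_deg, float))
    l = h_rise.sum(axis=-1)
    omega = np.deg2rad(h_twist).sum(axis=-1)
    return np.squeeze(l), np.squeeze(omega)


@dataclass
class GlobalElasticRecord:
    """Rod-level elastic constants of a duplex (or fragment)."""

    l0: float                 # equilibrium length, Å
    omega0: float             # equilibrium twist, rad
    sigma_rod: np.ndarray     # 2x2 covariance of (l, ω)
    k_rod: np.ndarray         # 2x2 stiffness kBT·l0·Σ⁻¹, kcal/mol units
    stretch_modulus_pn: float     # Y, pN
    twist_stiffness_nm: float     # C, nm
    twist_stretch_nm_per_turn: float  # k, nm/turn


def material_constants(l: np.ndarray, omega: np.ndarray,
                       l0: float | None = None) -> GlobalElasticRecord:
    """Rod constants from samples of global length (Å) and twist (rad).

    Y = kBT·l0/var(l) in pN; C = l0/var(ω) reported in nm; the
    twist-stretch coupling k = cov(l,ω)/var(ω) in Å/rad is reported in
    nm/turn (factor π/5).
    """
    l = np.asarray(l, float)
    omega = np.asarray(omega, float)
    if l.size < 2:
        raise ValueError("need at least 2 samples")
    if l0 is None:
        l0 = float(l.mean())
    omega0 = float(omega.mean())
    sigma = np.cov(np.stack([l, omega]))
    var_l, var_w = sigma[0, 0], sigma[1, 1]
    if var_l <= 0 or var_w <= 0:
        raise ValueError("zero variance in global coordinates")
    y_pn = KBT_PN_ANGSTROM * l0 / var_l
    c_nm = (l0 / var_w) / 10.0
    k_nm_turn = (sigma[0, 1] / var_w) * (np.pi / 5.0)
    k_rod = KBT * l0 * np.linalg.inv(sigma)
    return GlobalElasticRecord(l0, omega0, sigma, k_rod, y_pn, c_nm, k_nm_turn)


# ---------------------------------------------------------------------------
# Persistence lengths
# ---------------------------------------------------------------------------

@dataclass
class PersistenceFit:
    """Semilog fit of a correlation decay vs contour distance."""

    kind: str
    l_i0: np.ndarray          # abscissa, Å (mean contour distance to pair i)
    ratio: np.ndarray         # ordinate series (correlation ratio)
    persistence_nm: float     # decay length, nm (inf if no decay)
    alpha: float              # prefactor
    r_squared: float
    fit_range: tuple[int, int]
    excluded: list[int] = field(default_factory=list)

    @property
    def unbounded(self) -> bool:
        return not np.isfinite(self.persistence_nm)


def _semilog_fit(kind: str, l_i0: np.ndarray, ratio: np.ndarray,
                 fit_range: tuple[int, int] | None) -> PersistenceFit:
    n = ratio.size
    lo, hi = (1, n) if fit_range is None else fit_range
    idx = np.arange(lo - 1, min(hi, n))
    excluded = [int(i + 1) for i in idx if ratio[i] <= 0]
    use = np.array([i for i in idx if ratio[i] > 0], dtype=int)
    if use.size < 3:
        raise ValueError("fewer than 3 usable separations in fit range")
    x = l_i0[use]
    y = np.log(ratio[use])
    slope, intercept = np.polyfit(x, y, 1)
    yfit = slope * x + intercept
    ss_res = float(np.sum((y - yfit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0 or abs(slope) < 1e-14:
        lp = np.inf
    else:
        lp = (-1.0 / slope) / 10.0  # Å -> nm
    return PersistenceFit(kind, l_i0, ratio, lp, float(np.exp(intercept)),
                          r2, (lo, min(hi, n)), excluded)


def bending_persistence(series: FrameSeries,
                        fit_range: tuple[int, int] | None = None) -> PersistenceFit:
    """Dynamic bending persistence length from normal correlations.

    Fits log(⟨t_i·t_0⟩ / t̂_i·t̂_0) = log α_d − l_i0/l_d; the
    equilibrium normals factor out the static structure, so an
    intrinsically bent but fluctuation-free duplex has ratio ≡ 1.
    Distances l_i0 are ensemble means of the summed helical rises.
    """
    if series.equilibrium is None:
        raise ValueError("equilibrium frames required to factor out "
                         "the static structure")
    t = series.normals
    t_hat = series.equilibrium.normals[0]
    corr = np.mean(np.einsum("npi,ni->np", t[:, 1:], t[:, 0]), axis=0)
    eq_corr = t_hat[1:] @ t_hat[0]
    ratio = corr / eq_corr
    l_i0 = np.cumsum(series.h_rise.mean(axis=0))
    return _semilog_fit("dynamic-bend", l_i0, ratio, fit_range)


def twist_persistence(series: FrameSeries,
                      fit_range: tuple[int, int] | None = None) -> PersistenceFit:
    """Twist persistence length from ⟨cos Δω_i⟩ decay.

    ω_i is the accumulated helical twist from pair 0 to pair i;
    Δω_i = ω_i − ⟨ω_i⟩ removes the equilibrium twist.
    """
    omega = np.cumsum(np.deg2rad(series.h_twist), axis=1)
    d_omega = omega - omega.mean(axis=0)
    ratio = np.mean(np.cos(d_omega), axis=0)
    l_i0 = np.cumsum(series.h_rise.mean(axis=0))
    return _semilog_fit("twist", l_i0, ratio, fit_range)


def static_persistence(ps: ParameterSet, n_seq: int = 400, seq_len: int = 150,
                       seed: int = 0,
                       fit_range: tuple[int, int] | None = None,
                       ) -> tuple[PersistenceFit, PersistenceFit]:
    """Static bending/twist persistence lengths from sequence disorder.

    Random sequences' equilibrium structures are treated as snapshots
    of a virtual ensemble; the factored-out reference is the
    sequence-averaged static structure. Identical hexamer records give
    no static disorder (both lengths unbounded).
    """
    rng = np.random.default_rng(seed)
    alphabet = "ACGT" if ps.na_type == "DNA" else "ACGU"
    n_steps = seq_len - 1
    steps = np.empty((n_seq, n_steps, 6))
    for i in range(n_seq):
        letters = "".join(rng.choice(list(alphabet), size=seq_len))
        w = predict_mean_vector(DuplexSequence(letters, ps.na_type), ps)
        steps[i] = np.stack([w[p * 12 + 6:p * 12 + 12] for p in range(n_steps)])
    mean_steps = steps.mean(axis=0)
    series = build_frames(steps, equilibrium_steps=mean_steps)
    bend = bending_persistence(series, fit_range)
    bend.kind = "static-bend"
    twist = twist_persistence(series, fit_range)
    twist.kind = "static-twist"
    return bend, twist


def length_profile(h_rise: np.ndarray, h_twist_deg: np.ndarray,
                   fragment_range: tuple[int, int] | None = None):
    """Mean elastic constants per fragment length.

    For every contiguous fragment (all start offsets) of each length in
    ``fragment_range`` (bp, inclusive; default 2 up to the full
    duplex), the rod constants are computed across snapshots and then
    averaged over fragments of equal length. Returns a list of dicts
    with keys length, Y_pn, C_nm, k_nm_per_turn.
    """
    h_rise = np.asarray(h_rise, float)
    h_twist = np.asarray(h_twist_deg, float)
    n_steps = h_rise.shape[1]
    lo, hi = fragment_range or (2, n_steps + 1)
    out = []
    for length in range(max(2, lo), min(hi, n_steps + 1) + 1):
        m = length - 1  # steps in the fragment
        ys, cs, ks = [], [], []
        for start in range(n_steps - m + 1):
            l = h_rise[:, start:start + m].sum(axis=1)
            w = np.deg2rad(h_twist[:, start:start + m]).sum(axis=1)
            rec = material_constants(l, w)
            ys.append(rec.stretch_modulus_pn)
            cs.append(rec.twist_stiffness_nm)
            ks.append(rec.twist_stretch_nm_per_turn)
        out.append({"length": length, "Y_pn": float(np.mean(ys)),
                    "C_nm": float(np.mean(cs)),
                    "k_nm_per_turn": float(np.mean(ks))})
    return out


# ---------------------------------------------------------------------------
# Template threading
# ---------------------------------------------------------------------------

_SUBSET_DEFAULT = ("roll", "twist", "slide")


def thread_template_energy(seq: DuplexSequence | str, template: np.ndarray,
                           ps: ParameterSet,
                           step_subset: tuple[str, ...] = _SUBSET_DEFAULT,
                           lambda_c: float | None = None,
                           cutoff: bool = True) -> np.ndarray:
    """Deformation energy of threading a structural template along a
    sequence (partially relaxed model).

    ``template`` has shape (n_template_steps, len(step_subset)): imposed
    values of the subset coordinates (default roll, twist, slide — the
    step coordinates conserved among nucleosome structures). For each
    offset the model shape and stiffness of the local window are
    predicted, the stiffness is reduced to the constrained subset by
    the Schur complement (all other coordinates relax), and
    E = 1/2 Δᵀ K_eff Δ with Δ = template − predicted means. Returns the
    energy profile over offsets (kcal/mol).
    """
    if isinstance(seq, str):
        seq = DuplexSequence(seq, ps.na_type)
    template = np.asarray(template, float)
    m = template.shape[0]
    if template.shape != (m, len(step_subset)):
        raise ValueError("template shape must be (n_steps, len(step_subset))")
    n = len(seq)
    # window: template steps t..t+m-1 need hexamer context 2 pairs left,
    # 3 pairs right of the covered steps
    win_bp = m + 1 + 5
    if win_bp > n:
        raise ValueError("template longer than the sequence allows")
    energies = []
    for off in range(n - win_bp + 1):
        sub = DuplexSequence(seq.letters[off:off + win_bp], ps.na_type)
        K = model_stiffness(sub, ps, lambda_c=lambda_c, cutoff=cutoff)
        w_hat = predict_mean_vector(sub, ps)
        idx = []
        means = []
        for t in range(m):
            pos = t + 3  # 1-based step index inside the window (3..m+2)
            for c in step_subset:
                idx.append(vector_index(win_bp, "step", pos, c))
        idx = np.asarray(idx, dtype=np.intp)
        means = w_hat[idx]
        k_eff = effective_stiffness_for_subset(K, idx)
        delta = template.reshape(-1) - means
        energies.append(float(0.5 * delta @ k_eff @ delta))
    return np.asarray(energies)
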