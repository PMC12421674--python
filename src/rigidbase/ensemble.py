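"""Parameter estimation from coordinate ensembles.

This module goes from snapshot ensembles (MD-style coordinate time
series plus Watson-Crick hydrogen-bond distance series) to model
parameters: snapshots with a broken H-bond anywhere in the central part
of the duplex are filtered out (a bond is broken when its heavy-atom
distance exceeds 4 Å; the two outer G-C cap pairs are ignored); means
and covariances are estimated from the kept snapshots; the banded
stiffness matrix is the maximum-absolute-entropy completion whose
implied covariance matches the sample covariance on every entry inside
the hexameric band; hexameric blocks are cut out of it for reuse on
arbitrary sequences.

Base-pair opening kinetics are summarized by the survival function of
opening-event durations: an exponential survival S(t) = exp(-λt) has
mean open-pair lifetime τ_open = -1/λ, estimated by a straight-line fit
to ln S(t) on a window where it is close to linear.

A synthetic trajectory generator (Gaussian coordinates from a model,
H-bond distances with injected exponential-duration excursions) makes
the whole chain testable end to end without MD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KBT
from .core import block_slice, canonical_class, vector_length
from .parameter_io import ParameterSet
from .predictor import StiffnessMatrix

__all__ = [
    "CoordinateTimeSeries",
    "HBondSeries",
    "SurvivalFit",
    "filter_snapshots",
    "estimate_mean_cov",
    "banded_maxent_stiffness",
    "extract_hexamer_blocks",
    "convergence_error",
    "opening_events",
    "survival_fit",
    "synthetic_trajectory",
]

HBOND_BREAK_ANGSTROM = 4.0

#: Number of Watson-Crick hydrogen bonds per pair type.
_N_BONDS = {"A": 2, "T": 2, "U": 2, "G": 3, "C": 3}


@dataclass
class CoordinateTimeSeries:
    """Snapshots of the duplex coordinate vector.

    ``values`` has shape (n_snapshots, 12*n_bp-6); timestamps in ps.
    """

    sequence: str
    values: np.ndarray
    timestamps_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        n = self.values.shape[1]
        if n != vector_length(len(self.sequence)):
            raise ValueError("coordinate dimension inconsistent with sequence")
        if self.timestamps_ps is None:
            self.timestamps_ps = 10.0 * np.arange(self.values.shape[0])
        self.timestamps_ps = np.asarray(self.timestamps_ps, float)
        if np.any(np.diff(self.timestamps_ps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sequence: str) -> "CoordinateTimeSeries":
        """Build from a long table (snapshot, index, value)."""
        wide = df.pivot(index="snapshot", columns="index", values="value")
        return cls(sequence, wide.to_numpy(float))


@dataclass
class HBondSeries:
    """Heavy-atom H-bond distances per snapshot, pair, and bond.

    ``distances`` has shape (n_snapshots, n_pairs, max_bonds); unused
    bond slots (A-T/A-U pairs have 2 bonds, G-C 3) hold NaN.
    """

    sequence: str
    distances: np.ndarray
    timestep_ps: float = 10.0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, float)
        if self.distances.ndim != 3:
            raise ValueError("distances must be (snapshots, pairs, bonds)")
        if self.distances.shape[1] != len(self.sequence):
            raise ValueError("pair axis inconsistent with sequence")
        with np.errstate(invalid="ignore"):
            if np.any(self.distances <= 0):
                raise ValueError("distances must be positive")

    def broken(self) -> np.ndarray:
        """(n_snapshots, n_pairs) boolean: any bond of the pair > 4 Å."""
        with np.errstate(invalid="ignore"):
            return np.any(self.distances > HBOND_BREAK_ANGSTROM, axis=2)


def filter_snapshots(hb: HBondSeries,
                     central_range: tuple[int, int] | None = None) -> np.ndarray:
    """Keep-mask over snapshots: True where no central H-bond is broken.

    ``central_range`` is the (1-based, inclusive) pair range to watch;
    by default all pairs except the outermost pair on each side (the
    outer G-C caps) are watched. Idempotent by construction.
    """
    n_pairs = len(hb.sequence)
    if central_range is None:
        central_range = (2, n_pairs - 1)
    lo, hi = central_range
    if not (1 <= lo <= hi <= n_pairs):
        raise ValueError("central_range outside the duplex")
    broken = hb.broken()[:, lo - 1:hi]
    return ~np.any(broken, axis=1)


def estimate_mean_cov(ts: CoordinateTimeSeries,
                      mask: np.ndarray | None = None):
    """Ensemble mean ŵ, covariance Σ, and stiffness K = kBT·Σ⁻¹.

    Also returns the per-coordinate stiffness constants
    kx = kBT/var(x). If Σ is singular the full inversion is skipped
    (K is None) but ŵ and kx are still returned.
    """
    x = ts.values if mask is None else ts.values[np.asarray(mask, bool)]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 kept snapshots")
    w_hat = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False)
    var = np.diag(sigma)
    with np.errstate(divide="ignore"):
        kx = np.where(var > 0, KBT / var, np.inf)
    try:
        k = KBT * np.linalg.inv(sigma)
        k = 0.5 * (k + k.T)
    except np.linalg.LinAlgError:
        k = None
    return w_hat, sigma, k, kx


def banded_maxent_stiffness(sigma: np.ndarray, n_bp: int) -> StiffnessMatrix:
    """Maximum-absolute-entropy banded stiffness from a covariance.

    Each diagonal hexameric block of Σ is inverted and added at its
    slice; the covariance blocks of the 54-coordinate overlaps between
    adjacent hexamers are inverted and subtracted; the result is
    multiplied by kBT. The implied covariance kBT·K⁻¹ equals Σ on
    every in-band entry (and maximizes entropy outside the band).
    """
    sigma = np.asarray(sigma, float)
    dim = vector_length(n_bp)
    if sigma.shape != (dim, dim):
        raise ValueError(f"covariance must be {dim}x{dim} for {n_bp} bp")
    if n_bp < 6:
        raise ValueError("need at least 6 bp (one hexamer)")
    k = np.zeros_like(sigma)
    for start in range(1, n_bp - 4):
        sl = block_slice(start, n_bp)
        try:
            k[sl, sl] += np.linalg.inv(sigma[sl, sl])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular hexamer covariance block at pair {start}") from exc
    for start in range(1, n_bp - 5):
        lo = start * 12
        sl = slice(lo, lo + 54)  # overlap of hexamers at start and start+1
        k[sl, sl] -= np.linalg.inv(sigma[sl, sl])
    k = 0.5 * (k + k.T) * KBT
    return StiffnessMatrix(k, n_bp, banded=True, dimensionless=False,
                           meta={"method": "maxent-banded"})


def extract_hexamer_blocks(K: StiffnessMatrix | np.ndarray, seq: str,
                           na_type: str | None = None):
    """Cut 66x66 hexameric blocks out of a banded stiffness matrix.

    Blocks are keyed by canonical class (the complement transform is
    applied when the canonical representative is the reverse
    complement). For duplicate hexamers the first occurrence wins;
    deviations between duplicates are reported in the returned dict of
    maximum absolute differences.
    """
    from .core import complement_stiffness_block

    mat = K.matrix if isinstance(K, StiffnessMatrix) else np.asarray(K, float)
    n_bp = len(seq)
    seq = seq.upper()
    blocks: dict[str, np.ndarray] = {}
    deviations: dict[str, float] = {}
    for start in range(1, n_bp - 4):
        hexamer = seq[start - 1:start + 5]
        canon = canonical_class(hexamer, na_type)
        sl = block_slice(start, n_bp)
        b = mat[sl, sl]
        if hexamer != canon:
            b = complement_stiffness_block(b)
        if canon in blocks:
            deviations[canon] = max(
                deviations.get(canon, 0.0),
                float(np.abs(blocks[canon] - b).max()))
        else:
            blocks[canon] = b.copy()
    return blocks, deviations


def convergence_error(x_half1: float, x_half2: float,
                      x_full: float) -> tuple[float, float]:
    """Half-trajectory convergence errors.

    εa = 0.5(|x1−xfull| + |x2−xfull|); εr = εa/|xfull| (NaN if
    x_full is 0).
    """
    if not np.all(np.isfinite([x_half1, x_half2, x_full])):
        raise ValueError("inputs must be finite")
    eps_a = 0.5 * (abs(x_half1 - x_full) + abs(x_half2 - x_full))
    eps_r = eps_a / abs(x_full) if x_full != 0 else float("nan")
    return eps_a, eps_r


# ---------------------------------------------------------------------------
# Base-pair opening survival analysis
# ---------------------------------------------------------------------------

def opening_events(hb: HBondSeries, pair: int | None = None) -> np.ndarray:
    """Durations (ns) of base-pair opening events.

    An event is a maximal run of consecutive snapshots in which the
    pair has at least one broken bond; single-snapshot escapes count.
    With ``pair=None`` events of all pairs are pooled.
    """
    broken = hb.broken()
    if pair is not None:
        broken = broken[:, pair - 1:pair]
    durations = []
    for col in range(broken.shape[1]):
        b = broken[:, col].astype(int)
        d = np.diff(np.concatenate([[0], b, [0]]))
        starts = np.where(d == 1)[0]
        ends = np.where(d == -1)[0]
        durations.extend(ends - starts)
    return np.asarray(durations, float) * hb.timestep_ps / 1000.0


@dataclass
class SurvivalFit:
    """Exponential fit of the opening-time survival function."""

    durations_ns: np.ndarray
    t_grid: np.ndarray
    survival: np.ndarray
    rate_per_ns: float
    tau_open_ns: float
    fit_window: tuple[float, float]
    r_squared: float
    auto_window: bool = False


def _survival_curve(durations: np.ndarray):
    t = np.sort(np.unique(durations))
    s = np.array([(durations > x).mean() for x in t])
    return t, s


def survival_fit(durations_ns: np.ndarray,
                 fit_window: tuple[float, float] | None = None,
                 min_points: int = 3, r2_threshold: float = 0.98) -> SurvivalFit:
    """Fit ln S(t) = −λt on a (near-)linear window; τ_open = 1/λ.

    ln S(t) is nonlinear at short times (transient escapes) and
    ill-defined at long times, so the fit is restricted to a window:
    either user-given or auto-selected as the longest interval of
    support points whose straight-line fit reaches the R² threshold.
    """
    durations = np.asarray(durations_ns, float)
    if durations.size < 1:
        raise ValueError("no opening events")
    t, s = _survival_curve(durations)
    pos = s > 0
    tp, sp = t[pos], np.log(s[pos])
    if fit_window is not None:
        lo, hi = fit_window
        sel = (tp >= lo) & (tp <= hi)
        if sel.sum() < min_points:
            raise ValueError("fit window has fewer than 3 support points")
        use_t, use_y = tp[sel], sp[sel]
        auto = False
        window = (float(lo), float(hi))
    else:
        if tp.size < min_points:
            raise ValueError("fit refused: fewer than 3 distinct durations")
        # scan candidate windows on a decimated grid (keeps the search
        # quadratic in at most ~60 points), then fit on all support
        # points inside the best window
        grid = np.unique(np.linspace(0, tp.size - 1, min(tp.size, 60)).astype(int))
        tg, sg = tp[grid], sp[grid]
        best = None
        n = tg.size
        for i in range(n - min_points + 1):
            for j in range(i + min_points, n + 1):
                xt, yt = tg[i:j], sg[i:j]
                slope, icpt = np.polyfit(xt, yt, 1)
                pred = slope * xt + icpt
                ss_tot = np.sum((yt - yt.mean()) ** 2)
                r2 = 1 - np.sum((yt - pred) ** 2) / ss_tot if ss_tot > 0 else 0.0
                if r2 >= r2_threshold and slope < 0:
                    span = xt[-1] - xt[0]
                    if best is None or span > best[0]:
                        best = (span, i, j)
        if best is None:
            i, j = 0, n  # fall back to the full range
        else:
            _, i, j = best
        sel = (tp >= tg[i]) & (tp <= tg[j - 1])
        use_t, use_y = tp[sel], sp[sel]
        auto = True
        window = (float(use_t[0]), float(use_t[-1]))
    if np.unique(use_t).size < 2:
        raise ValueError("degenerate fit window (all durations equal)")
    slope, icpt = np.polyfit(use_t, use_y, 1)
    if slope >= 0:
        raise ValueError("survival function does not decay on the fit window")
    pred = slope * use_t + icpt
    ss_tot = float(np.sum((use_y - use_y.mean()) ** 2))
    r2 = 1 - float(np.sum((use_y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    lam = -slope
    return SurvivalFit(durations, t, s, lam, 1.0 / lam, window, r2, auto)


# ---------------------------------------------------------------------------
# Synthetic trajectory generator
# ---------------------------------------------------------------------------

def synthetic_trajectory(
    w_hat: np.ndarray,
    K: StiffnessMatrix | np.ndarray,
    sequence: str,
    n: int,
    seed: int = 0,
    opening_rate_per_ns: float = 0.0,
    mean_open_ns: float = 2.0,
    timestep_ps: float = 10.0,
    baseline_angstrom: float = 2.9,
    noise_angstrom: float = 0.15,
) -> tuple[CoordinateTimeSeries, HBondSeries]:
    """Generate a synthetic (coordinates, H-bond) snapshot ensemble.

    Coordinates are Gaussian with mean ŵ and covariance kBT·K⁻¹.
    H-bond distances fluctuate around a paired baseline; opening
    excursions above 4 Å are injected per pair as a Poisson process
    with exponential durations of mean ``mean_open_ns``. Deterministic
    given ``seed``.
    """
    from .mechanics import sample_ensemble

    sequence = sequence.upper()
    n_pairs = len(sequence)
    samples = sample_ensemble(w_hat, K, n, seed=seed)
    ts = CoordinateTimeSeries(sequence, samples,
                              timestamps_ps=timestep_ps * np.arange(n))
    rng = np.random.default_rng([seed, 1])
    max_bonds = 3
    dist = np.full((n, n_pairs, max_bonds), np.nan)
    for p, base in enumerate(sequence):
        nb = _N_BONDS[base]
        dist[:, p, :nb] = baseline_angstrom + \
            np.abs(rng.normal(0.0, noise_angstrom, (n, nb)))
    if opening_rate_per_ns > 0:
        dt_ns = timestep_ps / 1000.0
        p_start = 1.0 - np.exp(-opening_rate_per_ns * dt_ns)
        for p, base in enumerate(sequence):
            t = 0
            while t < n:
                if rng.uniform() < p_start:
                    dur = max(1, int(round(rng.exponential(mean_open_ns) / dt_ns)))
                    bond = rng.integers(0, _N_BONDS[base])
                    hi = min(n, t + dur)
                    dist[t:hi, p, bond] = HBOND_BREAK_ANGSTROM + \
                        0.5 + np.abs(rng.normal(0, 0.5, hi - t))
                    t = hi + 1
                else:
                    t += 1
    hb = HBondSeries(sequence, dist, timestep_ps=timestep_ps)
    return ts, hb
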