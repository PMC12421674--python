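"""Parameter tables: CSV I/O, validation, and a synthetic generator.

A parameter set maps every canonical hexamer class (2080 for a
four-letter alphabet) to a :class:`~rigidbase.core.HexamerRecord`;
records for non-canonical hexamers are always derived through the
complement transform, never stored, so complement consistency is exact
by construction. Heptamer records are assembled on demand from the two
overlapping hexamers.

The synthetic generator produces a complete, schema-identical stand-in
for an MD-derived parameter deposit, so that every downstream module is
testable without any external download. Central-step means are anchored
to published crystallographic/MD dinucleotide averages with a smooth,
seeded hexameric-context perturbation on the scale of the observed
context variability; intra-basepair coordinates and groove widths are
anchored to the sequence-averaged helix parameters; stiffness blocks
are symmetric positive definite with physically sensible diagonal
magnitudes and distance-decaying couplings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core
from .constants import ANGLE_SCALE
from .core import (
    HexamerRecord,
    HeptamerRecord,
    canonical_class,
    complement_hexamer_record,
    heptamer_from_hexamers,
    is_self_complementary,
    reverse_complement,
)

__all__ = [
    "ParameterSet",
    "ValidationReport",
    "generate_synthetic_parameters",
    "load_parameter_set",
    "save_parameter_set",
    "validate_parameter_set",
    "DNA_DIMER_ANCHORS",
    "RNA_DIMER_ANCHORS",
]

_ALPHABET = {"DNA": "ACGT", "RNA": "ACGU"}

# Central-step equilibrium coordinates per canonical dinucleotide
# (shift, slide, rise, tilt, roll, twist) in Å/deg; MD-derived averages
# over all hexameric contexts of the step. Odd coordinates of
# self-complementary dimers are exactly zero.
DNA_DIMER_ANCHORS: dict[str, tuple[float, ...]] = {
    "CG": (0.00, 0.24, 3.33, 0.00, 6.16, 34.31),
    "CA": (-0.23, 0.15, 3.29, -0.11, 6.70, 33.13),
    "TA": (0.00, 0.29, 3.25, 0.00, 5.26, 34.51),
    "AG": (-0.32, -0.37, 3.37, -2.70, 3.93, 33.46),
    "GG": (-0.20, -0.25, 3.45, -0.06, 4.85, 34.90),
    "AA": (-0.36, -0.06, 3.31, -2.27, 1.63, 35.99),
    "GA": (-0.45, 0.23, 3.32, -1.08, 2.22, 37.74),
    "AT": (0.00, -0.71, 3.24, 0.00, -0.53, 30.70),
    "AC": (0.19, -0.49, 3.29, -0.40, 0.22, 32.69),
    "GC": (0.00, -0.28, 3.35, 0.00, 0.20, 36.60),
}

# A-RNA anchors: sequence-averaged step coordinates (slide -1.64, rise
# 3.30, roll 8.83, twist 30.08) with mild synthetic per-dimer offsets
# within the printed sequence variability. SYNTHETIC stand-in for the
# RNA dimer table, which is not reproduced here.
_RNA_BASE = (0.00, -1.64, 3.30, 0.00, 8.83, 30.08)
_RNA_OFFSETS = {
    "CG": (0.00, 0.10, 0.02, 0.00, 1.5, 0.9),
    "CA": (-0.05, 0.05, -0.03, -0.3, 1.0, 0.5),
    "UA": (0.00, 0.12, -0.05, 0.00, 2.5, -0.6),
    "AG": (-0.08, -0.10, 0.04, -0.6, -1.0, -0.4),
    "GG": (-0.04, -0.06, 0.08, -0.1, -0.5, 0.6),
    "AA": (-0.09, -0.02, 0.01, -0.5, -2.0, 1.0),
    "GA": (-0.11, 0.06, 0.02, -0.2, -1.5, 1.3),
    "AU": (0.00, -0.15, -0.06, 0.00, -3.0, -1.2),
    "AC": (0.05, -0.12, -0.01, -0.2, -2.2, -0.8),
    "GC": (0.00, -0.08, 0.03, 0.00, -1.8, 1.1),
}
RNA_DIMER_ANCHORS = {
    d: tuple(b + o for b, o in zip(_RNA_BASE, off))
    for d, off in _RNA_OFFSETS.items()
}

# Sequence-averaged intra-basepair coordinates (shear, stretch, stagger,
# buckle, propeller, opening) and groove widths (Å).
_PAIR_ANCHORS = {
    "DNA": (0.0, -0.02, 0.03, 0.0, -11.03, 0.24),
    "RNA": (0.0, -0.02, -0.07, 0.0, -12.61, 0.28),
}
_GROOVES = {"DNA": (12.04, 18.36), "RNA": (17.11, 18.11)}  # minor, major

# Context-perturbation scales (one standard-deviation-like bound).
_PAIR_SPREAD = {
    "DNA": (0.12, 0.04, 0.10, 5.0, 3.0, 0.8),
    "RNA": (0.10, 0.04, 0.08, 4.0, 1.5, 0.8),
}
_STEP_SPREAD = {
    "DNA": (0.15, 0.12, 0.06, 0.8, 1.0, 1.5),
    "RNA": (0.06, 0.08, 0.05, 0.4, 1.0, 0.8),
}
_GROOVE_SPREAD = {"DNA": (0.6, 0.5), "RNA": (0.2, 0.3)}

# Baseline per-coordinate stiffness constants kx = kBT/var(x)
# (kcal/mol/Å^2 for translations, kcal/mol/deg^2 for rotations); buckle
# is by far the softest rotational coordinate.
_PAIR_K = (7.0, 40.0, 8.5, 0.0066, 0.010, 0.030)
_STEP_K = (1.7, 4.0, 10.0, 0.033, 0.020, 0.050)
_GROOVE_K = (0.40, 0.30)  # minor, major


def _seq_code(seq: str) -> int:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    code = 0
    for b in seq:
        code = code * 4 + idx[b]
    return code


@dataclass
class ValidationReport:
    ok: bool
    n_classes: int
    issues: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


class ParameterSet:
    """Canonical hexamer class -> record map with derived complements."""

    def __init__(self, na_type: str, records: dict[str, HexamerRecord],
                 metadata: dict | None = None):
        self.na_type = na_type.upper()
        self.records: dict[str, HexamerRecord] = {}
        for seq, rec in records.items():
            canon = canonical_class(seq, self.na_type)
            if canon != seq:
                rec = complement_hexamer_record(rec)
            elif is_self_complementary(seq, self.na_type):
                rec = complement_hexamer_record(rec)  # symmetrizes in place
            self.records[canon] = rec
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, seq: str) -> bool:
        return canonical_class(seq.upper(), self.na_type) in self.records

    def hexamer(self, seq: str) -> HexamerRecord:
        """Record for any hexamer; complements derived on the fly."""
        seq = seq.upper()
        canon = canonical_class(seq, self.na_type)
        try:
            rec = self.records[canon]
        except KeyError:
            raise KeyError(f"no parameters for hexamer class {canon!r}") from None
        if seq == canon:
            return rec
        return complement_hexamer_record(rec)

    def heptamer(self, seq: str) -> HeptamerRecord:
        """Record for any heptamer, averaged from its two hexamers."""
        seq = seq.upper()
        if len(seq) != 7:
            raise ValueError("heptamer must have 7 letters")
        return heptamer_from_hexamers(self.hexamer(seq[:6]), self.hexamer(seq[1:]))

    def classes(self) -> list[str]:
        return sorted(self.records)


def _all_canonical_hexamers(na_type: str) -> list[str]:
    alphabet = _ALPHABET[na_type.upper()]
    seen = set()
    for code in range(4 ** 6):
        s = ""
        c = code
        for _ in range(6):
            s = alphabet[c % 4] + s
            c //= 4
        seen.add(canonical_class(s, na_type))
    return sorted(seen)


def _dimer_anchor(dimer: str, na_type: str,
                  table: dict[str, tuple[float, ...]]) -> np.ndarray:
    if dimer in table:
        return np.asarray(table[dimer], dtype=float)
    rc = reverse_complement(dimer, na_type)
    vals = np.asarray(table[rc], dtype=float).copy()
    vals[list(core.ODD_STEP_IDX)] *= -1.0
    return vals


def _spd_block(rng: np.random.Generator, diag_nd: np.ndarray,
               coupling: float = 0.12, decay: float = 0.25) -> np.ndarray:
    """Random SPD 66x66 block with given nondimensional diagonal scale.

    Built as sqrt(D) C sqrt(D) with C = A A^T / normalization and
    A = I + eps*G, G having position-distance-decaying entries: SPD by
    construction, couplings strongest between nearby coordinates.
    """
    n = diag_nd.size
    pos = np.repeat(np.arange(11), 6)[:n]  # 6 pairs + 5 steps interleaved
    dist = np.abs(pos[:, None] - pos[None, :])
    g = rng.standard_normal((n, n)) * np.exp(-decay * dist)
    a = np.eye(n) + coupling * g
    c = a @ a.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    root = np.sqrt(diag_nd)
    return c * np.outer(root, root)


def generate_synthetic_parameters(
    seed: int = 0,
    na_type: str = "DNA",
    dimer_anchor_table: dict[str, tuple[float, ...]] | None = None,
    with_blocks: bool = True,
) -> ParameterSet:
    """Generate a complete synthetic hexamer parameter set.

    Deterministic given ``seed``; each canonical hexamer gets its own
    substream so results do not depend on iteration order. Complements
    are never drawn independently — they are derived by the exact
    complement transform, and self-complementary records are
    symmetrized so their odd central coordinates are literal zeros.
    """
    na_type = na_type.upper()
    anchors = dimer_anchor_table or (
        DNA_DIMER_ANCHORS if na_type == "DNA" else RNA_DIMER_ANCHORS)
    pair_anchor = np.asarray(_PAIR_ANCHORS[na_type])
    pair_spread = np.asarray(_PAIR_SPREAD[na_type])
    step_spread = np.asarray(_STEP_SPREAD[na_type])
    minor0, major0 = _GROOVES[na_type]
    minor_sd, major_sd = _GROOVE_SPREAD[na_type]

    # nondimensional block diagonal scale per coordinate position
    scales = np.array([1.0, 1.0, 1.0, ANGLE_SCALE, ANGLE_SCALE, ANGLE_SCALE])
    pair_k_nd = np.asarray(_PAIR_K) * scales ** 2
    step_k_nd = np.asarray(_STEP_K) * scales ** 2
    diag_nd = np.concatenate([
        np.concatenate([pair_k_nd, step_k_nd]) for _ in range(5)
    ] + [pair_k_nd])
    dim_scale = np.concatenate([
        np.concatenate([scales, scales]) for _ in range(5)
    ] + [scales])

    records: dict[str, HexamerRecord] = {}
    for hexamer in _all_canonical_hexamers(na_type):
        rng = np.random.default_rng([seed, _seq_code(hexamer)])
        pair_coords = pair_anchor + pair_spread * rng.uniform(-1, 1, (6, 6))
        step_coords = np.empty((5, 6))
        for s in range(5):
            anchor = _dimer_anchor(hexamer[s:s + 2], na_type, anchors)
            step_coords[s] = anchor + step_spread * rng.uniform(-1, 1, 6)
        minor = np.full(6, np.nan)
        minor[2:4] = minor0 + minor_sd * rng.uniform(-1, 1, 2)
        major = major0 + major_sd * rng.uniform(-1, 1)
        pair_k = np.asarray(_PAIR_K) * rng.uniform(0.8, 1.2, (6, 6))
        step_k = np.asarray(_STEP_K) * rng.uniform(0.8, 1.2, (5, 6))
        minor_k = np.full(6, np.nan)
        minor_k[2:4] = _GROOVE_K[0] * rng.uniform(0.8, 1.2, 2)
        major_k = _GROOVE_K[1] * rng.uniform(0.8, 1.2)
        block = None
        if with_blocks:
            block_nd = _spd_block(rng, diag_nd)
            block = block_nd / np.outer(dim_scale, dim_scale)
        rec = HexamerRecord(hexamer, na_type, pair_coords, step_coords,
                            minor, major, pair_k, step_k, minor_k, major_k, block)
        if is_self_complementary(hexamer, na_type):
            rec = complement_hexamer_record(rec)
        records[hexamer] = rec
    return ParameterSet(na_type, records,
                        {"source": "synthetic", "seed": int(seed)})


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_parameter_set(
    ps: ParameterSet, require_complete: bool = True, check_blocks: bool = True,
) -> ValidationReport:
    """Check completeness, block symmetry/SPD, and complement rules."""
    issues: list[str] = []
    expected = _all_canonical_hexamers(ps.na_type)
    missing = sorted(set(expected) - set(ps.records))
    if require_complete and missing:
        head = ", ".join(missing[:5])
        issues.append(f"missing {len(missing)} hexamer classes (e.g. {head})")
    for seq, rec in sorted(ps.records.items()):
        if rec.sequence != seq:
            issues.append(f"{seq}: record sequence mismatch ({rec.sequence})")
        if is_self_complementary(seq, ps.na_type):
            if np.any(rec.step_coords[2, list(core.ODD_STEP_IDX)] != 0.0):
                issues.append(f"{seq}: self-complementary hexamer with nonzero "
                              "odd central-step coordinates")
        if np.any(rec.pair_stiffness <= 0) or np.any(rec.step_stiffness <= 0):
            issues.append(f"{seq}: non-positive coordinate stiffness")
        if check_blocks and rec.stiffness_block is not None:
            b = rec.stiffness_block
            if not np.allclose(b, b.T, atol=1e-8):
                issues.append(f"{seq}: stiffness block not symmetric")
            else:
                lo = np.linalg.eigvalsh(b)[0]
                if lo <= 0:
                    issues.append(f"{seq}: block not positive definite "
                                  f"(min eigenvalue {lo:.3g})")
    return ValidationReport(not issues, len(ps.records), issues)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SHAPE_COLS = ["sequence", "kind", "position", "coordinate", "mean", "stiffness"]


def _shape_frame(ps: ParameterSet) -> pd.DataFrame:
    rows = []
    for seq in ps.classes():
        rec = ps.records[seq]
        for p in range(6):
            for c, name in enumerate(core.PAIR_COORDS):
                rows.append((seq, "pair", p + 1, name,
                             rec.pair_coords[p, c], rec.pair_stiffness[p, c]))
        for s in range(5):
            for c, name in enumerate(core.STEP_COORDS):
                rows.append((seq, "step", s + 1, name,
                             rec.step_coords[s, c], rec.step_stiffness[s, c]))
        for p in (3, 4):
            rows.append((seq, "pair", p, "minor-groove-width",
                         rec.minor_groove[p - 1], rec.minor_groove_stiffness[p - 1]))
        rows.append((seq, "step", 3, "major-groove-width",
                     rec.major_groove_width, rec.major_groove_stiffness))
    return pd.DataFrame(rows, columns=_SHAPE_COLS)


def _blocks_frame(ps: ParameterSet) -> pd.DataFrame:
    rows = []
    for seq in ps.classes():
        b = ps.records[seq].stiffness_block
        if b is None:
            continue
        iu, ju = np.triu_indices(66)
        rows.append(pd.DataFrame({
            "sequence": seq, "i": iu, "j": ju, "value": b[iu, ju]}))
    if not rows:
        return pd.DataFrame(columns=["sequence", "i", "j", "value"])
    return pd.concat(rows, ignore_index=True)


def save_parameter_set(ps: ParameterSet, directory: str | Path,
                       with_blocks: bool = True) -> dict[str, Path]:
    """Write shape/stiffness tables (and blocks) as CSV + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"shape": directory / "hexamer_shape.csv",
             "meta": directory / "metadata.json"}
    _shape_frame(ps).to_csv(paths["shape"], index=False, float_format="%.10g")
    meta = {"na_type": ps.na_type, **ps.metadata}
    paths["meta"].write_text(json.dumps(meta, indent=1))
    if with_blocks:
        paths["blocks"] = directory / "hexamer_blocks.csv"
        _blocks_frame(ps).to_csv(paths["blocks"], index=False,
                                 float_format="%.10g")
    return paths


def _records_from_shape(df: pd.DataFrame, na_type: str,
                        source: str) -> dict[str, HexamerRecord]:
    required = set(_SHAPE_COLS)
    if not required <= set(df.columns):
        raise ValueError(f"{source}: shape table must have columns {_SHAPE_COLS}")
    records: dict[str, HexamerRecord] = {}
    for seq, grp in df.groupby("sequence", sort=True):
        seq = str(seq).upper()
        pair = np.full((6, 6), np.nan)
        step = np.full((5, 6), np.nan)
        pair_k = np.full((6, 6), np.nan)
        step_k = np.full((5, 6), np.nan)
        minor = np.full(6, np.nan)
        minor_k = np.full(6, np.nan)
        major = major_k = np.nan
        for row in grp.itertuples(index=False):
            kind = row.kind.lower()
            name = row.coordinate.lower()
            p = int(row.position) - 1
            try:
                if name == "minor-groove-width":
                    minor[p] = row.mean
                    minor_k[p] = row.stiffness
                elif name == "major-groove-width":
                    major, major_k = row.mean, row.stiffness
                elif kind == "pair":
                    c = core.PAIR_COORDS.index(name)
                    pair[p, c], pair_k[p, c] = row.mean, row.stiffness
                elif kind == "step":
                    c = core.STEP_COORDS.index(name)
                    step[p, c], step_k[p, c] = row.mean, row.stiffness
                else:
                    raise ValueError(f"unknown kind {row.kind!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{source}: malformed row for {seq}: {exc}") from exc
        for arr, what in ((pair, "pair coords"), (step, "step coords"),
                          (pair_k, "pair stiffness"), (step_k, "step stiffness")):
            if np.isnan(arr).any():
                raise ValueError(f"{source}: {seq}: incomplete {what}")
        if np.isnan(major):
            raise ValueError(f"{source}: {seq}: missing major groove width")
        records[seq] = HexamerRecord(seq, na_type, pair, step, minor, major,
                                     pair_k, step_k, minor_k, major_k)
    return records


def _attach_blocks(records: dict[str, HexamerRecord], path: Path,
                   na_type: str) -> None:
    df = pd.read_csv(path)
    if {"sequence", "i", "j", "value"} <= set(df.columns):
        for seq, grp in df.groupby("sequence", sort=False):
            seq = str(seq).upper()
            canon = canonical_class(seq, na_type)
            b = np.zeros((66, 66))
            i = grp["i"].to_numpy(int)
            j = grp["j"].to_numpy(int)
            v = grp["value"].to_numpy(float)
            b[i, j] = v
            b[j, i] = v
            if canon in records and seq == canon:
                records[canon].stiffness_block = b
            elif canon in records:
                records[canon].stiffness_block = core.complement_stiffness_block(b)
    else:
        # single dense 66x66 matrix, file name carries the hexamer
        b = pd.read_csv(path, header=None).to_numpy(float)
        if b.shape != (66, 66):
            raise ValueError(f"{path}: expected 66x66 matrix, got {b.shape}")
        seq = path.stem.split("_")[-1].upper()
        canon = canonical_class(seq, na_type)
        if canon in records:
            if seq != canon:
                b = core.complement_stiffness_block(b)
            records[canon].stiffness_block = b


def load_parameter_set(
    shape_csv: str | Path,
    blocks: str | Path | None = None,
    na_type: str | None = None,
    metadata_json: str | Path | None = None,
) -> ParameterSet:
    """Load a parameter set from deposit-style CSV tables.

    ``blocks`` may be a long-format CSV (sequence, i, j, value) or a
    directory of per-hexamer 66x66 matrix files; both layouts are
    sniffed. Tables containing a hexamer and its complement are checked
    for parity consistency; classes stored only once are completed via
    the complement transform.
    """
    shape_csv = Path(shape_csv)
    df = pd.read_csv(shape_csv)
    if na_type is None:
        if metadata_json and Path(metadata_json).exists():
            na_type = json.loads(Path(metadata_json).read_text())["na_type"]
        else:
            letters = "".join(df["sequence"].astype(str))
            na_type = "RNA" if "U" in letters.upper() else "DNA"
    na_type = na_type.upper()

    raw = _records_from_shape(df, na_type, str(shape_csv))
    records: dict[str, HexamerRecord] = {}
    for seq, rec in raw.items():
        canon = canonical_class(seq, na_type)
        canon_rec = rec if seq == canon else complement_hexamer_record(rec)
        if canon in records:
            prev = records[canon]
            if not (np.allclose(prev.pair_coords, canon_rec.pair_coords, atol=1e-6)
                    and np.allclose(prev.step_coords, canon_rec.step_coords,
                                    atol=1e-6)):
                raise ValueError(
                    f"{shape_csv}: hexamer {seq} and its complement are stored "
                    "with inconsistent parity signs")
        else:
            records[canon] = canon_rec

    if blocks is not None:
        blocks = Path(blocks)
        if blocks.is_dir():
            for f in sorted(blocks.glob("*.csv")):
                _attach_blocks(records, f, na_type)
        else:
            _attach_blocks(records, blocks, na_type)

    meta = {"source": str(shape_csv)}
    if metadata_json and Path(metadata_json).exists():
        meta.update(json.loads(Path(metadata_json).read_text()))
    return ParameterSet(na_type, records, meta)
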