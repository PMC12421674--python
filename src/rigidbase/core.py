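"""Coordinate conventions and complement algebra for rigid-base duplex models.

A duplex of N base pairs is described by 12N-6 rigid-base coordinates:
six intra-basepair coordinates per pair (shear, stretch, stagger,
buckle, propeller, opening) and six step coordinates per junction
(shift, slide, rise, tilt, roll, twist), interleaved in the natural
order pair 1, step 1, pair 2, ..., pair N. Helical coordinates (X-disp,
Y-disp, h-rise, inclination, tip, h-twist) are an alternative step
parametrization used for global length/twist analysis.

The double helix has no preferred strand: reading the same molecule
from the other strand reverses the pair/step order and flips the sign
of the *odd* coordinates (shear, buckle, shift, tilt, Y-disp, tip),
while the even ones — including both groove widths and all stiffness
constants — are unchanged. Every complement transform in the package
(sequences, per-context parameter records, 66x66 stiffness blocks,
whole assembled matrices) is derived from this single parity rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PAIR_COORDS",
    "STEP_COORDS",
    "HELICAL_COORDS",
    "ODD_COORDS",
    "DuplexSequence",
    "HexamerRecord",
    "HeptamerRecord",
    "parity",
    "unit_class",
    "reverse_complement",
    "is_self_complementary",
    "canonical_class",
    "complement_hexamer_record",
    "complement_heptamer_record",
    "complement_stiffness_block",
    "heptamer_from_hexamers",
    "vector_length",
    "vector_index",
    "block_slice",
    "complement_permutation",
    "complement_signs",
]

PAIR_COORDS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
STEP_COORDS = ("shift", "slide", "rise", "tilt", "roll", "twist")
HELICAL_COORDS = ("x-disp", "y-disp", "h-rise", "inclination", "tip", "h-twist")
GROOVE_COORDS = ("minor-groove-width", "major-groove-width")

#: Coordinates that change sign when the reference strand is flipped.
ODD_COORDS = frozenset({"shear", "buckle", "shift", "tilt", "y-disp", "tip"})

#: Translational coordinates (Å); all others are rotations (deg).
_TRANSLATIONS = frozenset(
    {"shear", "stretch", "stagger", "shift", "slide", "rise",
     "x-disp", "y-disp", "h-rise"} | set(GROOVE_COORDS)
)

_ALL_COORDS = PAIR_COORDS + STEP_COORDS + HELICAL_COORDS + GROOVE_COORDS

# 0-based positions of odd coordinates inside the pair and step sextets;
# identical for both groups (shear/buckle and shift/tilt).
ODD_PAIR_IDX = (0, 3)
ODD_STEP_IDX = (0, 3)

_DNA = "ACGT"
_RNA = "ACGU"
_COMPLEMENT = {
    "A": {"DNA": "T", "RNA": "U"},
    "C": {"DNA": "G", "RNA": "G"},
    "G": {"DNA": "C", "RNA": "C"},
    "T": {"DNA": "A", "RNA": "A"},
    "U": {"DNA": "A", "RNA": "A"},
}


def parity(name: str) -> str:
    """Return ``"odd"`` or ``"even"`` for a named coordinate.

    Groove widths are even; unknown names raise ``KeyError``.
    """
    key = name.strip().lower()
    if key not in _ALL_COORDS:
        raise KeyError(f"unknown coordinate name: {name!r}")
    return "odd" if key in ODD_COORDS else "even"


def unit_class(name: str) -> str:
    """Return ``"translation"`` (Å) or ``"rotation"`` (deg) for a coordinate."""
    key = name.strip().lower()
    if key not in _ALL_COORDS:
        raise KeyError(f"unknown coordinate name: {name!r}")
    return "translation" if key in _TRANSLATIONS else "rotation"


def _infer_na_type(letters: str) -> str:
    if "U" in letters and "T" in letters:
        raise ValueError("sequence mixes T and U")
    return "RNA" if "U" in letters else "DNA"


@dataclass(frozen=True)
class DuplexSequence:
    """A double-helical sequence read 5'->3' along the reference strand."""

    letters: str
    na_type: str = ""

    def __post_init__(self) -> None:
        letters = self.letters.upper()
        object.__setattr__(self, "letters", letters)
        na_type = self.na_type.upper() or _infer_na_type(letters)
        object.__setattr__(self, "na_type", na_type)
        if na_type not in ("DNA", "RNA"):
            raise ValueError(f"na_type must be DNA or RNA, got {na_type!r}")
        alphabet = _DNA if na_type == "DNA" else _RNA
        if len(letters) < 1:
            raise ValueError("sequence must have length >= 1")
        bad = set(letters) - set(alphabet)
        if bad:
            raise ValueError(f"invalid {na_type} letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters

    def reverse_complement(self) -> "DuplexSequence":
        rc = "".join(_COMPLEMENT[b][self.na_type] for b in reversed(self.letters))
        return DuplexSequence(rc, self.na_type)


def _as_seq(seq: "DuplexSequence | str", na_type: str | None = None) -> DuplexSequence:
    if isinstance(seq, DuplexSequence):
        return seq
    return DuplexSequence(seq, na_type or "")


def reverse_complement(seq: "DuplexSequence | str", na_type: str | None = None):
    """Watson-Crick reverse complement (A<->T or A<->U, C<->G).

    Returns the same type as the input (``str`` in, ``str`` out).
    """
    ds = _as_seq(seq, na_type)
    rc = ds.reverse_complement()
    return rc if isinstance(seq, DuplexSequence) else rc.letters


def is_self_complementary(seq: "DuplexSequence | str", na_type: str | None = None) -> bool:
    ds = _as_seq(seq, na_type)
    return ds.letters == ds.reverse_complement().letters


def canonical_class(kmer: "DuplexSequence | str", na_type: str | None = None):
    """Representative of the reverse-complement class {s, revcomp(s)}.

    The representative is the lexicographic minimum of the two strands,
    so it is stable under complementation.
    """
    ds = _as_seq(kmer, na_type)
    rc = ds.reverse_complement()
    rep = ds if ds.letters <= rc.letters else rc
    return rep if isinstance(kmer, DuplexSequence) else rep.letters


# ---------------------------------------------------------------------------
# Coordinate-vector indexing (Fig-style interleaved layout)
# ---------------------------------------------------------------------------

def vector_length(n_bp: int) -> int:
    """Length of the duplex coordinate vector: 12*n_bp - 6."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return 12 * n_bp - 6


def vector_index(n_bp: int, kind: str, position: int, coordinate: str) -> int:
    """0-based index of a named coordinate in the duplex coordinate vector.

    ``kind`` is ``"pair"`` or ``"step"``; ``position`` is 1-based
    (pairs run 1..n_bp, steps 1..n_bp-1).
    """
    kind = kind.lower()
    key = coordinate.strip().lower()
    if kind == "pair":
        if not 1 <= position <= n_bp:
            raise IndexError(f"pair position {position} out of range 1..{n_bp}")
        offset = PAIR_COORDS.index(key)
        return (position - 1) * 12 + offset
    if kind == "step":
        if not 1 <= position <= n_bp - 1:
            raise IndexError(f"step position {position} out of range 1..{n_bp - 1}")
        offset = STEP_COORDS.index(key)
        return (position - 1) * 12 + 6 + offset
    raise ValueError(f"kind must be 'pair' or 'step', got {kind!r}")


def block_slice(hexamer_start: int, n_bp: int | None = None) -> slice:
    """Slice of the coordinate vector covered by the hexamer starting at
    pair ``hexamer_start`` (1-based): 6 pairs + 5 steps = 66 coordinates.

    Adjacent hexamer slices overlap in exactly 54 indices.
    """
    if hexamer_start < 1:
        raise IndexError("hexamer_start must be >= 1")
    if n_bp is not None and hexamer_start + 5 > n_bp:
        raise IndexError(f"hexamer starting at {hexamer_start} exceeds {n_bp} bp")
    lo = (hexamer_start - 1) * 12
    return slice(lo, lo + 66)


def coordinate_names(n_bp: int) -> list[tuple[str, int, str]]:
    """(kind, position, coordinate) labels of the vector, in order."""
    out: list[tuple[str, int, str]] = []
    for p in range(1, n_bp + 1):
        out.extend(("pair", p, c) for c in PAIR_COORDS)
        if p < n_bp:
            out.extend(("step", p, c) for c in STEP_COORDS)
    return out


def complement_permutation(n_bp: int) -> np.ndarray:
    """Index permutation of the coordinate vector under a strand flip.

    ``perm[i]`` is the source index of entry ``i`` in the complemented
    vector: pair p maps to pair n_bp+1-p, step s to step n_bp-s, the
    coordinate name within each sextet is unchanged.
    """
    n = vector_length(n_bp)
    perm = np.empty(n, dtype=np.intp)
    for p in range(1, n_bp + 1):
        src = (n_bp - p) * 12
        dst = (p - 1) * 12
        perm[dst:dst + 6] = np.arange(src, src + 6)
        if p < n_bp:
            src = (n_bp - 1 - p) * 12 + 6
            perm[dst + 6:dst + 12] = np.arange(src, src + 6)
    return perm


def complement_signs(n_bp: int) -> np.ndarray:
    """Sign vector (+1/-1) of the coordinates under a strand flip."""
    pair_signs = np.ones(6)
    pair_signs[list(ODD_PAIR_IDX)] = -1.0
    step_signs = np.ones(6)
    step_signs[list(ODD_STEP_IDX)] = -1.0
    parts = []
    for p in range(1, n_bp + 1):
        parts.append(pair_signs)
        if p < n_bp:
            parts.append(step_signs)
    return np.concatenate(parts)


def complement_vector(w: np.ndarray, n_bp: int) -> np.ndarray:
    """Coordinate vector of the same duplex read from the other strand."""
    w = np.asarray(w, dtype=float)
    if w.shape[-1] != vector_length(n_bp):
        raise ValueError("vector length inconsistent with n_bp")
    perm = complement_permutation(n_bp)
    return w[..., perm] * complement_signs(n_bp)


def complement_stiffness_block(block: np.ndarray, n_bp: int = 6) -> np.ndarray:
    """Stiffness block (or full matrix) of the reverse-complement duplex.

    The transform is a signed permutation: rows/columns are rearranged
    (the last pair becomes the first, etc.) and entries coupling an odd
    with an even coordinate change sign. Being orthogonal, it preserves
    symmetry and the eigenvalue spectrum.
    """
    block = np.asarray(block, dtype=float)
    n = vector_length(n_bp)
    if block.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} matrix for n_bp={n_bp}")
    if not np.allclose(block, block.T, atol=1e-10 * max(1.0, np.abs(block).max())):
        raise ValueError("stiffness block must be symmetric")
    perm = complement_permutation(n_bp)
    signs = complement_signs(n_bp)
    out = block[np.ix_(perm, perm)] * np.outer(signs, signs)
    return 0.5 * (out + out.T)


# ---------------------------------------------------------------------------
# Per-context parameter records
# ---------------------------------------------------------------------------

@dataclass
class HexamerRecord:
    """Model parameters for one hexameric sequence context.

    Shapes: ``pair_coords`` (6, 6) — one row per pair, columns in
    ``PAIR_COORDS`` order; ``step_coords`` (5, 6) in ``STEP_COORDS``
    order. The central step is row 2 (0-based) of ``step_coords``.
    ``minor_groove`` holds per-pair minor groove widths where defined
    (the two interior pentamers, pairs 3 and 4; NaN elsewhere);
    ``major_groove_width`` belongs to the central step. Stiffness
    constants ``*_stiffness`` mirror the coordinate layout and are even
    (strand-flip invariant) quantities. ``stiffness_block`` is the
    66x66 symmetric stiffness over the hexamer's coordinate vector.
    """

    sequence: str
    na_type: str
    pair_coords: np.ndarray
    step_coords: np.ndarray
    minor_groove: np.ndarray
    major_groove_width: float
    pair_stiffness: np.ndarray
    step_stiffness: np.ndarray
    minor_groove_stiffness: np.ndarray
    major_groove_stiffness: float
    stiffness_block: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != 6:
            raise ValueError("hexamer sequence must have 6 letters")
        self.pair_coords = np.asarray(self.pair_coords, dtype=float).reshape(6, 6)
        self.step_coords = np.asarray(self.step_coords, dtype=float).reshape(5, 6)
        self.minor_groove = np.asarray(self.minor_groove, dtype=float).reshape(6)
        self.pair_stiffness = np.asarray(self.pair_stiffness, dtype=float).reshape(6, 6)
        self.step_stiffness = np.asarray(self.step_stiffness, dtype=float).reshape(5, 6)
        self.minor_groove_stiffness = np.asarray(
            self.minor_groove_stiffness, dtype=float).reshape(6)
        if self.stiffness_block is not None:
            self.stiffness_block = np.asarray(
                self.stiffness_block, dtype=float).reshape(66, 66)

    @property
    def central_step(self) -> np.ndarray:
        return self.step_coords[2]

    def copy(self) -> "HexamerRecord":
        return HexamerRecord(
            self.sequence, self.na_type,
            self.pair_coords.copy(), self.step_coords.copy(),
            self.minor_groove.copy(), self.major_groove_width,
            self.pair_stiffness.copy(), self.step_stiffness.copy(),
            self.minor_groove_stiffness.copy(), self.major_groove_stiffness,
            None if self.stiffness_block is None else self.stiffness_block.copy(),
        )


@dataclass
class HeptamerRecord:
    """Central-pair parameters for one heptameric sequence context."""

    sequence: str
    na_type: str
    central_pair: np.ndarray
    minor_groove_width: float
    pair_stiffness: np.ndarray
    minor_groove_stiffness: float

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != 7:
            raise ValueError("heptamer sequence must have 7 letters")
        self.central_pair = np.asarray(self.central_pair, dtype=float).reshape(6)
        self.pair_stiffness = np.asarray(self.pair_stiffness, dtype=float).reshape(6)


def _raw_complement_hexamer(rec: HexamerRecord) -> HexamerRecord:
    pc = rec.pair_coords[::-1].copy()
    pc[:, list(ODD_PAIR_IDX)] *= -1.0
    sc = rec.step_coords[::-1].copy()
    sc[:, list(ODD_STEP_IDX)] *= -1.0
    block = None
    if rec.stiffness_block is not None:
        block = complement_stiffness_block(rec.stiffness_block, 6)
    return HexamerRecord(
        reverse_complement(rec.sequence, rec.na_type), rec.na_type,
        pc, sc,
        rec.minor_groove[::-1].copy(), rec.major_groove_width,
        rec.pair_stiffness[::-1].copy(), rec.step_stiffness[::-1].copy(),
        rec.minor_groove_stiffness[::-1].copy(), rec.major_groove_stiffness,
        block,
    )


def complement_hexamer_record(rec: HexamerRecord) -> HexamerRecord:
    """Record of the reverse-complement hexamer.

    Pairs and steps are reversed, odd coordinates negated; groove widths
    and stiffness constants are even (only re-indexed). For a
    self-complementary hexamer the record is averaged with its own
    transform, which forces the odd central-step coordinates (and the
    odd-even couplings of the central-step block) to exactly zero.
    """
    out = _raw_complement_hexamer(rec)
    if is_self_complementary(rec.sequence, rec.na_type):
        out.pair_coords = 0.5 * (out.pair_coords + rec.pair_coords)
        out.step_coords = 0.5 * (out.step_coords + rec.step_coords)
        out.step_coords[2, list(ODD_STEP_IDX)] = 0.0
        out.minor_groove = 0.5 * (out.minor_groove + rec.minor_groove)
        out.pair_stiffness = 0.5 * (out.pair_stiffness + rec.pair_stiffness)
        out.step_stiffness = 0.5 * (out.step_stiffness + rec.step_stiffness)
        out.minor_groove_stiffness = 0.5 * (
            out.minor_groove_stiffness + rec.minor_groove_stiffness)
        if out.stiffness_block is not None and rec.stiffness_block is not None:
            out.stiffness_block = 0.5 * (out.stiffness_block + rec.stiffness_block)
    return out


def complement_heptamer_record(rec: HeptamerRecord) -> HeptamerRecord:
    """Record of the reverse-complement heptamer (odd coords negated)."""
    cp = rec.central_pair.copy()
    cp[list(ODD_PAIR_IDX)] *= -1.0
    if is_self_complementary(rec.sequence, rec.na_type):
        cp = 0.5 * (cp + rec.central_pair)
        cp[list(ODD_PAIR_IDX)] = 0.0
    return HeptamerRecord(
        reverse_complement(rec.sequence, rec.na_type), rec.na_type,
        cp, rec.minor_groove_width,
        rec.pair_stiffness.copy(), rec.minor_groove_stiffness,
    )


def heptamer_from_hexamers(rec_a: HexamerRecord, rec_b: HexamerRecord) -> HeptamerRecord:
    """Build a heptamer record from its two overlapping hexamers.

    The heptamer's central pair is the 4th pair of the first hexamer
    and the 3rd of the second; its values (and the minor groove width
    and stiffness constants) are arithmetic means of the two.
    """
    if rec_a.sequence[1:] != rec_b.sequence[:5]:
        raise ValueError(
            f"hexamers {rec_a.sequence} and {rec_b.sequence} do not overlap in 5 letters")
    seq = rec_a.sequence + rec_b.sequence[-1]
    central = 0.5 * (rec_a.pair_coords[3] + rec_b.pair_coords[2])
    groove = 0.5 * (rec_a.minor_groove[3] + rec_b.minor_groove[2])
    k_pair = 0.5 * (rec_a.pair_stiffness[3] + rec_b.pair_stiffness[2])
    k_groove = 0.5 * (rec_a.minor_groove_stiffness[3] + rec_b.minor_groove_stiffness[2])
    rec = HeptamerRecord(seq, rec_a.na_type, central, groove, k_pair, k_groove)
    if is_self_complementary(seq, rec_a.na_type):
        rec = complement_heptamer_record(rec)
    return rec
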