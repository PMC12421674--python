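"""Design of minimal sequences covering every k-mer class once.

On a double helix a k-mer and its reverse complement are the same
molecular context, so the unit of coverage is the reverse-complement
class {s, revcomp(s)}. There are 4^k/2 classes for odd k (no odd-length
k-mer is self-complementary) and (4^k + 4^(k/2))/2 for even k (the
4^(k/2) self-complementary k-mers form singleton classes).

A depth-first search extends the sequence one letter at a time, only
accepting letters whose new k-mer window covers a class not seen
before; dead ends are handled by seeded random restarts. For odd k
this finds a sequence of the optimal length 4^k/2 + k - 1 in which
every class occurs exactly once (counting both strands). For even k,
where self-complementary classes make the search tree unfavorable, the
designer falls back to allowing duplicated classes when stuck and
reports the duplicates instead of failing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .core import DuplexSequence, canonical_class, reverse_complement

__all__ = [
    "count_kmer_classes",
    "minimal_covering_sequence",
    "partition_into_oligomers",
    "kmer_census",
    "DesignReport",
    "OligomerSet",
]

_ALPHABET = {"DNA": "ACGT", "RNA": "ACGU"}
_RC_TABLE = {
    "DNA": str.maketrans("ACGT", "TGCA"),
    "RNA": str.maketrans("ACGU", "UGCA"),
}


def _fast_canon(s: str, table) -> str:
    r = s.translate(table)[::-1]
    return s if s <= r else r


def count_kmer_classes(k: int) -> int:
    """Number of reverse-complement k-mer classes.

    4^k/2 for odd k; (4^k + 4^(k/2))/2 for even k (self-complementary
    k-mers are their own class). E.g. 512 pentamer and 2080 hexamer
    classes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k % 2 == 1:
        return 4 ** k // 2
    return (4 ** k + 4 ** (k // 2)) // 2


@dataclass
class DesignReport:
    """Census summary of a designed covering sequence."""

    k: int
    length: int
    n_classes: int
    counts: dict[str, int]
    duplicated: dict[str, int] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return not self.duplicated and all(c == 1 for c in self.counts.values())


@dataclass
class OligomerSet:
    """Capped oligomers tiling a designed sequence."""

    oligomers: list[str]
    cores: list[str]
    core_len: int
    cap: str = "GCGC"


def kmer_census(
    seqs, k: int, collapse_complement: bool = True, na_type: str | None = None
) -> dict[str, int]:
    """Count k-mer windows of one or more sequences.

    With ``collapse_complement`` the counts are per canonical
    reverse-complement class (each window counted once, under its class
    representative); otherwise per literal window on the given strand.
    """
    if isinstance(seqs, (str, DuplexSequence)):
        seqs = [seqs]
    counts: dict[str, int] = {}
    for seq in seqs:
        s = seq.letters if isinstance(seq, DuplexSequence) else seq.upper()
        nt = seq.na_type if isinstance(seq, DuplexSequence) else na_type
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if collapse_complement:
                w = canonical_class(w, nt)
            counts[w] = counts.get(w, 0) + 1
    return counts


def minimal_covering_sequence(
    k: int, rng_seed: int = 0, na_type: str = "DNA"
) -> tuple[DuplexSequence, DesignReport]:
    """Design a short sequence containing every k-mer class.

    For odd k the result has the optimal length
    ``count_kmer_classes(k) + k - 1`` and contains every class exactly
    once; for even k duplicated classes may be unavoidable and are
    listed in the report. Deterministic for a given seed: candidate
    letters are tried in a seeded random order with lexicographic
    tie-breaking within equal preference.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alphabet = _ALPHABET[na_type.upper()]
    n_classes = count_kmer_classes(k)
    rng = random.Random(rng_seed)

    if k == 1:
        # Two classes {A/T} and {C/G}; any 2-letter sequence with one of each.
        letters = [rng.choice("AT" if na_type.upper() == "DNA" else "AU"),
                   rng.choice("CG")]
        rng.shuffle(letters)
        seq = DuplexSequence("".join(letters), na_type)
        rep = DesignReport(k, 2, n_classes, kmer_census(seq, 1))
        return seq, rep

    target_len = n_classes + k - 1
    table = _RC_TABLE[na_type.upper()]

    def attempt_exact() -> str | None:
        """One randomized descent; None on a dead end before full cover."""
        start = "".join(rng.choice(alphabet) for _ in range(k))
        text = start
        suffix = start[1:]
        covered = {_fast_canon(start, table)}
        while len(text) < target_len:
            opts = [c for c in alphabet
                    if _fast_canon(suffix + c, table) not in covered]
            if not opts:
                return None
            c = rng.choice(opts)
            covered.add(_fast_canon(suffix + c, table))
            text += c
            suffix = text[-(k - 1):]
        return text

    # Dead ends are rare for odd k (no self-complementary classes), so a
    # restarting DFS finds an optimal sequence within a few dozen tries.
    max_restarts = 20000 if k % 2 == 1 else 200
    for _ in range(max_restarts):
        text = attempt_exact()
        if text is not None:
            seq = DuplexSequence(text, na_type)
            counts = kmer_census(seq, k)
            return seq, DesignReport(k, len(seq), n_classes, counts)

    # Even-k fallback: greedy cover allowing duplicated classes when stuck.
    start = "".join(rng.choice(alphabet) for _ in range(k))
    text = start
    covered = {_fast_canon(start, table)}
    while len(covered) < n_classes:
        suffix = text[-(k - 1):]
        opts = [c for c in alphabet
                if _fast_canon(suffix + c, table) not in covered]
        c = rng.choice(opts) if opts else rng.choice(alphabet)
        covered.add(_fast_canon(suffix + c, table))
        text += c
    out = DuplexSequence(text, na_type)
    counts = kmer_census(out, k)
    dup = {cls: c for cls, c in counts.items() if c > 1}
    return out, DesignReport(k, len(out), n_classes, counts, duplicated=dup)


def partition_into_oligomers(
    seq: DuplexSequence | str, core_len: int, k: int,
    cap: str = "GCGC", na_type: str | None = None,
) -> OligomerSet:
    """Split a designed sequence into capped synthesis-sized duplexes.

    Cores tile the sequence with stride ``core_len - (k - 1)`` so that
    adjacent cores overlap in k-1 letters and no interior k-mer window
    is lost; the last core is right-aligned to the sequence end. Each
    core is capped on both ends (GCGC by default) to isolate end
    fraying; caps are excluded from any census or model fitting.
    """
    s = seq.letters if isinstance(seq, DuplexSequence) else seq.upper()
    nt = seq.na_type if isinstance(seq, DuplexSequence) else (na_type or "DNA")
    if core_len < k:
        raise ValueError("core_len must be >= k")
    if core_len > len(s):
        raise ValueError("core_len longer than the sequence")
    if nt == "RNA":
        cap = cap.replace("T", "U")
    stride = core_len - (k - 1)
    starts = list(range(0, len(s) - core_len, stride))
    starts.append(len(s) - core_len)  # right-aligned last core
    cores = [s[i:i + core_len] for i in starts]
    oligos = [cap + c + cap for c in cores]
    return OligomerSet(oligos, cores, core_len, cap)
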