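"""Small sequence helpers shared across modules."""

from __future__ import annotations

import hashlib

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

#: canonical base pairs recognised by the folder (Watson-Crick + GU wobble),
#: expressed on the DNA alphabet used internally (T, not U)
CANONICAL_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and U->T normalise."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Lowercase RNA alphabet (t->u), the convention used for mature products."""
    return seq.lower().replace("t", "u")


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings (case/U-T normalised)."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    a, b = to_dna(a), to_dna(b)
    return sum(x != y for x, y in zip(a, b))


def can_pair(x: str, y: str) -> bool:
    """True if bases x and y form a canonical or GU-wobble pair; N never pairs."""
    return (to_dna(x), to_dna(y)) in CANONICAL_PAIRS


def stable_read_id(seq: str) -> str:
    """Deterministic short identifier derived from the sequence itself."""
    return "r" + hashlib.sha1(to_dna(seq).encode()).hexdigest()[:10]


def phred_to_string(quals) -> str:
    """Integer Phred scores -> Sanger Phred+33 ASCII."""
    return "".join(chr(int(q) + 33) for q in quals)


def string_to_phred(qstr: str) -> list[int]:
    return [ord(c) - 33 for c in qstr]
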