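"""Low-level sequence helpers shared across modules.

Sequences are handled as plain Python strings of A/C/G/T (uppercase);
Bio.Seq is used for translation and FASTA I/O goes through Bio.SeqIO.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: transition partner of each base
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: the two transversion partners of each base
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string (standard code), trailing partial codon dropped."""
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def random_dna(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> str:
    """I.i.d. nucleotide sequence at the given GC fraction."""
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0,1), got {gc_content}")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return "".join(bases)


def is_transition(a: str, b: str) -> bool:
    """True when a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and TRANSITION.get(a) == b


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3 (anything else -> 4) as a uint8 array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.uint8)
    for i, base in enumerate(b"ACGT"):
        codes[arr == base] = i
    return codes
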