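"""Small shared helpers: sequence alphabet handling, IUPAC codes, rounding."""

from __future__ import annotations

import re
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_VALID_DNA_RE = re.compile(r"^[ACGTNRYSWKMBDHV]*$")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> str:
    """Uppercase and validate against the IUPAC DNA alphabet."""
    s = seq.upper()
    if not _VALID_DNA_RE.match(s):
        bad = sorted(set(re.sub(r"[ACGTNRYSWKMBDHV]", "", s)))
        raise ValueError(f"{name} contains non-IUPAC characters: {bad}")
    return s


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate pattern into a regex over ACGT text."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def iupac_match(pattern: str, seq: str) -> bool:
    return bool(iupac_regex(pattern).fullmatch(seq.upper()))


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero at the given decimal place (49.855 -> 49.86)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a DNA string for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=n))
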