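"""Composition and gapped k-mer features.

Thirteen blocks in a fixed order: the three terminal Z-curve coordinates,
GC content, AT/GC ratio, the two cumulative skews, word frequencies for
lengths 1..K ("pseudo composition"), and the eight gapped-pair families
(left word of length a in {1,2,3}, g wildcard bases, right word of length b)
for g = 1..n.  With K=3 and n=5 the full vector has 14,891 entries.

All counts are raw overlapping occurrence counts; an optional span
normalization divides each count by the number of valid placements.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .errors import ConfigError, EmptySequenceError, UndefinedRatioError
from .features import FeatureSchema, FeatureVector
from .io import SequenceRecord

ALPHABET = "ACGT"
_CODE = {ord(b): i for i, b in enumerate(ALPHABET)}

# (family name, left word length, right word length), in schema order.
KGAP_FAMILIES: tuple[tuple[str, int, int], ...] = (
    ("monoMonoKGap", 1, 1),
    ("monoDiKGap", 1, 2),
    ("monoTriKGap", 1, 3),
    ("diMonoKGap", 2, 1),
    ("diDiKGap", 2, 2),
    ("diTriKGap", 2, 3),
    ("triMonoKGap", 3, 1),
    ("triDiKGap", 3, 2),
)

DEFAULT_K = 3
DEFAULT_GAP = 5


def _codes(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for byte, code in _CODE.items():
        codes[arr == byte] = code
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters; sanitize first")
    return codes


def _words(length: int) -> list[str]:
    return ["".join(w) for w in itertools.product(ALPHABET, repeat=length)]


def _word_codes(codes: np.ndarray, length: int) -> np.ndarray:
    """Base-4 code of every overlapping word of ``length``; empty if too short."""
    n_words = codes.size - length + 1
    if n_words <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n_words, dtype=np.int64)
    for offset in range(length):
        out = out * 4 + codes[offset : offset + n_words]
    return out


def zcurve_terminal(seq: SequenceRecord | str) -> tuple[float, float, float]:
    """Final (x, y, z) of the cumulative Z-curve."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise EmptySequenceError("empty sequence")
    a = residues.count("A")
    c = residues.count("C")
    g = residues.count("G")
    t = residues.count("T")
    return float((a + g) - (c + t)), float((a + c) - (g + t)), float((a + t) - (c + g))


def gc_content(seq: SequenceRecord | str) -> float:
    """Percent of G+C among all bases."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise EmptySequenceError("empty sequence")
    gc = residues.count("G") + residues.count("C")
    return 100.0 * gc / len(residues)


def atgc_ratio(seq: SequenceRecord | str) -> float:
    """(A+T)/(G+C); raises when the sequence has no G or C."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    gc = residues.count("G") + residues.count("C")
    if gc == 0:
        raise UndefinedRatioError("AT/GC ratio undefined: no G or C bases")
    return (residues.count("A") + residues.count("T")) / gc


def cumulative_skew(seq: SequenceRecord | str) -> tuple[float, float]:
    """(GC skew, AT skew) = ((G-C)/(G+C), (A-T)/(A+T)); 0 on a zero denominator."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise EmptySequenceError("empty sequence")
    a = residues.count("A")
    c = residues.count("C")
    g = residues.count("G")
    t = residues.count("T")
    gc_skew = (g - c) / (g + c) if g + c else 0.0
    at_skew = (a - t) / (a + t) if a + t else 0.0
    return gc_skew, at_skew


def pseudo_composition(seq: SequenceRecord | str, K: int = DEFAULT_K) -> np.ndarray:
    """Overlapping counts of every word of length 1..K, ordered by length
    then lexicographically (A<C<G<T)."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if K < 1:
        raise ConfigError("K must be >= 1")
    codes = _codes(residues)
    parts = []
    for o in range(1, K + 1):
        counts = np.bincount(_word_codes(codes, o), minlength=4**o).astype(float)
        parts.append(counts)
    return np.concatenate(parts)


def kgap_block(
    seq: SequenceRecord | str,
    left: int,
    right: int,
    n: int = DEFAULT_GAP,
    normalize: bool = False,
) -> np.ndarray:
    """Counts of left-word / g-wildcard / right-word patterns.

    Ordering: gap g = 1..n ascending (outer), then left word then right word
    lexicographically.  ``normalize`` divides by the number of placements
    L - (a+g+b) + 1 (0 stays 0 when no placement fits).
    """
    if (left, right) not in {(a, b) for _, a, b in KGAP_FAMILIES}:
        raise ConfigError(f"unsupported k-gap family: left={left}, right={right}")
    if n < 1:
        raise ConfigError("max gap n must be >= 1")
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    codes = _codes(residues)
    L = codes.size
    lcodes = _word_codes(codes, left)
    rcodes = _word_codes(codes, right)
    width = 4**left * 4**right
    out = np.zeros(n * width, dtype=float)
    for g in range(1, n + 1):
        span = left + g + right
        n_placements = L - span + 1
        if n_placements > 0:
            pair = lcodes[:n_placements] * 4**right + rcodes[left + g :][:n_placements]
            counts = np.bincount(pair, minlength=width).astype(float)
            if normalize:
                counts /= n_placements
            out[(g - 1) * width : g * width] = counts
    return out


def build_schema(K: int = DEFAULT_K, n: int = DEFAULT_GAP) -> FeatureSchema:
    """Canonical 13-block schema; 14,891 features at K=3, n=5."""
    blocks: list[tuple[str, list[str]]] = [
        ("zcurve", ["zcurve_x", "zcurve_y", "zcurve_z"]),
        ("gccontent", ["gccontent"]),
        ("atgc_ratio", ["atgc_ratio"]),
        ("cumulative_skew", ["gc_skew", "at_skew"]),
        (
            "pseudo_composition",
            [f"pseudo_{w}" for o in range(1, K + 1) for w in _words(o)],
        ),
    ]
    for name, a, b in KGAP_FAMILIES:
        blocks.append(
            (
                name,
                [
                    f"{name}_g{g}_{lw}_{rw}"
                    for g in range(1, n + 1)
                    for lw in _words(a)
                    for rw in _words(b)
                ],
            )
        )
    return FeatureSchema.from_blocks(blocks)


def expected_block_sizes(K: int = DEFAULT_K, n: int = DEFAULT_GAP) -> dict[str, int]:
    """Closed-form block sizes (used as an arithmetic cross-check)."""
    sizes = {
        "zcurve": 3,
        "gccontent": 1,
        "atgc_ratio": 1,
        "cumulative_skew": 2,
        "pseudo_composition": sum(4**o for o in range(1, K + 1)),
    }
    for name, a, b in KGAP_FAMILIES:
        sizes[name] = 4**a * 4**b * n
    return sizes


def pyfeat_vector(
    seq: SequenceRecord,
    K: int = DEFAULT_K,
    n: int = DEFAULT_GAP,
    normalize: bool = False,
    schema: FeatureSchema | None = None,
) -> FeatureVector:
    """Full 13-block composition/k-gap vector for one sanitized record.

    An undefined AT/GC ratio (no G or C) is stored as NaN; downstream
    selection imputes it.
    """
    if schema is None:
        schema = build_schema(K, n)
    try:
        ratio = atgc_ratio(seq)
    except UndefinedRatioError:
        ratio = math.nan
    parts = [
        np.array(zcurve_terminal(seq)),
        np.array([gc_content(seq)]),
        np.array([ratio]),
        np.array(cumulative_skew(seq)),
        pseudo_composition(seq, K),
    ]
    for _, a, b in KGAP_FAMILIES:
        parts.append(kgap_block(seq, a, b, n, normalize=normalize))
    return FeatureVector(
        record_id=seq.id, values=np.concatenate(parts), schema=schema
    )
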