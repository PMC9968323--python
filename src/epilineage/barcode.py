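"""Degenerate barcode template and lineage-barcode primitives.

The lineage barcode is a 12-nt random sequence embedded in a reporter
3'UTR as three 4-nt blocks separated by fixed spacers, giving the
template ``NNNNGCGNNNNTGANNNN``.  The informative barcode is the
concatenation of the N positions with the spacers removed; the template
therefore addresses 4**12 = 16,777,216 distinct barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

DEFAULT_TEMPLATE_PATTERN = "NNNNGCGNNNNTGANNNN"


@dataclass(frozen=True)
class BarcodeTemplate:
    """A barcode template: fixed spacers interleaved with degenerate N runs.

    Parameters
    ----------
    pattern
        String over ``{A, C, G, T, N}``; N marks a degenerate (random)
        position, any other letter is a fixed spacer base.
    """

    pattern: str = DEFAULT_TEMPLATE_PATTERN
    random_positions: tuple[int, ...] = field(init=False)
    spacer_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("template pattern must be non-empty")
        bad = set(self.pattern) - set(ALPHABET + "N")
        if bad:
            raise ValueError(f"template pattern contains invalid characters: {sorted(bad)}")
        object.__setattr__(
            self,
            "random_positions",
            tuple(i for i, c in enumerate(self.pattern) if c == "N"),
        )
        object.__setattr__(
            self,
            "spacer_positions",
            tuple(i for i, c in enumerate(self.pattern) if c != "N"),
        )
        if not self.random_positions:
            raise ValueError("template pattern must contain at least one N position")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def barcode_length(self) -> int:
        """Number of informative (degenerate) positions."""
        return len(self.random_positions)

    @property
    def capacity(self) -> int:
        """Number of distinct barcodes the template can encode (4**n_random)."""
        return 4 ** self.barcode_length

    def instantiate(self, barcode: str) -> str:
        """Fill the N positions with ``barcode``, returning a full template instance."""
        if len(barcode) != self.barcode_length:
            raise ValueError(
                f"barcode length {len(barcode)} != template degenerate length {self.barcode_length}"
            )
        chars = list(self.pattern)
        for pos, base in zip(self.random_positions, barcode):
            chars[pos] = base
        return "".join(chars)


DEFAULT_TEMPLATE = BarcodeTemplate()

BARCODE_LENGTH = DEFAULT_TEMPLATE.barcode_length
BARCODE_SPACE = DEFAULT_TEMPLATE.capacity


def int_to_seq(value: int, length: int) -> str:
    """Encode an integer as a DNA string (base-4, A=0 C=1 G=2 T=3, big-endian)."""
    chars = []
    for _ in range(length):
        chars.append(ALPHABET[value & 3])
        value >>= 2
    return "".join(reversed(chars))


def ints_to_seqs(values: np.ndarray, length: int) -> list[str]:
    """Vector version of :func:`int_to_seq`."""
    return [int_to_seq(int(v), length) for v in values]


def seq_to_int(seq: str) -> int:
    value = 0
    for c in seq:
        value = (value << 2) | _BASE_INDEX[c]
    return value


def is_valid_barcode(seq: str, length: int = BARCODE_LENGTH) -> bool:
    return len(seq) == length and all(c in _BASE_INDEX for c in seq)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Draw ``n`` random DNA strings uniformly (with replacement) from 4**length."""
    values = rng.integers(0, 4**length, size=n, dtype=np.int64)
    return ints_to_seqs(values, length)


def random_distinct_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Draw ``n`` distinct random DNA strings (rejection sampling on duplicates)."""
    space = 4**length
    if n > space:
        raise ValueError("cannot draw more distinct sequences than the space holds")
    seen: dict[int, None] = {}
    while len(seen) < n:
        for v in rng.integers(0, space, size=n - len(seen), dtype=np.int64):
            if len(seen) == n:
                break
            seen.setdefault(int(v), None)
    return ints_to_seqs(np.array(list(seen)), length)
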