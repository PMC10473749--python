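"""Canonical k-mer counting and count-based trust classification.

K-mers are counted strand-agnostically: every window of length ``k`` over the
input reads increments the count of its *canonical* form, the lexicographic
minimum of the window and its reverse complement. Counts from accurate short
reads separate k-mers into trust regimes — sequencing-error k-mers are rare,
heterozygous k-mers sit near half the homozygous coverage peak, unique
homozygous k-mers near the peak, and repetitive k-mers far above it. Three
count thresholds delimit these regimes and drive both error-site detection
and anchor selection in the polisher.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Tuple

__all__ = [
    "KmerClass",
    "KmerClassConfig",
    "KmerCountTable",
    "canonical",
    "classify_kmer",
    "count_kmers",
    "kmer_histogram",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# 2-bit codes in alphabetical order so integer order equals lexicographic
# order on equal-length k-mers.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


class KmerClass(enum.Enum):
    """Trust regime of a k-mer count under a :class:`KmerClassConfig`."""

    ERROR = "ERROR"
    HET = "HET"
    SOLID = "SOLID"
    REPETITIVE = "REPETITIVE"


@dataclass(frozen=True)
class KmerClassConfig:
    """Count thresholds delimiting the k-mer trust regimes.

    ERROR: count < err_threshold; HET: [err_threshold, het_threshold);
    SOLID: [het_threshold, unique_threshold]; REPETITIVE: above that.
    Each named parameter is the first count of its regime, except
    ``unique_threshold`` which caps SOLID.
    """

    err_threshold: int = 11
    het_threshold: int = 30
    unique_threshold: int = 65

    def __post_init__(self) -> None:
        if not (0 < self.err_threshold <= self.het_threshold <= self.unique_threshold):
            raise ValueError(
                "thresholds must satisfy 0 < err_threshold <= het_threshold "
                f"<= unique_threshold, got {self.err_threshold}, "
                f"{self.het_threshold}, {self.unique_threshold}"
            )


def classify_kmer(count: int, config: KmerClassConfig = KmerClassConfig()) -> KmerClass:
    """Map a k-mer count to its trust regime.

    Raises
    ------
    ValueError
        If ``count`` is negative.
    """
    if count < 0:
        raise ValueError(f"k-mer count must be non-negative, got {count}")
    if count < config.err_threshold:
        return KmerClass.ERROR
    if count < config.het_threshold:
        return KmerClass.HET
    if count <= config.unique_threshold:
        return KmerClass.SOLID
    return KmerClass.REPETITIVE


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _iter_canonical_codes(seq: str, k: int) -> Iterator[Tuple[int, int]]:
    """Yield ``(start, canonical_code)`` for every clean window of ``seq``.

    Windows containing any character outside A/C/G/T (after uppercasing)
    are skipped entirely. Rolling 2-bit encoding keeps this O(len(seq))
    for any k.
    """
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    code = _CODE
    fwd = 0
    rev = 0
    valid = 0  # number of consecutive valid bases ending at current position
    for i in range(n):
        c = code.get(seq[i])
        if c is None:
            valid = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rev = (rev >> 2) | ((3 - c) << shift)
        valid += 1
        if valid >= k:
            yield i - k + 1, fwd if fwd <= rev else rev


class KmerCountTable:
    """Multiset of canonical k-mers with integer counts for a fixed ``k``.

    The public ``counts`` mapping is keyed by canonical k-mer strings; an
    integer-encoded mirror backs fast lookups during contig scanning.
    """

    def __init__(self, k: int, counts: Mapping[str, int] | None = None):
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        self.k = int(k)
        self.counts: Dict[str, int] = {}
        self._enc: Dict[int, int] = {}
        if counts:
            for kmer, count in counts.items():
                self._insert_validated(kmer, count)

    def _insert_validated(self, kmer: str, count: int) -> None:
        k = self.k
        if len(kmer) != k:
            raise ValueError(f"key {kmer!r} does not have length k={k}")
        if any(b not in _CODE for b in kmer):
            raise ValueError(f"key {kmer!r} contains characters outside ACGT")
        if kmer != canonical(kmer):
            raise ValueError(f"key {kmer!r} is not in canonical form")
        if count < 0:
            raise ValueError(f"count for {kmer!r} is negative")
        self.counts[kmer] = self.counts.get(kmer, 0) + int(count)
        code = 0
        for b in kmer:
            code = (code << 2) | _CODE[b]
        self._enc[code] = self._enc.get(code, 0) + int(count)

    @classmethod
    def _from_encoded(cls, k: int, enc: Dict[int, int]) -> "KmerCountTable":
        table = cls(k)
        table._enc = enc
        table.counts = {_decode(code, k): n for code, n in enc.items()}
        return table

    @property
    def total_kmers(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, kmer: str) -> int:
        """Count of a k-mer queried in either orientation (0 if absent)."""
        return self.counts.get(canonical(kmer.upper()), 0)

    def get_code(self, canonical_code: int) -> int:
        return self._enc.get(canonical_code, 0)

    def window_counts(self, seq: str) -> Dict[int, int]:
        """Counts for every clean window of ``seq``, keyed by window start.

        Starts of windows containing non-ACGT characters are absent from
        the result; callers treat those windows as untrusted.
        """
        enc = self._enc
        return {i: enc.get(code, 0) for i, code in _iter_canonical_codes(seq, self.k)}


def count_kmers(reads: Iterable, k: int) -> KmerCountTable:
    """Count canonical k-mers over an iterable of reads.

    ``reads`` may yield plain strings, ``(id, sequence)`` pairs, or objects
    with a ``seq`` attribute (e.g. Biopython ``SeqRecord``). Lowercase is
    accepted; windows with ambiguity codes contribute nothing.

    Raises
    ------
    ValueError
        If ``k < 2``. Empty input yields an empty table.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    enc: Dict[int, int] = {}
    get = enc.get
    for read in reads:
        if hasattr(read, "seq"):
            seq = str(read.seq)
        elif isinstance(read, tuple):
            seq = read[1]
        else:
            seq = read
        for _, code in _iter_canonical_codes(seq, k):
            enc[code] = get(code, 0) + 1
    return KmerCountTable._from_encoded(k, enc)


def kmer_histogram(table: KmerCountTable, max_bin: int) -> Dict[int, int]:
    """Tally distinct k-mers by count, saturating counts above ``max_bin``.

    Raises
    ------
    ValueError
        If ``max_bin < 1``.
    """
    if max_bin < 1:
        raise ValueError(f"max_bin must be >= 1, got {max_bin}")
    hist: Dict[int, int] = {}
    for count in table.counts.values():
        b = count if count < max_bin else max_bin
        hist[b] = hist.get(b, 0) + 1
    return hist
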