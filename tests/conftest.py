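"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's implementation paths:
counting is done by naive window enumeration, and the patch search by
exhaustive depth-first path enumeration.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

import kmerpatch as kp

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def oracle_count(seqs, k: int) -> Dict[str, int]:
    """Brute-force canonical k-mer counting by window enumeration."""
    counts: Dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(b not in "ACGT" for b in window):
                continue
            canon = min(window, oracle_revcomp(window))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def oracle_assemble(
    left: str,
    right: str,
    ref_span: int,
    table: kp.KmerCountTable,
    config: kp.PolishConfig,
) -> Optional[Tuple[int, int, str]]:
    """Exhaustive DFS over all anchor-connecting paths within the length
    bound; returns the optimal (min_interior, total_interior, interior) or
    None when no path exists. Applies the library's path ordering —
    bottleneck desc, length asc, total desc, lexicographic — but is
    otherwise independent of the best-first search."""
    k = table.k
    err = config.class_config.err_threshold
    max_len = 2 * k + math.ceil(config.dist_multiplier * ref_span) + k
    best: Optional[Tuple[int, int, str]] = None

    def better(a, b) -> bool:
        if a[0] != b[0]:
            return a[0] > b[0]
        if len(a[2]) != len(b[2]):
            return len(a[2]) < len(b[2])
        if a[1] != b[1]:
            return a[1] > b[1]
        return a[2] < b[2]

    def visit(spelled: str, mn: float, total: int) -> None:
        nonlocal best
        if len(spelled) >= max_len:
            return
        for base in "ACGT":
            node = spelled[-(k - 1) :] + base
            count = table.get(node)
            if count < err:
                continue
            t = spelled + base
            if node == right and len(t) >= 2 * k:
                cand = (mn, total, t[k:-k])
                if best is None or better(cand, best):
                    best = cand
            visit(t, min(mn, count), total + count)

    visit(left, float("inf"), 0)
    if best is None:
        return None
    return int(best[0]), int(best[1]), best[2]


def table_from_weighted_reads(reads: List[Tuple[str, int]], k: int) -> kp.KmerCountTable:
    """Count each read with an integer multiplicity."""
    expanded: List[str] = []
    for seq, mult in reads:
        expanded.extend([seq] * mult)
    return kp.count_kmers(expanded, k)


# --- standard fixture (shared across unit and acceptance tests) -----------


@pytest.fixture(scope="session")
def std_truth() -> kp.TruthSet:
    """Standard fixture: 100 kb genome, 50 SUB + 10 INS + 10 DEL, seed 1."""
    return kp.make_truth_set(seed=1)


@pytest.fixture(scope="session")
def std_reads(std_truth) -> List[str]:
    """Error-free 40x 150 bp reads over the standard truth genome."""
    cid = next(iter(std_truth.genome))
    pairs = kp.simulate_reads(
        std_truth.genome[cid], coverage=40, read_len=150, error_rate=0.0, seed=101
    )
    return [seq for _, seq in pairs]


@pytest.fixture(scope="session")
def std_table21(std_reads) -> kp.KmerCountTable:
    return kp.count_kmers(std_reads, 21)


@pytest.fixture(scope="session")
def std_polished(std_truth, std_reads):
    """Default two-round polish of the standard draft; (contigs, report)."""
    return kp.run_polish(std_truth.draft, std_reads, kp.PolishConfig())
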