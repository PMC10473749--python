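"""Consensus accuracy assessment.

Two complementary views: a reference-free, Merqury-style k-mer QV estimate
(what fraction of assembly k-mers is unsupported by the reads), and exact
truth-based scoring against a synthetic fixture's error ledger.

The QV model: if an assembly of K_total k-mer instances has K_err instances
absent from the read set, the probability that a single base is correct is
P = (1 - K_err/K_total)^(1/k), because one base error corrupts k overlapping
k-mers. The per-base error rate is E = 1 - P and QV = -10*log10(E) on the
Phred scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import edlib

from .kmer_core import KmerCountTable, _iter_canonical_codes

__all__ = ["CorrectionScore", "QvEstimate", "compare_to_truth", "estimate_qv"]


@dataclass
class QvEstimate:
    """K-mer based consensus quality estimate of an assembly."""

    k: int
    assembly_kmers_total: int
    assembly_kmers_missing: int
    per_base_error: float
    qv: float
    errors_per_10kb: float
    qv_capped: bool = False  # True when no k-mer was missing (qv = sentinel)

    def to_dict(self) -> Dict[str, object]:
        return {
            "k": self.k,
            "K_total": self.assembly_kmers_total,
            "K_err": self.assembly_kmers_missing,
            "E": self.per_base_error,
            "qv": self.qv,
            "errors_per_10kb": self.errors_per_10kb,
            "qv_capped": self.qv_capped,
        }


def estimate_qv(
    assembly: Iterable[Tuple[str, str]] | Dict[str, str] | str,
    table: KmerCountTable,
    qmax: float = 99.0,
) -> QvEstimate:
    """Estimate consensus QV of an assembly from a read k-mer table.

    Assembly k-mers are counted as instances (multiset): K_total is the
    number of valid-alphabet windows over all contigs, K_err the number of
    those whose canonical form is absent from the read table. When K_err is
    zero the error rate is 0 and qv is reported as the ``qmax`` sentinel.

    Raises
    ------
    ValueError
        If the assembly contributes no valid k-mer instance (undefined
        estimate).
    """
    if isinstance(assembly, str):
        seqs: List[str] = [assembly]
    elif isinstance(assembly, dict):
        seqs = list(assembly.values())
    else:
        seqs = [seq for _, seq in assembly]
    k = table.k
    total = 0
    missing = 0
    for seq in seqs:
        for _, code in _iter_canonical_codes(seq, k):
            total += 1
            if table.get_code(code) == 0:
                missing += 1
    if total == 0:
        raise ValueError("assembly contains no valid k-mer instance; QV undefined")
    if missing == 0:
        return QvEstimate(k, total, 0, 0.0, qmax, 0.0, qv_capped=True)
    p_correct = (1.0 - missing / total) ** (1.0 / k)
    err = 1.0 - p_correct
    qv = -10.0 * math.log10(err)
    return QvEstimate(k, total, missing, err, qv, err * 1e4)


@dataclass
class CorrectionScore:
    """Exact polishing score against a synthetic truth set."""

    injected: int
    corrected: int
    introduced: int
    precision: float
    recall: float

    def to_dict(self) -> Dict[str, object]:
        return {
            "injected": self.injected,
            "corrected": self.corrected,
            "introduced": self.introduced,
            "precision": self.precision,
            "recall": self.recall,
        }


def _diff_positions(query: str, ref: str) -> List[int]:
    """Reference positions at which query and ref differ (mismatch or indel).

    Equal-length inputs are compared directly; otherwise a global
    edit-distance alignment (edlib NW) is walked and each mismatch, inserted
    run or deleted run contributes the reference position where it starts.
    """
    if query == ref:
        return []
    if len(query) == len(ref):
        direct = [i for i, (a, b) in enumerate(zip(query, ref)) if a != b]
        # Fall back to alignment when a same-length draft still carries
        # offsetting indels (e.g. one insertion plus one deletion).
        if len(direct) <= 0.01 * len(ref):
            return direct
    aln = edlib.align(query, ref, mode="NW", task="path")
    positions: List[int] = []
    rpos = 0
    for n, op in _cigar_ops(aln["cigar"]):
        if op == "=":
            rpos += n
        elif op == "X":
            positions.extend(range(rpos, rpos + n))
            rpos += n
        elif op == "D":  # present in ref, absent in query
            positions.append(rpos)
            rpos += n
        elif op == "I":  # present in query, absent in ref
            positions.append(rpos)
    return positions


def _cigar_ops(cigar: str) -> Iterable[Tuple[int, str]]:
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def compare_to_truth(
    polished: Iterable[Tuple[str, str]] | Dict[str, str],
    truth,
    tolerance: int = 10,
) -> CorrectionScore:
    """Score polished contigs against a :class:`~kmerpatch.synth.TruthSet`.

    Every difference between a polished contig and its truth contig is
    located in truth coordinates and classified: within ``tolerance`` bases
    of an injected-error locus it is a residual injected error (alignment of
    indels is ambiguous within homopolymers, hence the tolerance); anywhere
    else it counts as introduced. Injected loci with no nearby residual
    difference are corrected.

    Raises
    ------
    KeyError
        If polished contig IDs do not match the truth set's.
    """
    if isinstance(polished, dict):
        contigs = dict(polished)
    else:
        contigs = {cid: seq for cid, seq in polished}
    if set(contigs) != set(truth.genome):
        raise KeyError(
            f"contig IDs {sorted(contigs)} do not match truth IDs "
            f"{sorted(truth.genome)}"
        )
    ledger_by_contig: Dict[str, List[int]] = {cid: [] for cid in truth.genome}
    for entry in truth.ledger:
        ledger_by_contig[entry.contig_id].append(entry.position)
    injected = len(truth.ledger)
    introduced = 0
    residual_loci = 0
    for cid, ref in truth.genome.items():
        loci = sorted(ledger_by_contig[cid])
        diffs = _diff_positions(contigs[cid].upper(), ref.upper())
        hit = set()
        for p in diffs:
            nearest = _nearest(loci, p)
            if nearest is not None and abs(nearest - p) <= tolerance:
                hit.add(nearest)
            else:
                introduced += 1
        residual_loci += len(hit)
    corrected = injected - residual_loci
    recall = corrected / injected if injected > 0 else 1.0
    denom = corrected + introduced
    precision = corrected / denom if denom > 0 else 1.0
    return CorrectionScore(injected, corrected, introduced, precision, recall)


def _nearest(sorted_loci: List[int], p: int) -> Optional[int]:
    if not sorted_loci:
        return None
    import bisect

    i = bisect.bisect_left(sorted_loci, p)
    cands = []
    if i < len(sorted_loci):
        cands.append(sorted_loci[i])
    if i > 0:
        cands.append(sorted_loci[i - 1])
    return min(cands, key=lambda q: abs(q - p))
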