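"""K-mer based draft-assembly polishing via anchored local reassembly.

The polisher scans a draft contig with the k-mer counts of accurate short
reads. Positions covered by at least one untrusted (ERROR-class) window form
error sites. Each site is anchored in trusted flanking sequence, and a
replacement is assembled by searching the implicit de Bruijn graph of
non-error read k-mers from the left anchor to the right anchor. The highest
coverage path — maximal bottleneck count, ties broken by total count, then
by lexicographically smallest spelled sequence — is applied as the patch.
One polishing pass is run per configured k (default 21 then 51): the small
k localizes errors finely, the large k resolves regions that are repetitive
at small k.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import enum
import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .kmer_core import (
    KmerClass,
    KmerClassConfig,
    KmerCountTable,
    classify_kmer,
    count_kmers,
)

__all__ = [
    "AnchorRef",
    "ErrorSite",
    "PatchResult",
    "PatchStatus",
    "PolishConfig",
    "PolishReport",
    "RoundReport",
    "assemble_patch",
    "find_error_sites",
    "polish_contig",
    "run_polish",
    "select_anchors",
]


@dataclass(frozen=True)
class PolishConfig:
    """All polishing parameters.

    Parameters
    ----------
    class_config
        Count thresholds separating ERROR / HET / SOLID / REPETITIVE k-mers.
    anchor_threshold
        Maximum number of window start positions scanned outward from an
        error site, per side, when hunting a trusted anchor.
    max_nodes_to_search
        Node-expansion budget of the best-first graph search per site.
    dist_multiplier
        Slack factor bounding the assembled interior length relative to the
        anchor-to-anchor span on the draft.
    rounds
        Ordered k values; one polishing pass is run per entry.
    """

    class_config: KmerClassConfig = field(default_factory=KmerClassConfig)
    anchor_threshold: int = 50
    max_nodes_to_search: int = 1000
    dist_multiplier: float = 1.2
    rounds: Tuple[int, ...] = (21, 51)

    def __post_init__(self) -> None:
        if self.anchor_threshold < 1:
            raise ValueError("anchor_threshold must be >= 1")
        if self.max_nodes_to_search < 1:
            raise ValueError("max_nodes_to_search must be >= 1")
        if self.dist_multiplier < 1.0:
            raise ValueError("dist_multiplier must be >= 1.0")
        if not self.rounds or any(k < 2 for k in self.rounds):
            raise ValueError("rounds must be non-empty with every k >= 2")
        object.__setattr__(self, "rounds", tuple(int(k) for k in self.rounds))


@dataclass(frozen=True)
class AnchorRef:
    """A trusted k-mer flanking an error site, on the contig forward strand."""

    kmer: str
    start: int
    count: int


@dataclass
class ErrorSite:
    """Maximal untrusted span of a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    left_anchor: Optional[AnchorRef] = None
    right_anchor: Optional[AnchorRef] = None


class PatchStatus(enum.Enum):
    PATCHED = "PATCHED"
    NO_ANCHOR = "NO_ANCHOR"
    NO_PATH = "NO_PATH"
    BUDGET_EXHAUSTED = "BUDGET_EXHAUSTED"


@dataclass
class PatchResult:
    site: ErrorSite
    status: PatchStatus
    replacement: Optional[str] = None
    path_min_count: Optional[int] = None
    nodes_expanded: int = 0


@dataclass
class RoundReport:
    """Per-round polishing summary."""

    k: int
    sites_detected: int
    sites_patched: int
    status_counts: Dict[str, int]
    results: List[PatchResult]
    contig_lengths: Dict[str, int]


@dataclass
class PolishReport:
    rounds: List[RoundReport] = field(default_factory=list)

    def total_patched(self) -> int:
        return sum(r.sites_patched for r in self.rounds)

    def summary(self) -> List[Dict[str, object]]:
        return [
            {
                "k": r.k,
                "sites_detected": r.sites_detected,
                "sites_patched": r.sites_patched,
                "status_counts": dict(r.status_counts),
            }
            for r in self.rounds
        ]


def find_error_sites(
    contig: str,
    table: KmerCountTable,
    config: PolishConfig = PolishConfig(),
    contig_id: str = "contig",
) -> List[ErrorSite]:
    """Locate maximal untrusted spans of a contig.

    A position belongs to a site iff at least one window covering it is
    ERROR-class: its canonical count in the read table is below
    ``err_threshold`` (absent counts as 0), or the window contains a
    non-ACGT character. Runs separated by fewer than k trusted bases are
    merged, since the gap cannot host a full anchor window. Contigs shorter
    than k yield no sites.
    """
    k = table.k
    contig = contig.upper()
    n = len(contig)
    if n < k:
        return []
    err = config.class_config.err_threshold
    counts = table.window_counts(contig)
    # Error windows: count below threshold, or window invalid (absent key).
    n_windows = n - k + 1
    intervals: List[List[int]] = []  # footprints of maximal error-window runs
    run_start = None
    for i in range(n_windows):
        bad = counts.get(i, 0) < err
        if bad and run_start is None:
            run_start = i
        elif not bad and run_start is not None:
            intervals.append([run_start, i - 1 + k])
            run_start = None
    if run_start is not None:
        intervals.append([run_start, n_windows - 1 + k])
    # Merge footprints separated by fewer than k trusted bases.
    merged: List[List[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < k:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    return [ErrorSite(contig_id, s, e) for s, e in merged]


def select_anchors(
    contig: str,
    site: ErrorSite,
    table: KmerCountTable,
    config: PolishConfig = PolishConfig(),
) -> ErrorSite:
    """Populate a site's anchors from its trusted flanks.

    The left anchor is the nearest HET- or SOLID-class window whose footprint
    ends at or before ``site.start``; the right anchor the nearest one
    starting at or after ``site.end``. At most ``anchor_threshold`` window
    start positions are scanned outward per side; a failed scan leaves the
    anchor absent (downstream status NO_ANCHOR). REPETITIVE windows are
    rejected: a repeat k-mer has many graph locations and cannot pin the
    patch.
    """
    k = table.k
    contig = contig.upper()
    n = len(contig)
    cc = config.class_config
    counts = table.window_counts(contig)

    def trusted(start: int) -> Optional[AnchorRef]:
        count = counts.get(start)
        if count is None:  # invalid window
            return None
        if classify_kmer(count, cc) in (KmerClass.HET, KmerClass.SOLID):
            return AnchorRef(kmer=contig[start : start + k], start=start, count=count)
        return None

    left = None
    hi = site.start - k  # nearest start whose footprint ends at site.start
    lo = max(0, hi - config.anchor_threshold + 1)
    for start in range(hi, lo - 1, -1):
        left = trusted(start)
        if left is not None:
            break

    right = None
    lo = site.end
    hi = min(n - k, lo + config.anchor_threshold - 1)
    for start in range(lo, hi + 1):
        right = trusted(start)
        if right is not None:
            break

    return replace(site, left_anchor=left, right_anchor=right)


_INF = float("inf")


def assemble_patch(
    left: AnchorRef,
    right: AnchorRef,
    ref_span: int,
    table: KmerCountTable,
    config: PolishConfig = PolishConfig(),
    site: Optional[ErrorSite] = None,
) -> PatchResult:
    """Assemble the highest-coverage path between two anchors.

    Searches the implicit de Bruijn graph whose nodes are non-ERROR read
    k-mers (queried canonically, traversed in contig orientation) and whose
    edges are (k-1)-base overlaps, from ``left.kmer`` to ``right.kmer``.
    Accepted paths spell at most ``ceil(dist_multiplier * ref_span) + k``
    interior bases. Expansion is best-first by (bottleneck count descending,
    path length ascending); every expanded node counts against
    ``max_nodes_to_search``. Among all goal-reaching paths found within the
    budget, the winner maximizes the minimum interior count (bottleneck
    coverage); ties prefer the shortest path, then the highest total
    interior count, then the lexicographically smallest spelled sequence.
    Shorter-on-tie matters because canonical counting can alias a k-mer to
    its reverse complement elsewhere in the reads, creating cycles whose
    traversal would inflate a raw total-count criterion without adding any
    evidence. The anchors themselves are excluded from the interior scores.
    """
    if left is None or right is None:
        raise ValueError("assemble_patch requires both anchors")
    k = table.k
    err = config.class_config.err_threshold
    goal = right.kmer
    bound_interior = math.ceil(config.dist_multiplier * ref_span) + k
    max_len = 2 * k + bound_interior  # spelled-string length cap

    # State: spelled string s (starts with left.kmer); stats (min, total)
    # over its non-initial nodes. Candidates are recorded at generation time
    # with the parent's stats, which cover exactly the interior nodes
    # (everything strictly between the anchors).
    # Heap entries ordered by (-bottleneck, length, spelled) for determinism.
    best: Optional[Tuple[float, int, str]] = None  # (min, total, interior)
    heap: List[Tuple[float, int, str, float, int]] = [(-_INF, k, left.kmer, _INF, 0)]
    expanded = 0
    budget = config.max_nodes_to_search
    exhausted = False
    get = table.get
    while heap:
        if expanded >= budget:
            exhausted = True
            break
        neg_b, length, spelled, mn, total = heapq.heappop(heap)
        expanded += 1
        if length >= max_len:
            continue
        suffix = spelled[-(k - 1) :]
        for base in "ACGT":
            node = suffix + base
            count = get(node)
            if count < err:
                continue
            t = spelled + base
            if node == goal and len(t) >= 2 * k:
                cand = (mn, total, t[k:-k])
                if best is None or _better(cand, best):
                    best = cand
            nmn = count if count < mn else mn
            heapq.heappush(heap, (-nmn, length + 1, t, nmn, total + count))

    if site is None:
        site = ErrorSite("contig", left.start + k, right.start)
    if best is not None:
        mn, _, interior = best
        return PatchResult(
            site=site,
            status=PatchStatus.PATCHED,
            replacement=interior,
            path_min_count=int(mn),
            nodes_expanded=expanded,
        )
    status = PatchStatus.BUDGET_EXHAUSTED if exhausted else PatchStatus.NO_PATH
    return PatchResult(site=site, status=status, nodes_expanded=expanded)


def _better(a: Tuple[float, int, str], b: Tuple[float, int, str]) -> bool:
    """Path preference: higher bottleneck, then shorter, then higher total,
    then lexicographically smaller interior."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if len(a[2]) != len(b[2]):
        return len(a[2]) < len(b[2])
    if a[1] != b[1]:
        return a[1] > b[1]
    return a[2] < b[2]


def polish_contig(
    contig: str,
    table: KmerCountTable,
    config: PolishConfig = PolishConfig(),
    contig_id: str = "contig",
) -> Tuple[str, List[PatchResult]]:
    """One polishing pass over a single contig at the table's k.

    Sites are detected left-to-right on the input contig; PATCHED sites have
    the span strictly between their anchors replaced by the assembled
    interior. Patches are applied right-to-left in original coordinates so
    earlier replacements cannot shift later ones. Bases outside
    anchor-to-anchor spans are never modified.
    """
    contig = contig.upper()
    k = table.k
    sites = find_error_sites(contig, table, config, contig_id)
    results: List[PatchResult] = []
    for site in sites:
        site = select_anchors(contig, site, table, config)
        if site.left_anchor is None or site.right_anchor is None:
            results.append(PatchResult(site=site, status=PatchStatus.NO_ANCHOR))
            continue
        ref_span = site.right_anchor.start - (site.left_anchor.start + k)
        results.append(
            assemble_patch(
                site.left_anchor, site.right_anchor, ref_span, table, config, site
            )
        )
    out = contig
    limit = len(contig)  # leftmost already-rewritten coordinate
    for res in reversed(results):
        if res.status is not PatchStatus.PATCHED:
            continue
        a = res.site.left_anchor.start + k
        b = res.site.right_anchor.start
        if b > limit:
            # Anchor spans of adjacent sites overlap (possible only when the
            # gap between them is entirely repetitive); applying both would
            # misalign, so this patch is dropped as unusable.
            res.status = PatchStatus.NO_PATH
            res.replacement = None
            res.path_min_count = None
            continue
        out = out[:a] + res.replacement + out[b:]
        limit = a
    return out, results


def run_polish(
    assembly: Iterable[Tuple[str, str]] | Dict[str, str],
    reads: Sequence,
    config: PolishConfig = PolishConfig(),
) -> Tuple[Dict[str, str], PolishReport]:
    """Polish an assembly over the configured multi-round k schedule.

    For each k in ``config.rounds``, read k-mers are counted once and every
    contig of the current (possibly already-patched) assembly is polished.
    Contig IDs and order are preserved. The polisher is deterministic:
    identical inputs and config produce bit-identical outputs.
    """
    if isinstance(assembly, dict):
        contigs = dict(assembly)
    else:
        contigs = {cid: seq for cid, seq in assembly}
    reads = list(reads)
    report = PolishReport()
    for k in config.rounds:
        table = count_kmers(reads, k)
        round_results: List[PatchResult] = []
        for cid in contigs:
            polished, results = polish_contig(contigs[cid], table, config, cid)
            contigs[cid] = polished
            round_results.extend(results)
        status_counts: Dict[str, int] = {s.value: 0 for s in PatchStatus}
        for r in round_results:
            status_counts[r.status.value] += 1
        report.rounds.append(
            RoundReport(
                k=k,
                sites_detected=len(round_results),
                sites_patched=status_counts[PatchStatus.PATCHED.value],
                status_counts=status_counts,
                results=round_results,
                contig_lengths={cid: len(seq) for cid, seq in contigs.items()},
            )
        )
    return contigs, report
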