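"""Deterministic synthetic fixtures: truth genomes, corrupted drafts, reads.

The generator emulates the regime the polisher targets: a draft consensus
carrying sparse single-base errors (substitutions and 1 bp indels), backed
by accurate short reads at moderate coverage, over a genome of very low
heterozygosity. Injected loci are spaced at least 3 * k_max apart so error
sites never interact, and kept away from contig ends so both anchors always
exist. Every operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "HetSite",
    "LedgerEntry",
    "TruthSet",
    "apply_ledger",
    "inject_errors",
    "make_truth_set",
    "simulate_genome",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))

DEFAULT_SPACING = 3 * 51  # 3 * largest default round k: sites never interact


@dataclass(frozen=True)
class LedgerEntry:
    """One injected error, in truth-genome coordinates (0-based).

    SUB: draft carries ``alt`` instead of ``ref`` at ``position``.
    INS: draft carries an extra base ``alt`` inserted before ``position``.
    DEL: truth base ``ref`` at ``position`` is absent from the draft.
    """

    contig_id: str
    position: int
    type: str  # SUB | INS | DEL
    ref: str
    alt: str


@dataclass(frozen=True)
class HetSite:
    """A heterozygous site carried 50/50 by the simulated reads."""

    contig_id: str
    position: int
    allele_a: str  # the allele present in genome and draft
    allele_b: str


@dataclass
class TruthSet:
    """Truth genome, corrupted draft, injected-error ledger, het sites."""

    genome: Dict[str, str]
    draft: Dict[str, str]
    ledger: List[LedgerEntry]
    het_sites: List[HetSite] = field(default_factory=list)
    seed: int = 0


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random genome with the given GC fraction.

    Raises
    ------
    ValueError
        If ``length < 1`` or ``gc`` is not strictly inside (0, 1).
    """
    if length < 1:
        raise ValueError(f"length must be positive, got {length}")
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must be strictly between 0 and 1, got {gc}")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def _spaced_positions(
    rng: np.random.Generator, n: int, low: int, high: int, spacing: int
) -> np.ndarray:
    """``n`` sorted positions in [low, high), pairwise >= spacing apart."""
    span = (high - low) - (n - 1) * spacing
    if n < 1 or span <= n:
        raise ValueError(
            f"cannot place {n} loci with spacing >= {spacing} in "
            f"[{low}, {high}): interval too small"
        )
    base = np.sort(rng.choice(span, size=n, replace=False))
    return low + base + spacing * np.arange(n)


def inject_errors(
    genome: str,
    n_sub: int = 50,
    n_ins: int = 10,
    n_del: int = 10,
    seed: int = 0,
    spacing: int = DEFAULT_SPACING,
    margin: int = DEFAULT_SPACING,
    contig_id: str = "contig_1",
) -> Tuple[str, List[LedgerEntry]]:
    """Corrupt a genome with spaced single-base errors; return the ledger.

    Loci are uniform within ``[margin, len(genome) - margin)`` subject to the
    pairwise spacing constraint; event types are shuffled over the loci.
    Replaying the ledger onto the genome reproduces the draft exactly.
    """
    n_total = n_sub + n_ins + n_del
    if n_total == 0:
        return genome, []
    rng = np.random.default_rng(seed)
    positions = _spaced_positions(rng, n_total, margin, len(genome) - margin, spacing)
    types = np.array(["SUB"] * n_sub + ["INS"] * n_ins + ["DEL"] * n_del)
    rng.shuffle(types)
    ledger: List[LedgerEntry] = []
    for pos, typ in zip(positions, types):
        pos = int(pos)
        ref = genome[pos]
        if typ == "SUB":
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            ledger.append(LedgerEntry(contig_id, pos, "SUB", ref, alt))
        elif typ == "INS":
            alt = str(rng.choice(list("ACGT")))
            ledger.append(LedgerEntry(contig_id, pos, "INS", "", alt))
        else:
            ledger.append(LedgerEntry(contig_id, pos, "DEL", ref, ""))
    return apply_ledger(genome, ledger), ledger


def apply_ledger(genome: str, ledger: Sequence[LedgerEntry]) -> str:
    """Replay a ledger onto a truth genome, reproducing the draft."""
    draft = genome
    for entry in sorted(ledger, key=lambda e: e.position, reverse=True):
        p = entry.position
        if entry.type == "SUB":
            draft = draft[:p] + entry.alt + draft[p + 1 :]
        elif entry.type == "INS":
            draft = draft[:p] + entry.alt + draft[p:]
        elif entry.type == "DEL":
            draft = draft[:p] + draft[p + 1 :]
        else:
            raise ValueError(f"unknown ledger event type {entry.type!r}")
    return draft


def make_het_sites(
    genome: str,
    n_het: int,
    seed: int = 0,
    spacing: int = DEFAULT_SPACING,
    margin: int = DEFAULT_SPACING,
    contig_id: str = "contig_1",
) -> List[HetSite]:
    """Choose spaced heterozygous SNP sites; allele A is the genome base."""
    if n_het == 0:
        return []
    rng = np.random.default_rng(seed)
    positions = _spaced_positions(rng, n_het, margin, len(genome) - margin, spacing)
    sites = []
    for pos in positions:
        pos = int(pos)
        a = genome[pos]
        b = str(rng.choice([x for x in "ACGT" if x != a]))
        sites.append(HetSite(contig_id, pos, a, b))
    return sites


def simulate_reads(
    genome: str,
    coverage: float = 40.0,
    read_len: int = 150,
    error_rate: float = 0.0,
    het_sites: Sequence[HetSite] = (),
    seed: int = 0,
) -> List[Tuple[str, str]]:
    """Uniform error-bearing short reads as ``(read_id, sequence)`` pairs.

    Reads are unpaired, strands 50/50, total bases >= coverage * genome
    length. When het sites are given, each read is drawn from haplotype A
    (the genome) or haplotype B (het alleles substituted) with equal
    probability. Substitution errors are i.i.d. per base at ``error_rate``.

    Raises
    ------
    ValueError
        If ``read_len`` exceeds the genome length or ``error_rate`` is not
        in [0, 0.1).
    """
    n = len(genome)
    if read_len > n:
        raise ValueError(f"read_len {read_len} exceeds genome length {n}")
    if not (0.0 <= error_rate < 0.1):
        raise ValueError(f"error_rate must be in [0, 0.1), got {error_rate}")
    rng = np.random.default_rng(seed)
    hap_a = genome
    hap_b = genome
    if het_sites:
        hb = list(genome)
        for site in het_sites:
            hb[site.position] = site.allele_b
        hap_b = "".join(hb)
    n_reads = math.ceil(coverage * n / read_len)
    starts = rng.integers(0, n - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    haplotypes = rng.integers(0, 2, size=n_reads) if het_sites else np.zeros(n_reads, int)
    comp = str.maketrans("ACGT", "TGCA")
    reads: List[Tuple[str, str]] = []
    for i in range(n_reads):
        s = int(starts[i])
        src = hap_b if haplotypes[i] else hap_a
        seq = src[s : s + read_len]
        if error_rate > 0.0:
            errs = np.nonzero(rng.random(read_len) < error_rate)[0]
            if errs.size:
                chars = list(seq)
                for j in errs:
                    chars[j] = str(rng.choice([b for b in "ACGT" if b != chars[j]]))
                seq = "".join(chars)
        if strands[i]:
            seq = seq.translate(comp)[::-1]
        reads.append((f"read_{i}", seq))
    return reads


def make_truth_set(
    length: int = 100_000,
    gc: float = 0.5,
    n_sub: int = 50,
    n_ins: int = 10,
    n_del: int = 10,
    n_het: int = 0,
    seed: int = 1,
    spacing: int = DEFAULT_SPACING,
    margin: int = DEFAULT_SPACING,
    contig_id: str = "contig_1",
) -> TruthSet:
    """Build a complete single-contig truth set.

    Defaults give the standard polishing fixture: a 100 kb genome with 50
    substitutions, 10 insertions and 10 deletions injected into the draft.
    Sub-streams are seeded independently (but deterministically) from
    ``seed`` so each component is reproducible in isolation. Het sites, when
    requested, are placed on loci disjoint from the injected errors.
    """
    genome = simulate_genome(length, gc, seed=seed)
    draft, ledger = inject_errors(
        genome, n_sub, n_ins, n_del, seed=seed + 1_000_003,
        spacing=spacing, margin=margin, contig_id=contig_id,
    )
    het_sites: List[HetSite] = []
    if n_het:
        occupied = [e.position for e in ledger]
        het_sites = _disjoint_het_sites(
            genome, n_het, occupied, seed + 2_000_003, spacing, margin, contig_id
        )
    return TruthSet(
        genome={contig_id: genome},
        draft={contig_id: draft},
        ledger=ledger,
        het_sites=het_sites,
        seed=seed,
    )


def _disjoint_het_sites(
    genome: str,
    n_het: int,
    occupied: Sequence[int],
    seed: int,
    spacing: int,
    margin: int,
    contig_id: str,
) -> List[HetSite]:
    rng = np.random.default_rng(seed)
    for attempt in range(100):
        cand = make_het_sites(
            genome, n_het, seed=int(rng.integers(0, 2**31 - 1)),
            spacing=spacing, margin=margin, contig_id=contig_id,
        )
        if all(
            min((abs(s.position - p) for p in occupied), default=spacing) >= spacing
            for s in cand
        ):
            return cand
    raise ValueError(
        "could not place het sites disjoint from injected errors under the "
        f"spacing >= {spacing} constraint"
    )
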