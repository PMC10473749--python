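# Methods

## The polishing model

`kmerpatch` corrects residual consensus errors in a draft assembly using
only the k-mer spectrum of accurate short reads — no alignment is ever
performed. The model rests on a single observation: a consensus error
corrupts every k-mer window covering it, and corrupted k-mers are (with
overwhelming probability) absent from, or rare in, the reads. Conversely,
genuine genomic k-mers — including both alleles of a heterozygous site —
occur at counts near the sequencing coverage.

Counting is canonical: each read window increments the lexicographic
minimum of itself and its reverse complement, making the table
strand-agnostic. Four count regimes are delimited by three thresholds
(defaults in parentheses):

| regime     | count range                | meaning                         |
|------------|----------------------------|---------------------------------|
| ERROR      | `< err_threshold` (11)     | unsupported; likely an error    |
| HET        | `[11, het_threshold)` (30) | one haplotype's worth of support|
| SOLID      | `[30, unique_threshold]` (65) | unique homozygous sequence   |
| REPETITIVE | `> 65`                     | multi-copy sequence             |

Each named threshold is the first count of its regime, except
`unique_threshold`, which caps SOLID. The defaults presume an effective
k-mer coverage whose homozygous peak sits between `het_threshold` and
`unique_threshold` (≈ 35–45×); for read sets with substantially different
coverage the thresholds should be rescaled accordingly.

The HET band is the reason the classifier has four regimes rather than two:
in a diploid (even one of very low heterozygosity), a k-mer carried by only
one haplotype counts at roughly half coverage. Treating such k-mers as
trusted prevents the polisher from "correcting" real heterozygous variation
toward whichever allele the consensus happens to carry.

## Error sites, anchors, patches

**Detection.** A contig position is untrusted iff at least one window
covering it is ERROR-class (windows containing non-ACGT characters are
untrusted by fiat). Maximal untrusted runs become error sites; runs
separated by fewer than k trusted bases are merged, because the gap cannot
host a complete anchor window. Coordinates are 0-based, half-open
everywhere, including the BED patch report.

**Anchoring.** Each site is flanked by the nearest HET- or SOLID-class
window on either side, scanning at most `anchor_threshold` (50) window
start positions outward per side. REPETITIVE windows are rejected as
anchors — a multi-copy k-mer has many graph locations and cannot pin a
patch — but are traversable inside a patch, since repeats may legitimately
lie within the replaced span. A failed scan yields status `NO_ANCHOR` and
the site is left untouched.

**Patch assembly.** The replacement is found by best-first search over the
implicit de Bruijn graph whose nodes are non-ERROR read k-mers and whose
edges are (k−1)-base overlaps, from the left anchor to the right anchor,
traversed in contig orientation with canonical count lookups. The
expansion order is (current bottleneck count descending, path length
ascending), and every expanded node counts against `max_nodes_to_search`
(1000). A path is accepted only if its interior spells at most
`ceil(dist_multiplier × ref_span) + k` bases, where `ref_span` is the
anchor-to-anchor span on the draft and `dist_multiplier` = 1.2; the `+k`
absorbs anchor-overlap bookkeeping. Among all anchor-connecting paths found
within the budget, the winner is the "highest coverage path": maximal
minimum interior count, ties broken by shortest interior, then highest
total interior count, then lexicographically smallest spelled sequence.
The anchors are excluded from the interior scores.

Two details of this ordering were genuinely open design choices:

- *Shortest-on-tie before total count.* Canonical counting can alias a
  k-mer to its reverse complement occurring elsewhere, creating cycles in
  the local graph. A raw total-count tie-break would reward traversing such
  cycles (more nodes, more total) without any added evidence; preferring
  the shorter path on bottleneck ties removes that pathology and makes the
  chosen patch the parsimonious one.
- *Candidate recording at generation time.* A goal-reaching path is scored
  the moment it is generated, and the goal state is also re-expanded, so a
  path may pass through the right-anchor k-mer and terminate on a later
  visit, provided it respects the length bound.

With an ample node budget the search provably degenerates to exhaustive
enumeration, which is how it is tested: an independent depth-first
enumerator applying the same ordering must agree exactly on every
constructed local graph.

**Application.** Patches replace the span strictly between the two anchors.
They are applied right-to-left in original-contig coordinates so earlier
replacements cannot shift later ones; bases outside anchor-to-anchor spans
are never modified. In the rare case that the anchor spans of adjacent
sites overlap (possible only when the gap between them is entirely
repetitive), the later patch is dropped (`NO_PATH`) rather than risk a
misaligned double edit.

**Rounds.** One polishing pass is run per configured k, default `[21, 51]`:
k=21 localizes errors finely and is sensitive even at modest coverage;
k=51 disambiguates regions that are repetitive at 21 bp scale. Read k-mers
are recounted once per round at that round's k. The polisher contains no
randomness; identical inputs and configuration give bit-identical outputs.

## Consensus QV

With `K_total` assembly k-mer instances of which `K_err` are absent from
the read table, the probability that a base is correct is
`P = (1 − K_err/K_total)^(1/k)` (one base error corrupts k overlapping
k-mers), the per-base error rate is `E = 1 − P`, and `QV = −10·log10(E)`.
Assembly k-mers are counted as instances (a multiset), not distinct keys,
matching the per-base reading of the formula. When `K_err = 0` the QV is
reported as a configurable sentinel (default 99) since −log 0 is unbounded.
Note that QV 31 corresponds to `E = 10^−3.1`, i.e. ≈ 7.9 errors per 10 kb.

Truth-based scoring (`compare_to_truth`) complements the reference-free QV
on synthetic fixtures: polished contigs are compared to the truth genome —
directly when lengths permit, otherwise through a global edit-distance
alignment (edlib) — and every difference is assigned, in truth coordinates,
either to an injected-error locus within 10 bp (a *residual* error;
the tolerance absorbs indel placement ambiguity inside homopolymers) or to
*introduced* damage. Recall is the fraction of injected errors with no
residual difference.

## Synthetic fixtures

The generator emulates the regime the polisher targets: a long
deterministic i.i.d. genome (GC fraction configurable), a draft carrying
sparse single-base substitutions and 1 bp indels, and uniform error-free or
error-bearing unpaired short reads, optionally drawn 50/50 from two
haplotypes differing at chosen SNP sites. Injected loci are pairwise
separated by ≥ 3×51 bases and kept that far from contig ends, so error
sites never interact and always have flanking anchor material. Every
operation consumes an explicit integer seed; the same seed reproduces the
same bytes.

Standard problem sizes used by the test-suite and the acceptance script:
a 100 kb genome with 50 substitutions + 10 insertions + 10 deletions and
error-free 40× 150 bp reads for correction recovery (per-allele effective
21-mer coverage ≈ 35×, placing homozygous k-mers in SOLID); and a 50 kb
genome with 20 heterozygous sites at 60× for heterozygosity preservation
(per-allele 21-mer coverage ≈ 26, keeping both alleles comfortably above
`err_threshold`; a single k=21 round). These sizes make each property
checkable in well under a minute per seed while leaving the count regimes
in the same relationship to the thresholds as in the data the defaults were
designed for.

What the fixtures do **not** emulate — and hence what passing tests do not
demonstrate about real data: repeat families and segmental duplications
(an i.i.d. genome has essentially no repetitive k-mers, so `REPETITIVE`
handling is exercised only by dedicated constructed cases), clustered or
systematic sequencing errors, GC-biased or quality-dependent error
profiles, structural errors larger than 1 bp, and the sheer scale of a
multi-Gb genome. The polisher is written for desk-scale inputs (tens of
Mb); counting is in-memory pure Python and is the runtime bottleneck at
roughly 2–4 s per Mb of reads per round.

## LTR insertion-time dating

The two long terminal repeats of an LTR retrotransposon are identical at
insertion; their divergence afterwards clocks the element's age as
`T = K/(2r)`, with `K = 1 − identity` between the paired LTRs and `r` the
neutral substitution rate per site per year (default 2.2×10⁻⁹, a standard
conifer value). Identity columns are auto-detected as fractions or
percents (values above 1.5 are treated as percents), and divergence is
used raw — deliberately no Jukes-Cantor or K2P correction, and
identity = 1 elements are retained at age 0. Ages are reported in years
and My and histogrammed with a configurable bin width (default 0.5 My).

## Numerical and degenerate-input conventions

- Counting uses 2-bit rolling codes with A<C<G<T, so integer comparison of
  equal-length codes equals lexicographic string comparison; any window
  containing a non-ACGT character (after uppercasing) contributes nothing.
- Contigs shorter than k yield no sites; an empty read set yields an empty
  table (not an error); an assembly with no valid window has undefined QV
  and raises.
- A site touching a contig end has no flank on that side: `NO_ANCHOR`.
- `k < 2`, non-positive rates, out-of-range GC or identity, negative
  counts, and threshold orderings violating
  `0 < err ≤ het ≤ unique` all raise `ValueError` before any work is done.
- Gzip output omits the mtime/filename header fields so identical content
  gives identical bytes.

## Known limitations

- The anchor scan interprets `anchor_threshold` as a per-side limit on
  scanned window start positions; other readings of the released tool's
  parameter are possible.
- Errors within ~k bases of a contig end cannot be anchored and are left
  uncorrected by design.
- Whole-genome (Gb) performance is out of scope; the counter is exact and
  in-memory.
- `compare_to_truth` attributes differences to loci within a fixed 10 bp
  tolerance; fixtures with error spacing below ~20 bp would need a
  different attribution rule.
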