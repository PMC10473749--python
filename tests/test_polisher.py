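"""Error-site detection, anchoring, patch assembly and whole-contig polishing."""

import numpy as np
import pytest

import kmerpatch as kp
from kmerpatch.polisher import PatchStatus

from conftest import oracle_assemble, table_from_weighted_reads


def substitute(seq: str, pos: int) -> str:
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
    return seq[:pos] + alt + seq[pos + 1 :]


@pytest.fixture(scope="module")
def region_fixture(std_truth, std_table21):
    """A 500 bp truth substring with one substitution at offset 250."""
    cid = next(iter(std_truth.genome))
    genome = std_truth.genome[cid]
    region = genome[40_000:40_500]
    return substitute(region, 250), region


class TestFindErrorSites:
    def test_single_substitution_site_footprint(self, region_fixture, std_table21):
        contig, _ = region_fixture
        sites = kp.find_error_sites(contig, std_table21)
        # the 21 windows covering the substituted base span [230, 271)
        assert [(s.start, s.end) for s in sites] == [(230, 271)]

    def test_membership_matches_per_window_oracle(self, region_fixture, std_table21):
        """A position is in a site iff some ERROR-class window covers it."""
        contig, _ = region_fixture
        k, err = 21, 11
        bad = np.zeros(len(contig), dtype=bool)
        for i in range(len(contig) - k + 1):
            if std_table21.get(contig[i : i + k]) < err:
                bad[i : i + k] = True
        sites = kp.find_error_sites(contig, std_table21)
        covered = np.zeros(len(contig), dtype=bool)
        for s in sites:
            covered[s.start : s.end] = True
        assert np.array_equal(bad, covered)

    def test_clean_region_has_no_sites(self, region_fixture, std_table21):
        _, truth_region = region_fixture
        assert kp.find_error_sites(truth_region, std_table21) == []

    def test_foreign_contig_is_one_whole_site(self, std_table21):
        rng = np.random.default_rng(99)
        foreign = "".join(rng.choice(list("ACGT"), size=300))
        sites = kp.find_error_sites(foreign, std_table21)
        assert [(s.start, s.end) for s in sites] == [(0, 300)]

    def test_contig_shorter_than_k_yields_no_sites(self, std_table21):
        assert kp.find_error_sites("ACGT", std_table21) == []

    def test_nearby_runs_merge(self):
        # two error k-mers separated by fewer than k trusted bases
        k = 5
        genome = "ACGTGTGACCTAGCTAGGCTAACGGTCCAGTA" * 4
        table = kp.count_kmers([genome] * 30, k)
        contig = substitute(substitute(genome, 40), 47)  # 7 < k apart... merged
        config = kp.PolishConfig(rounds=(k,))
        sites = kp.find_error_sites(contig, table, config)
        assert len(sites) == 1


class TestSelectAnchors:
    def test_anchor_positions_flank_the_site(self, region_fixture, std_table21):
        contig, _ = region_fixture
        site = kp.find_error_sites(contig, std_table21)[0]
        site = kp.select_anchors(contig, site, std_table21)
        assert site.left_anchor.start == site.start - 21  # footprint ends at start
        assert site.right_anchor.start == site.end
        assert site.left_anchor.kmer == contig[site.left_anchor.start : site.start]
        for anchor in (site.left_anchor, site.right_anchor):
            assert 11 <= anchor.count <= 65  # HET or SOLID

    def test_no_left_flank_means_no_left_anchor(self, std_truth, std_table21):
        cid = next(iter(std_truth.genome))
        region = std_truth.genome[cid][50_000:50_400]
        contig = substitute(region, 5)  # site touches the contig start
        sites = kp.find_error_sites(contig, std_table21)
        site = kp.select_anchors(contig, sites[0], std_table21)
        assert site.left_anchor is None
        assert site.right_anchor is not None

    def test_repetitive_flank_yields_no_anchor(self):
        # left flank is a 60-copy tandem repeat: every flank window counts
        # far above unique_threshold and is rejected as an anchor
        k = 5
        rng = np.random.default_rng(5)
        unique = "ACGTGATCCGTAGGCTAACG"
        repeat = "ACGTG" * 60
        genome = repeat + unique
        table = kp.count_kmers([genome] * 40, k)
        contig = repeat + substitute(unique, 10)
        config = kp.PolishConfig(rounds=(k,), anchor_threshold=50)
        sites = kp.find_error_sites(contig, table, config)
        assert sites, "substitution must be detected"
        site = kp.select_anchors(contig, sites[0], table, config)
        assert site.left_anchor is None


class TestAssemblePatch:
    def test_single_read_path(self):
        """Toy graph from one read at count 30: the patch is its interior."""
        read = "ACGTACGGTATTCGG"
        k = 5
        table = table_from_weighted_reads([(read, 30)], k)
        left = kp.AnchorRef(kmer="ACGTA", start=0, count=30)
        right = kp.AnchorRef(kmer="TTCGG", start=10, count=30)
        config = kp.PolishConfig(rounds=(k,))
        res = kp.assemble_patch(left, right, ref_span=5, table=table, config=config)
        assert res.status is PatchStatus.PATCHED
        assert res.replacement == read[5:10]
        assert res.path_min_count == 30
        # agrees with the exhaustive enumerator
        oracle = oracle_assemble("ACGTA", "TTCGG", 5, table, config)
        assert oracle is not None
        assert (oracle[0], oracle[2]) == (res.path_min_count, res.replacement)

    def test_two_bubble_prefers_higher_coverage(self):
        """Two haplotype paths at counts 12 vs 25: the 25-path wins."""
        flank_l = "ACGGTAGCTT"
        flank_r = "TCCAGATGCA"
        hap1 = flank_l + "AATCG" + flank_r
        hap2 = flank_l + "GGCTA" + flank_r
        k = 5
        table = table_from_weighted_reads([(hap1, 12), (hap2, 25)], k)
        left = kp.AnchorRef(kmer=flank_l[-5:], start=5, count=37)
        right = kp.AnchorRef(kmer=flank_r[:5], start=15, count=37)
        config = kp.PolishConfig(rounds=(k,))
        res = kp.assemble_patch(left, right, ref_span=5, table=table, config=config)
        assert res.status is PatchStatus.PATCHED
        assert res.replacement == "GGCTA"
        assert res.path_min_count == 25
        oracle = oracle_assemble(left.kmer, right.kmer, 5, table, config)
        assert (res.path_min_count, oracle[1], res.replacement) == oracle

    def test_unreachable_goal_is_no_path(self):
        read = "ACGTACGGTATTCGG"
        k = 5
        table = table_from_weighted_reads([(read, 30)], k)
        left = kp.AnchorRef(kmer="ACGTA", start=0, count=30)
        right = kp.AnchorRef(kmer="AAAAA", start=10, count=0)
        res = kp.assemble_patch(
            left, right, ref_span=5, table=table, config=kp.PolishConfig(rounds=(k,))
        )
        assert res.status is PatchStatus.NO_PATH
        assert res.replacement is None

    def test_missing_anchor_is_caller_bug(self):
        table = kp.KmerCountTable(5)
        with pytest.raises(ValueError):
            kp.assemble_patch(None, None, 5, table, kp.PolishConfig(rounds=(5,)))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle_on_random_graphs(self, seed):
        """Random local graphs (with mutated alternate haplotypes creating
        bubbles): the best-first search equals exhaustive enumeration.

        k=7 keeps chance k-mer collisions (which would create cycles and an
        exponential path count) essentially impossible at these lengths, so
        the exhaustive enumerator stays tractable while bubbles from the
        mutated haplotypes still exercise the path ordering."""
        rng = np.random.default_rng(seed)
        k = 7
        n = int(rng.integers(35, 70))
        base = "".join(rng.choice(list("ACGT"), size=n))
        reads = [(base, int(rng.integers(12, 40)))]
        for _ in range(int(rng.integers(0, 3))):
            pos = int(rng.integers(k, n - k))
            reads.append((substitute(base, pos), int(rng.integers(12, 40))))
        table = table_from_weighted_reads(reads, k)
        left_kmer, right_kmer = base[:k], base[-k:]
        config = kp.PolishConfig(rounds=(k,), max_nodes_to_search=200_000)
        ref_span = n - 2 * k
        res = kp.assemble_patch(
            kp.AnchorRef(left_kmer, 0, table.get(left_kmer)),
            kp.AnchorRef(right_kmer, n - k, table.get(right_kmer)),
            ref_span,
            table,
            config,
        )
        oracle = oracle_assemble(left_kmer, right_kmer, ref_span, table, config)
        if oracle is None:
            assert res.status is not PatchStatus.PATCHED
        else:
            assert res.status is PatchStatus.PATCHED
            assert (res.path_min_count, oracle[1], res.replacement) == oracle


class TestPolishContig:
    def test_single_substitution_fully_corrected(self, region_fixture, std_table21):
        contig, truth_region = region_fixture
        out, results = kp.polish_contig(contig, std_table21)
        assert out == truth_region
        assert [r.status for r in results] == [PatchStatus.PATCHED]

    def test_error_free_contig_untouched(self, region_fixture, std_table21):
        _, truth_region = region_fixture
        out, results = kp.polish_contig(truth_region, std_table21)
        assert out == truth_region
        assert results == []

    def test_edge_error_unanchored_others_corrected(self, std_truth, std_table21):
        cid = next(iter(std_truth.genome))
        genome = std_truth.genome[cid]
        region = genome[60_000:61_000]
        contig = substitute(substitute(substitute(region, 995), 300), 600)
        out, results = kp.polish_contig(contig, std_table21)
        statuses = sorted(r.status.value for r in results)
        assert statuses == ["NO_ANCHOR", "PATCHED", "PATCHED"]
        # the two interior errors are corrected; the edge error remains
        assert out[:990] == region[:990]
        assert out != region

    def test_edits_confined_to_anchor_spans(self, std_truth, std_table21):
        """Soundness: output differs from input only inside reported spans."""
        cid = next(iter(std_truth.genome))
        region = std_truth.genome[cid][70_000:71_000]
        contig = substitute(region, 400)
        out, results = kp.polish_contig(contig, std_table21)
        spans = [
            (r.site.left_anchor.start + 21, r.site.right_anchor.start)
            for r in results
            if r.status is PatchStatus.PATCHED
        ]
        assert len(spans) == 1
        a, b = spans[0]
        assert out[:a] == contig[:a]
        assert out[len(out) - (len(contig) - b) :] == contig[b:]


class TestRunPolish:
    def test_identity_on_error_free_assembly(self, std_truth, std_reads):
        cid = next(iter(std_truth.genome))
        config = kp.PolishConfig(rounds=(21,))
        polished, report = kp.run_polish(std_truth.genome, std_reads, config)
        assert polished[cid] == std_truth.genome[cid]
        assert report.rounds[0].sites_patched == 0

    def test_budget_starvation_is_monotone(self, std_truth, std_reads):
        """max_nodes_to_search=1 patches strictly fewer sites than the
        default, and the patched set under a small budget is a subset of
        the patched set under a larger one."""
        def patched_sites(budget):
            config = kp.PolishConfig(rounds=(21,), max_nodes_to_search=budget)
            _, report = kp.run_polish(std_truth.draft, std_reads, config)
            return {
                (r.site.contig_id, r.site.start, r.site.end)
                for r in report.rounds[0].results
                if r.status is PatchStatus.PATCHED
            }

        starved = patched_sites(1)
        small = patched_sites(120)
        rich = patched_sites(1000)
        assert len(starved) < len(rich)
        assert starved <= small <= rich

    def test_determinism(self, std_truth, std_reads):
        config = kp.PolishConfig(rounds=(21,))
        out1, rep1 = kp.run_polish(std_truth.draft, std_reads, config)
        out2, rep2 = kp.run_polish(std_truth.draft, std_reads, config)
        assert out1 == out2
        assert rep1.summary() == rep2.summary()

    def test_heterozygous_locus_left_alone(self):
        """Reads carry a 50/50 SNP, the contig one allele: both alleles'
        k-mers count in the trusted range, so no site is called and the
        contig allele survives polishing."""
        ts = kp.make_truth_set(
            length=30_000, n_sub=0, n_ins=0, n_del=0, n_het=6, seed=3
        )
        cid = next(iter(ts.genome))
        reads = [
            seq
            for _, seq in kp.simulate_reads(
                ts.genome[cid], coverage=60, read_len=150,
                het_sites=ts.het_sites, seed=33,
            )
        ]
        config = kp.PolishConfig(rounds=(21,))
        polished, report = kp.run_polish(ts.genome, reads, config)
        het_positions = {h.position for h in ts.het_sites}
        for res in report.rounds[0].results:
            assert not any(
                res.site.start <= p < res.site.end for p in het_positions
            )
        for h in ts.het_sites:
            assert polished[cid][h.position] == h.allele_a


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"anchor_threshold": 0},
            {"max_nodes_to_search": 0},
            {"dist_multiplier": 0.9},
            {"rounds": ()},
            {"rounds": (21, 1)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            kp.PolishConfig(**kwargs)
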