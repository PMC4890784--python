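"""Unmapped-read triage, greedy assembly, ORF/layout/slippery annotation."""

import pytest

from vsrna.align import align_library, build_index, revcomp
from vsrna.discovery import (Contig, OrfRecord, annotate_layout, annotate_virus,
                             canonical_xxxyyyz_rule, collect_unmapped, find_orfs,
                             find_slippery_site, greedy_assemble, rank_contigs,
                             select_layout_orfs)
from vsrna.errors import ConfigurationError


class TestCollectUnmapped:
    def test_exactly_the_nonreference_reads(self, rng):
        genome = {"c1": "".join(rng.choice(list("ACGT"), 3000))}
        genomic = [genome["c1"][i:i + 50] for i in range(0, 500, 25)]
        foreign = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(5)]
        reads = genomic + foreign
        alignment = align_library(build_index(genome), reads)
        assert collect_unmapped(alignment, reads) == foreign

    def test_all_genomic_gives_empty(self, rng):
        genome = {"c1": "".join(rng.choice(list("ACGT"), 1000))}
        reads = [genome["c1"][i:i + 40] for i in range(10)]
        alignment = align_library(build_index(genome), reads)
        assert collect_unmapped(alignment, reads) == []

    def test_empty_input(self, rng):
        genome = {"c1": "".join(rng.choice(list("ACGT"), 200))}
        assert collect_unmapped(align_library(build_index(genome), []), []) == []


class TestGreedyAssemble:
    def test_tiled_reads_reconstruct_genome_exactly(self, reference):
        virus = reference.virus
        reads = [virus[i:i + 50] for i in range(0, len(virus) - 50 + 1, 10)]
        reads.append(virus[-50:])
        contigs = greedy_assemble(reads, min_overlap=20)
        assert len(contigs) == 1
        assert contigs[0].sequence in (virus, revcomp(virus))
        assert contigs[0].support == len(set(reads))

    def test_mixed_orientation_tiling_still_reconstructs(self, reference):
        virus = reference.virus
        reads = [virus[i:i + 50] if (i // 10) % 2 else revcomp(virus[i:i + 50])
                 for i in range(0, len(virus) - 50 + 1, 10)]
        reads.append(virus[-50:])
        contigs = greedy_assemble(reads, min_overlap=20)
        assert contigs[0].sequence in (virus, revcomp(virus))

    def test_zero_overlap_reads_stay_separate(self, rng):
        a = "".join(rng.choice(list("ACGT"), 50))
        b = "".join(rng.choice(list("ACGT"), 50))
        assert a != b
        contigs = greedy_assemble([a, b], min_overlap=15)
        assert len(contigs) == 2

    def test_read_and_its_reverse_complement_collapse(self):
        read = "ACGTTGCAGGCTATCGGATCAAGCTT"
        contigs = greedy_assemble([read, revcomp(read)], min_overlap=15)
        assert len(contigs) == 1
        assert contigs[0].support == 2

    def test_min_overlap_floor(self):
        with pytest.raises(ConfigurationError):
            greedy_assemble(["A" * 30], min_overlap=10)

    def test_deterministic_output(self, reference):
        virus = reference.virus
        reads = [virus[i:i + 50] for i in range(0, 800, 13)]
        c1 = greedy_assemble(reads, min_overlap=20)
        c2 = greedy_assemble(list(reversed(reads)), min_overlap=20)
        assert [c.sequence for c in c1] == [c.sequence for c in c2]


class TestRankContigs:
    def test_dominant_contig_fraction(self, rng, reference):
        virus = reference.virus
        viral = [virus[int(p):int(p) + 50]
                 for p in rng.integers(0, len(virus) - 49, 800)]
        junk = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(200)]
        contigs = greedy_assemble(sorted(set(viral)), min_overlap=20)
        ranked = rank_contigs(contigs, viral + junk)
        assert ranked[0].assigned_fraction == pytest.approx(0.8, abs=0.02)

    def test_unassignable_reads(self):
        contigs = [Contig("A" * 100, 1)]
        ranked = rank_contigs(contigs, ["G" * 30, "C" * 30])
        assert ranked[0].assigned_fraction == 0.0

    def test_duplicate_contigs_no_double_counting(self):
        contigs = [Contig("ACGT" * 25, 1), Contig("ACGT" * 25, 1)]
        ranked = rank_contigs(contigs, ["ACGT" * 10])
        assert ranked[0].assigned_fraction == 1.0
        assert ranked[1].assigned_fraction == 0.0


class TestFindOrfs:
    def brute_force(self, seq, min_len):
        """Independent oracle: enumerate every ATG, extend codon-wise to the
        first stop, keep the first ATG per stop (maximal ORFs)."""
        seq = seq.upper().replace("U", "T")
        stops = {"TAA", "TAG", "TGA"}
        orfs = {}
        for i in range(len(seq) - 2):
            if seq[i:i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= len(seq):
                codon = seq[j:j + 3]
                if codon in stops:
                    if (j + 3) not in orfs or i < orfs[j + 3]:
                        orfs.setdefault(j + 3, i)
                    break
                j += 3
        out = []
        for end, start in orfs.items():
            length = end - start
            if length >= min_len:
                out.append((start + 1, end, (start % 3) + 1, (length - 3) // 3))
        return sorted(out)

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(300, 2000))))
            got = [(o.start, o.end, o.frame, o.length_aa)
                   for o in find_orfs(seq, min_len_nt=60)]
            assert got == self.brute_force(seq, 60)

    def test_synthetic_virus_declared_orfs(self, reference):
        orfs = select_layout_orfs(find_orfs(reference.virus, min_len_nt=300))
        assert [(o.start, o.end, o.frame, o.length_aa) for o in orfs] == \
            [(17, 991, 2, 324), (1081, 2817, 1, 578)]

    def test_no_atg_gives_empty(self):
        assert find_orfs("CCCGGGCCCGGG" * 20) == []

    def test_minus_strand_search(self):
        plus = "ATG" + "GCT" * 30 + "TAA"
        seq = revcomp("CC" + plus + "GG")
        orfs = find_orfs(seq, min_len_nt=60, strand="-")
        assert len(orfs) == 1 and orfs[0].strand == "-"


class TestLayout:
    def test_published_layout_arithmetic(self):
        orfs = [OrfRecord(17, 991, 2, 975, 324), OrfRecord(1081, 2817, 1, 1737, 578)]
        layout = annotate_layout("A" * 2923, orfs)
        assert (layout.five_prime_utr_nt, layout.three_prime_utr_nt,
                layout.spacer_nt) == (16, 106, 89)
        assert layout.frameshift_candidate

    def test_single_orf_no_spacer(self):
        seq = "CCC" + "ATG" + "GCT" * 40 + "TAA" + "GGG"
        orfs = find_orfs(seq, min_len_nt=60)
        layout = annotate_layout(seq, orfs)
        assert layout.five_prime_utr_nt == layout.three_prime_utr_nt == 3
        assert layout.spacer_nt is None

    def test_overlapping_orfs_flagged(self):
        orfs = [OrfRecord(1, 300, 1, 300, 99), OrfRecord(200, 400, 2, 201, 66)]
        layout = annotate_layout("A" * 500, orfs)
        assert layout.overlap_flag and layout.spacer_nt < 0

    def test_roundtrip_on_generator_output(self, base_cfg, reference):
        layout = annotate_virus(reference.virus)
        assert (layout.orfs[0].start, layout.orfs[0].end) == base_cfg.orf1_span
        assert (layout.orfs[1].start, layout.orfs[1].end) == base_cfg.orf2_span

    def test_minimal_orf_boundary(self):
        """The shortest legal ORF (ATG + stop) at position 1 gives a 0-nt
        5' UTR."""
        from vsrna.synthetic import SimConfig, simulate_reference
        cfg = SimConfig(seed=2, orf1_span=(1, 9), orf2_span=(13, 27),
                        slippery_heptamer=None, virus_length=60)
        ref = simulate_reference(cfg)
        orfs = find_orfs(ref.virus, min_len_nt=9)
        first = [o for o in orfs if o.start == 1]
        assert first and annotate_layout(ref.virus, first).five_prime_utr_nt == 0


class TestSlipperySite:
    def test_planted_heptamer_at_zero_distance(self, reference):
        orfs = select_layout_orfs(find_orfs(reference.virus, min_len_nt=300))
        sites, truncated = find_slippery_site(reference.virus, orfs[0])
        assert not truncated
        assert any(s.sequence == "GGAUUUU" and s.distance_to_stop == 0
                   for s in sites)

    def test_no_qualifying_heptamer(self):
        seq = "CCC" + "ATG" + "GCA" * 40 + "TAA"
        orf = find_orfs(seq, min_len_nt=60)[0]
        sites, _ = find_slippery_site(seq, orf)
        assert sites == []

    def test_custom_pattern_rule_finds_planted_sites(self):
        # two NNNUUUU-style heptamers planted in the scan window (codons
        # chosen stop-free; T-runs of exactly four so matches are unique);
        # positions and distances enumerated by hand
        body = "GCA" + "CTT" + "TTG" + "CGC" + "ACA" + "CTT" + "TTG" + "CGC" + "GCA"
        seq = "ATG" + body + "TAA"
        orf = find_orfs(seq, min_len_nt=15)[0]
        assert (orf.start, orf.end) == (1, 33)
        rule = lambda h: h[3:] == "TTTT"
        sites, _ = find_slippery_site(seq, orf, window_nt=27, pattern_rule=rule)
        assert [(s.position, s.sequence, s.distance_to_stop) for s in sites] == \
            [(5, "CACUUUU", 19), (17, "CACUUUU", 7)]

    def test_window_truncation_flag(self):
        seq = "ATG" + "GCA" * 3 + "TAA"
        orf = find_orfs(seq, min_len_nt=9)[0]
        _, truncated = find_slippery_site(seq, orf, window_nt=50)
        assert truncated

    def test_canonical_rule(self):
        assert canonical_xxxyyyz_rule("AAATTTC")
        assert not canonical_xxxyyyz_rule("GGATTTT")
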