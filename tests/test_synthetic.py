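"""Generator self-consistency: determinism, configured laws, truth tables."""

import numpy as np
import pytest
from scipy import stats as sps

from vsrna.errors import ConfigurationError
from vsrna.synthetic import (SIZES, GenotypeProfile, SimConfig,
                             default_genotypes, expected_observed_profile,
                             simulate_reference, simulate_rnaseq_run,
                             simulate_small_rna_run, write_reference)
from tests.conftest import two_genotype_config


class TestValidation:
    def test_orf_span_too_short_names_field(self):
        cfg = SimConfig(orf1_span=(17, 20))
        with pytest.raises(ConfigurationError, match="orf1_span"):
            cfg.validate()

    def test_orf_length_not_codon_multiple(self):
        cfg = SimConfig(orf2_span=(1081, 2818))
        with pytest.raises(ConfigurationError, match="orf2_span"):
            cfg.validate()

    def test_overlapping_orfs_rejected(self):
        cfg = SimConfig(orf1_span=(17, 991), orf2_span=(900, 2819))
        with pytest.raises(ConfigurationError, match="overlap"):
            cfg.validate()

    def test_pmf_must_sum_to_one(self):
        bad = GenotypeProfile(name="x")
        bad.five_prime_pmf["U"] = 0.9
        cfg = SimConfig(genotypes=[bad])
        with pytest.raises(ConfigurationError, match="five_prime_pmf"):
            cfg.validate()

    def test_duplicate_barcodes_rejected(self, reference, tmp_path):
        cfg = two_genotype_config(reads=10)
        names = [s for s, _, _ in cfg.samples()]
        cfg.barcode_map = {n: "AAAAA" for n in names}
        with pytest.raises(ConfigurationError, match="barcode"):
            simulate_small_rna_run(cfg, reference, tmp_path)


class TestReference:
    def test_same_seed_byte_identical_outputs(self, base_cfg, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_reference(simulate_reference(base_cfg), d1)
        p2 = write_reference(simulate_reference(base_cfg), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_published_layout_parameters_reproduced(self, base_cfg, reference):
        """The emitted virus carries the declared spans: 16-nt 5' UTR, 89-nt
        spacer, 106-nt 3' UTR, ORFs in frames 2 and 1."""
        from vsrna.discovery import annotate_virus
        layout = annotate_virus(reference.virus)
        assert layout.genome_length == base_cfg.virus_length == 2923
        assert layout.five_prime_utr_nt == 16
        assert layout.spacer_nt == 89
        assert layout.three_prime_utr_nt == 106
        assert [o.frame for o in layout.orfs] == [2, 1]

    def test_orfs_are_well_formed(self, base_cfg, reference):
        virus = reference.virus
        for start, end in (base_cfg.orf1_span, base_cfg.orf2_span):
            orf = virus[start - 1:end]
            assert orf.startswith("ATG")
            assert orf[-3:] in ("TAA", "TAG", "TGA")
            codons = [orf[i:i + 3] for i in range(3, len(orf) - 3, 3)]
            assert not any(c in ("TAA", "TAG", "TGA") for c in codons)

    def test_slippery_heptamer_abuts_orf1_stop(self, base_cfg, reference):
        # heptamer's last base sits immediately 5' of the ORF1 stop codon
        end = base_cfg.orf1_span[1]
        assert reference.virus[end - 10:end - 3] == "GGATTTT"
        assert reference.virus[end - 3:end] in ("TAA", "TAG", "TGA")

    def test_adapter_absent_from_both_senses(self, base_cfg, reference):
        from vsrna.align import revcomp
        for seq in reference.expanded.values():
            assert base_cfg.adapter not in seq
            assert base_cfg.adapter not in revcomp(seq)


class TestSmallRnaRun:
    def test_zero_reads_gives_valid_empty_outputs(self, reference, tmp_path):
        cfg = two_genotype_config(reads=0)
        run = simulate_small_rna_run(cfg, reference, tmp_path)
        assert run.fastq_path.read_text() == ""
        assert run.truth.empty
        assert len(run.sample_sheet) == 4

    def test_same_seed_identical_fastq(self, base_cfg, reference, tmp_path):
        r1 = simulate_small_rna_run(base_cfg, reference, tmp_path / "a")
        r2 = simulate_small_rna_run(base_cfg, reference, tmp_path / "b")
        assert r1.fastq_path.read_bytes() == r2.fastq_path.read_bytes()

    def test_child_streams_stable_under_added_genotype(self, reference, tmp_path):
        """Adding a genotype must not change any existing sample's reads."""
        cfg1 = two_genotype_config(reads=500)
        cfg2 = two_genotype_config(reads=500)
        cfg2.genotypes = cfg2.genotypes + [
            g for g in default_genotypes(n_replicates=1) if g.name == "ago1"]
        r1 = simulate_small_rna_run(cfg1, reference, tmp_path / "a")
        r2 = simulate_small_rna_run(cfg2, reference, tmp_path / "b")
        t1 = r1.truth.query("sample == 'control_r1'").reset_index(drop=True)
        t2 = r2.truth.query("sample == 'control_r1'").reset_index(drop=True)
        assert t1.equals(t2)

    def test_truth_counts_within_multinomial_error(self, base_cfg, srna_run):
        n = base_cfg.reads_per_library
        for sample, profile, _ in base_cfg.samples():
            sub = srna_run.truth.query("sample == @sample")
            assert len(sub) == n
            p = profile.viral_fraction_srna
            n_viral = (sub["category"] == "viral").sum()
            assert abs(n_viral - n * p) <= 4 * np.sqrt(n * p * (1 - p))

    def test_five_prime_law_recovered_from_truth(self, reference, tmp_path):
        """With 1e5 reads the truth-table 5'U share of true siRNAs sits
        within 3 binomial SE of the configured 0.75."""
        cfg = two_genotype_config(seed=21, reads=100_000)
        cfg.genotypes = [g for g in cfg.genotypes if g.name == "control"]
        cfg.genotypes[0].n_replicates = 1
        run = simulate_small_rna_run(cfg, reference, tmp_path)
        sirna = run.truth.query("origin == 'sirna'")
        p_hat = (sirna["first_base"] == "T").mean()
        se = np.sqrt(0.75 * 0.25 / len(sirna))
        assert abs(p_hat - 0.75) < 3 * se

    def test_configured_pmfs_pass_chi_square_across_seeds(self, reference, tmp_path):
        """Goodness of fit of the size law over 20 seeds: reject at most
        once at alpha=0.01 (the generator draws exactly the configured PMF)."""
        rejections = 0
        for seed in range(20):
            cfg = two_genotype_config(seed=100 + seed, reads=20_000)
            cfg.genotypes = [g for g in cfg.genotypes if g.name == "control"]
            cfg.genotypes[0].n_replicates = 1
            run = simulate_small_rna_run(cfg, reference, tmp_path / str(seed))
            sirna = run.truth.query("origin == 'sirna'")
            observed = sirna["length"].value_counts().reindex(SIZES, fill_value=0)
            pmf = cfg.genotypes[0].size_pmf
            expected = np.array([pmf[s] for s in SIZES]) * len(sirna)
            _, p = sps.chisquare(observed.to_numpy(), expected)
            rejections += p < 0.01
        assert rejections <= 1

    def test_expected_observed_profile_mixture(self, reference):
        profile = GenotypeProfile(name="x", degradation_fraction=0.5,
                                  sense_fraction=0.6)
        expected = expected_observed_profile(profile, reference.virus)
        assert expected["sense_fraction"] == pytest.approx(0.8)
        assert sum(expected["five_prime"].values()) == pytest.approx(1.0)
        assert sum(expected["size_pmf"].values()) == pytest.approx(1.0)


class TestRnaSeqRun:
    def test_zero_antisense_fraction(self, reference, tmp_path):
        cfg = two_genotype_config(reads=100)
        for g in cfg.genotypes:
            g.rnaseq_antisense_fraction = 0.0
        run = simulate_rnaseq_run(cfg, reference, tmp_path)
        viral = run.truth.query("origin == 'viral'")
        assert (viral["strand"] == "+").all()

    def test_same_seed_identical_fastq(self, base_cfg, reference, tmp_path):
        r1 = simulate_rnaseq_run(base_cfg, reference, tmp_path / "a")
        r2 = simulate_rnaseq_run(base_cfg, reference, tmp_path / "b")
        for sample in r1.fastq_paths:
            assert r1.fastq_paths[sample].read_bytes() == \
                r2.fastq_paths[sample].read_bytes()

    def test_read_length_exceeding_contig_rejected(self, reference, tmp_path):
        cfg = two_genotype_config()
        cfg.rnaseq_read_length = 5000
        with pytest.raises(ConfigurationError, match="read_length"):
            simulate_rnaseq_run(cfg, reference, tmp_path)
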