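"""Viral small-RNA statistics: scaling, distributions, densities, IP."""

from collections import Counter

import numpy as np
import pytest

from vsrna.align import Hit
from vsrna.errors import ConfigurationError
from vsrna.profiling import (five_prime_distribution, ip_enrichment,
                             per_nt_density, rpm, size_strand_distribution,
                             sr_to_rnaseq_ratio, strand_ratio)


class TestRpm:
    @pytest.mark.parametrize("count,total,expected", [
        (500, 1_000_000, 500.0),
        (0, 12345, 0.0),
        (123, 456_789, 123 / 456_789 * 1e6),  # 269.2704...
    ])
    def test_values(self, count, total, expected):
        assert rpm(count, total) == pytest.approx(expected, rel=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ConfigurationError):
            rpm(1, 0)

    def test_scale_invariance(self):
        assert rpm(2 * 37, 2 * 1234) == pytest.approx(rpm(37, 1234))


class TestStrandRatio:
    def test_printed_control_value(self):
        assert strand_ratio(148, 100) == pytest.approx(1.48)

    def test_zero_antisense_is_undefined_not_infinite(self):
        assert strand_ratio(10, 0) is None

    def test_binomial_sampling(self, rng):
        n = 200_000
        sense = int(rng.binomial(n, 0.9))
        ratio = strand_ratio(sense, n - sense)
        se = 3 * np.sqrt(0.9 * 0.1 / n)  # on the fraction scale
        assert 0.9 - se < sense / n < 0.9 + se
        assert ratio == pytest.approx(9.0, rel=0.05)


class TestSizeDistribution:
    def test_percentages(self):
        table, pooled = size_strand_distribution(
            Counter({21: 4, 24: 1}), Counter())
        assert table.loc[21, "sense"] == pytest.approx(80.0)
        assert table.loc[24, "sense"] == pytest.approx(20.0)
        assert pooled == 0

    def test_empty_strand_reported_empty(self):
        table, _ = size_strand_distribution(Counter({21: 3}), Counter())
        assert table["antisense"].isna().all()
        assert table["sense"].sum() == pytest.approx(100.0)

    def test_out_of_range_sizes_pooled_into_edges(self):
        table, pooled = size_strand_distribution(
            Counter({17: 1, 21: 2, 35: 1}), Counter())
        assert pooled == 2
        assert table.loc[18, "sense"] == pytest.approx(25.0)
        assert table.loc[30, "sense"] == pytest.approx(25.0)

    def test_dcl_loss_depletes_21nt_antisense(self, rng):
        """A DCL-loss profile loses the 21-nt antisense peak of the control."""
        from vsrna.synthetic import CONTROL_SIZE_PMF, DCL_LOSS_SIZE_PMF, SIZES
        draws = {}
        for name, pmf in (("control", CONTROL_SIZE_PMF), ("dcl1", DCL_LOSS_SIZE_PMF)):
            sizes = rng.choice(SIZES, p=[pmf[s] for s in SIZES], size=5000)
            table, _ = size_strand_distribution(Counter(), Counter(sizes.tolist()))
            draws[name] = table["antisense"]
        assert draws["dcl1"][21] < draws["control"][21] / 2
        assert draws["dcl1"].loc[23:].sum() > draws["control"].loc[23:].sum()


class TestFivePrime:
    def test_t_reported_as_u(self):
        dist = five_prime_distribution(Counter({"T": 3, "A": 1}))
        assert dist == {"A": 25.0, "C": 0.0, "G": 0.0, "U": 75.0}

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError, match="no viral reads"):
            five_prime_distribution(Counter())


class TestSrToRnaseq:
    def test_printed_arithmetic_instance(self):
        # 46.66 sRNA RPM over 2.0 RNA-seq RPM -> 23.33
        ratios, mean = sr_to_rnaseq_ratio([46.66], 2.0)
        assert ratios[0] == pytest.approx(23.33)
        assert mean == pytest.approx(23.33)

    def test_zero_numerator(self):
        assert sr_to_rnaseq_ratio([0.0], 5.0)[0] == [0.0]

    def test_zero_rnaseq_mean_undefined(self):
        assert sr_to_rnaseq_ratio([10.0], 0.0) is None


class TestPerNtDensity:
    def test_single_read_footprint(self):
        hits = [(Hit("virus", 99, "+", 21), 1)]  # 1-based 100..120
        dens = per_nt_density(hits, "virus", 500, "+", total_reads=1_000_000)
        assert dens[99:120].tolist() == [1.0] * 21
        assert dens.sum() == pytest.approx(21.0)

    def test_linearity_in_multiplicity(self):
        hits1 = [(Hit("virus", 10, "+", 20), 1)]
        hits2 = [(Hit("virus", 10, "+", 20), 2)]
        d1 = per_nt_density(hits1, "virus", 100, "+", 1000)
        d2 = per_nt_density(hits2, "virus", 100, "+", 1000)
        assert np.allclose(d2, 2 * d1)

    def test_mass_conservation(self, rng):
        hits = [(Hit("virus", int(p), "+", int(l)), 1)
                for p, l in zip(rng.integers(0, 400, 50), rng.integers(18, 31, 50))]
        dens = per_nt_density(hits, "virus", 500, "+", total_reads=1000)
        total_nt = sum(h.length for h, _ in hits)
        assert dens.sum() == pytest.approx(total_nt / 1000 * 1e6)

    def test_normalizer_divides_every_position(self):
        hits = [(Hit("virus", 0, "+", 20), 1)]
        raw = per_nt_density(hits, "virus", 100, "+", 1000)
        norm = per_nt_density(hits, "virus", 100, "+", 1000, normalizer=4.0)
        assert np.allclose(norm, raw / 4.0)
        with pytest.raises(ConfigurationError):
            per_nt_density(hits, "virus", 100, "+", 1000, normalizer=0.0)

    def test_hotspot_recovery(self, tmp_path):
        """Hotspot weights concentrating half the siRNA starts on one window
        reappear as a density peak holding roughly that share of mass."""
        from vsrna.pipeline import analyze_small_rna
        from vsrna.synthetic import (GenotypeProfile, SimConfig,
                                     simulate_reference, simulate_small_rna_run)
        weights = np.ones(2923)
        weights[500:521] = (2923 - 21) / 21.0  # ~half the total weight
        profile = GenotypeProfile(name="hot", n_replicates=1,
                                  viral_fraction_srna=0.5,
                                  hotspot_weights={"+": weights, "-": weights})
        cfg = SimConfig(seed=5, reads_per_library=20_000, genotypes=[profile])
        ref = simulate_reference(cfg)
        run = simulate_small_rna_run(cfg, ref, tmp_path)
        ana = analyze_small_rna(run.fastq_path, run.barcodes, ref.expanded,
                                ref.features)
        dens = ana.profiles["hot_r1"].per_nt_sense + \
            ana.profiles["hot_r1"].per_nt_antisense
        # reads *start* in the window; mass extends one read length past it
        peak = dens[500:521 + 30].sum() / dens.sum()
        assert 0.35 < peak < 0.65


class TestIpEnrichment:
    def test_identical_samples_correlate_perfectly(self):
        counts = Counter({"ACGT" * 5: 10, "TTTT" * 5: 3, "GGCC" * 5: 7})
        result = ip_enrichment(counts, counts)
        assert result.pearson_r == pytest.approx(1.0)
        assert result.n_sequences == 3

    def test_independent_samples_near_zero(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(2000)]
        a = Counter({s: int(x) for s, x in zip(seqs, rng.poisson(5, 2000))})
        b = Counter({s: int(x) for s, x in zip(seqs, rng.poisson(5, 2000))})
        result = ip_enrichment(a, b)
        assert abs(result.pearson_r) < 3 / np.sqrt(2000)

    def test_too_few_shared_sequences_undefined(self):
        result = ip_enrichment(Counter({"A" * 20: 5}), Counter({"C" * 20: 2}))
        assert result.pearson_r is None

    def test_outer_join_zero_fills(self):
        result = ip_enrichment(Counter({"A" * 20: 5}), Counter({"C" * 20: 2}))
        table = result.table.set_index("sequence")
        assert table.loc["A" * 20, "ip"] == 0
        assert table.loc["C" * 20, "input"] == 0

    def test_ip_retains_5pU_reads(self, tmp_path):
        """An AGO-IP drawn with near-exclusive 5'U retention shows ~99% 5'U
        viral reads, far above its input fraction."""
        from vsrna.pipeline import analyze_small_rna
        from vsrna.synthetic import (SimConfig, ip_experiment_genotypes,
                                     simulate_reference, simulate_small_rna_run)
        cfg = SimConfig(seed=9, reads_per_library=20_000,
                        genotypes=ip_experiment_genotypes(n_replicates=1))
        ref = simulate_reference(cfg)
        run = simulate_small_rna_run(cfg, ref, tmp_path)
        ana = analyze_small_rna(run.fastq_path, run.barcodes, ref.expanded,
                                ref.features)
        ip = ana.profiles["ago1ip_r1"].five_prime["U"]
        inp = ana.profiles["ago1ip_input_r1"].five_prime["U"]
        assert ip > 97.0
        assert inp < 80.0
        result = ip_enrichment(ana.viral_unique["ago1ip_input_r1"],
                               ana.viral_unique["ago1ip_r1"],
                               input_viral_rpm=ana.profiles["ago1ip_input_r1"].viral_rpm,
                               ip_viral_rpm=ana.profiles["ago1ip_r1"].viral_rpm)
        assert result.viral_rpm_difference > 0  # viral siRNA enriched in the IP
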