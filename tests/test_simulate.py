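"""Generator ground truth: site placement, backcross genetics, observation,
and NB count moments."""

import numpy as np
import pandas as pd
import pytest

from introscan import io as iio
from introscan import simulate as sim
from introscan.simulate import (
    DONOR,
    RECIPIENT,
    BreedingModel,
    CountSimSpec,
    GenomeMosaic,
    GenomeSpec,
    ObservationModel,
    flanking_lengths_cM,
    observe_variants,
    simulate_backcross,
    simulate_backcross_chrom_cM,
    simulate_counts,
    simulate_parental_genomes,
)


class TestParentalGenomes:
    def test_zero_density_gives_empty_truth_sets(self):
        spec = GenomeSpec(chromosomes=(("chr1", 5_000_000),), snp_density=0.0, seed=1)
        parents = simulate_parental_genomes(spec)
        assert len(parents.sites) == 0
        assert len(parents.gene_models) > 0

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="length"):
            GenomeSpec(chromosomes=(("chr1", 0),))

    def test_seed_reproducibility_is_byte_identical(self, tmp_path):
        spec = GenomeSpec(chromosomes=(("chr1", 8_000_000),), snp_density=20, seed=9)
        a = simulate_parental_genomes(spec)
        b = simulate_parental_genomes(spec)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        assert [g.coding_sequence for g in a.gene_models] == [
            g.coding_sequence for g in b.gene_models
        ]
        pa = iio.write_gff(a.gene_models, tmp_path / "a.gff3")
        pb = iio.write_gff(b.gene_models, tmp_path / "b.gff3")
        assert pa.read_bytes() == pb.read_bytes()

    def test_site_count_within_poisson_error(self):
        # density 15/Mbp on a 100-Mbp chromosome: expect 1500 +/- 3*sqrt(1500)
        spec = GenomeSpec(chromosomes=(("chr1", 100_000_000),), snp_density=15, seed=2)
        parents = simulate_parental_genomes(spec)
        count = sum(1 for _ in parents.sites.itertuples())  # brute-force tally
        assert abs(count - 1500) <= 3 * np.sqrt(1500)

    def test_sites_lie_inside_cds_and_record_true_ref(self, small_parents):
        by_chrom = {}
        for g in small_parents.gene_models:
            by_chrom.setdefault(g.chrom, []).append(g)
        comp = str.maketrans("ACGT", "TGCA")
        for row in small_parents.sites.sample(200, random_state=0).itertuples():
            hits = [
                g
                for g in by_chrom[row.chrom]
                if any(s <= row.pos <= e for s, e in g.cds_intervals)
            ]
            assert len(hits) == 1
            g = hits[0]
            base = g.coding_sequence[g.genomic_to_cds(row.pos) - 1]
            expected = base if g.strand == "+" else base.translate(comp)
            assert row.ref == expected
            assert row.alt != row.ref
            # exactly one parent deviates from the reference
            assert {row.donor_allele, row.recipient_allele} == {row.ref, row.alt}


class _NoCrossoverRng:
    """Stub generator: no crossovers ever occur."""

    def poisson(self, lam):
        return 0

    def uniform(self, lo, hi, size=None):
        return np.zeros(size or 0)

    def integers(self, *args, **kwargs):
        return 0


class TestBackcross:
    def test_zero_crossovers_keeps_whole_chromosome_donor(self):
        hap = simulate_backcross_chrom_cM(145.0, [50.0], 8, _NoCrossoverRng())
        assert hap == [(0.0, 145.0, DONOR)]

    def test_marker_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            BreedingModel(
                chrom_lengths_bp=(("chr1", 1_000_000),),
                selected_markers=(("chr1", (2_000_000,)),),
            )

    def test_mosaic_tiles_after_breeding(self, rng):
        model = BreedingModel(
            n_backcrosses=4,
            chrom_lengths_bp=(("chr1", 60_000_000), ("chr2", 40_000_000)),
            selected_markers=(("chr1", (30_000_000,)),),
        )
        for _ in range(20):
            mosaic = simulate_backcross(model, rng)
            mosaic.validate()  # tiling invariant
            assert mosaic.origin_at("chr1", 30_000_000) == DONOR

    def test_mean_flank_matches_independent_oracle_at_n4(self):
        # implementation: full gamete bookkeeping with marker selection
        rng = np.random.default_rng(21)
        n, reps = 4, 4000
        flanks = []
        for _ in range(reps):
            hap = simulate_backcross_chrom_cM(400.0, [200.0], n, rng)
            l, r = flanking_lengths_cM(hap, 200.0)
            flanks.extend([l, r])
        observed = np.mean(flanks)
        # independent oracle, different RNG stream: the one-sided flank is
        # the minimum over N meioses of the Exp(100 cM) distance from the
        # marker to the first crossover, truncated at the chromosome arm
        orng = np.random.default_rng(987654321)
        oracle = np.minimum(
            orng.exponential(100.0, size=(50_000, n)).min(axis=1), 200.0
        ).mean()
        assert oracle == pytest.approx(100.0 / n, rel=0.05)
        sem = np.std(flanks) / np.sqrt(len(flanks))
        assert abs(observed - oracle) < 4 * sem + 0.5

    @pytest.mark.parametrize("n,reps", [(2, 1200), (4, 1200), (8, 2500)])
    def test_unselected_chromosome_donor_fraction_halves_per_generation(self, n, reps):
        rng = np.random.default_rng(100 + n)
        fracs = np.empty(reps)
        for i in range(reps):
            hap = simulate_backcross_chrom_cM(100.0, [], n, rng)
            fracs[i] = sum(e - s for s, e, o in hap if o == DONOR) / 100.0
        expected = 0.5**n
        sem = fracs.std() / np.sqrt(reps)
        assert abs(fracs.mean() - expected) < 4 * sem


class TestObserveVariants:
    def test_full_dropout_gives_empty_vcf_body(self, small_parents):
        obs = ObservationModel(coverage_dropout=1.0)
        table, covered = observe_variants(None, small_parents.sites, obs, DONOR, 5)
        assert len(table) == 0 and len(covered) == 0

    def test_noise_free_observation_matches_mosaic_exactly(self, small_parents):
        obs = ObservationModel(coverage_dropout=0.0, error_rate=0.0)
        mosaic = GenomeMosaic.from_segments(
            {"chr1": 20_000_000}, {"chr1": [(5_000_000, 12_000_000)]}
        )
        table, covered = observe_variants(mosaic, small_parents.sites, obs, "cg", 5)
        emitted = {(r.chrom, r.pos): r.alt for r in table.variants.itertuples()}
        covered_set = set(zip(covered.chrom, covered.pos))
        for row in small_parents.sites.itertuples():  # position-wise brute force
            origin = mosaic.origin_at(row.chrom, row.pos)
            allele = row.donor_allele if origin == DONOR else row.recipient_allele
            if allele == row.ref:
                assert (row.chrom, row.pos) in covered_set
            else:
                assert emitted[(row.chrom, row.pos)] == allele

    def test_same_seed_writes_identical_file(self, small_parents, tmp_path):
        obs = ObservationModel()
        t1, _ = observe_variants(None, small_parents.sites, obs, DONOR, 77)
        t2, _ = observe_variants(None, small_parents.sites, obs, DONOR, 77)
        p1 = iio.write_vcf(t1, tmp_path / "1.vcf", seed=77)
        p2 = iio.write_vcf(t2, tmp_path / "2.vcf", seed=77)
        assert p1.read_bytes() == p2.read_bytes()


class TestSimulateCounts:
    def test_zero_de_fraction_gives_empty_truth(self):
        m, truth = simulate_counts(CountSimSpec(n_genes=100, de_fraction=0.0, seed=1))
        assert not truth.is_de.any()

    def test_same_seed_gives_identical_matrix(self):
        spec = CountSimSpec(n_genes=50, seed=11)
        m1, _ = simulate_counts(spec)
        m2, _ = simulate_counts(spec)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_moments_match_nb_parameterisation(self):
        # var = mu + alpha * mu^2, checked on 1000 samples per group
        alpha = 0.1
        spec = CountSimSpec(
            n_genes=30,
            n_samples_per_group=500,
            nb_mean_range=(50, 500),
            nb_dispersion=alpha,
            de_fraction=0.0,
            seed=8,
        )
        m, _ = simulate_counts(spec)
        k = m.counts.to_numpy(float)
        mu = k.mean(axis=1)
        expected_var = mu + alpha * mu**2
        ratio = k.var(axis=1, ddof=1) / expected_var
        assert np.all(np.abs(ratio - 1) < 0.35)
        assert abs(ratio.mean() - 1) < 0.1

    def test_de_genes_shift_group2_mean(self):
        spec = CountSimSpec(
            n_genes=400,
            n_samples_per_group=200,
            nb_mean_range=(100, 100),
            de_fraction=0.25,
            de_log2fc_values=(2.0,),
            seed=3,
        )
        m, truth = simulate_counts(spec)
        k = m.counts
        g2 = [c for c in k.columns if c.startswith("B")]
        g1 = [c for c in k.columns if c.startswith("A")]
        de = truth[truth.is_de].gene_id
        lfc = np.log2(k.loc[de, g2].mean(axis=1) / k.loc[de, g1].mean(axis=1))
        assert lfc.mean() == pytest.approx(2.0, abs=0.1)


class TestGenomeMosaic:
    def test_from_segments_tiles_and_alternates(self):
        mosaic = GenomeMosaic.from_segments(
            {"chr1": 100}, {"chr1": [(10, 20), (30, 40)]}
        )
        assert mosaic.intervals["chr1"] == [
            (0, 10, RECIPIENT),
            (10, 20, DONOR),
            (20, 30, RECIPIENT),
            (30, 40, DONOR),
            (40, 100, RECIPIENT),
        ]

    def test_gap_or_overlap_rejected(self):
        with pytest.raises(ValueError):
            GenomeMosaic(intervals={"chr1": [(0, 10, DONOR), (12, 20, RECIPIENT)]})
        with pytest.raises(ValueError):
            GenomeMosaic(intervals={"chr1": [(0, 10, DONOR), (10, 20, DONOR)]})


class TestFixture:
    def test_fixture_write_is_verbatim_copy(self, tmp_path):
        path = sim.write_candidate_snp_fixture(tmp_path / "t.tsv")
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 22
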