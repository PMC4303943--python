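"""Strain-of-origin classification against brute-force oracles and truth."""

import numpy as np
import pandas as pd
import pytest

from introscan import classify as cl
from introscan import simulate as sim
from introscan.classify import (
    DONOR_INFORMATIVE,
    RECIPIENT_INFORMATIVE,
    UNINFORMATIVE,
    candidate_snp_filter,
    classify_congenic_origin,
    strain_specific_sites,
)
from introscan.io import StrainVariantTable


def _table(rows, strain="s"):
    return StrainVariantTable(
        strain=strain,
        variants=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"]),
    )


def _random_tables(rng, n_sites=200):
    """Two variant tables over a shared site pool with random membership."""
    donor_rows, recipient_rows, truth = [], [], {}
    positions = rng.choice(100_000, size=n_sites, replace=False) + 1
    for pos in positions:
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        in_d, in_r = rng.random() < 0.6, rng.random() < 0.6
        if in_d:
            donor_rows.append(("chr1", int(pos), ref, alt, 150.0))
        if in_r:
            recipient_rows.append(("chr1", int(pos), ref, alt, 150.0))
        truth[("chr1", int(pos), alt)] = (in_d, in_r)
    return _table(donor_rows, "d"), _table(recipient_rows, "r"), truth


class TestStrainSpecificSites:
    def test_alt_in_donor_only_is_donor_specific(self):
        d = _table([("chr1", 10, "A", "G", 150.0)])
        r = _table([])
        part = strain_specific_sites(d, r)
        assert len(part.donor_specific) == 1
        assert len(part.recipient_specific) == 0

    def test_shared_alt_excluded_from_both(self):
        row = [("chr1", 10, "A", "G", 150.0)]
        part = strain_specific_sites(_table(row), _table(row))
        assert len(part.donor_specific) == 0
        assert len(part.recipient_specific) == 0
        assert len(part.shared) == 1

    def test_conflicting_ref_discarded(self):
        d = _table([("chr1", 10, "A", "G", 150.0)])
        r = _table([("chr1", 10, "C", "G", 150.0)])
        part = strain_specific_sites(d, r)
        assert part.n_discarded == 1
        assert len(part.donor_specific) == len(part.recipient_specific) == 0

    def test_partition_matches_bruteforce_set_algebra(self, rng):
        d, r, truth = _random_tables(rng)
        part = strain_specific_sites(d, r)
        expect_d = {k for k, (i, j) in truth.items() if i and not j}
        expect_r = {k for k, (i, j) in truth.items() if j and not i}
        expect_s = {k for k, (i, j) in truth.items() if i and j}
        key = lambda df: set(zip(df.chrom, df.pos, df.alt))
        assert key(part.donor_specific) == expect_d
        assert key(part.recipient_specific) == expect_r
        assert key(part.shared) == expect_s

    def test_swapping_tables_swaps_labels(self, rng):
        d, r, _ = _random_tables(rng)
        a = strain_specific_sites(d, r)
        b = strain_specific_sites(r, d)
        pd.testing.assert_frame_equal(a.donor_specific, b.recipient_specific)
        pd.testing.assert_frame_equal(a.recipient_specific, b.donor_specific)


class TestClassifyCongenicOrigin:
    def _partition(self):
        d = _table([("chr1", 10, "A", "G", 150.0), ("chr1", 30, "C", "T", 150.0)])
        r = _table([("chr1", 20, "G", "A", 150.0)])
        return strain_specific_sites(d, r)

    def test_matching_alt_is_donor_informative(self):
        part = self._partition()
        cong = _table([("chr1", 10, "A", "G", 150.0)])
        calls = classify_congenic_origin(cong, part)
        got = calls.set_index("pos").origin
        assert got[10] == DONOR_INFORMATIVE

    def test_absence_without_coverage_is_uninformative(self):
        part = self._partition()
        calls = classify_congenic_origin(_table([]), part, covered_ref=None)
        assert (calls.origin == UNINFORMATIVE).all()

    def test_covered_reference_at_donor_site_is_recipient_informative(self):
        part = self._partition()
        covered = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        calls = classify_congenic_origin(_table([]), part, covered)
        got = calls.set_index("pos").origin
        assert got[10] == RECIPIENT_INFORMATIVE
        assert got[30] == UNINFORMATIVE

    def test_recipient_specific_site_logic_is_symmetric(self):
        part = self._partition()
        cong = _table([("chr1", 20, "G", "A", 150.0)])
        covered = pd.DataFrame({"chrom": ["chr1"], "pos": [30]})
        calls = classify_congenic_origin(cong, part, covered)
        got = calls.set_index("pos").origin
        assert got[20] == RECIPIENT_INFORMATIVE  # carries recipient alt
        assert got[30] == RECIPIENT_INFORMATIVE  # covered ref at donor site

    def test_every_site_gets_exactly_one_label(self, rng):
        d, r, _ = _random_tables(rng)
        part = strain_specific_sites(d, r)
        calls = classify_congenic_origin(_table([]), part)
        n_sites = len(part.donor_specific) + len(part.recipient_specific)
        assert len(calls) == n_sites
        assert calls.origin.isin(
            [DONOR_INFORMATIVE, RECIPIENT_INFORMATIVE, UNINFORMATIVE]
        ).all()


class TestAgainstSimulationTruth:
    def _run(self, parents, obs, seed):
        mosaic = sim.GenomeMosaic.from_segments(
            {"chr1": 20_000_000}, {"chr1": [(4_000_000, 14_000_000)]}
        )
        rng = np.random.default_rng(seed)
        tables, cov = {}, {}
        for strain in (sim.DONOR, sim.RECIPIENT, "congenic"):
            m = mosaic if strain == "congenic" else None
            tables[strain], cov[strain] = sim.observe_variants(
                m, parents.sites, obs, strain, rng
            )
            v = tables[strain].variants
            tables[strain].variants = v[v.qual >= 100].reset_index(drop=True)
        part = strain_specific_sites(tables[sim.DONOR], tables[sim.RECIPIENT])
        calls = classify_congenic_origin(tables["congenic"], part, cov["congenic"])
        return mosaic, calls

    def test_error_free_labels_match_mosaic_truth_everywhere(self, small_parents):
        obs = sim.ObservationModel(coverage_dropout=0.0, error_rate=0.0)
        mosaic, calls = self._run(small_parents, obs, 3)
        informative = calls[calls.origin != UNINFORMATIVE]
        assert len(informative) > 100
        for row in informative.itertuples():
            truth = mosaic.origin_at(row.chrom, row.pos)
            want = DONOR_INFORMATIVE if truth == sim.DONOR else RECIPIENT_INFORMATIVE
            assert row.origin == want

    def test_noisy_misclassification_rate_bounded_by_twice_error_rate(
        self, small_parents
    ):
        obs = sim.ObservationModel()  # defaults: dropout 0.2, error 0.005
        wrong = total = 0
        for seed in range(6):
            mosaic, calls = self._run(small_parents, obs, 100 + seed)
            informative = calls[calls.origin != UNINFORMATIVE]
            for row in informative.itertuples():
                truth = mosaic.origin_at(row.chrom, row.pos)
                want = (
                    DONOR_INFORMATIVE if truth == sim.DONOR else RECIPIENT_INFORMATIVE
                )
                total += 1
                wrong += row.origin != want
        assert total > 1000
        assert wrong / total <= 2 * obs.error_rate


class TestCandidateSnpFilter:
    def test_stated_rule_and_locus_membership(self):
        d = _table([("chr1", 100, "A", "G", 150.0), ("chr1", 900, "C", "T", 150.0)])
        c = _table([("chr1", 100, "A", "G", 150.0), ("chr1", 900, "C", "T", 150.0)])
        r = _table([])
        loci = [("chr1", 0, 500)]
        out = candidate_snp_filter(d, r, c, loci)
        assert list(out.pos) == [100]  # pos 900 outside the locus

    def test_alt_present_in_recipient_excluded(self):
        d = _table([("chr1", 100, "A", "G", 150.0)])
        c = _table([("chr1", 100, "A", "G", 150.0)])
        r = _table([("chr1", 100, "A", "G", 150.0)])
        assert len(candidate_snp_filter(d, r, c, [("chr1", 0, 500)])) == 0

    def test_empty_loci_returns_empty_with_warning(self, caplog):
        d = _table([("chr1", 100, "A", "G", 150.0)])
        with caplog.at_level("WARNING"):
            out = candidate_snp_filter(d, _table([]), d, [])
        assert len(out) == 0

    def test_matches_bruteforce_interval_and_allele_test(self, rng):
        rows_d, rows_r, rows_c = [], [], []
        pool = []
        for pos in rng.choice(50_000, size=500, replace=False) + 1:
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            in_d, in_r, in_c = rng.random(3) < (0.7, 0.3, 0.7)
            rec = ("chr1", int(pos), ref, alt, 150.0)
            if in_d:
                rows_d.append(rec)
            if in_r:
                rows_r.append(rec)
            if in_c:
                rows_c.append(rec)
            pool.append((rec, in_d, in_r, in_c))
        loci = [("chr1", 5_000, 20_000), ("chr1", 30_000, 40_000)]
        out = candidate_snp_filter(
            _table(rows_d), _table(rows_r), _table(rows_c), loci
        )
        expected = sorted(
            rec[1]
            for rec, in_d, in_r, in_c in pool
            if in_d and in_c and not in_r
            and any(s < rec[1] <= e for _, s, e in loci)
        )
        assert list(out.pos) == expected
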