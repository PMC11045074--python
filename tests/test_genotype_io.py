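"""Table IO, allele frequencies, Hardy–Weinberg QC and deduplication."""

import datetime as dt
import math

import numpy as np
import pytest

import kinlod as kl
from kinlod import genotype_io as gio

from .oracles import hand_chi_square


def _records_from_calls(loci, calls_per_sample, **meta):
    names = tuple(l.name for l in loci)
    return [kl.SampleRecord(sample_id=f"S{i:03d}", genotype=kl.Genotype(names, calls))
            for i, calls in enumerate(calls_per_sample)]


class TestLocusModel:
    def test_rejects_bad_frequencies(self):
        with pytest.raises(ValueError):
            kl.LocusModel("L", ("A", "B"), np.array([0.6, 0.6]))
        with pytest.raises(ValueError):
            kl.LocusModel("L", ("A", "B"), np.array([1.0, 0.0]))

    def test_monomorphic_flag(self):
        locus = kl.LocusModel("L", ("A",), np.array([1.0]))
        assert locus.is_monomorphic


class TestGenotypeCanonicalisation:
    def test_allele_order_is_irrelevant(self):
        g1 = kl.Genotype(("L1",), [("B", "A")])
        g2 = kl.Genotype(("L1",), [("A", "B")])
        assert g1 == g2
        assert g1.calls[0] == ("A", "B")


class TestReadWriteRoundTrip:
    @pytest.mark.parametrize("dialect", ["wide", "packed", "genepop"])
    def test_round_trip_preserves_tables(self, tmp_path, dialect, fixture_bundle):
        samples = fixture_bundle.samples[:30]
        config = gio.IOConfig(dialect=dialect)
        gpath, mpath = tmp_path / "g.csv", tmp_path / "m.csv"
        gio.write_samples(samples, gpath, mpath, config)
        back = gio.read_samples(gpath, mpath, config)
        assert len(back) == len(samples)
        by_id = {s.sample_id: s for s in back}
        for s in samples:
            r = by_id[s.sample_id]
            assert r.genotype == s.genotype
            assert (r.sex, r.mtdna_haplotype, r.date, r.vessel) == \
                (s.sex, s.mtdna_haplotype, s.date, s.vessel)
            assert r.field_obs == s.field_obs
        # second round trip is byte-identical (canonical dialect)
        g2, m2 = tmp_path / "g2.csv", tmp_path / "m2.csv"
        gio.write_samples(back, g2, m2, config)
        assert g2.read_bytes() == gpath.read_bytes()
        assert m2.read_bytes() == mpath.read_bytes()

    def test_row_count_preserved(self, tmp_path, fixture_bundle):
        gpath, mpath = tmp_path / "g.csv", tmp_path / "m.csv"
        gio.write_samples(fixture_bundle.samples, gpath, mpath)
        assert len(gio.read_samples(gpath, mpath)) == 183

    def test_missing_code_gives_missing_locus(self, tmp_path):
        (tmp_path / "g.csv").write_text(
            "sample_id,L1_1,L1_2,L2_1,L2_2\nA,0,0,100,104\n")
        (tmp_path / "m.csv").write_text("sample_id\nA\n")
        rec = gio.read_samples(tmp_path / "g.csv", tmp_path / "m.csv")[0]
        assert rec.genotype.calls[0] is None
        assert rec.genotype.calls[1] == (100, 104)
        assert rec.genotype.n_typed == 1

    def test_duplicate_sample_id_is_hard_error(self, tmp_path):
        (tmp_path / "g.csv").write_text("sample_id,L1_1,L1_2\nA,1,2\nA,1,2\n")
        (tmp_path / "m.csv").write_text("sample_id\nA\n")
        with pytest.raises(ValueError, match="duplicate"):
            gio.read_samples(tmp_path / "g.csv", tmp_path / "m.csv")

    def test_id_mismatch_lists_offenders(self, tmp_path):
        (tmp_path / "g.csv").write_text("sample_id,L1_1,L1_2\nA,1,2\nB,1,2\n")
        (tmp_path / "m.csv").write_text("sample_id\nA\nC\n")
        with pytest.raises(ValueError, match="B.*C|C.*B"):
            gio.read_samples(tmp_path / "g.csv", tmp_path / "m.csv")

    def test_single_sample_missing_two_loci(self, tmp_path, fixture_bundle):
        """One partially typed sample leaves every other sample fully typed."""
        samples = list(fixture_bundle.samples)
        target = samples[0]
        calls = list(target.genotype.calls)
        calls[2] = calls[7] = None
        samples[0] = gio.SampleRecord(
            sample_id=target.sample_id,
            genotype=kl.Genotype(target.genotype.loci, calls),
            sex=target.sex, date=target.date)
        gpath, mpath = tmp_path / "g.csv", tmp_path / "m.csv"
        gio.write_samples(samples, gpath, mpath)
        back = gio.read_samples(gpath, mpath)
        typed = sorted(s.genotype.n_typed for s in back)
        assert typed[0] == 12
        assert all(t == 14 for t in typed[1:])


class TestAlleleFrequencies:
    def test_counting_two_individuals(self):
        loci = [kl.LocusModel("L1", ("A", "B"), np.array([0.5, 0.5]))]
        recs = _records_from_calls(loci, [[("A", "A")], [("A", "B")]])
        model = gio.estimate_allele_freqs(recs)[0]
        assert dict(zip(model.alleles, model.freqs)) == {"A": 0.75, "B": 0.25}

    def test_monomorphic_flagged(self):
        loci = [kl.LocusModel("L1", ("A",), np.array([1.0]))]
        recs = _records_from_calls(loci, [[("A", "A")]] * 5)
        model = gio.estimate_allele_freqs(recs)[0]
        assert model.is_monomorphic and model.freqs[0] == 1.0

    def test_zero_typed_alleles_is_hard_error(self):
        recs = _records_from_calls([kl.LocusModel("L1", ("A",), np.array([1.0]))],
                                   [[None], [None]])
        with pytest.raises(ValueError, match="zero typed"):
            gio.estimate_allele_freqs(recs)

    def test_estimates_within_three_se_of_truth(self):
        """Binomial sampling: n=171 individuals from known (0.6, 0.3, 0.1)."""
        rng = np.random.default_rng(5)
        truth = np.array([0.6, 0.3, 0.1])
        n = 171
        draws = rng.choice(3, size=(n, 2), p=truth)
        names = ("L1",)
        recs = [kl.SampleRecord(sample_id=f"S{i}", genotype=kl.Genotype(
            names, [tuple(sorted((100 + 4 * draws[i, 0], 100 + 4 * draws[i, 1])))]))
            for i in range(n)]
        model = gio.estimate_allele_freqs(recs)[0]
        freqs = {a: f for a, f in zip(model.alleles, model.freqs)}
        for allele, p in zip((100, 104, 108), truth):
            se = math.sqrt(p * (1 - p) / (2 * n))
            assert abs(freqs[allele] - p) < 3 * se

    def test_invariant_to_sample_and_allele_order(self):
        loci = [kl.LocusModel("L1", ("A", "B", "C"), np.array([1 / 3] * 3))]
        recs = _records_from_calls(loci, [[("A", "B")], [("C", "B")], [("A", "A")]])
        flipped = [kl.SampleRecord(sample_id=r.sample_id, genotype=kl.Genotype(
            ("L1",), [tuple(reversed(r.genotype.calls[0]))])) for r in recs]
        a = gio.estimate_allele_freqs(recs)[0]
        b = gio.estimate_allele_freqs(flipped[::-1])[0]
        assert a.alleles == b.alleles
        assert np.allclose(a.freqs, b.freqs)


class TestHWECheck:
    def test_exact_hwe_counts_give_zero_statistic(self):
        loci_names = ("L1",)
        recs = []
        for geno, count in ((("A", "A"), 25), (("A", "B"), 50), (("B", "B"), 25)):
            for i in range(count):
                recs.append(kl.SampleRecord(sample_id=f"{geno}{i}",
                                            genotype=kl.Genotype(loci_names, [geno])))
        locus = gio.estimate_allele_freqs(recs)[0]
        res = gio.hwe_check(recs, locus)
        assert res.testable
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_all_heterozygotes_statistic_fifty(self):
        """n=50 all AB at p=0.5: hand chi-square = 12.5 + 25 + 12.5 = 50."""
        recs = [kl.SampleRecord(sample_id=f"S{i}",
                                genotype=kl.Genotype(("L1",), [("A", "B")]))
                for i in range(50)]
        locus = gio.estimate_allele_freqs(recs)[0]
        res = gio.hwe_check(recs, locus)
        assert hand_chi_square([0, 50, 0], [12.5, 25, 12.5]) == 50.0
        assert res.statistic == pytest.approx(50.0)

    def test_monomorphic_not_testable(self):
        recs = [kl.SampleRecord(sample_id=f"S{i}",
                                genotype=kl.Genotype(("L1",), [("A", "A")]))
                for i in range(10)]
        locus = gio.estimate_allele_freqs(recs)[0]
        res = gio.hwe_check(recs, locus)
        assert not res.testable

    def test_rejection_rate_near_nominal_alpha(self):
        """Type-I error of the chi-square under true HWE sampling."""
        rng = np.random.default_rng(11)
        n, reps, alpha = 120, 500, 0.05
        rejections = 0
        names = ("L1",)
        for _ in range(reps):
            draws = rng.choice(2, size=(n, 2), p=[0.6, 0.4])
            recs = [kl.SampleRecord(sample_id=f"S{i}", genotype=kl.Genotype(
                names, [tuple(sorted(("A" if a == 0 else "B", "A" if b == 0 else "B")))]))
                for i, (a, b) in enumerate(draws)]
            try:
                locus = gio.estimate_allele_freqs(recs)[0]
            except ValueError:
                continue
            res = gio.hwe_check(recs, locus)
            if res.testable and res.pvalue < alpha:
                rejections += 1
        rate = rejections / reps
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 4 * se


class TestDeduplicate:
    def test_fixture_collapses_to_171(self, fixture_run):
        dedup = fixture_run["dedup"]
        assert dedup.n_unique == 171
        kinds = [g.kind for g in dedup.duplicate_groups]
        assert kinds.count("same_place_time_duplicate") == 4
        assert kinds.count("resample") == 8

    def test_merged_groups_equal_planted_groups(self):
        for seed in (2, 3, 4):
            bundle = kl.study_fixture(seed)
            prov = kl.estimate_allele_freqs(bundle.samples)
            ctx = kl.KinshipModelContext(prov, kl.ErrorModel(0.0077))
            dedup = kl.deduplicate(bundle.samples, ctx, n_sim=20000, seed=9)
            merged = {frozenset(g.sample_ids) for g in dedup.duplicate_groups}
            planted = {frozenset((i, i + ".d")) for i in bundle.duplicate_ids} | \
                      {frozenset((i, i + ".r")) for i in bundle.resample_ids}
            assert merged == planted

    def test_no_shared_genotypes_no_merges(self, small_loci):
        samples, _, _ = kl.planted_kin_sample(7, n_individuals=20, n_po=0)
        loci = kl.estimate_allele_freqs(samples)
        ctx = kl.KinshipModelContext(loci, kl.ErrorModel(0.0077))
        dedup = kl.deduplicate(samples, ctx, n_sim=5000, seed=1)
        assert dedup.duplicate_groups == []
        assert dedup.n_unique == len(samples)

    def test_idempotent(self, fixture_run):
        dedup = fixture_run["dedup"]
        again = kl.deduplicate(dedup.unique_individuals, fixture_run["ctx"],
                               n_sim=20000, seed=3)
        assert again.n_unique == dedup.n_unique
        assert again.duplicate_groups == []

    def test_perturbed_duplicate_still_merged(self, fixture_run):
        """A re-typed biopsy with one allele miscalled still matches itself."""
        from kinlod import kinship_model as km
        ctx = fixture_run["ctx"]
        base = fixture_run["dedup"].unique_individuals[0]
        calls = list(base.genotype.calls)
        locus0 = ctx.loci[0]
        other = next(a for a in locus0.alleles if a != calls[0][0])
        calls[0] = (other, calls[0][1])
        twin = gio.SampleRecord(sample_id=base.sample_id + "X",
                                genotype=kl.Genotype(base.genotype.loci, calls),
                                date=base.date, lat=base.lat, lon=base.lon)
        # enumeration-oracle self-LOD of the perturbed pair stays far above
        # the default threshold
        self_lod = sum(
            math.log(kl.observed_pair_prob(c1, c2, ctx, "SELF", locus=k)
                     / kl.observed_pair_prob(c1, c2, ctx, "U", locus=k))
            for k, (c1, c2) in enumerate(zip(base.genotype.calls, twin.genotype.calls)))
        threshold = gio.default_dedup_threshold(ctx, 171 * 170 // 2,
                                                n_sim=20000, seed=5)
        assert self_lod > threshold
        dedup = kl.deduplicate([base, twin] + fixture_run["dedup"].unique_individuals[1:40],
                               ctx, n_sim=20000, seed=5)
        merged = {frozenset(g.sample_ids) for g in dedup.duplicate_groups}
        assert frozenset((base.sample_id, twin.sample_id)) in merged

    def test_retains_earliest_sample(self, small_loci):
        names = tuple(l.name for l in small_loci)
        calls = [(100, 104), (100, 108), (104, 112)]
        a = kl.SampleRecord(sample_id="B", genotype=kl.Genotype(names, calls),
                            date=dt.date(2000, 1, 1))
        b = kl.SampleRecord(sample_id="A", genotype=kl.Genotype(names, calls),
                            date=dt.date(1995, 1, 1))
        filler, _, _ = kl.planted_kin_sample(8, n_individuals=30, n_po=0,
                                             loci=small_loci)
        loci = kl.estimate_allele_freqs([a, b] + filler)
        ctx = kl.KinshipModelContext(loci, kl.ErrorModel(0.0077))
        dedup = kl.deduplicate([a, b] + filler, ctx, threshold=2.0)
        group = next(g for g in dedup.duplicate_groups if "A" in g.sample_ids)
        assert group.retained_id == "A"
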