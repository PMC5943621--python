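"""Synthetic community generator: truth bookkeeping and sampling laws."""

import numpy as np
import pytest
from scipy import stats

from kmersig.io import CASE, CONTROL
from kmersig.kmers import count_kmers, reverse_complement
from kmersig.simulate import (
    SMALL,
    SimConfig,
    load_truth,
    make_community,
    sample_abundances,
    simulate_dataset,
    simulate_reads,
    write_fixture,
)


class TestMakeCommunity:
    def test_degenerate_full_sharing(self):
        truth = make_community(genome_len=5000, shared_fraction=1.0, seed=0)
        assert truth.genome("case_only").sequence == truth.genome("shared_common").sequence
        assert truth.regions["case-specific"] == []

    def test_replaced_intervals_total_and_exactness(self):
        truth = make_community(genome_len=50_000, shared_fraction=0.87, seed=1)
        total = sum(e - s for _, s, e in truth.regions["case-specific"])
        assert total == round(0.13 * 50_000)
        shared = truth.genome("shared_common").sequence
        case = truth.genome("case_only").sequence
        # outside the recorded intervals the two strains are identical ...
        mask = np.zeros(50_000, dtype=bool)
        for _, s, e in truth.regions["case-specific"]:
            mask[s:e] = True
        arr_s = np.frombuffer(shared.encode(), dtype=np.uint8)
        arr_c = np.frombuffer(case.encode(), dtype=np.uint8)
        assert (arr_s[~mask] == arr_c[~mask]).all()
        # ... and inside them they are (almost everywhere) different
        assert (arr_s[mask] != arr_c[mask]).mean() > 0.5

    def test_common_regions_complement_case_specific(self):
        truth = make_community(genome_len=10_000, seed=2)
        covered = np.zeros(10_000, dtype=int)
        for cat in ("case-specific", "common"):
            for _, s, e in truth.regions[cat]:
                covered[s:e] += 1
        assert (covered == 1).all()

    def test_profiles_sum_to_one_and_fold_change_exact(self):
        for fc in (1.0, 2.0, 3.0):
            truth = make_community(genome_len=2000, fold_change=fc, seed=3)
            names = truth.genome_names
            i = names.index("differential")
            for grp in (CASE, CONTROL):
                assert truth.profiles[grp].sum() == pytest.approx(1.0, abs=1e-9)
            ratio = truth.profiles[CONTROL][i] / truth.profiles[CASE][i]
            assert ratio == pytest.approx(fc, rel=1e-9)

    def test_case_only_absent_from_controls(self):
        truth = make_community(genome_len=2000, seed=4)
        i = truth.genome_names.index("case_only")
        assert truth.profiles[CONTROL][i] == 0.0
        assert truth.profiles[CASE][i] > 0.0

    def test_invalid_shared_fraction(self):
        with pytest.raises(ValueError):
            make_community(shared_fraction=0.0)


class TestSampleAbundances:
    def test_zero_noise_limit_returns_central(self):
        truth = make_community(genome_len=2000, seed=5)

        class ZeroNoiseRng(np.random.Generator):
            def normal(self, loc=0.0, scale=1.0, size=None):
                return np.zeros_like(np.asarray(scale, dtype=float))

        rng = ZeroNoiseRng(np.random.PCG64(0))
        a = sample_abundances(truth, CONTROL, rng)
        np.testing.assert_allclose(a, truth.profiles[CONTROL])

    def test_absent_genome_stays_absent(self, rng):
        truth = make_community(genome_len=2000, seed=6)
        i = truth.genome_names.index("case_only")
        for _ in range(20):
            assert sample_abundances(truth, CONTROL, rng)[i] == 0.0

    def test_halfnormal_mean_montecarlo(self):
        """Before renormalization E[a_g] = c_g (1 + sqrt(2/pi))."""
        rng = np.random.default_rng(7)
        truth = make_community(genome_len=2000, seed=7)
        central = truth.profiles[CASE]
        draws = np.array(
            [central + np.abs(rng.normal(0, central)) for _ in range(10_000)]
        )
        expected = central * (1 + np.sqrt(2 / np.pi))
        np.testing.assert_allclose(
            draws.mean(axis=0)[central > 0], expected[central > 0], rtol=0.03
        )

    def test_composition_valid(self, rng):
        truth = make_community(genome_len=2000, seed=8)
        a = sample_abundances(truth, CASE, rng)
        assert a.sum() == pytest.approx(1.0)
        assert (a >= 0).all()


class TestSimulateReads:
    def test_error_free_reads_are_genome_substrings(self, rng):
        truth = make_community(genome_len=2000, seed=9)
        rs = simulate_reads(truth, CASE, n_reads=500, read_len=80, rng=rng)
        for i in range(0, 500, 37):
            g = truth.genomes[rs.provenance["genome_idx"][i]]
            pos = rs.provenance["pos"][i]
            window = g.sequence[pos : pos + 80]
            if rs.provenance["strand"][i]:
                window = reverse_complement(window)
            assert rs.reads[i] == window

    def test_read_count_ratio_follows_abundance(self):
        """Two-genome community, equal lengths, abundances 3:1."""
        rng = np.random.default_rng(10)
        truth = make_community(genome_len=1000, n_background=1, seed=10)
        counts = {"shared_common": 0, "background_1": 0}
        profiles = {
            CONTROL: np.array([0.75, 0.0, 0.0, 0.25]),
            CASE: np.array([0.75, 0.0, 0.0, 0.25]),
        }
        truth.profiles.update(profiles)
        # suppress abundance noise by drawing many reads across samples
        n = 100_000
        rs = simulate_reads(truth, CONTROL, n_reads=n, read_len=50, rng=rng)
        drawn = rs.provenance["abundances"]
        k = (rs.provenance["genome_idx"] == 0).sum()
        p = drawn[0] / (drawn[0] + drawn[3])
        assert stats.binomtest(int(k), n, p).pvalue > 1e-3

    def test_uniform_coverage_single_genome(self):
        rng = np.random.default_rng(11)
        truth = make_community(genome_len=1000, n_background=1, seed=11)
        truth.profiles[CONTROL] = np.array([1.0, 0.0, 0.0, 0.0])
        rs = simulate_reads(truth, CONTROL, n_reads=20_000, read_len=50, rng=rng)
        # chi-square on start-position bins over the valid start range
        pos = rs.provenance["pos"][rs.provenance["genome_idx"] == 0]
        hist, _ = np.histogram(pos, bins=20, range=(0, 951))
        chi2 = ((hist - hist.mean()) ** 2 / hist.mean()).sum()
        assert stats.chi2.sf(chi2, 19) > 1e-4

    def test_substitution_errors_at_rate(self):
        rng = np.random.default_rng(12)
        truth = make_community(genome_len=2000, seed=12)
        rs = simulate_reads(
            truth, CASE, n_reads=2000, read_len=100, err_rate=0.02, rng=rng
        )
        mismatches = 0
        for i in range(500):
            g = truth.genomes[rs.provenance["genome_idx"][i]]
            pos = rs.provenance["pos"][i]
            window = g.sequence[pos : pos + 100]
            if rs.provenance["strand"][i]:
                window = reverse_complement(window)
            mismatches += sum(a != b for a, b in zip(rs.reads[i], window))
        rate = mismatches / (500 * 100)
        assert 0.012 <= rate <= 0.028

    def test_invalid_args(self, rng):
        truth = make_community(genome_len=500, seed=13)
        with pytest.raises(ValueError):
            simulate_reads(truth, CASE, n_reads=0, rng=rng)
        with pytest.raises(ValueError):
            simulate_reads(truth, CASE, n_reads=10, read_len=600, rng=rng)


class TestDatasetAndFixture:
    def test_default_design_shape(self):
        cfg = SimConfig(genome_len=1000, n_reads=200, n_case=3, n_control=2)
        truth, readsets, sheet = simulate_dataset(cfg, seed=1)
        assert len(readsets) == 5
        assert sheet.n_case == 3 and sheet.n_control == 2
        assert all(len(rs.reads) == 200 for rs in readsets)

    def test_reproducible_from_seed(self):
        cfg = SimConfig(genome_len=800, n_reads=100, n_case=2, n_control=2)
        _, rs1, _ = simulate_dataset(cfg, seed=9)
        _, rs2, _ = simulate_dataset(cfg, seed=9)
        assert [r.reads for r in rs1] == [r.reads for r in rs2]

    def test_fixture_roundtrip_counts_and_truth(self, tmp_path):
        cfg = SimConfig(genome_len=600, n_reads=150, n_case=2, n_control=2)
        truth, readsets, sheet = simulate_dataset(cfg, seed=2)
        out = tmp_path / "fix"
        sheet2 = write_fixture(truth, readsets, out)
        assert len(list((out / "samples").glob("*.fa.gz"))) == 4
        # re-reading the written FASTA reproduces identical counts
        from kmersig.io import iter_reads

        rs = readsets[0]
        v_mem = count_kmers(rs.reads, 21, min_count=1, sample_id=rs.sample_id)
        v_disk = count_kmers(
            iter_reads(sheet2.entries[0].paths), 21, min_count=1,
            sample_id=rs.sample_id,
        )
        assert v_mem.counts == v_disk.counts
        # truth and BED round trip
        truth2 = load_truth(out)
        assert truth2.regions == truth.regions
        assert truth2.genome("case_only").sequence == truth.genome("case_only").sequence
        bed = (out / "regions.bed").read_text().splitlines()
        parsed = {}
        for line in bed:
            g, s, e, cat = line.split("\t")
            parsed.setdefault(cat, []).append((g, int(s), int(e)))
        for cat, regs in truth.regions.items():
            assert parsed.get(cat, []) == regs

    def test_existing_outdir_requires_force(self, tmp_path):
        cfg = SimConfig(genome_len=600, n_reads=50, n_case=2, n_control=2)
        truth, readsets, _ = simulate_dataset(cfg, seed=3)
        out = tmp_path / "fix"
        write_fixture(truth, readsets, out)
        with pytest.raises(FileExistsError):
            write_fixture(truth, readsets, out)
        write_fixture(truth, readsets, out, force=True)


class TestGroundTruthRecovery:
    def test_case_specific_kmers_separate_groups(self, small):
        """At >= 20x depth every case-specific k-mer shows up in case
        samples and in no control sample — the logical-track ground truth."""
        k = small.cfg.k
        truth = small.truth
        case_seq = truth.genome("case_only").sequence
        # canonical k-mers strictly inside the replaced blocks
        from kmersig.kmers import canonical

        specific = set()
        for _, s, e in truth.regions["case-specific"]:
            for i in range(s, e - k + 1):
                specific.add(canonical(case_seq[i : i + k]))
        assert specific
        labels = small.sheet.labels
        in_case = np.zeros(len(specific), dtype=int)
        in_ctrl = np.zeros(len(specific), dtype=int)
        for v, l in zip(small.vectors, labels):
            present = np.array([km in v.counts for km in sorted(specific)])
            if l:
                in_case += present
            else:
                in_ctrl += present
        assert (in_ctrl == 0).all()
        assert (in_case >= 1).mean() > 0.99
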