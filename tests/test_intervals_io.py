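"""Interval tracks, masking, recombination-class partition, and file IO."""

import numpy as np
import pytest

from demosfs import (
    HaplotypeDataset,
    IntervalTrack,
    JointSFS,
    SimConfig,
    apply_masks,
    build_joint_sfs,
    partition_by_recomb,
    simulate_dataset,
)
from demosfs.io import (
    read_bed,
    read_haploid_vcf,
    read_recmap,
    read_sfs,
    write_panel,
    write_sfs,
    write_vcf,
)


def _ds(positions, rates=None, contig="chr1"):
    n_sites = len(positions)
    geno = np.tile(np.array([1, 0, 0, 1], dtype=np.int8), (n_sites, 1))
    return HaplotypeDataset(
        samples=["a", "b", "c", "d"],
        populations=np.array(["p1", "p1", "p2", "p2"]),
        genotypes=geno,
        contig=np.array([contig] * n_sites, dtype=object),
        pos=np.array(positions),
        rec_rate=None if rates is None else np.array(rates, dtype=float),
    )


class TestIntervalTrack:
    def test_overlapping_unvalued_intervals_merge(self):
        t = IntervalTrack(
            np.array(["c", "c", "c"], dtype=object),
            np.array([10, 5, 30]),
            np.array([20, 12, 40]),
        )
        assert len(t) == 2
        assert list(t.start) == [5, 30] and list(t.end) == [20, 40]

    def test_overlapping_valued_intervals_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            IntervalTrack(
                np.array(["c", "c"], dtype=object),
                np.array([0, 5]),
                np.array([10, 15]),
                value=np.array([1.0, 2.0]),
            )

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="start must be < end"):
            IntervalTrack(
                np.array(["c"], dtype=object), np.array([5]), np.array([5])
            )


class TestMasking:
    def test_no_masks_is_identity(self):
        ds = _ds([10, 100, 200])
        out = apply_masks(ds, [], keep=None)
        assert out.n_sites == 3

    def test_half_open_convention(self):
        ds = _ds([100])

        def mask(lo, hi):
            return IntervalTrack(
                np.array(["chr1"], dtype=object),
                np.array([lo]), np.array([hi]),
            )

        assert apply_masks(ds, [mask(50, 150)]).n_sites == 0
        assert apply_masks(ds, [mask(100, 101)]).n_sites == 0
        assert apply_masks(ds, [mask(101, 200)]).n_sites == 1
        assert apply_masks(ds, [mask(50, 100)]).n_sites == 1

    def test_mask_removal_count(self):
        ds = _ds(list(range(0, 100, 10)))  # 10 sites at 0..90
        m = IntervalTrack(
            np.array(["chr1"], dtype=object), np.array([0]), np.array([35])
        )
        out = apply_masks(ds, [m])
        assert out.n_sites == 6

    def test_keep_tracks_restrict(self):
        ds = _ds([10, 50, 90])
        keep = IntervalTrack(
            np.array(["chr1"], dtype=object), np.array([40]), np.array([60])
        )
        out = apply_masks(ds, [], keep=[keep])
        assert list(out.pos) == [50]


class TestRecombinationPartition:
    def test_boundary_assigned_upward(self):
        ds = _ds([0, 1, 2, 3], rates=[0.5, 1.5, 3.0, 14.5])
        parts = partition_by_recomb(ds)
        assert [p.n_sites for p in parts] == [1, 1, 2]
        assert parts[0].rec_rate[0] == 0.5  # class 1: [0, 1.5)
        assert parts[1].rec_rate[0] == 1.5  # class 2: [1.5, 3)

    def test_rate_1_4_in_first_class(self):
        ds = _ds([0], rates=[1.4])
        parts = partition_by_recomb(ds)
        assert parts[0].n_sites == 1

    def test_out_of_range_rate_names_site(self):
        ds = _ds([7], rates=[20.0])
        with pytest.raises(ValueError, match="chr1:7"):
            partition_by_recomb(ds)

    def test_uncovered_site_raises(self):
        ds = _ds([100])
        recmap = IntervalTrack(
            np.array(["chr1"], dtype=object), np.array([0]), np.array([50]),
            value=np.array([2.0]),
        )
        with pytest.raises(ValueError, match="not covered"):
            partition_by_recomb(ds, recmap)

    def test_mask_and_partition_commute(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(10_000, size=60, replace=False))
        rates = rng.uniform(0, 14.5, size=60)
        ds = _ds(list(pos), rates=list(rates))
        m = IntervalTrack(
            np.array(["chr1"], dtype=object),
            np.array([2_000]), np.array([6_000]),
        )
        a = [apply_masks(p, [m]) for p in partition_by_recomb(ds)]
        b = partition_by_recomb(apply_masks(ds, [m]))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pos, y.pos)


class TestBedAndRecmap:
    def test_read_bed(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("2R\t0\t100\n2R\t50\t150\n3L\t10\t20\n")
        t = read_bed(p)
        assert len(t) == 2  # overlapping 2R intervals merged
        assert t.covers(np.array(["2R"], dtype=object), np.array([120]))[0]

    def test_read_recmap(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("2R\t0\t100000\t2.5\n2R\t100000\t200000\t0.4\n")
        t = read_recmap(p)
        vals = t.lookup(np.array(["2R", "2R"], dtype=object),
                        np.array([5, 150_000]))
        np.testing.assert_array_equal(vals, [2.5, 0.4])

    def test_bad_interval_reports_line(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("2R\t10\t10\n")
        with pytest.raises(ValueError, match=":1"):
            read_bed(p)

    def test_recmap_requires_numeric_rate(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("2R\t0\t10\thigh\n")
        with pytest.raises(ValueError, match="numeric"):
            read_recmap(p)


class TestVCF:
    def test_round_trip(self, tmp_path, asymig_spec, asymig_truth):
        ds = simulate_dataset(
            SimConfig(spec=asymig_spec, params=asymig_truth, n_loci=40,
                      theta_locus=3.0, seed=6)
        )
        vcf, panel = tmp_path / "d.vcf", tmp_path / "d.panel"
        write_vcf(ds, vcf)
        write_panel(ds, panel)
        ds2 = read_haploid_vcf(vcf, panel)
        assert ds2.samples == ds.samples
        np.testing.assert_array_equal(ds2.genotypes, ds.genotypes)
        np.testing.assert_array_equal(ds2.pos, ds.pos)
        assert ds2.polarization == "derived"

    def test_heterozygous_site_dropped(self, tmp_path):
        vcf = tmp_path / "h.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "c\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n"
            "c\t20\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        )
        panel = tmp_path / "p.txt"
        panel.write_text("s1\tp1\ns2\tp2\n")
        ds = read_haploid_vcf(vcf, panel)
        assert ds.n_sites == 1 and ds.pos[0] == 19
        assert ds.provenance["skipped"]["heterozygous"] == 1

    def test_sample_missing_from_panel(self, tmp_path):
        vcf = tmp_path / "h.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=c>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "c\t20\t.\tA\tT\t.\tPASS\t.\tGT\t0\t1\n"
        )
        panel = tmp_path / "p.txt"
        panel.write_text("s1\tp1\n")
        with pytest.raises(ValueError, match="s2"):
            read_haploid_vcf(vcf, panel)


class TestSFSText:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        j = JointSFS(rng.poisson(4.0, size=(3, 3)).astype(float))
        p = tmp_path / "x.fs"
        write_sfs(j, p)
        j2 = read_sfs(p)
        np.testing.assert_array_equal(j.counts, j2.counts)
        np.testing.assert_array_equal(j.mask, j2.mask)
        assert j2.folded is False

    def test_folded_flag_preserved(self, tmp_path):
        j = JointSFS(np.ones((3, 3))).fold()
        p = tmp_path / "x.fs"
        write_sfs(j, p)
        assert read_sfs(p).folded is True

    def test_mask_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.fs"
        p.write_text("2 2 unfolded\n1 2 3 4\n0 0 0\n")
        with pytest.raises(ValueError, match="mask"):
            read_sfs(p)
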