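import numpy as np
import pytest

from trscape.density import (
    class_profiles,
    compute_density,
    profile_bins,
    rc_pair_counts,
    relative_density,
    top_motifs,
    tr_presence_frequency,
    unit_size_frequency,
)
from trscape.detect import TandemRepeat
from trscape.errors import DensityError, StatsError
from trscape.io import GeneModel, SequenceRecord
from trscape.motifs import canonical_class
from trscape.regions import GenomicRegion, assign_trs, genome_regions


def _tr(start, end, unit="AAG", seq_id="chr1"):
    return TandemRepeat(
        seq_id, start, end, unit, canonical_class(unit), len(unit),
        (end - start) / len(unit), end - start, True,
    )


class TestComputeDensity:
    def test_definitional(self):
        rec = SequenceRecord("chr1", "A" * 1000)
        region = GenomicRegion("chr1", "CDS", 0, 1000, "+", "g", "m")
        trs = [_tr(0, 50)]
        assignments = assign_trs(trs, [region])
        (d,) = compute_density(assignments, [region], [rec])
        assert d.tr_bp == 50
        assert d.density == pytest.approx(50 / 1000 * 1e6)

    def test_zero_trs(self):
        rec = SequenceRecord("chr1", "ACGT" * 250)
        region = GenomicRegion("chr1", "CDS", 0, 1000, "+", "g", "m")
        (d,) = compute_density([], [region], [rec])
        assert d.density == 0.0 and d.tr_bp == 0

    def test_n_excluded_from_denominator(self):
        rec = SequenceRecord("chr1", "ACGT" * 100 + "N" * 600)
        region = GenomicRegion("chr1", "GENOME", 0, 1000, "+")
        trs = [_tr(0, 40)]
        (d,) = compute_density(assign_trs(trs, [region]), [region], [rec])
        assert d.total_valid_nt == 400
        assert d.density == pytest.approx(40 / 400 * 1e6)

    def test_shared_bases_counted_once(self):
        # two mRNAs sharing a CDS interval: union denominator, single TR count
        rec = SequenceRecord("chr1", "ACGT" * 250)
        r1 = GenomicRegion("chr1", "CDS", 0, 600, "+", "g", "m1")
        r2 = GenomicRegion("chr1", "CDS", 400, 1000, "+", "g", "m2")
        trs = [_tr(450, 474)]
        (d,) = compute_density(assign_trs(trs, [r1, r2]), [r1, r2], [rec])
        assert d.total_valid_nt == 1000
        assert d.tr_bp == 24

    def test_zero_valid_nt_error(self):
        rec = SequenceRecord("chr1", "N" * 100)
        region = GenomicRegion("chr1", "CDS", 0, 100, "+", "g", "m")
        with pytest.raises(DensityError, match="CDS"):
            compute_density([], [region], [rec])

    def test_genome_relative_is_100(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        rec = SequenceRecord("chr1", seq)
        regions = genome_regions([rec]) + [
            GenomicRegion("chr1", "CDS", 0, 500, "+", "g", "m")
        ]
        trs = [_tr(10, 34), _tr(600, 630)]
        recs = compute_density(assign_trs(trs, regions), regions, [rec])
        by_cls = {d.region_class: d for d in recs}
        assert by_cls["GENOME"].relative_density == 100.0
        expected = 100 * by_cls["CDS"].density / by_cls["GENOME"].density
        assert by_cls["CDS"].relative_density == pytest.approx(expected)

    def test_additivity_over_partition(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        rec = SequenceRecord("chr1", seq)
        parts = [
            GenomicRegion("chr1", f"P{i}", i * 1000, (i + 1) * 1000, "+")
            for i in range(3)
        ]
        whole = genome_regions([rec])
        trs = [_tr(980, 1010), _tr(1500, 1530), _tr(2990, 3000)]
        recs = compute_density(
            assign_trs(trs, parts + whole), parts + whole, [rec]
        )
        by_cls = {d.region_class: d for d in recs}
        assert (
            by_cls["P0"].tr_bp + by_cls["P1"].tr_bp + by_cls["P2"].tr_bp
            == by_cls["GENOME"].tr_bp
        )


class TestRelativeDensity:
    def test_genome_vs_itself(self):
        assert relative_density(20_000, 20_000) == 100.0

    def test_double(self):
        assert relative_density(40_000, 20_000) == 200.0

    def test_zero_region(self):
        assert relative_density(0.0, 20_000) == 0.0

    def test_zero_genome_error(self):
        with pytest.raises(DensityError):
            relative_density(10.0, 0.0)

    def test_scale_invariance(self):
        assert relative_density(300.0, 150.0) == relative_density(3.0, 1.5)


class TestProfileBins:
    def test_late_midpoint_bin9(self):
        region = GenomicRegion("chr1", "UI200", 0, 200, "+")
        p = profile_bins([_tr(179, 193)], region)  # midpoint 185
        assert p.bins[9] == 100.0

    def test_offset_zero_bin0(self):
        region = GenomicRegion("chr1", "UI200", 0, 200, "+")
        p = profile_bins([_tr(0, 2)], region)
        assert p.bins[0] == 100.0

    def test_minus_strand_mirror(self):
        # midpoint at assembly 1010 in a minus-strand [1000, 1200) region:
        # sense offset 189 -> bin 9
        region = GenomicRegion("chr1", "INTRON", 1000, 1200, "-")
        p = profile_bins([_tr(1004, 1017)], region)
        assert p.bins[9] == 100.0

    def test_bins_sum_to_100(self, rng):
        region = GenomicRegion("chr1", "CDS", 0, 1000, "+")
        trs = [
            _tr(int(s), int(s) + 12) for s in rng.integers(0, 980, size=57)
        ]
        p = profile_bins(trs, region)
        assert sum(p.bins) == pytest.approx(100.0, abs=1e-9)

    def test_empty_flagged(self):
        region = GenomicRegion("chr1", "CDS", 0, 1000, "+")
        p = profile_bins([], region)
        assert p.empty and p.bins == [0.0] * 10

    def test_reversal_reverses_bins(self, rng):
        fwd = GenomicRegion("chr1", "CDS", 0, 1000, "+")
        rev = GenomicRegion("chr1", "CDS", 0, 1000, "-")
        trs = [_tr(int(s), int(s) + 13) for s in rng.integers(0, 980, size=40)]
        assert profile_bins(trs, fwd).bins == profile_bins(trs, rev).bins[::-1]

    def test_class_aggregation_midpoint_rule(self):
        # TR straddling the boundary is binned only in the region holding
        # its midpoint
        r1 = GenomicRegion("chr1", "CDS", 0, 100, "+", "g", "m")
        r2 = GenomicRegion("chr1", "INTRON", 100, 200, "+", "g", "m")
        trs = [_tr(92, 112)]  # midpoint 101 -> INTRON
        profs = class_profiles(assign_trs(trs, [r1, r2]))
        assert "CDS" not in profs
        assert profs["INTRON"].n_trs == 1
        assert profs["INTRON"].bins[0] == 100.0


class TestMotifTables:
    def test_unit_length_percentages(self):
        trs = [_tr(0, 12, "A"), _tr(20, 32, "AT"), _tr(40, 52, "AT")]
        table = unit_size_frequency(trs)
        assert table.by_unit_length[1] == pytest.approx(100 / 3)
        assert table.by_unit_length[2] == pytest.approx(200 / 3)
        assert sum(table.by_unit_length.values()) == pytest.approx(100.0)

    def test_rc_pair_displayed_jointly_counted_separately(self):
        trs = [_tr(i * 20, i * 20 + 12, "AAG") for i in range(5)] + [
            _tr(200 + i * 20, 212 + i * 20, "CTT") for i in range(3)
        ]
        ranked = top_motifs(trs, k=2)
        assert ranked[0] == ("AAG/CTT", "AAG", 5)
        assert ranked[1] == ("CTT/AAG", "CTT", 3)
        assert rc_pair_counts(trs)["AAG/CTT"] == (5, 3)

    def test_empty_input(self):
        table = unit_size_frequency([])
        assert table.by_unit_length == {} and table.top_motifs == []

    def test_tie_broken_alphabetically(self):
        trs = [_tr(0, 12, "AC"), _tr(20, 32, "AG")]
        assert [m for _l, m, _c in top_motifs(trs, k=2)] == ["AC", "AG"]


def _model(mrna_id, seq_id="chr1"):
    return GeneModel("g_" + mrna_id, mrna_id, seq_id, "+", (0, 100), exons=[(0, 100)])


class TestPresenceFrequency:
    def test_fraction_per_class(self):
        models = [_model(f"m{i}") for i in range(3)]
        regions = [
            GenomicRegion("chr1", "INTRON", i * 1000, i * 1000 + 100, "+", m.gene_id, m.mrna_id)
            for i, m in enumerate(models)
        ]
        trs = [_tr(10, 30), _tr(1010, 1030)]  # hits m0 and m1 introns
        freq = tr_presence_frequency(assign_trs(trs, regions), models)
        assert freq["INTRON"] == pytest.approx(2 / 3)

    def test_mrna_counts_once_per_class(self):
        models = [_model("m0")]
        region = GenomicRegion("chr1", "INTRON", 0, 1000, "+", "g_m0", "m0")
        trs = [_tr(10, 30), _tr(100, 130), _tr(500, 530)]
        freq = tr_presence_frequency(assign_trs(trs, [region]), models)
        assert freq["INTRON"] == 1.0

    def test_no_models_error(self):
        with pytest.raises(StatsError):
            tr_presence_frequency([], [])
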