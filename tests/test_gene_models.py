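"""Annotation parsing, exon compression, projections and KO eligibility."""

import pytest

import armkit as ak
from armkit.fixtures import CCDS_HEADER
from armkit.gene_models import parse_ccds


def _row(
    ccds_id,
    exons,
    status="Public",
    gene_id="10",
    symbol="G1",
    chrom="1",
):
    locations = "[" + ", ".join(f"{s}-{e - 1}" for s, e in exons) + "]"
    return "\t".join(
        [
            chrom,
            "NC_TEST.1",
            symbol,
            gene_id,
            ccds_id,
            status,
            "+",
            str(exons[0][0]),
            str(exons[-1][1] - 1),
            locations,
            "Identical",
        ]
    )


def _table(tmp_path, rows, name="t.txt"):
    path = tmp_path / name
    path.write_text("\n".join([CCDS_HEADER] + rows) + "\n")
    return path


class TestParse:
    def test_status_filter_keeps_only_exact_public(self, tmp_path):
        rows = [
            _row("CCDS1.1", [(100, 200)]),
            _row("CCDS2.1", [(300, 400)], status="Withdrawn"),
            _row("CCDS3.1", [(500, 600)], status="Public, under review"),
            _row("CCDS4.1", [(700, 800)]),
        ]
        gms = parse_ccds(_table(tmp_path, rows))
        assert gms.n_transcripts == 2
        assert {t.ccds_id for t in gms.transcripts} == {"CCDS1.1", "CCDS4.1"}

    def test_empty_table_is_empty_model_set(self, tmp_path):
        gms = parse_ccds(_table(tmp_path, []))
        assert (gms.n_transcripts, gms.n_genes, gms.n_exons) == (0, 0, 0)

    def test_missing_column_errors_naming_column(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("#chromosome\tgene\n1\tG1\n")
        with pytest.raises(ValueError, match="ccds_status"):
            parse_ccds(path)

    def test_malformed_locations_error_names_line(self, tmp_path):
        rows = [
            _row("CCDS1.1", [(100, 200)]),
            _row("CCDS2.1", [(300, 400)]).replace("[300-399]", "[300..399]"),
        ]
        with pytest.raises(ValueError, match="line 3"):
            parse_ccds(_table(tmp_path, rows))

    def test_records_without_gene_id_or_locations_skipped(self, tmp_path):
        rows = [
            _row("CCDS1.1", [(100, 200)]),
            _row("CCDS2.1", [(300, 400)], gene_id="-"),
            _row("CCDS3.1", [(500, 600)]).replace("[500-599]", "-"),
        ]
        gms = parse_ccds(_table(tmp_path, rows))
        assert gms.n_transcripts == 1

    def test_inclusive_end_convention(self, tmp_path):
        # cds_locations 100-199 denotes 100 bases -> half-open [100, 200)
        gms = parse_ccds(_table(tmp_path, [_row("CCDS1.1", [(100, 200)])]))
        assert gms.transcripts[0].exons == ((100, 200),)


class TestCompression:
    def test_identical_coordinates_merge_tracking_ccds_ids(self, tmp_path):
        rows = [
            _row("CCDS1.1", [(100, 200)]),
            _row("CCDS2.1", [(100, 200)]),
        ]
        gms = parse_ccds(_table(tmp_path, rows))
        exons = ak.compress_exons(gms, 10)
        assert len(exons) == 1
        assert exons[0].ccds_ids == frozenset({"CCDS1.1", "CCDS2.1"})

    def test_off_by_one_coordinates_stay_distinct(self, tmp_path):
        rows = [
            _row("CCDS1.1", [(100, 200)]),
            _row("CCDS2.1", [(100, 201)]),
        ]
        gms = parse_ccds(_table(tmp_path, rows))
        assert len(ak.compress_exons(gms, 10)) == 2

    def test_full_sharing_collapses_to_one_transcripts_worth(self, tmp_path):
        exons = [(100, 200), (500, 650), (900, 1000)]
        rows = [_row(f"CCDS{i}.1", exons) for i in (1, 2, 3)]
        gms = parse_ccds(_table(tmp_path, rows))
        # brute-force dedupe oracle: set of coordinate pairs
        expected = sorted(set(exons))
        got = [(e.start, e.end) for e in ak.compress_exons(gms, 10)]
        assert got == expected

    def test_conservation_of_exon_occurrences(self, sim_instance):
        """No exon lost or duplicated: summed ccds memberships over unique
        exons equal the raw exon occurrences of the gene."""
        gms = sim_instance.gms
        for gid in gms.gene_ids():
            raw = sum(len(t.exons) for t in gms.transcripts_of(gid))
            merged = sum(len(e.ccds_ids) for e in gms.unique_exons(gid))
            assert merged == raw

    def test_unknown_gene_errors(self, tmp_path):
        gms = parse_ccds(_table(tmp_path, [_row("CCDS1.1", [(100, 200)])]))
        with pytest.raises(KeyError):
            ak.compress_exons(gms, 999)


class TestProjections:
    @pytest.mark.parametrize(
        "exon_sets, expected",
        [
            # outermost coordinates of an overlapping pair
            ([[(100, 200)], [(150, 250)]], [(100, 250)]),
            # transitive chain merges into one projection
            ([[(100, 200)], [(150, 250)], [(240, 300)]], [(100, 300)]),
            # disjoint exons stay separate projections
            ([[(100, 200)], [(500, 600)]], [(100, 200), (500, 600)]),
        ],
    )
    def test_projection_coordinates(self, tmp_path, exon_sets, expected):
        rows = [
            _row(f"CCDS{i}.1", exons) for i, exons in enumerate(exon_sets, 1)
        ]
        gms = parse_ccds(_table(tmp_path, rows))
        got = [(p.start, p.end) for p in ak.project_exons(gms, 10)]
        assert got == expected

    def test_projection_invariants_and_idempotence(self, sim_instance):
        gms = sim_instance.gms
        for gid in gms.gene_ids():
            projections = ak.project_exons(gms, gid)
            for p in projections:
                assert all(
                    p.start <= m.start and m.end <= p.end for m in p.members
                )
                assert p.length >= max(m.length for m in p.members)
                assert 1 <= p.commonality <= gms.transcript_count(gid)
            # pairwise disjoint
            intervals = sorted(p.interval for p in projections)
            assert all(
                a_end <= b_start
                for (_, a_end), (b_start, _) in zip(intervals, intervals[1:])
            )
            # fixed point: re-projecting the projection intervals changes nothing
            merged = []
            for start, end in intervals:
                if merged and start < merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            assert [tuple(m) for m in merged] == intervals

    def test_commonality_counts_containing_transcripts(self, tmp_path):
        rows = [
            _row("CCDS1.1", [(100, 200)]),
            _row("CCDS2.1", [(150, 250)]),
            _row("CCDS3.1", [(500, 600)]),
        ]
        gms = parse_ccds(_table(tmp_path, rows))
        projections = ak.project_exons(gms, 10)
        assert [(p.interval, p.commonality) for p in projections] == [
            ((100, 250), 2),
            ((500, 600), 1),
        ]


class TestKnockoutEligibility:
    @pytest.mark.parametrize(
        "length, n_carrying, eligible",
        [
            (100, 2, True),  # shared by all, 100 % 3 == 1
            (99, 2, False),  # in-frame length
            (100, 1, False),  # absent from one transcript
        ],
    )
    def test_eligibility_rules(self, tmp_path, length, n_carrying, eligible):
        target = (5000, 5000 + length)
        anchor = (1000, 1100)
        tx1 = [anchor, target]
        tx2 = [anchor, target] if n_carrying == 2 else [anchor]
        rows = [_row("CCDS1.1", tx1), _row("CCDS2.1", tx2)]
        gms = parse_ccds(_table(tmp_path, rows))
        got = {e.interval for e in ak.knockout_eligible_exons(gms, 10)}
        assert (target in got) is eligible

    def test_single_transcript_gene_all_exons_trivially_common(self, tmp_path):
        rows = [_row("CCDS1.1", [(100, 200), (500, 599)])]
        gms = parse_ccds(_table(tmp_path, rows))
        got = {e.interval for e in ak.knockout_eligible_exons(gms, 10)}
        assert got == {(100, 200)}  # 100 eligible, 99 in-frame

    def test_micro_fixture_truth(self, tmp_path):
        fx = ak.micro_fixture("ko-eligible", tmp_path)
        gms = ak.parse_ccds(fx.table_path)
        got = [[e.start, e.end] for e in ak.knockout_eligible_exons(gms, 2)]
        assert got == fx.expected["ko_eligible"]


def test_bed_export_is_half_open(tmp_path):
    rows = [_row("CCDS1.1", [(100, 200), (500, 600)])]
    gms = parse_ccds(_table(tmp_path, rows))
    out = tmp_path / "proj.bed"
    ak.projections_to_bed(gms, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t")[:3] == ["1", "100", "200"]
    assert len(lines) == 2
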