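"""Scaffold filtering, BLAST parsing, top-hit selection and contributions."""

import numpy as np
import pandas as pd
import pytest

from sigmeta.errors import ConfigError, DataError
from sigmeta.scaffolds import (
    BlastHit,
    annotation_summary,
    apply_quality_filters,
    contribution_fractions,
    filter_scaffolds,
    parse_blast_tabular,
    quality_mask,
    select_top_hit,
    select_top_hits,
)
from sigmeta.simulate import generate_blast_fixture


def _hit(**kw):
    base = dict(
        qseqid="q", sseqid="s", pident=95.0, length=1000, evalue=1e-20,
        bitscore=100.0, qlen=2000, staxids="", line=1,
    )
    base.update(kw)
    return BlastHit(**base)


class TestFilterScaffolds:
    def test_kilobase_boundary_inclusive(self):
        scaffolds = [("keep", "A" * 1000), ("drop", "A" * 999)]
        assert [sid for sid, _ in filter_scaffolds(scaffolds)] == ["keep"]

    def test_empty_assembly(self):
        assert filter_scaffolds([]) == []

    def test_fasta_path_input(self, tmp_path):
        path = tmp_path / "asm.fasta"
        path.write_text(">a\n" + "ACGT" * 300 + "\n>b\nACGT\n")
        assert [sid for sid, _ in filter_scaffolds(path)] == ["a"]


class TestParseBlast:
    LINE = "\t".join(
        ["scf1", "ref1", "98.5", "1500", "10", "2", "1", "1500", "5", "1504",
         "1e-50", "2000", "2000", "562"]
    )

    def test_well_formed_row(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("# comment\n" + self.LINE + "\n")
        hits = parse_blast_tabular(path)
        assert len(hits) == 1
        row = hits.iloc[0]
        assert row["qseqid"] == "scf1" and row["qlen"] == 2000
        assert row["staxids"] == "562"

    def test_truncated_row_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.LINE + "\nscf2\tref\t90.0\n")
        with pytest.raises(DataError, match="line 2"):
            parse_blast_tabular(path)

    def test_twelve_columns_is_config_error(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\t".join(self.LINE.split("\t")[:12]) + "\n")
        with pytest.raises(ConfigError, match="qlen"):
            parse_blast_tabular(path)

    def test_bad_numeric_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        bad = self.LINE.replace("98.5", "NA")
        path.write_text(self.LINE + "\n" + bad + "\n")
        with pytest.raises(DataError, match="line 2"):
            parse_blast_tabular(path)


class TestTopHit:
    def test_highest_bitscore_wins(self):
        hits = [_hit(bitscore=150.0, line=1), _hit(bitscore=200.0, line=2)]
        assert select_top_hit(hits).bitscore == 200.0

    def test_tie_broken_by_lower_evalue(self):
        hits = [
            _hit(bitscore=200.0, evalue=1e-40, sseqid="worse", line=1),
            _hit(bitscore=200.0, evalue=1e-50, sseqid="better", line=2),
        ]
        assert select_top_hit(hits).sseqid == "better"

    def test_no_hits_is_none(self):
        assert select_top_hit([]) is None

    def test_frame_version_order_invariant(self):
        rows = [
            dict(qseqid="q1", sseqid=f"s{i}", pident=90.0, length=100, mismatch=0,
                 gapopen=0, qstart=1, qend=100, sstart=1, send=100,
                 evalue=10.0 ** -(30 + i), bitscore=100.0 + (i % 3), qlen=1000,
                 staxids="", line=i)
            for i in range(6)
        ]
        frame = pd.DataFrame(rows)
        top = select_top_hits(frame)
        shuffled = select_top_hits(frame.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(top, shuffled)


class TestQualityFilters:
    @pytest.mark.parametrize(
        "pident,cov,evalue,expected",
        [
            (80.0, 0.25, 1e-7, True),   # all boundaries inclusive
            (79.9, 0.25, 1e-7, False),
            (80.0, 0.249, 1e-7, False),
            (80.0, 0.25, 1e-6, False),
            (95.0, 0.9, 1e-20, True),
        ],
    )
    def test_boundary_grid(self, pident, cov, evalue, expected):
        hit = _hit(pident=pident, length=int(cov * 2000), evalue=evalue)
        assert apply_quality_filters(hit) is expected

    def test_vectorised_matches_scalar(self):
        grid = [
            _hit(pident=p, length=int(c * 2000), evalue=e)
            for p in (79.9, 80.0, 80.1)
            for c in (0.249, 0.25, 0.251)
            for e in (1e-8, 1e-7, 1e-6)
        ]
        frame = pd.DataFrame([h.__dict__ for h in grid])
        vec = quality_mask(frame).tolist()
        assert vec == [apply_quality_filters(h) for h in grid]


class TestContributions:
    def test_single_fully_aligned_scaffold(self):
        top = pd.DataFrame([
            dict(qseqid="s1", sseqid="refA", length=2000, staxids="OrgA"),
        ])
        table = contribution_fractions(top, {"s1": 2000})
        assert table.set_index("organism").at["OrgA", "fraction"] == pytest.approx(1.0)

    def test_partial_alignment_and_unassigned(self):
        top = pd.DataFrame([
            dict(qseqid="s1", sseqid="refA", length=500, staxids="OrgA"),
            dict(qseqid="s2", sseqid="refB", length=500, staxids="OrgB"),
        ])
        table = contribution_fractions(top, {"s1": 1000, "s2": 1000}).set_index("organism")
        assert table.at["OrgA", "fraction"] == pytest.approx(0.25)
        assert table.at["OrgB", "fraction"] == pytest.approx(0.25)
        assert table.at["unassigned", "fraction"] == pytest.approx(0.5)

    def test_alignment_capped_at_scaffold_length(self):
        top = pd.DataFrame([
            dict(qseqid="s1", sseqid="refA", length=5000, staxids="OrgA"),
        ])
        table = contribution_fractions(top, {"s1": 2000}).set_index("organism")
        assert table.at["OrgA", "fraction"] == pytest.approx(1.0)

    def test_conservation_sums_to_one(self):
        rng = np.random.default_rng(0)
        lengths = {f"s{i}": int(rng.integers(1000, 3000)) for i in range(20)}
        top = pd.DataFrame([
            dict(qseqid=sid, sseqid=f"ref{i % 3}", staxids=f"Org{i % 3}",
                 length=int(rng.integers(300, 4000)))
            for i, sid in enumerate(lengths)
        ])
        table = contribution_fractions(top, lengths)
        assert table["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_hits_fully_unassigned(self):
        table = contribution_fractions(pd.DataFrame(columns=["qseqid", "sseqid", "length", "staxids"]), {"s1": 1500})
        assert table.set_index("organism").at["unassigned", "fraction"] == 1.0


class TestSummaryAndFixture:
    def test_summary_counts(self):
        fixture = generate_blast_fixture(seed=1)
        kept = filter_scaffolds(fixture.scaffolds)
        ids = [sid for sid, _ in kept]
        hits = fixture.hits.copy()
        hits["line"] = range(1, len(hits) + 1)
        hits = hits[hits["qseqid"].isin(ids)]
        summary = annotation_summary(ids, hits)
        assert summary["total_scaffolds"] == len(ids)
        assert summary["without_hits"] == 1  # scf_nohit only (scf_short was dropped)
        expected_hq = fixture.truth_boundary["expected_pass"].sum() + (
            summary["annotated"] - 1 - len(fixture.truth_boundary)
        )
        assert summary["high_quality"] == expected_hq + 1  # + tie scaffold

    def test_planted_contributions_recovered(self):
        fixture = generate_blast_fixture(seed=2)
        kept = filter_scaffolds(fixture.scaffolds)
        lengths = {sid: len(seq) for sid, seq in kept}
        hits = fixture.hits.copy()
        hits["line"] = range(1, len(hits) + 1)
        hits = hits[hits["qseqid"].isin(lengths)]
        top = select_top_hits(hits)
        passing = top[quality_mask(top)]
        table = contribution_fractions(passing, lengths).set_index("organism")
        truth = fixture.truth_contributions.set_index("organism")
        for organism, row in truth.iterrows():
            assert table.at[organism, "fraction"] == pytest.approx(
                row["fraction"], abs=1e-12
            ), organism

    def test_boundary_verdicts_recovered(self):
        fixture = generate_blast_fixture(seed=3)
        hits = fixture.hits.copy()
        hits["line"] = range(1, len(hits) + 1)
        verdicts = dict(zip(hits["qseqid"], quality_mask(hits)))
        for row in fixture.truth_boundary.itertuples():
            assert verdicts[row.qseqid] == row.expected_pass

    def test_empty_scaffold_list_rejected(self):
        with pytest.raises(DataError):
            annotation_summary([], pd.DataFrame(columns=["qseqid"]))
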