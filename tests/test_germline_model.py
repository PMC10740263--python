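import json

import pytest

from igannot.errors import (
    AlignmentFormatError,
    EmptyInputError,
    ModelBuildError,
    ModelNotFoundError,
    RegistryError,
)
from igannot.germline_model import (
    GermlineSegment,
    ModelRegistry,
    build_alignment,
    build_model,
    import_alignment,
    number_j_segment,
    number_v_segment,
    validate_alignment,
    write_alignment,
)
from igannot.fixtures import make_germline_set
from igannot.imgt import ImgtLabel


def _col(aln, position):
    return [c for c, lab in enumerate(aln.columns)
            if lab == ImgtLabel(position)][0]


class TestNumbering:
    def test_fixture_v_anchors(self, germlines):
        v, _ = germlines
        labels = number_v_segment(v[0].sequence)
        assert labels[22] == ImgtLabel(23)
        assert labels[36] == ImgtLabel(41)
        assert labels[-1] == ImgtLabel(104)
        assert len(labels) == len(v[0].sequence)

    def test_fixture_j_anchor(self, germlines):
        _, j = germlines
        labels = number_j_segment(j[0].sequence)
        assert labels[0] == ImgtLabel(118)
        assert labels[-1] == ImgtLabel(128)

    def test_no_anchors_rejected(self):
        with pytest.raises(ModelBuildError, match="anchor"):
            number_v_segment("A" * 96)
        with pytest.raises(ModelBuildError, match="anchor"):
            number_j_segment("AAAAAAAAAAA")


class TestBuildAlignment:
    def test_permutation_row_count(self, germlines):
        v, j = germlines
        aln = build_alignment(v, j)
        assert aln.n_rows == len(v) * len(j) == 12
        assert len({len(text) for _, text in aln.rows}) == 1

    def test_degenerate_single_pair_is_concatenation(self, germlines):
        v, j = germlines
        aln = build_alignment([v[0]], [j[0]])
        assert aln.n_rows == 1
        assert aln.rows[0][0] == f"{v[0].id}|{j[0].id}"
        assert aln.rows[0][1].replace("-", "") == \
            v[0].sequence + j[0].sequence

    def test_conserved_cys_columns(self, toy_alignment):
        aln = toy_alignment
        for pos in (23, 104):
            c = _col(aln, pos)
            assert all(text[c] == "C" for _, text in aln.rows)
        c118 = _col(aln, 118)
        assert all(text[c118] in "WF" for _, text in aln.rows)

    def test_no_residue_lost_or_duplicated(self, germlines, toy_alignment):
        v, j = germlines
        by_id = {s.id: s for s in v + j}
        for rid, text in toy_alignment.rows:
            vid, jid = rid.split("|")
            assert text.replace("-", "") == \
                by_id[vid].sequence + by_id[jid].sequence

    def test_empty_input(self, germlines):
        v, j = germlines
        with pytest.raises(EmptyInputError):
            build_alignment([], j)
        with pytest.raises(EmptyInputError):
            build_alignment(v, [])

    def test_unnumberable_segment_names_id(self, germlines):
        v, j = germlines
        bad = GermlineSegment(id="Vbad", kind="V", sequence="A" * 96)
        with pytest.raises(ModelBuildError, match="Vbad"):
            build_alignment(v + [bad], j)


class TestValidateAlignment:
    def test_fixture_alignment_passes(self, toy_alignment):
        assert validate_alignment(toy_alignment).passed

    def test_short_row_flagged(self, toy_alignment):
        aln = type(toy_alignment)(
            rows=[(toy_alignment.rows[0][0],
                   toy_alignment.rows[0][1][:-1])]
            + toy_alignment.rows[1:],
            columns=toy_alignment.columns,
            region_map=toy_alignment.region_map,
        )
        report = validate_alignment(aln)
        assert not report.passed
        codes = {f.code for f in report.findings if f.fatal}
        assert "rectangular" in codes

    def test_empty_region_flagged(self, toy_alignment):
        gap_cdr2 = [
            (rid, "".join("-" if reg == "CDR2" else ch
                          for ch, reg in zip(text,
                                             toy_alignment.region_map)))
            for rid, text in toy_alignment.rows
        ]
        aln = type(toy_alignment)(rows=gap_cdr2,
                                  columns=toy_alignment.columns,
                                  region_map=toy_alignment.region_map)
        report = validate_alignment(aln)
        assert not report.passed
        assert any(f.code == "empty_region" and "CDR2" in f.message
                   for f in report.findings)

    def test_duplicate_ids_flagged(self, toy_alignment):
        aln = type(toy_alignment)(
            rows=toy_alignment.rows + [toy_alignment.rows[0]],
            columns=toy_alignment.columns,
            region_map=toy_alignment.region_map,
        )
        assert any(f.code == "duplicate_id"
                   for f in validate_alignment(aln).findings)

    def test_broken_anchor_warns_but_passes(self):
        v, j = make_germline_set(3, 3, 2, break_anchors=True)
        # broken Cys23 in every V: numbering still finds a usable pair
        # or fails; bypass numbering by building from the good set and
        # substituting residues in the anchor column instead
        v_ok, j_ok = make_germline_set(3, 3, 2)
        aln = build_alignment(v_ok, j_ok)
        c23 = [c for c, lab in enumerate(aln.columns)
               if lab == ImgtLabel(23)][0]
        rows = [(rid, text[:c23] + "A" + text[c23 + 1:])
                for rid, text in aln.rows]
        aln2 = type(aln)(rows=rows, columns=aln.columns,
                         region_map=aln.region_map)
        report = validate_alignment(aln2)
        assert report.passed  # anchor findings are warnings
        assert any(f.code == "anchor" and "23" in f.message
                   for f in report.findings)


class TestAlignmentIO:
    def test_stockholm_round_trip(self, toy_alignment, tmp_path):
        p = tmp_path / "aln.sto"
        write_alignment(toy_alignment, p, fmt="stockholm")
        back = import_alignment(p)
        assert back.rows == toy_alignment.rows
        assert back.columns == toy_alignment.columns
        assert back.region_map == toy_alignment.region_map

    def test_fasta_import_recovers_region_map(self, toy_alignment,
                                              tmp_path):
        p = tmp_path / "aln.fasta"
        write_alignment(toy_alignment, p, fmt="fasta")
        back = import_alignment(p)
        assert back.rows == toy_alignment.rows
        assert back.region_map == toy_alignment.region_map

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(AlignmentFormatError):
            import_alignment(p)

    def test_garbled_file_reports_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACDE\nACD\n>b\nACDEACD\n")
        with pytest.raises(AlignmentFormatError, match="columns"):
            import_alignment(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(AlignmentFormatError, match="no such file"):
            import_alignment(tmp_path / "nope.fasta")


class TestRegistry:
    def test_fresh_registry_empty(self, tmp_path):
        reg = ModelRegistry(tmp_path / "models")
        assert reg.list_models() == []

    def test_build_list_remove(self, toy_alignment, tmp_path):
        reg = ModelRegistry(tmp_path / "models")
        build_model(toy_alignment, "toy", 20, registry=reg)
        entries = reg.list_models()
        assert [e["name"] for e in entries] == ["toy"]
        assert entries[0]["alphabet_size"] == 20
        loaded = reg.load("toy")
        assert loaded.n_match_states == 107
        reg.remove("toy")
        assert reg.list_models() == []
        with pytest.raises(ModelNotFoundError):
            reg.remove("toy")

    def test_duplicate_name_needs_overwrite(self, toy_alignment,
                                            tmp_path):
        reg = ModelRegistry(tmp_path / "models")
        build_model(toy_alignment, "toy", 20, registry=reg)
        with pytest.raises(RegistryError, match="exists"):
            build_model(toy_alignment, "toy", 20, registry=reg)
        build_model(toy_alignment, "toy", 8, registry=reg, overwrite=True)
        assert reg.load("toy").alphabet_size == 8

    def test_bad_name_rejected(self, toy_alignment, tmp_path):
        reg = ModelRegistry(tmp_path / "models")
        with pytest.raises(RegistryError, match="invalid model name"):
            build_model(toy_alignment, "bad name", 20, registry=reg)

    def test_corrupt_entry_listed_not_raised(self, toy_alignment,
                                             tmp_path):
        reg = ModelRegistry(tmp_path / "models")
        build_model(toy_alignment, "good", 20, registry=reg)
        (tmp_path / "models" / "good" / "metadata.json").write_text("{")
        entries = reg.list_models()
        assert entries == [{"name": "good", "corrupt": True}]

    def test_stored_profile_deterministic(self, toy_alignment, tmp_path):
        reg1 = ModelRegistry(tmp_path / "r1")
        reg2 = ModelRegistry(tmp_path / "r2")
        build_model(toy_alignment, "m", 12, registry=reg1)
        build_model(toy_alignment, "m", 12, registry=reg2)
        p1 = (tmp_path / "r1" / "m" / "profile.txt").read_text()
        p2 = (tmp_path / "r2" / "m" / "profile.txt").read_text()
        assert p1 == p2


def test_model_round_trip_through_registry(toy_alignment, tmp_path):
    """A registry-loaded model annotates identically to the in-memory
    one."""
    from igannot import annotate
    from igannot.fixtures import make_repertoire, make_germline_set

    reg = ModelRegistry(tmp_path / "models")
    build_model(toy_alignment, "toy", 20, registry=reg)
    model = reg.load("toy")
    reads, truths = make_repertoire(make_germline_set(1, 4, 3), 5,
                                    (0, 6), 0.0, seed=9)
    for rec, t in zip(reads, truths):
        res = annotate(rec.id, rec.sequence, [model])
        assert res.annotated
        assert [(r.region, r.start, r.end) for r in res.regions] == \
            t.regions
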