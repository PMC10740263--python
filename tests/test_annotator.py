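import numpy as np
import pytest

from igannot import annotate, annotate_batch, build_alignment, build_model
from igannot.annotator import (
    AnnotatorConfig,
    extract_regions,
    merge_hits,
    select_best_model,
    validate_consensus,
)
from igannot.fixtures import make_germline_set, make_repertoire
from igannot.hmm_engine import DomainHit, align
from igannot.imgt import ImgtLabel


def _hit(name, score, pairs):
    """DomainHit from (query index, IMGT position) match pairs."""
    return DomainHit(
        model_name=name,
        bit_score=score,
        query_start=pairs[0][0],
        query_end=pairs[-1][0] + 1,
        path=[(qi, "match", ImgtLabel(pos)) for qi, pos in pairs],
    )


class TestSelectBestModel:
    def test_only_model_with_hits_wins(self):
        hits = {"a": [], "b": [_hit("b", 30, [(0, 1), (1, 2), (2, 3)])]}
        assert select_best_model(hits) == "b"

    def test_max_single_hit_rule(self):
        hits = {
            "a": [_hit("a", 40, [(0, 1), (1, 2)])],
            "b": [_hit("b", 25, [(0, 1), (1, 2)]),
                  _hit("b", 24, [(5, 10), (6, 11)])],
        }
        assert select_best_model(hits) == "a"

    def test_lexical_tie_break(self):
        h = [_hit("x", 30, [(0, 1), (1, 2)])]
        assert select_best_model({"b": h, "a": h}) == "a"

    def test_all_empty_is_none(self):
        assert select_best_model({"a": [], "b": []}) is None

    def test_fixture_chain_discrimination(self, toy_model):
        """A query from one germline family picks that family's model
        over a model built from a disjoint family."""
        v2, j2 = make_germline_set(99, 3, 2)
        other = build_model(build_alignment(v2, j2), "other", 20)
        reads, _ = make_repertoire(make_germline_set(1, 4, 3), 5,
                                   (0, 5), 0.0, seed=4)
        for rec in reads:
            res = annotate(rec.id, rec.sequence, [toy_model, other])
            assert res.annotated and res.model_name == "toy"


class TestMergeHits:
    def test_single_hit_identity(self):
        query = "ACDEF"
        hit = _hit("m", 30, [(i, i + 20) for i in range(5)])
        cn = merge_hits([hit], query)
        assert [(qi, str(lab), res) for qi, lab, res in cn.entries] == [
            (i, str(i + 20), query[i]) for i in range(5)
        ]

    def test_ultralong_gap_gets_cdr3_insertion_codes(self):
        """Two hits ending IMGT 104 / starting IMGT 118 with 45 query
        residues between: the gap is numbered 105..111, 111.x up,
        112.x down, 112..117."""
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        query = "".join(aa[i] for i in rng.integers(0, 20, 150))
        hit_v = _hit("m", 200, [(i, i + 1) for i in range(104)])  # 1..104
        hit_j = _hit("m", 25, [(149 - k, 128 - k) for k in range(11)][::-1])
        cn = merge_hits([hit_v, hit_j], query)
        gap = [(qi, lab) for qi, lab, _ in cn.entries if 104 <= qi < 139]
        assert len(gap) == 35
        labels = [lab for _, lab in gap]
        assert labels[:7] == [ImgtLabel(p) for p in range(105, 112)]
        assert labels[-6:] == [ImgtLabel(p) for p in range(112, 118)]
        assert ImgtLabel(111, 11) in labels and ImgtLabel(112, 11) in labels
        from igannot.imgt import is_increasing
        assert is_increasing([lab for _, lab, _ in cn.entries])

    def test_overlapping_hits_dominance(self):
        query = "A" * 30
        strong = _hit("m", 30, [(i, i + 1) for i in range(20)])
        weak = _hit("m", 12, [(i + 5, i + 40) for i in range(20)])
        cn = merge_hits([strong, weak], query)
        assert cn.source_hits == [strong]

    def test_ambiguous_overlap_recorded(self):
        query = "A" * 30
        h1 = _hit("m", 20.0, [(i, i + 1) for i in range(15)])
        h2 = _hit("m", 19.5, [(i + 3, i + 30) for i in range(15)])
        cn = merge_hits([h2, h1], query)  # h2 scores lower, starts later
        assert "ambiguous_merge" in cn.findings or \
            cn.source_hits in ([h1], [h2])

    def test_every_residue_matches_query(self):
        query = "MKVLQTWAESA"
        hit = _hit("m", 20, [(i, i + 10) for i in range(len(query))])
        cn = merge_hits([hit], query)
        for qi, _, res in cn.entries:
            assert res == query[qi]


class TestValidateConsensus:
    def _consensus(self, model, sequence):
        hits = align(model.hmm, sequence,
                     column_positions=model.column_positions,
                     model_name=model.name)
        return merge_hits(hits, sequence, model=model)

    def test_full_length_read_passes(self, toy_model, zero_mut_reads):
        reads, _ = zero_mut_reads
        cn = self._consensus(toy_model, reads[0].sequence)
        report = validate_consensus(cn, toy_model)
        assert report.passed and report.reject_reasons == []

    def test_missing_fr4_fails(self, toy_model, zero_mut_reads):
        reads, _ = zero_mut_reads
        cn = self._consensus(toy_model, reads[0].sequence)
        fr4_cols = {c.key() for c, r in zip(toy_model.column_positions,
                                            toy_model.region_map)
                    if r == "FR4"}
        cn.entries = [e for e in cn.entries
                      if e[1].key() not in fr4_cols]
        report = validate_consensus(cn, toy_model)
        assert any(code.startswith("fr_coverage:FR4")
                   for code in report.reject_reasons)

    def test_sixty_residue_cdr3_passes(self, germlines, toy_model):
        """No CDR3 length cap: a 60-residue loop validates cleanly."""
        v, j = germlines
        rng = np.random.default_rng(8)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        insert = "".join(aa[i] for i in rng.integers(0, 20, 60))
        seq = v[0].sequence + insert + j[0].sequence
        cn = self._consensus(toy_model, seq)
        report = validate_consensus(cn, toy_model)
        assert report.passed

    def test_short_fragment_fails_span(self, toy_model, germlines):
        v, _ = germlines
        cn = self._consensus(toy_model, v[0].sequence[:30])
        report = validate_consensus(cn, toy_model)
        assert not report.passed


class TestExtractRegions:
    def test_partition_property(self, toy_model, zero_mut_reads):
        reads, _ = zero_mut_reads
        for rec in reads[:10]:
            res = annotate(rec.id, rec.sequence, [toy_model])
            assert res.annotated
            start, end = res.numbering.query_span
            joined = "".join(r.sequence for r in res.regions)
            assert joined == rec.sequence[start:end]

    def test_full_cdr3_is_13(self, toy_model, germlines):
        v, j = germlines
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        insert = "".join(aa[i] for i in rng.integers(0, 20, 13))
        seq = v[0].sequence + insert + j[0].sequence
        res = annotate("q", seq, [toy_model])
        cdr3 = res.region("CDR3")
        assert cdr3.end - cdr3.start == 13

    def test_zero_length_cdr3_reported(self, toy_model, germlines):
        v, j = germlines
        res = annotate("q", v[0].sequence + j[0].sequence, [toy_model])
        assert res.annotated
        cdr3 = res.region("CDR3")
        assert cdr3.zero_length and cdr3.start == cdr3.end == 96
        assert [r.region for r in res.regions] == \
            ["FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"]


class TestAnnotate:
    def test_round_trip_exact(self, toy_model, zero_mut_reads):
        reads, truths = zero_mut_reads
        for rec, t in zip(reads, truths):
            res = annotate(rec.id, rec.sequence, [toy_model])
            assert res.annotated
            assert [(r.region, r.start, r.end) for r in res.regions] == \
                t.regions

    def test_random_sequence_no_hit(self, toy_model):
        rng = np.random.default_rng(17)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seq = "".join(aa[i] for i in rng.integers(0, 20, 40))
        res = annotate("junk", seq, [toy_model])
        assert res.status == "rejected"
        assert res.reject_reasons == ["no_hit"]

    @pytest.mark.parametrize("bad", ["", "ACDE*FG", "ACDE-FG", "AC1DE"])
    def test_invalid_sequences_rejected(self, toy_model, bad):
        res = annotate("q", bad, [toy_model])
        assert res.status == "rejected"
        assert res.reject_reasons == ["invalid_sequence"]

    def test_mutation_robustness(self, germlines, toy_model):
        reads, truths = make_repertoire(germlines, 60, (0, 10), 0.05,
                                        seed=21)
        annotated = 0
        close = total = 0
        for rec, t in zip(reads, truths):
            res = annotate(rec.id, rec.sequence, [toy_model])
            if not res.annotated:
                continue
            annotated += 1
            for got, want in zip(res.regions, t.regions):
                for g, w in ((got.start, want[1]), (got.end, want[2])):
                    total += 1
                    close += abs(g - w) <= 1
        assert annotated >= 57  # >= 95%
        assert close / total >= 0.9


class TestAnnotateBatch:
    def test_worker_counts_agree(self, toy_model, zero_mut_reads):
        reads, _ = zero_mut_reads
        items = [(r.id, r.sequence) for r in reads]
        serial = list(annotate_batch(items, [toy_model], n_workers=1))
        parallel = list(annotate_batch(items, [toy_model], n_workers=4))
        assert [r.query_id for r in serial] == [r.query_id for r in parallel]
        for a, b in zip(serial, parallel):
            assert a.status == b.status
            assert a.bit_score == pytest.approx(b.bit_score)
            assert [(r.region, r.start, r.end) for r in a.regions] == \
                [(r.region, r.start, r.end) for r in b.regions]

    def test_empty_input(self, toy_model):
        assert list(annotate_batch([], [toy_model])) == []

    def test_record_conservation_and_order(self, toy_model,
                                           zero_mut_reads):
        reads, _ = zero_mut_reads
        items = [(r.id, r.sequence) for r in reads]
        out = list(annotate_batch(items, [toy_model], n_workers=2))
        assert [r.query_id for r in out] == [r.id for r in reads]

    def test_bad_record_does_not_stop_batch(self, toy_model,
                                            zero_mut_reads):
        reads, _ = zero_mut_reads
        items = [(reads[0].id, reads[0].sequence),
                 ("bad", "NOT A PROTEIN!!"),
                 (reads[1].id, reads[1].sequence)]
        out = list(annotate_batch(items, [toy_model], n_workers=1))
        assert [r.status for r in out] == \
            ["annotated", "rejected", "annotated"]
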