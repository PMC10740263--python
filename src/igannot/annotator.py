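"""Annotation: model choice, multi-hit consensus, validation, regions.

One good local alignment is enough to annotate a conventional antibody
domain.  The interesting cases are the ones a single alignment cannot
cover — above all ultralong CDR3s, where the junction is so long and so
unlike any germline that the profile aligns the V part and the J part
as two separate hits.  The consensus step merges the compatible hits
into one numbering, assigns IMGT labels (including 111.x/112.x
insertion codes) to every query residue caught between them, validates
the result against what the model itself says framework regions look
like, and only then cuts the seven regions.  No step imposes a CDR3
length cap.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .alphabet import AMINO_ACIDS, get_alphabet, reduce_sequence
from .germline_model import ProfileModel
from .hmm_engine import (
    DEFAULT_BIT_THRESHOLD,
    MAX_HITS,
    MIN_HIT_SPAN,
    DomainHit,
    align,
)
from .imgt import ImgtLabel, REGION_ORDER, gap_labels, \
    is_increasing, region_of

_VALID_QUERY = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class AnnotatorConfig:
    """Tunable thresholds of the annotation heuristics.

    The defaults implement the package's reading of "heuristic
    knowledge of FR and CDR regions derived from the input model";
    every one of them is a deliberate, overridable choice.
    """

    bit_score_threshold: float = DEFAULT_BIT_THRESHOLD
    min_hit_span: int = MIN_HIT_SPAN
    max_hits: int = MAX_HITS
    #: score margin (bits) by which one of two conflicting hits must win
    merge_margin: float = 1.0
    #: fraction of each FR1-FR3 model column set the consensus must cover
    fr_coverage: float = 0.8
    #: model-column conservation above which a Cys anchor is checked
    anchor_conservation: float = 0.9
    #: minimum matched span (query residues) for a credible domain
    min_total_span: int = 20


@dataclass
class ConsensusNumbering:
    """Merged per-residue IMGT assignment for one query domain."""

    entries: list[tuple[int, ImgtLabel, str]]  # (query idx, label, residue)
    source_hits: list[DomainHit]
    model_name: str
    findings: list[str] = field(default_factory=list)

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.entries[0][0], self.entries[-1][0] + 1)


@dataclass
class RegionAnnotation:
    region: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    sequence: str

    @property
    def zero_length(self) -> bool:
        return self.start == self.end


@dataclass
class ConsensusReport:
    findings: list[tuple[str, str, bool]] = field(default_factory=list)
    # (code, message, fatal)

    @property
    def passed(self) -> bool:
        return not any(fatal for _, _, fatal in self.findings)

    @property
    def reject_reasons(self) -> list[str]:
        return [code for code, _, fatal in self.findings if fatal]


@dataclass
class AnnotationResult:
    query_id: str
    status: str  # "annotated" | "rejected"
    reject_reasons: list[str] = field(default_factory=list)
    model_name: str = ""
    bit_score: float = 0.0
    numbering: Optional[ConsensusNumbering] = None
    regions: list[RegionAnnotation] = field(default_factory=list)
    query_length: int = 0

    @property
    def annotated(self) -> bool:
        return self.status == "annotated"

    def region(self, name: str) -> Optional[RegionAnnotation]:
        for r in self.regions:
            if r.region == name:
                return r
        return None


def select_best_model(
    hits_by_model: dict[str, list[DomainHit]]
) -> Optional[str]:
    """Model whose best single hit scores highest.

    Ties break on total summed score, then lexically smallest name.
    Returns None when every hit list is empty.
    """
    best: Optional[str] = None
    best_key = None
    for name in sorted(hits_by_model):
        hits = hits_by_model[name]
        if not hits:
            continue
        key = (max(h.bit_score for h in hits),
               sum(h.bit_score for h in hits))
        if best_key is None or key > best_key:
            best, best_key = name, key
    return best


def _compatible(a: DomainHit, b: DomainHit) -> bool:
    """True if hit b can follow or precede hit a in one domain."""
    a_labels = a.labels
    b_labels = b.labels
    if not a_labels or not b_labels:
        return False
    if b.query_start >= a.query_end:
        return b_labels[0].key() > a_labels[-1].key()
    if a.query_start >= b.query_end:
        return a_labels[0].key() > b_labels[-1].key()
    return False


def _segment_score(
    entries: Sequence[tuple[int, ImgtLabel]],
    query: str,
    model: Optional[ProfileModel],
) -> float:
    """Emission log-odds (bits) of matched (query idx, label) pairs.

    Used to decide which of two conflicting hit segments is the real
    one; falls back to the segment length when no model is given.
    """
    if model is None:
        return float(len(entries))
    import math

    state_of = {lab.key(): j
                for j, lab in enumerate(model.column_positions)}
    alpha = get_alphabet(model.alphabet_size)
    bg = 1.0 / len(model.hmm.alphabet)
    total = 0.0
    for qi, lab in entries:
        j = state_of.get(lab.key())
        if j is None:
            continue
        res = reduce_sequence(
            query[qi] if query[qi] in AMINO_ACIDS else "X", alpha)
        s = model.hmm.symbol_index(res)
        if s is None:
            continue
        total += math.log2(model.hmm.match_emit[j, s] / bg)
    return total


def _trim_hit(hit: DomainHit, keep: set[tuple[int, int]]) -> \
        Optional[DomainHit]:
    """Hit restricted to match entries whose label key is in ``keep``.

    Inserts survive only between retained matches; returns None when no
    match entry survives.
    """
    path = []
    pending: list[tuple[int, str, Optional[ImgtLabel]]] = []
    for qi, kind, lab in hit.path:
        if kind != "match":
            pending.append((qi, kind, lab))
            continue
        if lab.key() in keep:
            if path:  # inserts before the first kept match are dropped
                path.extend(pending)
            pending = []
            path.append((qi, kind, lab))
        else:
            pending = []
    if not path:
        return None
    return DomainHit(
        model_name=hit.model_name,
        bit_score=hit.bit_score,
        query_start=path[0][0],
        query_end=path[-1][0] + 1,
        path=path,
    )


def _realign_window(
    model: ProfileModel,
    reduced: str,
    qlo: int,
    qhi: int,
    s_lo: int,
    s_hi: int,
) -> Optional[DomainHit]:
    """Best local alignment of query window [qlo, qhi) against the
    match-state range [s_lo, s_hi) of the model.

    Used after a reconciliation cut: trimming labels off a hit leaves
    the rest of its alignment distorted (the spurious segment may have
    dragged neighbouring residues with it), so the surviving window is
    re-aligned against only the surviving states.
    """
    from .hmm_engine import slice_profile, viterbi_local

    if qhi - qlo < 1 or s_hi - s_lo < 1:
        return None
    sub = slice_profile(model.hmm, s_lo, s_hi)
    masked = set(range(0, qlo)) | set(range(qhi, len(reduced)))
    res = viterbi_local(sub, reduced, masked)
    if res is None:
        return None
    score, raw = res
    path = [
        (i, kind,
         model.column_positions[s_lo + j] if kind == "match" else None)
        for i, kind, j in raw
    ]
    return DomainHit(
        model_name=model.name,
        bit_score=float(score),
        query_start=raw[0][0],
        query_end=raw[-1][0] + 1,
        path=path,
    )


def _reconcile(
    a: DomainHit,
    b: DomainHit,
    query: str,
    model: Optional[ProfileModel],
    reduced: Optional[str] = None,
) -> Optional[tuple[DomainHit, DomainHit]]:
    """Resolve a label-range conflict between query-disjoint hits.

    With iterative masking, two hits never overlap on the query; they
    conflict when their IMGT label ranges do — typically because one of
    them co-opted junction residues into a spurious anchor-side segment
    (a fake FR4 tail on the V hit, or a fake V tail on the J hit).  The
    conflicting label segments of both hits are scored by model
    emissions and the weaker one is trimmed away.  Returns the
    reconciled (a, b) in query order, or None if no consistent pair
    remains.
    """
    first, second = (a, b) if a.query_start <= b.query_start else (b, a)
    f_matches = [(qi, lab) for qi, kind, lab in first.path
                 if kind == "match"]
    s_matches = [(qi, lab) for qi, kind, lab in second.path
                 if kind == "match"]
    if not f_matches or not s_matches:
        return None
    s_min = min(lab.key() for _, lab in s_matches)
    f_max = max(lab.key() for _, lab in f_matches)
    if s_min > f_max:
        return first, second
    # Both hits claim the label interval [s_min, f_max].  Choose the cut
    # that maximises emission support: the first hit keeps its matches
    # below the cut, the second its matches at or above it.  A small
    # positional prior breaks exact emission ties (typically a junction
    # residue coincidentally matching an anchor column): V-domain labels
    # (<= 104) lean to the earlier hit, FR4 labels (>= 118) to the later
    # one, so junction material stays in CDR3.
    eps = 1e-3
    f_over = [(qi, lab) for qi, lab in f_matches if lab.key() >= s_min]
    s_over = [(qi, lab) for qi, lab in s_matches if lab.key() <= f_max]

    def weight(qi: int, lab: ImgtLabel, is_first: bool) -> float:
        w = _segment_score([(qi, lab)], query, model)
        if is_first and lab.position <= 104:
            w += eps
        if not is_first and lab.position >= 118:
            w += eps
        return w

    cut_keys = sorted({lab.key() for _, lab in f_over}
                      | {lab.key() for _, lab in s_over})
    sentinel = (f_max[0] + 1, 0)
    best_cut, best_score = None, None
    for cut in cut_keys + [sentinel]:
        total = sum(weight(qi, lab, True) for qi, lab in f_over
                    if lab.key() < cut)
        total += sum(weight(qi, lab, False) for qi, lab in s_over
                     if lab.key() >= cut)
        # Structural bonus: unmatched residues between the two hits must
        # be numbered between the flanking labels, and the only place a
        # long junction belongs is CDR3.  A cut whose flanks bracket the
        # 111/112 apex is strongly preferred over one that would strand
        # the junction inside a framework region — emission evidence
        # alone cannot decide this when a junction residue happens to
        # resemble an anchor-side column better than the real segment.
        f_kept = [(qi, lab) for qi, lab in f_matches if lab.key() < cut]
        s_kept = [(qi, lab) for qi, lab in s_matches if lab.key() >= cut]
        if f_kept and s_kept:
            f_last_qi, f_last_lab = max(f_kept, key=lambda e: e[0])
            s_first_qi, s_first_lab = min(s_kept, key=lambda e: e[0])
            gap_n = s_first_qi - f_last_qi - 1
            if gap_n > 0 and f_last_lab.position <= 111 \
                    and s_first_lab.position >= 112:
                total += 3.0
        if best_score is None or total > best_score:
            best_cut, best_score = cut, total
    if model is not None and reduced is not None:
        # Re-align each hit's window against only its retained states:
        # trimming alone leaves the rest of the alignment distorted when
        # the spurious segment dragged neighbouring residues with it.
        p = sum(1 for lab in model.column_positions
                if lab.key() < best_cut)
        K = len(model.column_positions)
        new_first = _realign_window(
            model, reduced, first.query_start, first.query_end, 0, p)
        new_second = _realign_window(
            model, reduced, second.query_start, second.query_end, p, K)
        if new_first is not None and new_second is not None and \
                _compatible(new_first, new_second):
            return new_first, new_second
    first = _trim_hit(first, {lab.key() for _, lab in f_matches
                              if lab.key() < best_cut})
    second = _trim_hit(second, {lab.key() for _, lab in s_matches
                                if lab.key() >= best_cut})
    if first is None or second is None:
        return None
    if _compatible(first, second):
        return first, second
    return None


def merge_hits(hits: Sequence[DomainHit], query: str,
               margin: float = 1.0,
               model: Optional[ProfileModel] = None,
               reduced: Optional[str] = None) -> ConsensusNumbering:
    """Merge same-model hits into one consensus IMGT numbering.

    Hits are admitted best-score first; a candidate must be compatible
    (query interval and IMGT label range both strictly on one side) with
    every previously accepted hit.  Query-disjoint hits whose label
    ranges clash are reconciled by trimming the weaker conflicting
    segment (scored by model emissions) — this is what rescues ultralong
    CDR3s whose junction residues were co-opted into a spurious anchor-
    side segment.  When two query-overlapping hits conflict and neither
    dominates by the merge margin, the earlier-starting one is kept and
    an ``ambiguous_merge`` finding recorded.  Query residues between
    accepted hits — and insert-state residues inside hits — receive gap
    labels: integer positions when available, CDR3 insertion codes when
    the span brackets the 111/112 apex.
    """
    if not hits:
        raise ValueError("merge_hits needs at least one hit")
    if model is not None and reduced is None:
        reduced = reduce_sequence(query, get_alphabet(model.alphabet_size))
    findings: list[str] = []
    ordered = sorted(hits, key=lambda h: (-h.bit_score, h.query_start))
    accepted: list[DomainHit] = [ordered[0]]
    for cand in ordered[1:]:
        conflicts = [h for h in accepted if not _compatible(h, cand)]
        disjoint = [h for h in conflicts
                    if h.query_end <= cand.query_start
                    or cand.query_end <= h.query_start]
        if conflicts and len(conflicts) == len(disjoint):
            ok = True
            cur = cand
            for h in list(conflicts):
                pair = _reconcile(h, cur, query, model, reduced)
                if pair is None:
                    ok = False
                    break
                new_h, cur = (pair if h.query_start <= cur.query_start
                              else (pair[1], pair[0]))
                accepted[accepted.index(h)] = new_h
            if ok and all(_compatible(h, cur) for h in accepted):
                accepted.append(cur)
                continue
            conflicts = [h for h in accepted if not _compatible(h, cand)]
            if not conflicts:
                accepted.append(cand)
                continue
        if not conflicts:
            accepted.append(cand)
            continue
        close = [h for h in conflicts if h.bit_score - cand.bit_score < margin]
        if close and all(cand.query_start < h.query_start for h in close):
            # ambiguity: neither dominates; prefer the earlier-starting
            findings.append("ambiguous_merge")
            for h in close:
                accepted.remove(h)
            if all(_compatible(h, cand) for h in accepted):
                accepted.append(cand)
            else:
                for h in close:
                    accepted.append(h)
                findings.pop()
    accepted.sort(key=lambda h: h.query_start)

    entries: list[tuple[int, ImgtLabel, str]] = []
    pending: list[int] = []  # query indices awaiting labels
    prev_label: Optional[ImgtLabel] = None

    def flush(next_label: Optional[ImgtLabel]) -> None:
        nonlocal pending
        if not pending:
            return
        if prev_label is None or next_label is None:
            # unlabelled run at the domain edge: cannot be numbered
            pending = []
            return
        labels = gap_labels(prev_label, next_label, len(pending))
        for qi, lab in zip(pending, labels):
            entries.append((qi, lab, query[qi]))
        pending = []

    last_end: Optional[int] = None
    for hit in accepted:
        if last_end is not None:
            pending.extend(range(last_end, hit.query_start))
        for qi, kind, lab in hit.path:
            if kind == "match":
                flush(lab)
                entries.append((qi, lab, query[qi]))
                prev_label = lab
            else:
                pending.append(qi)
        last_end = hit.query_end
    pending = []  # trailing inserts of the final hit stay unlabelled

    entries.sort(key=lambda e: e[0])
    return ConsensusNumbering(
        entries=entries,
        source_hits=accepted,
        model_name=accepted[0].model_name,
        findings=findings,
    )


def validate_consensus(
    cn: ConsensusNumbering,
    model: ProfileModel,
    config: AnnotatorConfig = AnnotatorConfig(),
) -> ConsensusReport:
    """Heuristic checks of a consensus against its source model.

    Fatal: broken IMGT order; FR1-FR3 coverage below the threshold or
    FR4 absent; matched span shorter than the minimum.  Warn only:
    missing Cys at IMGT 23/104 when the model itself conserves it —
    unusual species may lack them.  Deliberately absent: any upper bound
    on CDR3 length.
    """
    report = ConsensusReport()
    for f in cn.findings:
        report.findings.append((f, "conflicting hits of similar score",
                                False))
    labels = [lab for _, lab, _ in cn.entries]
    if not is_increasing(labels):
        report.findings.append(
            ("order", "IMGT labels are not strictly increasing", True))
    covered = {lab.key() for lab in labels}
    for region in ("FR1", "FR2", "FR3"):
        cols = [c for c, r in zip(model.column_positions, model.region_map)
                if r == region]
        if not cols:
            continue
        frac = sum(1 for c in cols if c.key() in covered) / len(cols)
        if frac < config.fr_coverage:
            report.findings.append((
                f"fr_coverage:{region}",
                f"{region} coverage {frac:.2f} below "
                f"{config.fr_coverage:.2f}",
                True,
            ))
    fr4_cols = {c.key() for c, r in
                zip(model.column_positions, model.region_map) if r == "FR4"}
    if fr4_cols and not (fr4_cols & covered):
        report.findings.append(
            ("fr_coverage:FR4", "no FR4 positions matched", True))
    by_label = {lab.key(): res for _, lab, res in cn.entries}
    for pos in (23, 104):
        cons = model.anchor_conservation.get(pos, 0.0)
        if cons >= config.anchor_conservation:
            got = by_label.get(ImgtLabel(pos).key())
            expected = reduce_sequence(
                "C", get_alphabet(model.alphabet_size))
            if got is not None and reduce_sequence(
                    got if got in AMINO_ACIDS else "X",
                    get_alphabet(model.alphabet_size)) != expected:
                report.findings.append((
                    f"anchor:{pos}",
                    f"expected Cys-class residue at IMGT {pos}, got {got}",
                    False,
                ))
    start, end = cn.query_span
    if end - start < config.min_total_span:
        report.findings.append((
            "short_domain",
            f"matched span {end - start} below {config.min_total_span}",
            True,
        ))
    return report


def extract_regions(
    cn: ConsensusNumbering, model: ProfileModel
) -> list[RegionAnnotation]:
    """Cut the seven FR/CDR regions out of the consensus numbering.

    Regions are contiguous runs of consensus entries grouped by the
    IMGT region of their label.  Empty regions are emitted zero-length
    at the boundary they would occupy, so downstream code always sees
    all seven in order.
    """
    by_region: dict[str, list[int]] = {r: [] for r in REGION_ORDER}
    for qi, lab, _ in cn.entries:
        by_region[region_of(lab)].append(qi)
    regions: list[RegionAnnotation] = []
    cursor = cn.entries[0][0]
    query_residues = {qi: res for qi, _, res in cn.entries}
    for region in REGION_ORDER:
        idxs = by_region[region]
        if idxs:
            start, end = min(idxs), max(idxs) + 1
            seq = "".join(query_residues.get(i, "") for i in range(start, end))
            regions.append(RegionAnnotation(region, start, end, seq))
            cursor = end
        else:
            regions.append(RegionAnnotation(region, cursor, cursor, ""))
    return regions


def annotate(
    query_id: str,
    sequence: str,
    models: Sequence[ProfileModel],
    config: AnnotatorConfig = AnnotatorConfig(),
) -> AnnotationResult:
    """Annotate one amino-acid sequence against a set of models."""
    seq = sequence.strip().upper()
    if not seq or any(ch not in _VALID_QUERY for ch in seq):
        return AnnotationResult(
            query_id=query_id, status="rejected",
            reject_reasons=["invalid_sequence"], query_length=len(seq))
    hits_by_model: dict[str, list[DomainHit]] = {}
    model_by_name = {m.name: m for m in models}
    for model in models:
        reduced = reduce_sequence(seq, get_alphabet(model.alphabet_size))
        hits_by_model[model.name] = align(
            model.hmm, reduced,
            column_positions=model.column_positions,
            model_name=model.name,
            bit_threshold=config.bit_score_threshold,
            min_span=config.min_hit_span,
            max_hits=config.max_hits,
        )
    chosen = select_best_model(hits_by_model)
    if chosen is None:
        return AnnotationResult(
            query_id=query_id, status="rejected",
            reject_reasons=["no_hit"], query_length=len(seq))
    model = model_by_name[chosen]
    hits = hits_by_model[chosen]
    reduced = reduce_sequence(seq, get_alphabet(model.alphabet_size))
    cn = merge_hits(hits, seq, margin=config.merge_margin, model=model,
                    reduced=reduced)
    # Two strong, non-mergeable consensi indicate a multi-domain query
    # (e.g. an scFv); this version annotates single domains only.
    rejected_hits = [h for h in hits if h not in cn.source_hits]
    span = cn.query_span
    for h in rejected_hits:
        outside = h.query_end <= span[0] or h.query_start >= span[1]
        strong = h.bit_score >= config.bit_score_threshold and \
            (h.query_end - h.query_start) >= config.min_total_span
        if outside and strong:
            return AnnotationResult(
                query_id=query_id, status="rejected",
                reject_reasons=["multiple_domains"],
                model_name=chosen, query_length=len(seq))
    report = validate_consensus(cn, model, config)
    if not report.passed:
        return AnnotationResult(
            query_id=query_id, status="rejected",
            reject_reasons=report.reject_reasons,
            model_name=chosen,
            bit_score=sum(h.bit_score for h in cn.source_hits),
            numbering=cn, query_length=len(seq))
    regions = extract_regions(cn, model)
    return AnnotationResult(
        query_id=query_id, status="annotated",
        model_name=chosen,
        bit_score=sum(h.bit_score for h in cn.source_hits),
        numbering=cn, regions=regions, query_length=len(seq))


# ---------------------------------------------------------------------------
# Batch annotation
# ---------------------------------------------------------------------------

_WORKER_STATE: dict = {}


def _worker_init(models: Sequence[ProfileModel],
                 config: AnnotatorConfig) -> None:
    _WORKER_STATE["models"] = models
    _WORKER_STATE["config"] = config


def _worker_run(item: tuple[str, str]) -> AnnotationResult:
    qid, seq = item
    try:
        return annotate(qid, seq, _WORKER_STATE["models"],
                        _WORKER_STATE["config"])
    except Exception:
        return AnnotationResult(query_id=qid, status="rejected",
                                reject_reasons=["internal_error"],
                                query_length=len(seq))


def annotate_batch(
    records: Iterable[tuple[str, str]],
    models: Sequence[ProfileModel],
    config: AnnotatorConfig = AnnotatorConfig(),
    n_workers: int = 1,
) -> Iterator[AnnotationResult]:
    """Annotate (id, sequence) pairs, preserving input order.

    Results are identical for any worker count: each record is an
    independent, deterministic computation.  A failure inside a worker
    rejects that record with reason ``internal_error`` and the batch
    continues.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    items = list(records)
    if n_workers == 1 or len(items) <= 1:
        for qid, seq in items:
            try:
                yield annotate(qid, seq, models, config)
            except Exception:
                yield AnnotationResult(
                    query_id=qid, status="rejected",
                    reject_reasons=["internal_error"],
                    query_length=len(seq))
        return
    chunk = max(1, len(items) // (n_workers * 4))
    with ProcessPoolExecutor(
        max_workers=n_workers,
        initializer=_worker_init,
        initargs=(list(models), config),
    ) as pool:
        yield from pool.map(_worker_run, items, chunksize=chunk)
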