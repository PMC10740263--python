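"""Profile HMM training and local Viterbi alignment.

The engine is a plain profile HMM in the Krogh/Durbin style: one match
state per well-occupied alignment column, with insert and delete states
between them, trained by counting with Laplace pseudocounts.  Search is
local (Smith-Waterman-like): a path enters the model at any match state
(uniform entry probability 1/K), traverses match/insert/delete states,
and exits from any match state with a fixed exit probability.  Scores
are log-odds against a uniform background over the model's (possibly
reduced) alphabet, reported in bits.

Multiple hits per query — the mechanism that lets a single domain with
an ultralong CDR3 be recovered from two partial alignments — come from
iterative masking: the best-scoring local path is reported, its query
interval is masked, and the search repeats until nothing clears the
reporting threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateModelError
from .imgt import ImgtLabel

LN2 = math.log(2.0)

#: Probability reserved for exiting the model from any internal match state.
EXIT_PROB = 0.05

#: Default reporting threshold in bits and minimum hit span in residues.
DEFAULT_BIT_THRESHOLD = 8.0
MIN_HIT_SPAN = 5
MAX_HITS = 4

#: Columns with at least this fraction of residues become match states.
MATCH_OCCUPANCY = 0.5

#: Extra M->I pseudocount at states flagged as numbering junctions
#: (consecutive match columns that skip IMGT positions, i.e. the CDR3
#: gap in a V+J model).  Insert runs then strictly prefer the junction
#: state over its neighbours, so junction residues that coincidentally
#: match an anchor column still land in CDR3 instead of displacing it.
JUNCTION_INSERT_PSEUDO = 4.0


@dataclass
class ProfileHMM:
    """A trained profile with local entry/exit.

    ``alphabet`` holds the emission symbols (group representatives when a
    reduced alphabet is in force).  All stored distributions sum to 1;
    pseudocounts keep every probability strictly positive.
    """

    alphabet: str
    n_match: int
    match_emit: np.ndarray  # (K, A) match emission probabilities
    insert_emit: np.ndarray  # (A,) insert emission probabilities
    t_mm: np.ndarray  # (K,) M_j -> M_{j+1}
    t_mi: np.ndarray  # (K,) M_j -> I_j
    t_md: np.ndarray  # (K,) M_j -> D_{j+1}
    t_me: np.ndarray  # (K,) M_j -> End
    t_im: np.ndarray  # (K,) I_j -> M_{j+1}
    t_ii: np.ndarray  # (K,) I_j -> I_j
    t_dm: np.ndarray  # (K,) D_j -> M_{j+1}
    t_dd: np.ndarray  # (K,) D_j -> D_{j+1}
    entry: np.ndarray = field(default=None)  # (K,) Begin -> M_j

    def __post_init__(self):
        if self.entry is None:
            self.entry = np.full(self.n_match, 1.0 / self.n_match)

    @property
    def background(self) -> np.ndarray:
        """Uniform background over the alphabet (the null model)."""
        a = len(self.alphabet)
        return np.full(a, 1.0 / a)

    def symbol_index(self, ch: str) -> Optional[int]:
        """Index of a residue in the alphabet; None for X (background)."""
        i = self.alphabet.find(ch)
        return None if i < 0 else i


@dataclass
class DomainHit:
    """One local alignment of a query against one model."""

    model_name: str
    bit_score: float
    query_start: int  # 0-based inclusive
    query_end: int  # 0-based exclusive
    #: ordered (query index, "match"|"insert", ImgtLabel or None)
    path: list[tuple[int, str, Optional[ImgtLabel]]]

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def labels(self) -> list[ImgtLabel]:
        return [lab for _, kind, lab in self.path if kind == "match"]


def train_profile(
    rows: Sequence[str],
    alphabet: str,
    match_columns: Optional[Sequence[bool]] = None,
    junction_states: Optional[set[int]] = None,
) -> tuple[ProfileHMM, list[int]]:
    """Train a profile from aligned, already alphabet-reduced rows.

    Parameters
    ----------
    rows:
        Equal-length aligned strings over ``alphabet`` plus ``-`` gaps.
    alphabet:
        Emission symbols (20 letters, or the reduced representatives).
    match_columns:
        Optional externally supplied match-column mask; by default
        columns with >= 50% residue occupancy become match states.
    junction_states:
        Match-state indices whose following insert state receives the
        junction pseudocount boost (see JUNCTION_INSERT_PSEUDO).

    Returns
    -------
    (profile, match_column_indices)
        The trained profile and the alignment-column index of each match
        state, so callers can map match states back to column metadata.

    Raises
    ------
    DegenerateModelError
        If no column qualifies as a match state.
    """
    if not rows:
        raise DegenerateModelError("empty alignment")
    ncol = len(rows[0])
    nrow = len(rows)
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows differ in length")
    a = len(alphabet)
    sym = {ch: i for i, ch in enumerate(alphabet)}

    occupancy = np.zeros(ncol)
    for r in rows:
        occupancy += np.frombuffer(r.encode(), dtype=np.uint8) != ord("-")
    occupancy /= nrow
    if match_columns is None:
        match_mask = occupancy >= MATCH_OCCUPANCY
    else:
        match_mask = np.asarray(match_columns, dtype=bool)
    match_cols = [c for c in range(ncol) if match_mask[c]]
    K = len(match_cols)
    if K == 0:
        raise DegenerateModelError("no column reaches match-state occupancy")

    # Emission counts with Laplace pseudocount 1.
    emit = np.ones((K, a))
    for r in rows:
        for j, c in enumerate(match_cols):
            ch = r[c]
            if ch == "-":
                continue
            idx = sym.get(ch)
            if idx is not None:  # X contributes nothing
                emit[j, idx] += 1.0
    match_emit = emit / emit.sum(axis=1, keepdims=True)
    insert_emit = np.full(a, 1.0 / a)

    # Transition counts.  Each row is decoded into its state path
    # (match/delete at match columns, insert at the others) and adjacent
    # state pairs are counted; Laplace pseudocount 1 on every allowed
    # move, then the fixed local exit probability is carved out of each
    # match state's distribution.
    c_mm = np.ones(K)
    c_mi = np.ones(K)
    c_md = np.ones(K)
    c_im = np.ones(K)
    c_ii = np.ones(K)
    c_dm = np.ones(K)
    c_dd = np.ones(K)
    col_state = {}  # column -> (kind, j)
    for j, c in enumerate(match_cols):
        col_state[c] = j
    for r in rows:
        prev = None  # ("M"|"I"|"D", j) with j = match-state index
        for c in range(ncol):
            if c in col_state:
                j = col_state[c]
                cur = ("M", j) if r[c] != "-" else ("D", j)
            else:
                if r[c] == "-":
                    continue
                cur = ("I", col_state_before(match_cols, c))
            if cur[0] == "I" and cur[1] < 0:
                prev = cur  # N-terminal insert: local model ignores it
                continue
            if prev is not None and prev[1] >= 0:
                pk, pj = prev
                ck, cj = cur
                if pk == "M" and ck == "M" and cj == pj + 1:
                    c_mm[pj] += 1
                elif pk == "M" and ck == "I" and cj == pj:
                    c_mi[pj] += 1
                elif pk == "M" and ck == "D" and cj == pj + 1:
                    c_md[pj] += 1
                elif pk == "I" and ck == "M" and cj == pj + 1:
                    c_im[pj] += 1
                elif pk == "I" and ck == "I" and cj == pj:
                    c_ii[pj] += 1
                elif pk == "D" and ck == "M" and cj == pj + 1:
                    c_dm[pj] += 1
                elif pk == "D" and ck == "D" and cj == pj + 1:
                    c_dd[pj] += 1
            prev = cur

    if junction_states:
        for j in junction_states:
            if 0 <= j < K - 1:
                c_mi[j] += JUNCTION_INSERT_PSEUDO

    tot_m = c_mm + c_mi + c_md
    t_mm = (1.0 - EXIT_PROB) * c_mm / tot_m
    t_mi = (1.0 - EXIT_PROB) * c_mi / tot_m
    t_md = (1.0 - EXIT_PROB) * c_md / tot_m
    # Exit mass is identical at every match state (the last state's
    # residual mass goes to exit too).  A uniform exit charge matters:
    # if ending at the final state were cheaper, paths would be bribed
    # into faking a C-terminal segment out of junction residues.
    t_me = np.full(K, EXIT_PROB)
    t_mm[K - 1] = 0.0
    t_mi[K - 1] = 0.0
    t_md[K - 1] = 0.0
    t_me[K - 1] = 1.0
    t_im = c_im / (c_im + c_ii)
    t_ii = c_ii / (c_im + c_ii)
    t_dm = c_dm / (c_dm + c_dd)
    t_dd = c_dd / (c_dm + c_dd)
    # Final delete state is a dead end; normalise it to exit-to-match so
    # distributions still sum to 1 (it is unreachable in scoring).
    t_dm[K - 1] = 1.0
    t_dd[K - 1] = 0.0

    profile = ProfileHMM(
        alphabet=alphabet,
        n_match=K,
        match_emit=match_emit,
        insert_emit=insert_emit,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_me=t_me,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
    )
    return profile, match_cols


def col_state_before(match_cols: list[int], c: int) -> int:
    """Index of the match state preceding column c, -1 if none."""
    # match_cols is sorted; linear scan is fine at profile sizes
    j = -1
    for k, mc in enumerate(match_cols):
        if mc < c:
            j = k
        else:
            break
    return j


def slice_profile(profile: ProfileHMM, start: int, stop: int) -> ProfileHMM:
    """Sub-profile over match states [start, stop).

    Local entry/exit and the flat exit charge make slicing consistent:
    a path through the sub-profile scores exactly as the corresponding
    path through the full profile (up to the uniform entry term).
    """
    if not (0 <= start < stop <= profile.n_match):
        raise ValueError("bad profile slice")
    K = stop - start
    sl = slice(start, stop)

    def cut(arr):
        a = arr[sl].copy()
        return a

    t_mm, t_mi, t_md = cut(profile.t_mm), cut(profile.t_mi), \
        cut(profile.t_md)
    t_me = cut(profile.t_me)
    t_mm[K - 1] = 0.0
    t_mi[K - 1] = 0.0
    t_md[K - 1] = 0.0
    t_me[K - 1] = 1.0
    return ProfileHMM(
        alphabet=profile.alphabet,
        n_match=K,
        match_emit=profile.match_emit[sl].copy(),
        insert_emit=profile.insert_emit.copy(),
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_me=t_me,
        t_im=cut(profile.t_im),
        t_ii=cut(profile.t_ii),
        t_dm=cut(profile.t_dm),
        t_dd=cut(profile.t_dd),
        entry=np.full(K, 1.0 / K),
    )


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def viterbi_local(
    profile: ProfileHMM,
    seq: str,
    masked: Optional[set[int]] = None,
) -> Optional[tuple[float, list[tuple[int, str, int]]]]:
    """Best local alignment of ``seq`` to the profile.

    Returns ``(bit_score, path)`` where path entries are
    (query index, "match"|"insert", match-state index or -1), or None if
    no path exists (e.g. everything masked).  Residues outside the path
    are free under the null model, so the score depends only on the
    aligned span.  ``masked`` query positions cannot be emitted by any
    state.
    """
    L = len(seq)
    K = profile.n_match
    if L == 0 or K == 0:
        return None
    masked = masked or set()

    bg = profile.background
    log_bg = _log(bg)
    log_me = _log(profile.match_emit)
    # per-position match emission log-odds; X or unknown -> 0 (background)
    E = np.zeros((L, K))
    ins_odds = np.zeros(L)
    log_ins = _log(profile.insert_emit)
    for i, ch in enumerate(seq):
        if i in masked:
            E[i, :] = -np.inf
            ins_odds[i] = -np.inf
            continue
        s = profile.symbol_index(ch)
        if s is None:
            E[i, :] = 0.0
            ins_odds[i] = 0.0
        else:
            E[i, :] = log_me[:, s] - log_bg[s]
            ins_odds[i] = log_ins[s] - log_bg[s]

    l_mm = _log(profile.t_mm)
    l_mi = _log(profile.t_mi)
    l_md = _log(profile.t_md)
    l_im = _log(profile.t_im)
    l_ii = _log(profile.t_ii)
    l_dm = _log(profile.t_dm)
    l_dd = _log(profile.t_dd)
    l_entry = _log(profile.entry)

    NEG = -np.inf
    VM = np.full((L, K), NEG)
    VI = np.full((L, K), NEG)
    VD = np.full((L, K), NEG)
    # traceback codes: M: 0 from I, 1 from M, 2 from D, 3 entry
    #                  I: 1 from M, 2 from I;  D: 1 from M, 3 from D
    # The candidate order at match cells is deliberate: on exact ties an
    # insert predecessor wins over a match predecessor, which pushes
    # insert runs as far C-terminal as possible — junction residues that
    # happen to match an anchor column stay in CDR3, per the IMGT
    # convention that junction material belongs to the CDR3 loop.
    PM = np.zeros((L, K), dtype=np.uint8)
    PI = np.zeros((L, K), dtype=np.uint8)
    PD = np.zeros((L, K), dtype=np.uint8)

    for i in range(L):
        # Match states.
        cand_entry = l_entry  # start a new path at residue i
        if i > 0:
            from_m = np.full(K, NEG)
            from_i = np.full(K, NEG)
            from_d = np.full(K, NEG)
            from_m[1:] = VM[i - 1, :-1] + l_mm[:-1]
            from_i[1:] = VI[i - 1, :-1] + l_im[:-1]
            from_d[1:] = VD[i - 1, :-1] + l_dm[:-1]
            stacked = np.stack([from_i, from_m, from_d, cand_entry])
            PM[i] = np.argmax(stacked, axis=0)
            VM[i] = E[i] + stacked[PM[i], np.arange(K)]
        else:
            VM[i] = E[i] + cand_entry
            PM[i] = 3
        # Insert states (emit residue i, stay at state j).
        if i > 0:
            from_m = VM[i - 1] + l_mi
            from_i = VI[i - 1] + l_ii
            better = from_i > from_m
            VI[i] = np.where(better, from_i, from_m) + ins_odds[i]
            PI[i] = np.where(better, 2, 1)
        # Delete chain at position i (consumes no residue).
        # VD[i, j] best path ending in D_j having just emitted residue i.
        vd = VD[i]
        for j in range(1, K):
            fm = VM[i, j - 1] + l_md[j - 1]
            fd = vd[j - 1] + l_dd[j - 1]
            if fm >= fd:
                vd[j] = fm
                PD[i, j] = 1
            else:
                vd[j] = fd
                PD[i, j] = 3

    # Exit only from match states, at a flat EXIT_PROB charge for every
    # state (t_me stores the bookkeeping distribution; the flat charge
    # keeps the final state from being a privileged free exit).
    end_scores = VM + math.log(EXIT_PROB)
    best_flat = int(np.argmax(end_scores))
    bi, bj = divmod(best_flat, K)
    best = end_scores[bi, bj]
    if not np.isfinite(best):
        return None

    # Traceback.
    path: list[tuple[int, str, int]] = []
    i, j, kind = bi, bj, "M"
    while True:
        if kind == "M":
            path.append((i, "match", j))
            code = PM[i, j]
            if code == 3:
                break
            if code == 0:
                i, j, kind = i - 1, j - 1, "I"
            elif code == 1:
                i, j, kind = i - 1, j - 1, "M"
            else:
                j, kind = j - 1, "D"
        elif kind == "I":
            path.append((i, "insert", j))
            code = PI[i, j]
            if code == 1:
                i, kind = i - 1, "M"
            else:
                i, kind = i - 1, "I"
        else:  # D
            code = PD[i, j]
            if code == 1:
                j, kind = j - 1, "M"
            else:
                j, kind = j - 1, "D"
    path.reverse()
    return best / LN2, path


def align(
    profile: ProfileHMM,
    seq: str,
    column_positions: Optional[Sequence[ImgtLabel]] = None,
    model_name: str = "",
    bit_threshold: float = DEFAULT_BIT_THRESHOLD,
    min_span: int = MIN_HIT_SPAN,
    max_hits: int = MAX_HITS,
) -> list[DomainHit]:
    """All significant non-overlapping local hits of ``seq``.

    Iterative masking: the best hit is found, its query interval masked,
    and search repeats (at most ``max_hits`` times) until the best
    remaining path scores below ``bit_threshold`` or spans fewer than
    ``min_span`` residues.  Hits are returned ordered by bit score,
    descending; their query intervals are pairwise disjoint.
    """
    hits: list[DomainHit] = []
    if not seq:
        return hits
    masked: set[int] = set()
    for _ in range(max_hits):
        res = viterbi_local(profile, seq, masked)
        if res is None:
            break
        score, raw_path = res
        qstart = raw_path[0][0]
        qend = raw_path[-1][0] + 1
        if score < bit_threshold or (qend - qstart) < min_span:
            break
        path = [
            (
                i,
                kind,
                column_positions[j]
                if (kind == "match" and column_positions is not None)
                else None,
            )
            for i, kind, j in raw_path
        ]
        hits.append(
            DomainHit(
                model_name=model_name,
                bit_score=float(score),
                query_start=qstart,
                query_end=qend,
                path=path,
            )
        )
        masked.update(range(qstart, qend))
        if len(masked) >= len(seq):
            break
    hits.sort(key=lambda h: (-h.bit_score, h.query_start))
    return hits


# ---------------------------------------------------------------------------
# Serialization: a self-describing text format that round-trips bit-exactly
# (floats stored via repr).
# ---------------------------------------------------------------------------

FORMAT_VERSION = "igannot-profile/1"


def dump_profile(profile: ProfileHMM) -> str:
    lines = [FORMAT_VERSION, f"alphabet {profile.alphabet}",
             f"n_match {profile.n_match}"]

    def row(tag, arr):
        lines.append(tag + " " + " ".join(repr(float(x)) for x in arr))

    for j in range(profile.n_match):
        row(f"match_emit {j}", profile.match_emit[j])
    row("insert_emit", profile.insert_emit)
    for tag in ("t_mm", "t_mi", "t_md", "t_me", "t_im", "t_ii",
                "t_dm", "t_dd", "entry"):
        row(tag, getattr(profile, tag))
    return "\n".join(lines) + "\n"


def load_profile(text: str) -> ProfileHMM:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != FORMAT_VERSION:
        raise ValueError("not an igannot profile file")
    alphabet = lines[1].split(" ", 1)[1]
    n_match = int(lines[2].split()[1])
    a = len(alphabet)
    match_emit = np.zeros((n_match, a))
    vectors: dict[str, np.ndarray] = {}
    for ln in lines[3:]:
        parts = ln.split()
        if parts[0] == "match_emit":
            j = int(parts[1])
            match_emit[j] = [float(x) for x in parts[2:]]
        else:
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return ProfileHMM(
        alphabet=alphabet,
        n_match=n_match,
        match_emit=match_emit,
        insert_emit=vectors["insert_emit"],
        t_mm=vectors["t_mm"],
        t_mi=vectors["t_mi"],
        t_md=vectors["t_md"],
        t_me=vectors["t_me"],
        t_im=vectors["t_im"],
        t_ii=vectors["t_ii"],
        t_dm=vectors["t_dm"],
        t_dd=vectors["t_dd"],
        entry=vectors["entry"],
    )
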