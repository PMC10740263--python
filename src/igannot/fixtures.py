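"""Synthetic germline sets and repertoires with exact region truth.

Everything the rest of the package needs for testing is generated here,
deterministically from a seed, with no external data.  The generator
states a simple world:

* V germlines are 96 residues covering IMGT 1..104 with a canonical
  26-residue FR1 (Cys at IMGT 23), an 8-residue CDR1, a 17-residue FR2
  (Trp at IMGT 41), a 6-residue CDR2 and a full 39-residue FR3 ending
  in the Cys at IMGT 104.
* J germlines are 11 residues covering FR4 exactly (IMGT 118..128),
  beginning with the conserved Trp.
* A read is V + junction insert + J: the insert is the entire CDR3.
  Point mutations (substitutions only, never at anchors) are applied
  after the truth coordinates are recorded.

Sequences within a set differ at ~10% of non-anchor positions, giving
the 70-90% pairwise identity typical of germline families.  What this
world deliberately lacks: insertions/deletions, somatic-hypermutation
hotspots, allelic ambiguity and nucleotide-level V(D)J junctions — a
green test here shows the machinery is exact, not that any real
repertoire will behave as cleanly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS
from .germline_model import GermlineSegment
from .seqio import SeqRecord, write_fasta

# V segment layout (0-based offsets within the 96-residue V).
V_FR1_LEN = 26
V_CDR1_LEN = 8
V_FR2_LEN = 17
V_CDR2_LEN = 6
V_FR3_LEN = 39
V_LEN = V_FR1_LEN + V_CDR1_LEN + V_FR2_LEN + V_CDR2_LEN + V_FR3_LEN  # 96
J_LEN = 11  # FR4: IMGT 118..128

#: anchor offsets within V: Cys23, Trp41, Cys104
V_ANCHORS = {22: "C", V_FR1_LEN + V_CDR1_LEN + 2: "W", V_LEN - 1: "C"}
J_ANCHOR = {0: "W"}

#: fraction of non-anchor positions mutated between family members
FAMILY_DIVERGENCE = 0.1

#: residues never placed at random V positions: in this world the only
#: Cys and Trp in a V germline are the conserved anchors (both residues
#: are rare and structurally constrained in real frameworks)
V_EXCLUDED = "CW"

# Each generator op draws from its own child of the user's seed, so
# e.g. make_germline_set(seed=1) and make_repertoire(..., seed=1) use
# independent streams: replaying one stream inside the other would
# plant germline-like substrings in the "random" CDR3 junctions.
_STREAM_GERMLINE = 0
_STREAM_REPERTOIRE = 1
_STREAM_CODONS = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SyntheticTruth:
    """Ground truth for one generated read."""

    read_id: str
    v_id: str
    j_id: str
    regions: list[tuple[str, int, int]]  # (region, start, end) 0-based
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    cdr3_insert_length: int = 0


def _random_protein(rng: np.random.Generator, n: int,
                    exclude: str = "") -> list[str]:
    pool = "".join(aa for aa in AMINO_ACIDS if aa not in exclude)
    return [pool[i] for i in rng.integers(0, len(pool), n)]


def _diversify(rng: np.random.Generator, template: list[str],
               anchors: dict[int, str], exclude: str = "") -> str:
    seq = list(template)
    for i in range(len(seq)):
        if i in anchors:
            continue
        if rng.random() < FAMILY_DIVERGENCE:
            choices = "".join(aa for aa in AMINO_ACIDS
                              if aa != seq[i] and aa not in exclude)
            seq[i] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def make_germline_set(
    seed: int, n_v: int, n_j: int, break_anchors: bool = False
) -> tuple[list[GermlineSegment], list[GermlineSegment]]:
    """Deterministic family of V and J germline segments.

    ``break_anchors=True`` replaces the Cys23 anchor in every V, to
    exercise anchor-based validation; by default anchors are invariant.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need n_v >= 1 and n_j >= 1")
    rng = _rng(seed, _STREAM_GERMLINE)
    v_template = _random_protein(rng, V_LEN, exclude=V_EXCLUDED)
    for off, res in V_ANCHORS.items():
        v_template[off] = res
    j_template = _random_protein(rng, J_LEN)
    for off, res in J_ANCHOR.items():
        j_template[off] = res
    v_list = []
    for k in range(n_v):
        seq = _diversify(rng, v_template, V_ANCHORS, exclude=V_EXCLUDED)
        if break_anchors:
            seq = "A" + seq[1:22] + "G" + seq[23:]
        v_list.append(GermlineSegment(id=f"V{k + 1}", kind="V", sequence=seq))
    j_list = []
    for k in range(n_j):
        seq = _diversify(rng, j_template, J_ANCHOR)
        j_list.append(GermlineSegment(id=f"J{k + 1}", kind="J", sequence=seq))
    return v_list, j_list


def _truth_regions(insert_len: int) -> list[tuple[str, int, int]]:
    b0 = 0
    b1 = V_FR1_LEN
    b2 = b1 + V_CDR1_LEN
    b3 = b2 + V_FR2_LEN
    b4 = b3 + V_CDR2_LEN
    b5 = b4 + V_FR3_LEN  # == V_LEN
    b6 = b5 + insert_len
    b7 = b6 + J_LEN
    return [
        ("FR1", b0, b1), ("CDR1", b1, b2), ("FR2", b2, b3),
        ("CDR2", b3, b4), ("FR3", b4, b5), ("CDR3", b5, b6),
        ("FR4", b6, b7),
    ]


def make_repertoire(
    germlines: tuple[Sequence[GermlineSegment], Sequence[GermlineSegment]],
    n_reads: int,
    cdr3_insert_range: tuple[int, int] = (0, 10),
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[SyntheticTruth]]:
    """Rearranged reads with region truth recorded before mutation.

    Each read concatenates a random V, a junction insert of uniform
    random length within ``cdr3_insert_range`` (residues uniform over
    the 20 amino acids), and a random J.  Substitutions are then applied
    at ``mutation_rate`` per position, never at the four anchors.
    """
    if not (0.0 <= mutation_rate <= 0.2):
        raise ValueError("mutation_rate must be within [0, 0.2]")
    lo, hi = cdr3_insert_range
    if lo < 0 or hi < lo:
        raise ValueError("bad cdr3_insert_range")
    v_list, j_list = germlines
    rng = _rng(seed, _STREAM_REPERTOIRE)
    reads: list[SeqRecord] = []
    truths: list[SyntheticTruth] = []
    width = max(4, len(str(n_reads)))
    for k in range(n_reads):
        v = v_list[rng.integers(0, len(v_list))]
        j = j_list[rng.integers(0, len(j_list))]
        ins_len = int(rng.integers(lo, hi + 1))
        insert = "".join(_random_protein(rng, ins_len))
        seq = list(v.sequence + insert + j.sequence)
        anchor_positions = set(V_ANCHORS) | {V_LEN + ins_len + off
                                             for off in J_ANCHOR}
        mutations: list[tuple[int, str, str]] = []
        if mutation_rate > 0:
            for i in range(len(seq)):
                if i in anchor_positions:
                    continue
                if rng.random() < mutation_rate:
                    old = seq[i]
                    choices = AMINO_ACIDS.replace(old, "")
                    new = choices[rng.integers(0, len(choices))]
                    seq[i] = new
                    mutations.append((i, old, new))
        read_id = f"R{k + 1:0{width}d}"
        reads.append(SeqRecord(
            id=read_id,
            description=f"{v.id}|{j.id} ins={ins_len} seed={seed}",
            sequence="".join(seq),
        ))
        truths.append(SyntheticTruth(
            read_id=read_id, v_id=v.id, j_id=j.id,
            regions=_truth_regions(ins_len),
            mutations=mutations,
            cdr3_insert_length=ins_len,
        ))
    return reads, truths


def encode_nucleotide(
    records: Sequence[SeqRecord], seed: int = 0
) -> list[SeqRecord]:
    """Back-translate amino-acid reads into nucleotide reads.

    One codon is chosen uniformly at random (seeded) among the standard
    synonymous codons of each residue, giving deterministic nucleotide
    input for the six-frame protocol.
    """
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for codons in by_aa.values():
        codons.sort()
    rng = _rng(seed, _STREAM_CODONS)
    out = []
    for rec in records:
        codons = []
        for aa in rec.sequence:
            options = by_aa[aa]
            codons.append(options[rng.integers(0, len(options))])
        out.append(SeqRecord(
            id=rec.id, description=rec.description,
            sequence="".join(codons), molecule="nucleotide",
        ))
    return out


def write_truth_bed(truths: Sequence[SyntheticTruth],
                    path: str | os.PathLike) -> None:
    """Region truth as BED6 (score 0, strand '+')."""
    with open(path, "w") as fh:
        for t in truths:
            for region, start, end in t.regions:
                fh.write(f"{t.read_id}\t{start}\t{end}\t{region}\t0\t+\n")


def write_fixture_set(
    out_dir: str | os.PathLike,
    seed: int,
    n_v: int,
    n_j: int,
    n_reads: int,
    cdr3_insert_range: tuple[int, int] = (0, 10),
    mutation_rate: float = 0.0,
) -> dict[str, Path]:
    """Generate and write v.fasta, j.fasta, reads.fasta, truth.bed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v_list, j_list = make_germline_set(seed, n_v, n_j)
    reads, truths = make_repertoire(
        (v_list, j_list), n_reads, cdr3_insert_range, mutation_rate,
        seed=seed,
    )
    paths = {
        "v": out / "v.fasta",
        "j": out / "j.fasta",
        "reads": out / "reads.fasta",
        "truth": out / "truth.bed",
    }
    write_fasta(
        [SeqRecord(g.id, f"seed={seed}", g.sequence) for g in v_list],
        paths["v"],
    )
    write_fasta(
        [SeqRecord(g.id, f"seed={seed}", g.sequence) for g in j_list],
        paths["j"],
    )
    write_fasta(reads, paths["reads"])
    write_truth_bed(truths, paths["truth"])
    return paths
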