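# Methods

This note documents the models, numerical choices and open design
decisions behind `igannot`, in the spirit of a statistical-software
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## IMGT numbering and regions

Positions 1–128 with the conserved anchors Cys 23, Trp 41, Cys 104 and
Trp/Phe 118. Region boundaries (inclusive): FR1 1–26, CDR1 27–38,
FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128. Loops
shorter than canonical lose positions middle-out: a loop of $n$
residues over $[lo, hi]$ keeps the first $\lceil n/2 \rceil$ positions
from $lo$ and the last $\lfloor n/2 \rfloor$ before $hi$. CDR3s longer
than 13 receive insertion codes 111.1, 111.2, … ascending then …,
112.2, 112.1 descending, added alternately starting at 112.1 (the 112
side gets the extra residue when the overflow is odd). The comparator
orders 111 < 111.1 < … < 112.2 < 112.1 < 112; insertions anywhere else
follow their base position. Labels are `(position, insert)` pairs;
all query coordinates are 0-based half-open everywhere except
human-readable log lines.

## Germline numbering

The model builder must assign IMGT positions to arbitrary user
germlines, which published descriptions of this tool family presuppose
but do not define. Convention adopted:

* **V segments** — find a (Cys, Trp, Cys) triplet with feasible
  spacing: ≤ 22 residues before the first Cys (FR1, right-aligned so
  the residue before Cys is position 22), 5–17 residues between Cys 23
  and Trp 41 (CDR1 length = that count − 5, gapped middle-out), 52–62
  residues between Trp 41 and Cys 104 (CDR2 length = count − 52; FR3
  must be complete), ≤ 13 residues after Cys 104 (a CDR3 stub,
  105, 106, …). Candidate triplets are searched preferring the longest
  FR1 prefix and the latest second Cys. A V segment with no feasible
  triplet is a build error naming the segment.
* **J segments** — the first Trp/Phe with at most 10 residues after it
  (and ≤ 12 before) becomes 118; preceding residues count back from
  117, following ones run 119…128.

Limitations: FR3 gaps (e.g. a missing position 73, seen in some real
V genes) are not representable; such segments are rejected rather than
silently misnumbered.

## Model alignment and profile HMM

One row per ordered (V, J) pair — residues placed in their labelled
columns, `-` elsewhere; columns sorted by the IMGT comparator. The
model deliberately contains no CDR3 material: junction diversity is
handled at annotation time, not baked into the profile.

Training (Krogh/Durbin-style, all counts + Laplace pseudocount 1):

* match states = columns with ≥ 50% residue occupancy;
* match emissions from column counts over the (possibly reduced)
  alphabet; insert emissions = uniform background;
* transitions counted from each row's decoded state path;
* **junction insert boost**: where consecutive match columns skip IMGT
  positions (104 → 118 in a V+J model), the M→I pseudocount is raised
  by 4. Rationale: real rearrangements put junction material exactly
  there; without the boost, a junction residue that happens to match an
  anchor column produces exact Viterbi ties in which CDR3 residues leak
  into FR3 or FR4.

Scoring: natural-log space throughout; bit score = log-odds against a
uniform background over the alphabet, divided by ln 2. Local alignment
enters any match state with probability $1/K$ and exits any match
state at a **flat** charge of 0.05 (the bookkeeping distribution stores
the residual mass at the final state, but scoring charges every exit
equally — a free exit at state $K$ would bribe paths into faking a
C-terminal segment out of junction residues). Viterbi ties prefer an
insert predecessor at match cells, pushing insert runs C-terminal, per
the IMGT convention that junction material belongs to CDR3.

Hit reporting: threshold 8 bits (keeps random 10-mers out while
admitting the ~11-residue J-side fragment, which scores ≈ 17–25 bits on
the synthetic families), minimum span 5 residues, at most 4 hits per
query via iterative masking. All three are configuration, not
constants of nature; the sources describing this tool family do not
state their values.

## Consensus merging

Hits are admitted best-score first; a candidate must sit strictly on
one side (in both query coordinates and IMGT labels) of every accepted
hit. Conflicts:

* **Query-overlapping hits** — higher score wins; if the margin is
  below 1 bit the earlier-starting hit is kept and an
  `ambiguous_merge` finding recorded.
* **Query-disjoint hits with clashing label ranges** — the common case
  for ultralong CDR3s: with 40–60 random junction residues to choose
  from, the V-side hit frequently extends into a spurious FR4 start
  and/or the J-side hit grows a spurious V tail (any residue matching
  an anchor-adjacent column suffices). Discarding a whole hit here
  destroys the annotation, so the label overlap is resolved by a cut:
  among all candidate cut labels, choose the one maximising summed
  emission support (first hit keeps matches below the cut, second hit
  keeps matches at or above it), with two corrections emission evidence
  alone cannot supply: a 10⁻³-bit positional prior (labels ≤ 104 lean
  to the earlier hit, ≥ 118 to the later) that decides exact emission
  ties, and a 3-bit structural bonus for cuts whose flanking labels
  bracket the 111/112 apex whenever unmatched residues lie between the
  hits — the junction has to be numbered between the flanks, and CDR3
  is the only region where a long junction belongs, even when a lucky
  junction residue resembles an anchor-side column better than the
  real segment does. Each hit's query window is then
  **re-aligned against only its retained states** (a sliced
  sub-profile; consistent because entry is uniform and exit flat),
  since trimming alone leaves distortions that the spurious segment
  dragged into the neighbouring alignment.

Residues between accepted hits, and insert-state residues inside hits,
receive gap labels: integer positions while available (ends inward),
CDR3 insertion codes when the gap brackets the 111/112 apex. Nothing
anywhere bounds CDR3 length.

## Validation heuristics

Derived from the input model, all configurable: (a) coverage ≥ 0.8 of
the model's match columns per FR1–FR3, FR4 present at all; (b) IMGT
labels strictly increasing (hard fail); (c) Cys expected at 23/104 when
the model column is ≥ 90% conserved — warn only, since unusual species
legitimately deviate; (d) matched span ≥ 20 residues (sequences much
shorter than a domain cannot be aligned meaningfully). A query may
contain one domain; a second strong, disjoint, non-mergeable consensus
rejects the read as `multiple_domains`.

## Reduced alphabets

The Li-Wang-Wang grouping family, sizes 3–20, stored as a nested merge
hierarchy (one merge per step down from 20 singletons). The rows widely
reproduced in the literature at sizes 2–5 are matched exactly; the
intermediate merge order follows the same hierarchy and is fixed in
`alphabet.py`. Group representative = first member of the listed group.
Models remember their alphabet size and reduce queries themselves, so
callers never pre-reduce (doing so anyway is a no-op, by idempotence).

## Synthetic data: the stated world

V germlines: 96 residues = FR1(26) + CDR1(8) + FR2(17) + CDR2(6) +
FR3(39), anchors fixed, other positions drawn uniformly from 18 amino
acids (no Cys/Trp: in this world the only C and W in a V segment are
the anchors — both are rare and structurally constrained in real
frameworks, and spurious ones would make anchor-triplet numbering
ambiguous). J germlines: 11 residues (FR4 exactly), leading Trp.
Family members diverge at 10% of non-anchor positions (pairwise
identity ≈ 70–90%). Reads = V + uniform-random junction insert +
J, truth recorded before seeded point substitutions (never at anchors).
Each generator operation draws from its own child stream of the seed
(`SeedSequence` spawn keys); sharing one stream would replay germline
randomness inside the "random" junction and plant germline-like
substrings there.

What the world lacks — indels, hypermutation hotspots, allelic
ambiguity, nucleotide-level V(D)J junctions, FR-length variation
between family members. A green suite therefore establishes that the
machinery (numbering, stitching, extraction) is exact under clean
conditions and degrades gracefully under substitutions; it does not
certify performance on real repertoires.

## Numerical and tie-break summary

* All probability math in natural logs; comparisons exact; oracle
  equivalence asserted to 10⁻⁶ bits.
* Profile serialization stores floats via `repr`, so a dump–load–dump
  cycle is byte-identical and model building is deterministic.
* Batch annotation is order-preserving and worker-count-invariant;
  each record is pure and failures reject only that record.
* BED output: 0-based half-open, score = clamped integer bit score,
  zero-length regions emitted at their boundary so all seven regions
  always appear.

## Known limitations

* Only one grouping is offered per alphabet size; the literature
  contains alternative tables at some sizes.
* FR3 must be complete in V germlines (see above).
* Multi-domain constructs (scFv) are rejected, not split.
* The hit threshold is calibrated for domain-scale queries; peptides
  shorter than ~20 residues are rejected by design.
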