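"""Grouping satellites into families by cyclic, strand-aware alignment.

Tandem-repeat units are equivalent under cyclic rotation and reverse
complement, so two satellites belong together when some rotation of one
unit (on either strand) aligns well to the other.  Pairwise scores are
Needleman-Wunsch global alignments (match +1, mismatch -1, gap -2),
normalised by the length of the shorter unit so that a perfect match of
the shorter sequence scores 1.0 and unrelated sequences score ~0.
Families are built by agglomerative average-linkage merging down to a
normalised-score threshold (0.6 by default) and named ``Fam_a_b_c``:
rank by member count, repeat size, member count.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from Bio import Align

from ._seq import reverse_complement, rotate
from .records import RepeatConsensus, SatelliteFamily, SatelliteRecord

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def satellite_consensus(record: SatelliteRecord) -> RepeatConsensus:
    """Majority-rule consensus over the satellite's modal-length copies."""
    full = [r for r in record.repeats if len(r) == record.repeat_length]
    if not full:
        full = [record.repeats[0][: record.repeat_length]]
    arr = np.frombuffer("".join(full).encode(), dtype="S1").reshape(
        len(full), record.repeat_length
    )
    cols = []
    for j in range(arr.shape[1]):
        vals, cnt = np.unique(arr[:, j], return_counts=True)
        cols.append(sorted(zip(vals, cnt), key=lambda vc: (-vc[1], vc[0]))[0][0].decode())
    return RepeatConsensus(record.id, "".join(cols))


def _best_rotation(a: str, b: str) -> tuple[float, str, int]:
    """Max raw NW score of *a* against every rotation of *b* on both strands.

    Ties break toward the smallest rotation index, then the forward strand.
    """
    best = (-np.inf, "+", 0)
    rc = reverse_complement(b)
    for r in range(len(b)):
        for strand, seq in (("+", b), ("-", rc)):
            s = _aligner.score(a, rotate(seq, r))
            if s > best[0]:
                best = (s, strand, r)
    return best


def cyclic_alignment_score(a: str, b: str) -> tuple[float, str, int]:
    """Normalised cyclic alignment score of two repeat units.

    Returns ``(score, strand, rotation)``: the raw global-alignment score
    maximised over all cyclic rotations of either sequence and over the
    reverse complement, divided by the length of the shorter unit and
    clamped to [0, 1].  ``strand``/``rotation`` describe the best frame of
    *b* relative to *a*.  The score is symmetric in its arguments;
    ``score(a, a) == 1.0``.
    """
    for s in (a, b):
        if not s or len(s) > 200:
            raise ValueError("repeat units must be 1-200 nt")
    raw_b, strand, rot = _best_rotation(a, b)
    raw_a, _, _ = _best_rotation(b, a)
    raw = max(raw_b, raw_a)
    return min(1.0, max(0.0, raw) / min(len(a), len(b))), strand, rot


def build_score_matrix(
    consensuses: list[RepeatConsensus],
    max_length_ratio: float = 0.25,
) -> tuple[list[str], np.ndarray]:
    """All-vs-all cyclic alignment scores with a unit-length pre-filter.

    Pairs whose unit lengths differ by more than ``max_length_ratio`` of
    the longer unit get score 0 without alignment.
    """
    n = len(consensuses)
    ids = [c.satellite_id for c in consensuses]
    scores = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            la, lb = consensuses[i].length, consensuses[j].length
            if abs(la - lb) > max_length_ratio * max(la, lb):
                continue
            scores[i, j] = scores[j, i] = cyclic_alignment_score(
                consensuses[i].sequence, consensuses[j].sequence
            )[0]
    return ids, scores


def progressive_cluster(
    ids: list[str],
    scores: np.ndarray,
    threshold: float = 0.6,
) -> list[list[int]]:
    """Agglomerative average-linkage clustering on a similarity matrix.

    Repeatedly joins the pair of clusters with the highest mean pairwise
    member score while that score is >= ``threshold``; ties break toward
    the smallest cluster indices.  Returns member indices per family.
    """
    clusters: list[list[int]] = [[i] for i in range(len(ids))]
    while len(clusters) > 1:
        best, bi, bj = -1.0, -1, -1
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                link = float(
                    np.mean(scores[np.ix_(clusters[i], clusters[j])])
                )
                if link > best + 1e-12:
                    best, bi, bj = link, i, j
        if best < threshold:
            break
        clusters[bi] = clusters[bi] + clusters[bj]
        del clusters[bj]
    return clusters


def family_consensus(members: list[RepeatConsensus]) -> str:
    """Consensus unit of a family: members rotated/flipped into the frame of
    the first member, then per-column majority over members of the modal
    length."""
    if len(members) == 1:
        return members[0].sequence
    frame = members[0].sequence
    oriented = [frame]
    for m in members[1:]:
        _, strand, rot = _best_rotation(frame, m.sequence)
        seq = m.sequence if strand == "+" else reverse_complement(m.sequence)
        oriented.append(rotate(seq, rot))
    lengths = Counter(len(s) for s in oriented)
    modal_len = min(lengths, key=lambda L: (-lengths[L], L))
    voting = [s for s in oriented if len(s) == modal_len]
    arr = np.frombuffer("".join(voting).encode(), dtype="S1").reshape(len(voting), modal_len)
    cols = []
    for j in range(modal_len):
        vals, cnt = np.unique(arr[:, j], return_counts=True)
        cols.append(sorted(zip(vals, cnt), key=lambda vc: (-vc[1], vc[0]))[0][0].decode())
    return "".join(cols)


def assign_family_names(
    families: list[SatelliteFamily],
    positions: dict[str, tuple[str, int]],
) -> list[SatelliteFamily]:
    """Rank families and attach Fam_a_b_c names.

    Rank a = 1..F by descending member count, ties by ascending repeat
    size then by genome position of the family's first member.
    """

    def first_pos(f: SatelliteFamily) -> tuple[str, int]:
        return min(positions[m] for m in f.members)

    ordered = sorted(
        families, key=lambda f: (-f.n_members_c, f.repeat_size_b, first_pos(f))
    )
    for rank, fam in enumerate(ordered, start=1):
        fam.rank_a = rank
        fam.name = f"Fam_{rank}_{fam.repeat_size_b}_{fam.n_members_c}"
    return ordered


def cluster_families(
    records: list[SatelliteRecord],
    threshold: float = 0.6,
    max_length_ratio: float = 0.25,
) -> list[SatelliteFamily]:
    """Full family pipeline: consensus, score matrix, clustering, naming.

    Also writes each record's ``family`` attribute in place.
    """
    consensuses = [satellite_consensus(r) for r in records]
    ids, scores = build_score_matrix(consensuses, max_length_ratio)
    groups = progressive_cluster(ids, scores, threshold)
    by_id = {c.satellite_id: c for c in consensuses}
    families = []
    for group in groups:
        members = [ids[i] for i in sorted(group)]
        cons = family_consensus([by_id[m] for m in members])
        families.append(SatelliteFamily(members=members, consensus=cons))
    positions = {r.id: (r.chrom, r.start) for r in records}
    families = assign_family_names(families, positions)
    fam_of = {m: f.name for f in families for m in f.members}
    for r in records:
        r.family = fam_of[r.id]
    return families


def families_to_frame(families: list[SatelliteFamily]):
    import pandas as pd

    return pd.DataFrame(
        {
            "family_name": [f.name for f in families],
            "rank": [f.rank_a for f in families],
            "repeat_size": [f.repeat_size_b for f in families],
            "n_members": [f.n_members_c for f in families],
            "member_ids": [",".join(f.members) for f in families],
            "consensus": [f.consensus for f in families],
        }
    )
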