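"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration or full dynamic
programming, sharing no code path with the pipeline implementation it
checks (beyond third-party primitives used in a different way).
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import edlib
import numpy as np
from Bio import Align

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def primitive_brute(kmer: str) -> bool:
    """Try literally every candidate period against the string."""
    k = len(kmer)
    for p in range(1, k // 2 + 1):
        if k % p == 0:
            if all(kmer[i] == kmer[i % p] for i in range(k)):
                return False
    return True


def census_regions(
    seq: str, k: int = 10, min_copies: int = 4, window_nt: int = 800
) -> set[tuple[int, int]]:
    """Exhaustive decamer-position census of candidate regions.

    Every primitive k-mer's occurrence list is scanned for windows of
    ``min_copies`` consecutive occurrences spanning <= ``window_nt``;
    flagged occurrences form runs (broken at gaps > window_nt), runs
    become intervals, and overlapping intervals merge.
    """
    pos = defaultdict(list)
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km and primitive_brute(km):
            pos[km].append(i)
    intervals = []
    for km, ps in pos.items():
        flagged = set()
        for j in range(len(ps) - min_copies + 1):
            if ps[j + min_copies - 1] + k - ps[j] <= window_nt:
                flagged.update(range(j, j + min_copies))
        run = []
        for i in range(len(ps) + 1):
            if i < len(ps) and i in flagged:
                if run and ps[i] - run[-1] > window_nt:
                    intervals.append((run[0], run[-1] + k))
                    run = []
                run.append(ps[i])
            elif run:
                intervals.append((run[0], run[-1] + k))
                run = []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return {(s, e) for s, e in merged}


def mean_pairwise_identity(copies: list[str]) -> float:
    """All-pairs position-wise identity by direct double loop."""
    total = 0.0
    pairs = list(itertools.combinations(copies, 2))
    for a, b in pairs:
        total += sum(1 for x, y in zip(a, b) if x == y and x != "N") / len(a)
    return total / len(pairs)


_oracle_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def cyclic_score_brute(a: str, b: str) -> float:
    """Exhaustive rotation x strand x argument-order maximum, normalised."""
    best = -np.inf
    for x, y in ((a, b), (b, a)):
        for strand_seq in (y, revcomp(y)):
            for r in range(len(strand_seq)):
                rot = strand_seq[r:] + strand_seq[:r]
                best = max(best, _oracle_aligner.score(x, rot))
    return min(1.0, max(0.0, best) / min(len(a), len(b)))


def average_linkage_brute(scores: np.ndarray, threshold: float) -> set[frozenset[int]]:
    """Plain agglomerative average linkage run to the same threshold."""
    clusters = [{i} for i in range(len(scores))]
    while len(clusters) > 1:
        best, pair = -1.0, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                link = np.mean(
                    [scores[a, b] for a in clusters[i] for b in clusters[j]]
                )
                if link > best + 1e-12:
                    best, pair = link, (i, j)
        if best < threshold:
            break
        i, j = pair
        clusters[i] |= clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def match_reads_full_dp(
    reads: list[tuple[str, str]],
    windows,
    min_identity: float = 0.97,
    min_cov: float = 0.9,
) -> set[tuple[str, str]]:
    """Retained (read_id, satellite_id) pairs by aligning every read
    against every window on both strands — no seeding."""
    retained = set()
    for rid, seq in reads:
        for oriented in (seq, revcomp(seq)):
            for w in windows:
                res = edlib.align(oriented, w.sequence, mode="HW", task="path")
                if res["editDistance"] < 0 or not res["locations"]:
                    continue
                matches = cols = 0
                num = ""
                for ch in res["cigar"]:
                    if ch.isdigit():
                        num += ch
                    else:
                        n = int(num)
                        num = ""
                        cols += n
                        if ch == "=":
                            matches += n
                t0, t1 = res["locations"][0]
                if matches / cols >= min_identity and (t1 - t0 + 1) >= min_cov * len(seq):
                    retained.add((rid, w.satellite_id))
    return retained


def stack_coverage(length: int, spans: list[tuple[int, int]]) -> np.ndarray:
    """O(hits x positions) depth count: +1 on every covered position."""
    depth = np.zeros(length, dtype=int)
    for s, e in spans:  # e inclusive
        for p in range(s, e + 1):
            depth[p] += 1
    return depth
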