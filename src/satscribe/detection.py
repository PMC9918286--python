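"""Tandem-repeat satellite detection.

The search follows a seed-cluster strategy: every *primitive* decamer
(one that is not itself a whole-number tandem of a shorter unit) whose
occurrences recur at least ``min_copies`` times within a sliding window of
``window_nt`` bases seeds a candidate region.  Overlapping candidates are
merged, the repeat-unit length is inferred from the modal spacing between
consecutive seed occurrences, array boundaries are refined by consensus
extension plus base-level periodicity trimming, and arrays whose copies are
too irregular (fewer than 60% of copies sharing the modal length, by
default) are discarded.

With the default parameters (decamer seeds, >= 4 copies, 800-nt windows)
the detectable repeat units span 10-200 nt with no upper limit on copy
number.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict

import numpy as np

from ._seq import DNA_ALPHABET, identity
from .records import CandidateRegion, SatelliteRecord, SeedCluster

UNIT_MIN = 10
UNIT_MAX = 200


def is_primitive_kmer(kmer: str) -> bool:
    """True iff *kmer* is not an exact whole-number tandem of a shorter unit.

    Only periods ``p <= len(kmer) / 2`` that divide the k-mer length can tile
    it; for decamers these are p in {1, 2, 5}.
    """
    k = len(kmer)
    if k != 10:
        raise ValueError(f"expected a 10-mer, got length {k}")
    if not set(kmer) <= DNA_ALPHABET:
        raise ValueError(f"non-DNA characters in k-mer {kmer!r}")
    for p in range(1, k // 2 + 1):
        if k % p == 0 and kmer == kmer[:p] * (k // p):
            return False
    return True


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            pos[kmer].append(i)
    return pos


def find_seed_clusters(
    chrom: str,
    seq: str,
    k: int = 10,
    min_copies: int = 4,
    window_nt: int = 800,
) -> list[SeedCluster]:
    """Locate every maximal cluster of a recurring primitive k-mer.

    An occurrence is clustered when some window of ``window_nt`` bases holds
    it together with at least ``min_copies - 1`` other occurrences of the
    same k-mer; maximal runs of clustered occurrences form one SeedCluster.
    k-mers containing N never seed.
    """
    if window_nt < k * min_copies:
        raise ValueError("window_nt must be at least k * min_copies")
    clusters: list[SeedCluster] = []
    for kmer, positions in _kmer_positions(seq, k).items():
        n = len(positions)
        if n < min_copies:
            continue
        if not is_primitive_kmer(kmer):
            continue
        # occurrence i is "in" iff a window of min_copies consecutive
        # occurrences containing i spans <= window_nt bases
        flagged = [False] * n
        for j in range(n - min_copies + 1):
            if positions[j + min_copies - 1] + k - positions[j] <= window_nt:
                for t in range(j, j + min_copies):
                    flagged[t] = True
        run: list[int] = []
        for i in range(n + 1):
            # a run breaks on an unflagged occurrence or a gap wider than the
            # window (identical units elsewhere in the genome seed their own
            # clusters)
            if i < n and flagged[i]:
                if run and positions[i] - run[-1] > window_nt:
                    clusters.append(
                        SeedCluster(chrom, run[0], run[-1] + k, kmer, list(run))
                    )
                    run = []
                run.append(positions[i])
            elif run:
                clusters.append(
                    SeedCluster(chrom, run[0], run[-1] + k, kmer, list(run))
                )
                run = []
    clusters.sort(key=lambda c: (c.window_start, c.window_end))
    return clusters


def merge_seed_clusters(clusters: list[SeedCluster]) -> list[CandidateRegion]:
    """Union overlapping seed clusters (any k-mer) into candidate regions."""
    regions: list[CandidateRegion] = []
    for cl in sorted(clusters, key=lambda c: (c.chrom, c.window_start, c.window_end)):
        if (
            regions
            and regions[-1].chrom == cl.chrom
            and cl.window_start < regions[-1].end
        ):
            last = regions[-1]
            last.end = max(last.end, cl.window_end)
            last.clusters.append(cl)
        else:
            regions.append(
                CandidateRegion(cl.chrom, cl.window_start, cl.window_end, [cl])
            )
    return regions


def _modal_unit_length(spacings: list[int]) -> int | None:
    counts = Counter(s for s in spacings if s >= 2)
    if not counts:
        return None
    # ties broken toward the smaller unit length
    return min(counts, key=lambda s: (-counts[s], s))


_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# boundary refinement constants: stop extending once the trailing
# _STOP_WINDOW bases carry >= _STOP_MISMATCHES consensus mismatches
# (never triggered by the divergence tolerated inside an array, always
# triggered within ~a dozen bases of random flank), then trim back to an
# anchor run of _ANCHOR_RUN consecutive consensus matches (chance
# probability 4^-8 per flank position).
_STOP_WINDOW = 12
_STOP_MISMATCHES = 7
_ANCHOR_RUN = 8


class _RunningConsensus:
    """Per-column base counts of unit-length copies, majority-rule readout."""

    def __init__(self, unit: int) -> None:
        self.counts = np.zeros((unit, 4), dtype=np.int32)
        self.unit = unit

    def add(self, copy: str) -> None:
        for j, c in enumerate(copy):
            i = _BASE_INDEX.get(c)
            if i is not None:
                self.counts[j, i] += 1

    def consensus(self) -> str:
        # argmax takes the first maximum, i.e. ties break alphabetically
        return "".join(_BASES[i] for i in np.argmax(self.counts, axis=1))


def delimit_satellite(
    region: CandidateRegion,
    seq: str,
    extension_min_identity: float = 0.7,
) -> SatelliteRecord | None:
    """Resolve a candidate region into a tandem array, or reject it.

    The unit length is the modal spacing between consecutive occurrences of
    the clustered k-mers.  Starting from the densest seed, unit-length
    windows are annexed left and right while they match the running
    majority-rule consensus at ``extension_min_identity`` or better.  Each
    boundary is then refined at base resolution: extend while the local
    neighbourhood still matches the consensus (stopping once the trailing
    12 bases carry 7+ mismatches, the signature of random flank), trim back
    to the last run of 8 consecutive consensus matches, and finally take
    single matching bases.  On a perfect array this lands exactly on the
    edge of the tandem span; under per-base noise it stays within a few
    bases of it.  Returns None when the inferred unit is outside [10, 200]
    nt or fewer than four copies remain.
    """
    unit = _modal_unit_length(region.spacings)
    if unit is None or not (UNIT_MIN <= unit <= UNIT_MAX):
        return None

    # anchor at the first occurrence that starts a modal-spacing pair; a
    # stray off-array occurrence of a unit k-mer must never anchor the core
    a0 = None
    for cl in sorted(region.clusters, key=lambda c: -len(c.positions)):
        ps = cl.positions
        for i in range(len(ps) - 1):
            if ps[i + 1] - ps[i] == unit:
                a0 = ps[i]
                break
        if a0 is not None:
            break
    if a0 is None:
        a0 = max(region.clusters, key=lambda c: len(c.positions)).positions[0]
    n = len(seq)
    if a0 + unit > n:
        return None

    rc = _RunningConsensus(unit)
    rc.add(seq[a0 : a0 + unit])
    start, end = a0, a0 + unit
    # annex whole units rightwards then leftwards against the consensus
    while end + unit <= n:
        cand = seq[end : end + unit]
        if identity(cand, rc.consensus()) < extension_min_identity:
            break
        rc.add(cand)
        end += unit
    while start - unit >= 0:
        cand = seq[start - unit : start]
        if identity(cand, rc.consensus()) < extension_min_identity:
            break
        rc.add(cand)
        start -= unit

    cons = rc.consensus()

    def cons_at(i: int) -> str:
        return cons[(i - a0) % unit]

    def match(i: int) -> bool:
        return seq[i] == cons_at(i) != "N"

    # ---- right boundary ----
    e = end
    hist = [not match(i) for i in range(max(start, e - _STOP_WINDOW), e)]
    while e < n:
        if len(hist) >= _STOP_WINDOW and sum(hist[-_STOP_WINDOW:]) >= _STOP_MISMATCHES:
            break
        hist.append(not match(e))
        e += 1
    while e > start + unit:
        if e - _ANCHOR_RUN >= start and all(
            match(i) for i in range(e - _ANCHOR_RUN, e)
        ):
            break
        e -= 1
    while e < n and match(e):
        e += 1
    end = e

    # ---- left boundary ----
    s = start
    hist = [not match(i) for i in range(s, min(end, s + _STOP_WINDOW))][::-1]
    while s > 0:
        if len(hist) >= _STOP_WINDOW and sum(hist[-_STOP_WINDOW:]) >= _STOP_MISMATCHES:
            break
        hist.append(not match(s - 1))
        s -= 1
    while s < end - unit:
        if s + _ANCHOR_RUN <= end and all(match(i) for i in range(s, s + _ANCHOR_RUN)):
            break
        s += 1
    while s > 0 and match(s - 1):
        s -= 1
    start = s

    span = end - start
    n_full = span // unit
    if n_full < 4:
        return None
    # partition: tile unit-length copies from the left edge; a remainder
    # shorter than half a unit is absorbed into the last copy, a longer one
    # stands as its own (short) copy
    remainder = span - n_full * unit
    copies = [seq[start + j * unit : start + (j + 1) * unit] for j in range(n_full)]
    if remainder:
        tail = seq[start + n_full * unit : end]
        if remainder < unit / 2:
            copies[-1] = copies[-1] + tail
        else:
            copies.append(tail)

    same_len = sum(1 for c in copies if len(c) == unit)
    return SatelliteRecord(
        chrom=region.chrom,
        start=start,
        end=end,
        repeat_length=unit,
        repeats=copies,
        similarity=repeat_similarity(copies, unit),
        same_length_frac=same_len / len(copies),
    )


def repeat_similarity(repeats: list[str], repeat_length: int) -> float:
    """Mean pairwise ungapped identity over copies of the modal length.

    Copies of any other length are excluded; with fewer than two same-length
    copies the statistic is undefined and reported as NaN.
    """
    full = [r for r in repeats if len(r) == repeat_length]
    m = len(full)
    if m < 2:
        return math.nan
    arr = np.frombuffer("".join(full).encode(), dtype="S1").reshape(m, repeat_length)
    n_pairs = m * (m - 1) // 2
    match_pairs = 0.0
    for j in range(repeat_length):
        vals, cnt = np.unique(arr[:, j], return_counts=True)
        for v, c in zip(vals, cnt):
            if v != b"N":
                match_pairs += c * (c - 1) / 2
    return match_pairs / (n_pairs * repeat_length)


def filter_satellites(
    records: list[SatelliteRecord],
    min_same_length_frac: float = 0.6,
) -> list[SatelliteRecord]:
    """Apply the regularity filter and sort by genomic position."""
    kept = [
        r
        for r in records
        if r.same_length_frac >= min_same_length_frac
        and r.n_repeats >= 4
        and UNIT_MIN <= r.repeat_length <= UNIT_MAX
    ]
    kept.sort(key=lambda r: (r.chrom, r.start))
    return kept


def _dedup_overlapping(records: list[SatelliteRecord]) -> list[SatelliteRecord]:
    # keep the longer span when two delimited arrays overlap
    out: list[SatelliteRecord] = []
    for r in sorted(records, key=lambda r: (r.chrom, r.start, -(r.end - r.start))):
        if out and out[-1].chrom == r.chrom and r.start < out[-1].end:
            if r.length_nt > out[-1].length_nt:
                out[-1] = r
        else:
            out.append(r)
    return out


def detect_satellites(
    genome: dict[str, str],
    k: int = 10,
    min_copies: int = 4,
    window_nt: int = 800,
    min_same_length_frac: float = 0.6,
    extension_min_identity: float = 0.7,
) -> list[SatelliteRecord]:
    """Run the full detection pipeline over a genome (dict chrom -> seq)."""
    records: list[SatelliteRecord] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        clusters = find_seed_clusters(chrom, seq, k, min_copies, window_nt)
        for region in merge_seed_clusters(clusters):
            rec = delimit_satellite(region, seq, extension_min_identity)
            if rec is not None:
                records.append(rec)
    records = _dedup_overlapping(records)
    return filter_satellites(records, min_same_length_frac)
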