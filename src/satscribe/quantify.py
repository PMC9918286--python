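"""RNA-seq quantification of satellite transcription.

Reads are matched against satellite reference windows (the satellite span
plus up to 250 nt of flank each side, which absorbs edge artifacts) by a
seed-and-extend strategy: exact 12-mer seeds nominate candidate windows,
then a banded semi-global alignment (edlib, whole read aligned inside the
window) scores each candidate.  Hits are kept at >= 97% identity over the
alignment (gaps count against identity) and, per read, only the hit or
hits tied at the maximum identity contribute a count — a read matching
several near-identical family members equally well counts once for each,
since it cannot be attributed to one of them.

Per-sample expression is RPKM = hits * 1e9 / (satellite length in nt) /
(library size in reads); tissue-level values are the *sums* over the
tissue's samples (hits summed, RPKM summed), and a satellite counts as
positively transcribed in a tissue when its tissue RPKM exceeds that
tissue's mean over all satellites.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._seq import reverse_complement
from .records import ReadHit, ReferenceWindow, SampleMeta, SatelliteRecord

SEED_SIZE = 12


def build_reference_windows(
    sats: list[SatelliteRecord],
    genome: dict[str, str],
    flank_nt: int = 250,
) -> list[ReferenceWindow]:
    """One window per satellite: span +- flank, clipped at contig ends."""
    windows = []
    for s in sats:
        if s.chrom not in genome:
            raise ValueError(f"satellite {s.id}: chromosome {s.chrom!r} not in genome")
        seq = genome[s.chrom]
        if s.end > len(seq):
            raise ValueError(f"satellite {s.id} extends past the end of {s.chrom}")
        start = max(0, s.start - flank_nt)
        end = min(len(seq), s.end + flank_nt)
        windows.append(
            ReferenceWindow(
                satellite_id=s.id,
                chrom=s.chrom,
                start=start,
                end=end,
                sat_start=s.start,
                sat_end=s.end,
                sequence=seq[start:end],
            )
        )
    return windows


class WindowIndex:
    """Exact 12-mer seed index over a set of reference windows."""

    def __init__(self, windows: list[ReferenceWindow], seed_size: int = SEED_SIZE):
        self.windows = windows
        self.seed_size = seed_size
        self.seeds: dict[str, set[int]] = defaultdict(set)
        for wi, w in enumerate(windows):
            for i in range(len(w.sequence) - seed_size + 1):
                kmer = w.sequence[i : i + seed_size]
                if "N" not in kmer:
                    self.seeds[kmer].add(wi)

    def candidates(self, read: str) -> set[int]:
        out: set[int] = set()
        for i in range(len(read) - self.seed_size + 1):
            hit = self.seeds.get(read[i : i + self.seed_size])
            if hit:
                out |= hit
        return out


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an edlib extended cigar."""
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def _align(read: str, window: ReferenceWindow, strand: str) -> ReadHit | None:
    res = edlib.align(read, window.sequence, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t_start, t_end = res["locations"][0]
    matches, columns = _cigar_stats(res["cigar"])
    flank_only = (
        t_end < window.sat_start - window.start
        or t_start > window.sat_end - window.start - 1
    )
    return ReadHit(
        read_id="",
        satellite_id=window.satellite_id,
        identity=matches / columns,
        matches=matches,
        columns=columns,
        target_start=t_start,
        target_end=t_end,
        strand=strand,
        flank_only=flank_only,
    )


def match_read(
    read: str,
    windows: list[ReferenceWindow] | WindowIndex,
    min_identity: float = 0.97,
    min_cov: float = 0.9,
    read_id: str = "",
) -> list[ReadHit]:
    """Align one read (both orientations) against the candidate windows.

    Retains hits with identity >= ``min_identity`` over the aligned region
    and aligned span >= ``min_cov`` of the read length.  At most one hit
    per window is returned (the better orientation).
    """
    index = windows if isinstance(windows, WindowIndex) else WindowIndex(windows)
    rc = reverse_complement(read)
    best_per_window: dict[int, ReadHit] = {}
    for strand, oriented in (("+", read), ("-", rc)):
        for wi in index.candidates(oriented):
            hit = _align(oriented, index.windows[wi], strand)
            if hit is None:
                continue
            if hit.identity < min_identity or hit.aligned_length < min_cov * len(read):
                continue
            prev = best_per_window.get(wi)
            if prev is None or hit.identity > prev.identity:
                hit.read_id = read_id
                best_per_window[wi] = hit
    return [best_per_window[wi] for wi in sorted(best_per_window)]


def assign_best_hits(hits: list[ReadHit]) -> list[ReadHit]:
    """Keep only the hit(s) of one read tied at the maximum identity.

    A read matching several windows equally well (identical family
    members) contributes one count to each of them.
    """
    if not hits:
        return []
    best = max(h.identity for h in hits)
    return [h for h in hits if h.identity >= best - 1e-9]


def rpkm(hits: int, satellite_length_nt: int, total_reads: int) -> float:
    """hits * 1e9 / satellite length / library size."""
    if satellite_length_nt <= 0:
        raise ValueError("satellite length must be positive")
    if total_reads <= 0:
        raise ValueError("library size must be positive")
    return hits * 1e9 / satellite_length_nt / total_reads


@dataclass
class HitTable:
    """Per-satellite x per-sample counts plus tissue-level summaries."""

    counts: pd.DataFrame          # satellites x samples, int hit counts
    sample_rpkm: pd.DataFrame     # satellites x samples
    samples: list[SampleMeta]
    hits: dict[str, list[ReadHit]] = field(default_factory=dict)  # per satellite
    tissue_counts: pd.DataFrame | None = None
    tissue_rpkm: pd.DataFrame | None = None
    transcribed: pd.DataFrame | None = None


def count_hits(
    reads_per_sample: dict[str, list[tuple[str, str]]],
    windows: list[ReferenceWindow],
    samples: list[SampleMeta],
    sat_lengths: dict[str, int],
    min_identity: float = 0.97,
    min_cov: float = 0.9,
    keep_hits: bool = False,
) -> HitTable:
    """Match every sample's reads and tabulate per-satellite counts.

    ``reads_per_sample`` maps sample_id -> [(read_id, sequence), ...];
    library size defaults to the number of reads supplied unless the
    sample metadata carries an explicit ``total_reads``.
    """
    index = WindowIndex(windows)
    sat_ids = [w.satellite_id for w in windows]
    counts = pd.DataFrame(
        0, index=sat_ids, columns=[s.sample_id for s in samples], dtype=int
    )
    per_sat_hits: dict[str, list[ReadHit]] = defaultdict(list)
    for meta in samples:
        reads = reads_per_sample[meta.sample_id]
        if meta.total_reads <= 0:
            meta.total_reads = len(reads)
        for rid, seq in reads:
            hits = assign_best_hits(
                match_read(seq, index, min_identity, min_cov, read_id=rid)
            )
            for h in hits:
                counts.loc[h.satellite_id, meta.sample_id] += 1
                if keep_hits:
                    h.sample_id = meta.sample_id
                    per_sat_hits[h.satellite_id].append(h)
    lengths = np.array([sat_lengths[sid] for sid in sat_ids], dtype=float)
    totals = np.array([s.total_reads for s in samples], dtype=float)
    sample_rpkm = counts * 1e9 / lengths[:, None] / totals[None, :]
    return HitTable(
        counts=counts,
        sample_rpkm=sample_rpkm,
        samples=samples,
        hits=dict(per_sat_hits),
    )


def summarize_by_tissue(table: HitTable) -> HitTable:
    """Aggregate per-sample results per tissue, in place.

    Tissue hit totals are summed counts; tissue RPKM is the *sum* of the
    per-sample RPKM values (not recomputed from pooled counts).  A
    satellite is flagged transcribed in a tissue when its tissue RPKM
    exceeds the tissue's mean RPKM over all satellites.
    """
    tissue_of = {s.sample_id: s.tissue for s in table.samples}
    unknown = [c for c in table.counts.columns if c not in tissue_of]
    if unknown:
        raise ValueError(f"samples with no tissue assignment: {unknown}")
    tissues = sorted({s.tissue for s in table.samples})
    table.tissue_counts = pd.DataFrame(
        {
            t: table.counts[[c for c in table.counts.columns if tissue_of[c] == t]].sum(axis=1)
            for t in tissues
        }
    )
    table.tissue_rpkm = pd.DataFrame(
        {
            t: table.sample_rpkm[
                [c for c in table.sample_rpkm.columns if tissue_of[c] == t]
            ].sum(axis=1)
            for t in tissues
        }
    )
    table.transcribed = table.tissue_rpkm.gt(table.tissue_rpkm.mean(axis=0), axis=1)
    return table
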