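"""Domain record types used throughout the pipeline.

Coordinates are 0-based half-open internally; every table written to disk
uses 1-based inclusive coordinates (browser style), converted at the I/O
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class SeedCluster:
    """Occurrences of one primitive k-mer repeated within a sliding window.

    ``positions`` are the 0-based starts of the clustered occurrences;
    ``window_start``/``window_end`` delimit the genomic span they cover.
    """

    chrom: str
    window_start: int
    window_end: int
    kmer: str
    positions: list[int]


@dataclass
class CandidateRegion:
    """Union of overlapping seed clusters, input to satellite delimitation."""

    chrom: str
    start: int
    end: int
    clusters: list[SeedCluster] = field(default_factory=list)

    @property
    def spacings(self) -> list[int]:
        """Consecutive same-k-mer spacings pooled over all member clusters."""
        out: list[int] = []
        for cl in self.clusters:
            ps = cl.positions
            out.extend(ps[i + 1] - ps[i] for i in range(len(ps) - 1))
        return out


@dataclass
class SatelliteRecord:
    """One detected tandem array.

    ``start``/``end`` are 0-based half-open; ``repeats`` is the ordered
    partition of the span into tandem copies (lengths may differ when the
    array carries indels or a short terminal remainder). ``similarity`` is
    the mean pairwise ungapped identity among copies of the modal length,
    NaN when fewer than two such copies exist.
    """

    chrom: str
    start: int
    end: int
    repeat_length: int
    repeats: list[str]
    similarity: float
    same_length_frac: float
    location: str | None = None
    repeat_labels: list[str] = field(default_factory=list)
    family: str | None = None

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def sequence(self) -> str:
        return "".join(self.repeats)

    @property
    def id(self) -> str:
        # paper-style name: chromosome + 1-based start, e.g. "X_17441768"
        return f"{self.chrom}_{self.start + 1}"

    def __post_init__(self) -> None:
        if sum(len(r) for r in self.repeats) != self.end - self.start:
            raise ValueError(
                f"copy lengths do not sum to the span for {self.chrom}:{self.start}"
            )
        if not (math.isnan(self.similarity) or 0.0 <= self.similarity <= 1.0):
            raise ValueError("similarity outside [0, 1]")


@dataclass
class RepeatConsensus:
    """Majority-rule consensus of one satellite's same-length repeat copies."""

    satellite_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SatelliteFamily:
    """A cluster of satellites with alignable repeat consensuses.

    Named ``Fam_a_b_c``: a = rank by descending member count, b = consensus
    repeat size in nt, c = member count. A family with c = 1 is a unique
    satellite.
    """

    members: list[str]
    consensus: str
    rank_a: int = 0
    name: str = ""

    @property
    def repeat_size_b(self) -> int:
        return len(self.consensus)

    @property
    def n_members_c(self) -> int:
        return len(self.members)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RepeatAnnotation:
    chrom: str
    start: int
    end: int
    label: str


@dataclass
class ReferenceWindow:
    """Satellite span plus up to ``flank`` nt of genomic context each side."""

    satellite_id: str
    chrom: str
    start: int
    end: int
    sat_start: int
    sat_end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadHit:
    read_id: str
    satellite_id: str
    identity: float
    matches: int
    columns: int
    target_start: int  # window-local, 0-based
    target_end: int    # inclusive, edlib convention
    strand: str
    flank_only: bool
    sample_id: str | None = None

    @property
    def aligned_length(self) -> int:
        return self.target_end - self.target_start + 1


@dataclass
class SampleMeta:
    sample_id: str
    tissue: str
    total_reads: int = 0
    fastq_path: str | None = None
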