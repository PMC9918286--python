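"""Synthetic genomes, gene models, Helitron-style loci and tissue reads.

Every pipeline stage is testable without downloads: genomes carry planted
imperfect tandem arrays with known coordinates and units, gene models are
written so that each planted array has a chosen location class, a
Helitron-style locus reproduces the canonical layout of a complete
rolling-circle transposon (15-nt satellite, 32-nt satellite, 5'UTR,
central gene, 31-nt satellite abutting the gene, 3'UTR), and per-tissue
FASTQ reads are drawn from chosen satellite sub-regions with known
expression weights.  All outputs are pure functions of (spec, seed).

Planted arrays are maximal tandem spans by construction: the eight bases
just outside each array edge are resampled to break the unit periodicity,
so "the planted coordinates" and "the boundaries of the tandem array" are
the same thing.  In an i.i.d. background without this guarantee a planted
array extends past its nominal edge with probability ~1/4 per base and
exact boundary recovery would be ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import reverse_complement
from .records import GeneModel, RepeatAnnotation, SampleMeta

_BASES = np.array(list("ACGT"))
_EDGE_BREAK = 8  # bases of guaranteed periodicity break outside each array

TISSUES = ("hypodermis", "intestine", "neurons", "muscle")


@dataclass
class PlantedSatelliteSpec:
    chrom: str
    position: int           # array start, final genome coordinates
    unit: str               # primitive repeat unit, 10-200 nt
    n_copies: int
    substitution_rate: float = 0.0
    indel_rate: float = 0.0  # per copy
    location_class: str = "intergenic"
    truncate_to: int | None = None  # total array length; last copy partial

    def __post_init__(self) -> None:
        if not 10 <= len(self.unit) <= 200:
            raise ValueError("unit length must be 10-200 nt")
        if self.n_copies < 4:
            raise ValueError("need at least 4 copies")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 0.5:
                raise ValueError("rates must be in [0, 0.5]")
        if not _is_primitive(self.unit):
            raise ValueError(f"unit {self.unit!r} is not primitive")
        if self.truncate_to is not None:
            full = self.n_copies * len(self.unit)
            if not full - len(self.unit) < self.truncate_to <= full:
                raise ValueError("truncate_to must shorten only the last copy")


@dataclass
class PlantedSatellite:
    chrom: str
    start: int
    end: int
    unit: str
    n_copies: int
    location_class: str
    family_label: str = ""

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.start + 1}"


@dataclass
class ExpressionMatrix:
    """Per-satellite per-tissue expression weights, optional sub-regions.

    ``subregions[sat_id]`` is a list of (start_frac, end_frac, weight)
    triples over the satellite span, emulating non-uniform transcription;
    absent entries mean uniform sampling over the whole satellite.
    """

    weights: dict[str, dict[str, float]]
    subregions: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        out: set[str] = set()
        for w in self.weights.values():
            out |= set(w)
        return sorted(out)

    def tissue_weights(self, tissue: str) -> dict[str, float]:
        return {sid: w.get(tissue, 0.0) for sid, w in self.weights.items()}


@dataclass
class PlantedTruth:
    satellites: list[PlantedSatellite]
    genes: list[GeneModel] = field(default_factory=list)
    repeat_annotations: list[RepeatAnnotation] = field(default_factory=list)
    true_counts: pd.DataFrame | None = None          # satellites x samples
    read_origins: dict[str, list[str]] = field(default_factory=dict)
    library_sizes: dict[str, int] = field(default_factory=dict)

    def by_id(self) -> dict[str, PlantedSatellite]:
        return {s.id: s for s in self.satellites}


def _is_primitive(unit: str) -> bool:
    L = len(unit)
    for p in range(1, L // 2 + 1):
        if L % p == 0 and unit == unit[:p] * (L // p):
            return False
    return True


def random_unit(rng: np.random.Generator, length: int) -> str:
    """A uniform-random primitive DNA unit of the given length."""
    while True:
        u = "".join(rng.choice(_BASES, size=length))
        if _is_primitive(u):
            return u


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def mutate_copy(
    rng: np.random.Generator,
    unit: str,
    substitution_rate: float,
    indel_rate: float,
) -> str:
    """One tandem copy of *unit* with per-base substitutions and, with
    probability ``indel_rate``, a single 1-nt insertion or deletion."""
    seq = list(unit)
    if substitution_rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < substitution_rate)[0]
        for i in hits:
            others = [b for b in "ACGT" if b != seq[i]]
            seq[i] = others[rng.integers(3)]
    if indel_rate > 0 and rng.random() < indel_rate:
        pos = int(rng.integers(len(seq)))
        if rng.random() < 0.5 and len(seq) > 1:
            del seq[pos]
        else:
            seq.insert(pos, str(rng.choice(_BASES)))
    return "".join(seq)


def build_array(rng: np.random.Generator, spec: PlantedSatelliteSpec) -> str:
    array = "".join(
        mutate_copy(rng, spec.unit, spec.substitution_rate, spec.indel_rate)
        for _ in range(spec.n_copies)
    )
    if spec.truncate_to is not None:
        array = array[: spec.truncate_to]
    return array


def _break_periodicity(g: np.ndarray, start: int, end: int, unit_len: int, rng) -> None:
    # left edge: g[start-j] must differ from g[start-j+unit_len]
    for j in range(1, _EDGE_BREAK + 1):
        i = start - j
        if 0 <= i and i + unit_len < len(g):
            if g[i] == g[i + unit_len]:
                others = [b for b in "ACGT" if b != g[i + unit_len]]
                g[i] = others[rng.integers(3)]
    # right edge: g[x] must differ from g[x-unit_len]
    for x in range(end, min(end + _EDGE_BREAK, len(g))):
        if g[x] == g[x - unit_len]:
            others = [b for b in "ACGT" if b != g[x - unit_len]]
            g[x] = others[rng.integers(3)]


def _gene_for(spec_class: str, chrom: str, start: int, end: int, gid: str) -> GeneModel | None:
    if spec_class == "intron":
        return GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand="+",
            start=start - 150,
            end=end + 150,
            exons=[(start - 150, start - 50), (end + 50, end + 150)],
        )
    if spec_class == "exon":
        return GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand="+",
            start=start - 100,
            end=end + 100,
            exons=[(start - 50, end + 50)],
        )
    return None


def simulate_genome(
    specs: list[PlantedSatelliteSpec],
    background_length: int,
    gc: float = 0.36,
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneModel], PlantedTruth]:
    """Plant tandem arrays into i.i.d. background chromosomes.

    Arrays are written over the background at their stated positions (the
    genome length stays ``background_length`` per chromosome); gene models
    are emitted so that every spec's location class holds.  Specs must not
    overlap, including a 400-nt margin for gene models and edge breaks.
    Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted({s.chrom for s in specs})
    genome_arrays = {c: _random_background(rng, background_length, gc) for c in chroms}

    by_chrom: dict[str, list[PlantedSatelliteSpec]] = {c: [] for c in chroms}
    for s in specs:
        by_chrom[s.chrom].append(s)
    planted: list[PlantedSatellite] = []
    genes: list[GeneModel] = []
    for chrom in chroms:
        placed: list[tuple[int, int]] = []
        for i, spec in enumerate(sorted(by_chrom[chrom], key=lambda s: s.position)):
            array = build_array(rng, spec)
            start, end = spec.position, spec.position + len(array)
            if start < 400 or end > background_length - 400:
                raise ValueError(f"array at {chrom}:{start} too close to contig edge")
            if placed and start - placed[-1][1] < 400:
                raise ValueError(f"arrays overlap or are closer than 400 nt on {chrom}")
            placed.append((start, end))
            g = genome_arrays[chrom]
            g[start:end] = np.array(list(array))
            _break_periodicity(g, start, end, len(spec.unit), rng)
            planted.append(
                PlantedSatellite(chrom, start, end, spec.unit, spec.n_copies, spec.location_class)
            )
            gene = _gene_for(spec.location_class, chrom, start, end, f"gene_{chrom}_{i}")
            if gene is not None:
                genes.append(gene)

    genome = {c: "".join(genome_arrays[c]) for c in chroms}
    return genome, genes, PlantedTruth(satellites=planted, genes=genes)


def write_gff3(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Helitron-style locus
# ---------------------------------------------------------------------------

_HELITRON_UTR5 = 905   # nt, conserved region upstream of the transposon gene
_HELITRON_UTR3 = 674   # nt, conserved region downstream of the 31-nt satellite


def simulate_helitron_locus(
    gene_length: int = 4874,
    sat31_len: int = 1179,
    sat32_len: int = 351,
    sat15_len: int = 76,
    orientation: str = "+",
    seed: int = 0,
    label: str = "Helitron1_CE",
) -> tuple[str, list[RepeatAnnotation]]:
    """A complete Helitron-style locus with its three associated satellites.

    Parts appear in the canonical order — 15-nt satellite, 32-nt satellite,
    5'UTR, central transposon gene, 31-nt satellite in direct contact with
    the end of the gene, 3'UTR — and the whole locus is reverse complemented
    for orientation '-'.  Coordinates in the returned annotation are local
    to the locus sequence; a whole-locus interval carries the bare label,
    each part a suffixed one.
    """
    if orientation not in "+-":
        raise ValueError("orientation must be + or -")
    rng = np.random.default_rng(seed)

    def sat(unit_len: int, total: int) -> str:
        unit = random_unit(rng, unit_len)
        reps = -(-total // unit_len)
        return (unit * reps)[:total]

    parts = [
        ("sat15", sat(15, sat15_len)),
        ("sat32", sat(32, sat32_len)),
        ("5UTR", "".join(_random_background(rng, _HELITRON_UTR5, 0.36))),
        ("gene", "".join(_random_background(rng, gene_length, 0.42))),
        ("sat31", sat(31, sat31_len)),
        ("3UTR", "".join(_random_background(rng, _HELITRON_UTR3, 0.36))),
    ]
    seq = "".join(p[1] for p in parts)
    spans = []
    off = 0
    for name, s in parts:
        spans.append((name, off, off + len(s)))
        off += len(s)
    if orientation == "-":
        n = len(seq)
        seq = reverse_complement(seq)
        spans = [(name, n - e, n - s) for name, s, e in spans]
    annos = [RepeatAnnotation("locus", 0, len(seq), label)]
    annos += [
        RepeatAnnotation("locus", s, e, f"{label}_{name}") for name, s, e in sorted(
            spans, key=lambda t: t[1]
        )
    ]
    return seq, annos


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def simulate_reads(
    genome: dict[str, str],
    truth: PlantedTruth,
    expr: ExpressionMatrix,
    samples: list[SampleMeta],
    reads_per_sample: int = 1000,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Draw tissue-stratified reads from planted satellites.

    Per sample, satellites (and optional sub-regions) are chosen with
    probability proportional to the tissue's expression weights, read
    starts are uniform within the chosen region, strands are random, and
    substitution errors are applied at ``error_rate``.  True per-satellite
    counts, read origins and library sizes land in *truth*.  Raises when a
    requested tissue has no positive expression weight.  Identical seeds
    give identical reads.
    """
    sats = truth.by_id()
    seeds = np.random.SeedSequence(seed).spawn(len(samples))
    reads_per: dict[str, list[tuple[str, str]]] = {}
    sat_ids = sorted(expr.weights)
    counts = pd.DataFrame(0, index=sat_ids, columns=[s.sample_id for s in samples])
    for meta, ss in zip(samples, seeds):
        rng = np.random.default_rng(ss)
        w = expr.tissue_weights(meta.tissue)
        ids = [sid for sid in sat_ids if w[sid] > 0]
        if not ids:
            raise ValueError(f"tissue {meta.tissue!r} has all-zero expression")
        probs = np.array([w[sid] for sid in ids], dtype=float)
        probs /= probs.sum()
        reads: list[tuple[str, str]] = []
        origins: list[str] = []
        for r in range(reads_per_sample):
            sid = ids[rng.choice(len(ids), p=probs)]
            sat = sats[sid]
            regions = expr.subregions.get(sid, [(0.0, 1.0, 1.0)])
            rw = np.array([t[2] for t in regions], dtype=float)
            ri = rng.choice(len(regions), p=rw / rw.sum())
            f0, f1, _ = regions[ri]
            span = sat.end - sat.start
            rs = sat.start + int(f0 * span)
            re_ = sat.start + int(f1 * span)
            if re_ - rs < read_length:  # widen a too-short sub-region
                mid = (rs + re_) // 2
                rs, re_ = mid - read_length // 2 - 1, mid + read_length // 2 + 1
            lo = max(0, rs)
            hi = min(len(genome[sat.chrom]), re_) - read_length
            pos = int(rng.integers(lo, max(lo + 1, hi + 1)))
            seq = genome[sat.chrom][pos : pos + read_length]
            if error_rate > 0:
                seq = mutate_copy(rng, seq, error_rate, 0.0)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append((f"{meta.sample_id}_r{r}", seq))
            origins.append(sid)
            counts.loc[sid, meta.sample_id] += 1
        reads_per[meta.sample_id] = reads
        truth.read_origins[meta.sample_id] = origins
        truth.library_sizes[meta.sample_id] = len(reads)
        meta.total_reads = len(reads)
    truth.true_counts = counts
    return reads_per


# ---------------------------------------------------------------------------
# Default desk-scale scene
# ---------------------------------------------------------------------------

DEFAULT_FAMILY_PLAN = (
    # (family label, unit length, n members, copy-count range)
    ("famA", 35, 10, (6, 20)),
    ("famB", 94, 6, (4, 12)),
    ("famC", 21, 4, (8, 30)),
)

# Each family member's unit carries mutations at a member-specific block of
# unit positions, disjoint across members, so every member pair differs at
# exactly 2k positions: few enough that all within-family alignments stay
# above the clustering threshold, many enough that a read maps uniquely to
# its member at the 97% identity cut-off.  k = max(2, round(L / 12)).


def _member_block_size(unit_len: int) -> int:
    return max(2, round(unit_len / 12))


@dataclass
class Scene:
    genome: dict[str, str]
    truth: PlantedTruth
    expr: ExpressionMatrix
    samples: list[SampleMeta]
    reads: dict[str, list[tuple[str, str]]]


def default_scene(
    seed: int = 42,
    substitution_rate: float = 0.0,
    reads_per_sample: int = 1000,
    read_length: int = 100,
    error_rate: float = 0.0,
    samples_per_tissue: int = 2,
) -> Scene:
    """The standard synthetic study: 20 satellites in 3 planted families
    across 2 chromosomes, 12/5/3 intergenic/intron/exon, 4 tissues.

    Family units are sampled until mutually dissimilar (pairwise cyclic
    score < 0.4), so the planted partition is unambiguous; members of a
    family share one unit, placed as forward or reverse-complement copies.
    Tissue expression weights are log-uniform with one tissue boosted
    per satellite (neurons most often, echoing real tissue bias).
    """
    from .families import cyclic_alignment_score  # local import, avoids cycle

    rng = np.random.default_rng(seed)
    units: list[str] = []
    for _, unit_len, _, _ in DEFAULT_FAMILY_PLAN:
        while True:
            u = random_unit(rng, unit_len)
            if all(cyclic_alignment_score(u, v)[0] < 0.4 for v in units):
                units.append(u)
                break

    classes = ["intergenic"] * 12 + ["intron"] * 5 + ["exon"] * 3
    rng.shuffle(classes)

    specs: list[PlantedSatelliteSpec] = []
    member_family: list[str] = []
    i = 0
    for (label, unit_len, n_members, copies_rng), unit in zip(DEFAULT_FAMILY_PLAN, units):
        k_mut = _member_block_size(unit_len)
        blocks = rng.permutation(unit_len)[: n_members * k_mut].reshape(n_members, k_mut)
        for block in blocks:
            while True:
                u = list(unit)
                for pos in block:
                    others = [b for b in "ACGT" if b != unit[pos]]
                    u[pos] = others[rng.integers(3)]
                u = "".join(u)
                if _is_primitive(u):
                    break
            if rng.random() >= 0.7:
                u = reverse_complement(u)
            n_cop = int(rng.integers(*copies_rng))
            chrom = "chrI" if i % 2 == 0 else "chrII"
            specs.append(
                PlantedSatelliteSpec(
                    chrom=chrom,
                    position=0,  # assigned below
                    unit=u,
                    n_copies=n_cop,
                    substitution_rate=substitution_rate,
                    location_class=classes[i],
                )
            )
            member_family.append(label)
            i += 1

    # lay out positions with generous margins per chromosome
    background_length = 60_000
    next_pos = {"chrI": 1500, "chrII": 1500}
    order = sorted(range(len(specs)), key=lambda j: specs[j].chrom)
    for j in order:
        sp = specs[j]
        sp.position = next_pos[sp.chrom]
        next_pos[sp.chrom] += sp.n_copies * len(sp.unit) + 1600 + int(rng.integers(0, 400))
    if max(next_pos.values()) > background_length - 1000:
        background_length = max(next_pos.values()) + 1000

    genome, genes, truth = simulate_genome(specs, background_length, gc=0.36, seed=int(rng.integers(2**31)))
    for planted, fam in zip(truth.satellites, [member_family[j] for j in order]):
        planted.family_label = fam

    # expression: every satellite expressed in all tissues, one boosted
    weights: dict[str, dict[str, float]] = {}
    boost_choices = ["neurons"] * 5 + ["hypodermis", "intestine", "muscle"]
    for s in truth.satellites:
        base = {t: float(10 ** rng.uniform(-1, 0)) for t in TISSUES}
        boosted = boost_choices[int(rng.integers(len(boost_choices)))]
        base[boosted] *= float(rng.uniform(4, 10))
        weights[s.id] = base
    expr = ExpressionMatrix(weights=weights)

    samples = [
        SampleMeta(f"{t[:3]}_{k}", t)
        for t in TISSUES
        for k in range(samples_per_tissue)
    ]
    reads = simulate_reads(
        genome,
        truth,
        expr,
        samples,
        reads_per_sample=reads_per_sample,
        read_length=read_length,
        error_rate=error_rate,
        seed=int(rng.integers(2**31)),
    )
    return Scene(genome, truth, expr, samples, reads)
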