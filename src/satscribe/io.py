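"""Reading and writing the pipeline's file formats.

Genomes come in as FASTA (optionally gzipped) via Biopython; tabular
outputs are TSV through pandas.  All tables use 1-based inclusive
coordinates; the in-memory records are 0-based half-open.
"""

from __future__ import annotations

import gzip
import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import clean_sequence
from .records import RepeatAnnotation, SampleMeta, SatelliteRecord

SATELLITE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "length",
    "n_repeats",
    "repeat_length",
    "similarity",
    "same_length_frac",
    "sequence",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into ``{chrom: sequence}``.

    Sequences are upper-cased and letters outside {A,C,G,T} map to N.
    """
    with _open_text(path) as fh:
        genome = {rec.id: clean_sequence(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_genome(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def satellites_to_frame(records: list[SatelliteRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "start": r.start + 1,  # 1-based inclusive on disk
            "end": r.end,
            "length": r.length_nt,
            "n_repeats": r.n_repeats,
            "repeat_length": r.repeat_length,
            "similarity": round(r.similarity, 6) if not math.isnan(r.similarity) else float("nan"),
            "same_length_frac": round(r.same_length_frac, 6),
            "sequence": r.sequence,
        }
        if r.location is not None:
            row["location"] = r.location
            row["repeat_labels"] = ",".join(r.repeat_labels)
        if r.family is not None:
            row["family"] = r.family
        rows.append(row)
    return pd.DataFrame(rows)


def write_satellite_table(records: list[SatelliteRecord], path: str | Path) -> None:
    satellites_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


def _partition_copies(sequence: str, unit: int) -> list[str]:
    # same partition rule as detection: tile from the left edge, absorb a
    # short remainder (< unit/2) into the last copy
    n_full = len(sequence) // unit
    copies = [sequence[j * unit : (j + 1) * unit] for j in range(n_full)]
    tail = sequence[n_full * unit :]
    if tail:
        if len(tail) < unit / 2:
            copies[-1] = copies[-1] + tail
        else:
            copies.append(tail)
    return copies


def read_satellite_table(path: str | Path) -> list[SatelliteRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    records = []
    for row in df.itertuples(index=False):
        rec = SatelliteRecord(
            chrom=str(row.chrom),
            start=int(row.start) - 1,
            end=int(row.end),
            repeat_length=int(row.repeat_length),
            repeats=_partition_copies(str(row.sequence), int(row.repeat_length)),
            similarity=float(row.similarity) if not pd.isna(row.similarity) else math.nan,
            same_length_frac=float(row.same_length_frac),
        )
        if hasattr(row, "location") and not pd.isna(row.location):
            rec.location = str(row.location)
            labels = getattr(row, "repeat_labels", "")
            rec.repeat_labels = str(labels).split(",") if not pd.isna(labels) and str(labels) else []
        if hasattr(row, "family") and not pd.isna(row.family):
            rec.family = str(row.family)
        records.append(rec)
    return records


def write_satellite_bed(records: list[SatelliteRecord], path: str | Path) -> None:
    """BED6 export: name SAT_<chrom>_<start1>, score = round(1000*similarity)."""
    with open(path, "w") as fh:
        for r in records:
            score = 0 if math.isnan(r.similarity) else round(1000 * r.similarity)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tSAT_{r.chrom}_{r.start + 1}\t{score}\t+\n"
            )


def read_repeat_bed(path: str | Path) -> list[RepeatAnnotation]:
    """Read BED4 (chrom, start, end, label) transposon/repeat annotation."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(RepeatAnnotation(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return out


def write_repeat_bed(annos: list[RepeatAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annos:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.label}\n")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Sample sheet TSV with columns sample_id, tissue, fastq_path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tissue", "fastq_path"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return [
        SampleMeta(str(r.sample_id), str(r.tissue), fastq_path=str(r.fastq_path))
        for r in df.itertuples(index=False)
    ]


def iter_fastq(path: str | Path):
    """Yield (read_id, sequence) from a possibly gzipped FASTQ."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, clean_sequence(str(rec.seq))


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
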