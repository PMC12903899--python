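"""Read counting and tabular I/O for pooled screen data.

Counting is exact-match, forward orientation: a merged amplicon read
increments a guide when exactly one library spacer occurs verbatim as a
20-mer substring of the read.  Reads matching zero spacers, or spacers of
two or more distinct guides, contribute nothing; a spacer occurring twice
in one read still counts once.  Quality values are ignored.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .core import SPACER_LENGTH, CountTable, TargetSite

__all__ = [
    "ReadSet",
    "count_guides",
    "read_reads",
    "read_count_table",
    "write_count_table",
    "read_sites_tsv",
]


@dataclass
class ReadSet:
    """Sequencing reads for one sample: (read id, sequence) pairs."""

    sample_id: str
    reads: list[tuple[str, str]] = field(default_factory=list)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_reads(path: str | Path, sample_id: str | None = None) -> ReadSet:
    """Load FASTA or FASTQ reads (plain or gzip), format sniffed from the name."""
    path = Path(path)
    stem = path.name[: -len(".gz")] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_maybe_gzip(path) as fh:
        reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
    return ReadSet(sample_id=sample_id or path.stem, reads=reads)


def count_guides(reads: ReadSet, library: list[TargetSite]) -> pd.Series:
    """Per-guide read counts for one sample by exact 20-mer spacer matching."""
    if not library:
        raise ValueError("empty guide library")
    spacer_to_guide: dict[str, str] = {}
    for site in library:
        if site.spacer in spacer_to_guide:
            raise ValueError(f"duplicate spacer in library: {site.spacer}")
        spacer_to_guide[site.spacer] = site.guide_id
    counts = {site.guide_id: 0 for site in library}
    for _, seq in reads.reads:
        hits: set[str] = set()
        for i in range(len(seq) - SPACER_LENGTH + 1):
            guide = spacer_to_guide.get(seq[i : i + SPACER_LENGTH])
            if guide is not None:
                hits.add(guide)
                if len(hits) > 1:
                    break
        if len(hits) == 1:
            counts[hits.pop()] += 1
    return pd.Series(counts, name=reads.sample_id)


def write_count_table(table: CountTable, path: str | Path, conditions_path: str | Path | None = None) -> None:
    """Write counts as TSV plus a sample->condition sidecar carrying the assay direction."""
    path = Path(path)
    if conditions_path is None:
        conditions_path = path.with_suffix(".conditions.tsv")
    table.counts.rename_axis("guide_id").to_csv(path, sep="\t")
    with open(conditions_path, "w") as fh:
        fh.write(f"# direction={table.direction}\n")
        fh.write("sample_id\tcondition\n")
        for sid in table.sample_ids:
            fh.write(f"{sid}\t{table.conditions[sid]}\n")


def read_count_table(path: str | Path, conditions_path: str | Path | None = None) -> CountTable:
    path = Path(path)
    if conditions_path is None:
        conditions_path = path.with_suffix(".conditions.tsv")
    counts = pd.read_csv(path, sep="\t", index_col="guide_id")
    direction = None
    with open(conditions_path) as fh:
        first = fh.readline()
        if first.startswith("# direction="):
            direction = first.strip().split("=", 1)[1]
            side = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            side = pd.read_csv(fh, sep="\t")
    if direction is None:
        raise ValueError("conditions sidecar is missing the '# direction=' header line")
    if side["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in conditions sidecar")
    conditions = dict(zip(side["sample_id"].astype(str), side["condition"].astype(str)))
    missing = set(counts.columns) - set(conditions)
    if missing:
        raise ValueError(f"samples missing from conditions sidecar: {sorted(missing)}")
    counts.index = counts.index.astype(str)
    return CountTable(
        counts=counts[list(counts.columns)],
        conditions={s: conditions[s] for s in counts.columns},
        direction=direction,
    )


def read_sites_tsv(path: str | Path) -> list[TargetSite]:
    """Load the 6-column BED-like site table written by the simulator."""
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        seq = str(row.sequence)
        sites.append(
            TargetSite(
                guide_id=str(row.guide_id),
                contig_id=str(row.contig),
                strand=str(row.strand),
                spacer_start=int(row.start),
                spacer=seq[:SPACER_LENGTH],
                pam=seq[SPACER_LENGTH:],
            )
        )
    return sites
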