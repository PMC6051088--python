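"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA (via Biopython, with duplicate-ID checking), 6-column BED
(0-based half-open), TSV matrices with a header row of sample IDs, GMT
gene sets, and a minimal mapped-records SAM reader (via pysam) so real
alignments can stand in for the synthetic read table.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from None
            if end <= start or start < 0:
                raise ValueError(f"{path}:{ln}: empty or negative interval [{start}, {end})")
            rows.append({
                "chrom": parts[0], "start": start, "end": end,
                "name": parts[3] if len(parts) > 3 else ".",
                "score": parts[4] if len(parts) > 4 else ".",
                "strand": parts[5] if len(parts) > 5 else "+",
            })
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    df = intervals.copy()
    for col, default in (("name", "."), ("score", "."), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.read().rstrip("\n").split("\n")
    ncols = len(lines[0].split("\t"))
    for ln, line in enumerate(lines[1:], start=2):
        w = len(line.split("\t"))
        if w != ncols:
            raise ValueError(f"{path}:{ln}: ragged row ({w} fields, header has {ncols})")
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row ID {dup!r}")
    return df


def write_tsv_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT needs name, description, >= 1 gene")
            name = parts[0]
            if name in pathways:
                raise ValueError(f"{path}:{ln}: duplicate pathway {name!r}")
            pathways[name] = {g for g in parts[2:] if g}
    return pathways


def read_read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "chrom", "start", "end", "strand", "sequence", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: read table missing columns {sorted(missing)}")
    return df


def write_read_table(path: str | Path, reads: pd.DataFrame) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_sam_reads(path: str | Path, sample: str = "sam") -> pd.DataFrame:
    """Mapped records of a SAM file as a read table (forward/reverse
    strand from the flag; unmapped records skipped)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            rows.append({
                "read_id": rec.query_name,
                "chrom": rec.reference_name,
                "start": rec.reference_start,
                "end": rec.reference_end,
                "strand": "-" if rec.is_reverse else "+",
                "sequence": rec.query_sequence or "",
                "sample": sample,
            })
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end",
                                       "strand", "sequence", "sample"])


def write_sam_reads(path: str | Path, reads: pd.DataFrame, genome_length: int,
                    chrom: str = "chr1") -> None:
    """Minimal single-reference SAM with fully-matched mapped records."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{genome_length}\n")
        for _, r in reads.iterrows():
            flag = 16 if r["strand"] == "-" else 0
            seq = r["sequence"]
            fh.write(f"{r['read_id']}\t{flag}\t{r['chrom']}\t{r['start'] + 1}\t255\t"
                     f"{len(seq)}M\t*\t0\t0\t{seq}\t*\n")
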