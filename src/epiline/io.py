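"""Readers and writers for the pipeline's plain-text formats.

FASTA/FASTQ go through Biopython; tables are TSV with a header row and
optional ``#``-prefixed provenance comments (tool version, config hash,
seed — no timestamps, so re-runs are byte-identical).  A minimal SAM subset
(QNAME, FLAG strand/mate bits, RNAME, 1-based POS, MAPQ, CIGAR with match
operations only) is accepted for alignments produced elsewhere.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthgen import ReadPair

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "write_fastq_pairs",
    "read_fastq_pairs",
    "read_cytosine_tsv",
    "write_cytosine_tsv",
    "read_sam_subset",
    "write_sam_subset",
    "write_bedlike",
    "read_tsv",
    "write_tsv",
    "provenance_lines",
]


class FormatError(ValueError):
    """A malformed record, reported with its line number."""


def provenance_lines(stage: str, seed: int, config_hash: str, version: str) -> list[str]:
    return [
        f"# epiline {version}",
        f"# stage: {stage}",
        f"# seed: {seed}",
        f"# config: {config_hash}",
    ]


# ---------------------------------------------------------------------------
# Sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq_pairs(prefix: str | Path, pairs: Iterable[ReadPair]) -> tuple[Path, Path]:
    """Write mates to <prefix>_R1.fastq / <prefix>_R2.fastq (quality 'I')."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{'I' * len(pair.seq1)}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{'I' * len(pair.seq2)}\n")
    return p1, p2


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> list[ReadPair]:
    """Re-pair mates from two FASTQ files (ids '<name>/1' and '<name>/2')."""
    mates1 = {rec.id.rsplit("/", 1)[0]: str(rec.seq) for rec in SeqIO.parse(str(path_r1), "fastq")}
    mates2 = {rec.id.rsplit("/", 1)[0]: str(rec.seq) for rec in SeqIO.parse(str(path_r2), "fastq")}
    if set(mates1) != set(mates2):
        raise FormatError("R1 and R2 files contain different read ids")
    return [ReadPair(rid, mates1[rid], mates2[rid], "", -1, -1) for rid in mates1]


# ---------------------------------------------------------------------------
# Tables

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]


def write_tsv(path: str | Path, frame: pd.DataFrame, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_cytosine_tsv(path: str | Path, records: pd.DataFrame, header_lines=None) -> None:
    write_tsv(path, records[CYTOSINE_COLUMNS], header_lines)


def read_cytosine_tsv(path: str | Path) -> pd.DataFrame:
    frame = read_tsv(path)
    missing = set(CYTOSINE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    # report invariant violations with 1-based data line numbers
    bad = frame.index[frame["count_methylated"] > frame["count_total"]]
    if len(bad):
        raise FormatError(
            f"{path}: count_methylated > count_total at data line {int(bad[0]) + 2}"
        )
    if (frame["pos"] < 0).any():
        line = int(frame.index[frame["pos"] < 0][0]) + 2
        raise FormatError(f"{path}: negative position at data line {line}")
    if not frame["context"].isin(["CG", "CHG", "CHH"]).all():
        line = int(frame.index[~frame["context"].isin(["CG", "CHG", "CHH"])][0]) + 2
        raise FormatError(f"{path}: invalid context at data line {line}")
    return frame[CYTOSINE_COLUMNS]


# ---------------------------------------------------------------------------
# SAM subset

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def read_sam_subset(path: str | Path) -> pd.DataFrame:
    """Parse a minimal SAM file into the internal alignment table.

    Uses QNAME, FLAG (0x10 strand, 0x40/0x80 mate index), RNAME, POS
    (converted to 0-based), MAPQ (0 marks a non-unique placement) and
    CIGAR, which may contain only match operations (M/=/X).  Returns
    columns read_id, mate, contig, start, strand, length, unique.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: truncated SAM record at line {lineno}")
            qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
            try:
                flag, pos, mapq = int(flag_s), int(pos_s), int(mapq_s)
            except ValueError as exc:
                raise FormatError(f"{path}: bad numeric field at line {lineno}") from exc
            if rname == "*" or flag & 0x4:
                continue
            length = 0
            for count, op in _CIGAR_RE.findall(cigar):
                if op not in ("M", "=", "X"):
                    raise FormatError(
                        f"{path}: unsupported CIGAR op {op!r} at line {lineno} "
                        "(match-only subset)"
                    )
                length += int(count)
            if length <= 0:
                raise FormatError(f"{path}: empty alignment at line {lineno}")
            mate = 2 if flag & 0x80 else 1
            rows.append(
                {
                    "read_id": qname,
                    "mate": mate,
                    "contig": rname,
                    "start": pos - 1,
                    "strand": "-" if flag & 0x10 else "+",
                    "length": length,
                    "unique": mapq > 0,
                }
            )
    return pd.DataFrame(
        rows, columns=["read_id", "mate", "contig", "start", "strand", "length", "unique"]
    )


def write_sam_subset(path: str | Path, alignments: pd.DataFrame) -> None:
    """Write the internal alignment table as the minimal SAM subset."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig in pd.unique(alignments["contig"]):
            fh.write(f"@SQ\tSN:{contig}\tLN:0\n")
        for row in alignments.itertuples(index=False):
            flag = 0
            if row.strand == "-":
                flag |= 0x10
            flag |= 0x40 if row.mate == 1 else 0x80
            mapq = 60 if row.unique else 0
            fh.write(
                f"{row.read_id}\t{flag}\t{row.contig}\t{row.start + 1}\t{mapq}\t"
                f"{row.length}M\t*\t0\t0\t*\t*\n"
            )


def write_bedlike(path: str | Path, calls, header_lines=None) -> None:
    """Insertion calls as BED-like TSV: chrom, lo, hi, name, support, orientation,
    tsd_length, tsd_seq."""
    rows = [
        {
            "chrom": c.chrom,
            "lo": c.lo,
            "hi": c.hi,
            "name": f"insertion_{i + 1}",
            "support": min(c.left_support, c.right_support),
            "orientation": c.orientation,
            "tsd_length": c.tsd_length,
            "tsd_seq": c.tsd_sequence or ".",
        }
        for i, c in enumerate(calls)
    ]
    frame = pd.DataFrame(
        rows, columns=["chrom", "lo", "hi", "name", "support", "orientation", "tsd_length", "tsd_seq"]
    )
    write_tsv(path, frame, header_lines)
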