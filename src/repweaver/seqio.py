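"""Sequence I/O: paired-end read loading and repeat FASTA output.

Reads come as FASTQ or FASTA, either as two split mate files or one
interleaved file.  Qualities are ignored; mate 2 is stored exactly as
given (not reverse-complemented).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO


@dataclass
class ReadSet:
    """Paired short reads with a uniform read length."""

    pairs: list[tuple[str, str]]
    read_length: int
    source: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def mates(self) -> Iterable[str]:
        """All read sequences, forward mates first in each pair."""
        for fwd, rev in self.pairs:
            yield fwd
            yield rev


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    with open(path) as handle:
        for line in handle:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    return "fasta"


def _parse_records(path: Path) -> list[str]:
    fmt = _sniff_format(path)
    seqs: list[str] = []
    try:
        for record in SeqIO.parse(str(path), fmt):
            seqs.append(str(record.seq).upper())
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: record {len(seqs)}: malformed {fmt} record ({exc})") from exc
    return seqs


def load_reads(
    paths: Sequence[str | Path] | str | Path,
    paired_layout: str = "split",
    min_read_length: int | None = None,
) -> ReadSet:
    """Load paired reads from one interleaved or two split FASTQ/FASTA files.

    Pairs are preserved in file order.  All reads must share one length;
    ragged input is rejected, as are reads shorter than
    ``min_read_length`` when given.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)

    if paired_layout == "split":
        if len(paths) != 2:
            raise ValueError("split layout requires exactly two files")
        mates1 = _parse_records(paths[0])
        mates2 = _parse_records(paths[1])
        if len(mates1) != len(mates2):
            raise ValueError(
                f"pairing error: {paths[0]} has {len(mates1)} records but "
                f"{paths[1]} has {len(mates2)}"
            )
        pairs = list(zip(mates1, mates2))
    elif paired_layout == "interleaved":
        if len(paths) != 1:
            raise ValueError("interleaved layout requires exactly one file")
        seqs = _parse_records(paths[0])
        if len(seqs) % 2 != 0:
            raise ValueError(f"pairing error: {paths[0]} has an odd record count")
        pairs = [(seqs[i], seqs[i + 1]) for i in range(0, len(seqs), 2)]
    else:
        raise ValueError(f"unknown paired_layout {paired_layout!r}")

    if not pairs:
        raise ValueError("no reads loaded")
    read_length = len(pairs[0][0])
    for i, (fwd, rev) in enumerate(pairs):
        if len(fwd) != read_length or len(rev) != read_length:
            raise ValueError(f"ragged input: pair {i} has lengths "
                             f"{len(fwd)}/{len(rev)}, expected {read_length}")
    if min_read_length is not None and read_length < min_read_length:
        raise ValueError(
            f"reads of length {read_length} are shorter than the required "
            f"minimum {min_read_length}"
        )
    return ReadSet(pairs=pairs, read_length=read_length,
                   source=",".join(str(p) for p in paths))


def write_repeats(repeats, path: str | Path) -> None:
    """Write assembled repeats to FASTA, 60 columns, uppercase.

    Headers carry id, length, constituent contig count and mean coverage.
    """
    with open(path, "w") as handle:
        for rep in repeats:
            cov = rep.mean_coverage
            cov_text = f"{cov:.2f}" if cov is not None else "NA"
            handle.write(
                f">{rep.id} length={len(rep.sequence)} "
                f"contigs={len(rep.path)} mean_cov={cov_text}\n"
            )
            seq = rep.sequence.upper()
            for start in range(0, len(seq), 60):
                handle.write(seq[start:start + 60] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as handle:
        for name, seq in items:
            handle.write(f">{name}\n")
            for start in range(0, len(seq), 60):
                handle.write(seq[start:start + 60].upper() + "\n")
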