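"""FASTA input and the CSV/FASTA output contracts of the pipeline.

Reading is strict by design: duplicate record ids, non-nucleotide
characters and headerless files are reported with the offending line
number so problems in user-supplied genomes surface early rather than as
silently wrong statistics.
"""

from __future__ import annotations

import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as _seqio_write
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError
from .genetic_code import ALL_CODONS, GeneticCode

if TYPE_CHECKING:  # pragma: no cover
    from .heg_search import HegHit

_NUCLEOTIDES = set("ACGTN")


@dataclass
class CdsRecord:
    """One coding sequence.

    ``coords`` is ``(contig_id, start, end, strand)`` with 0-based
    half-open coordinates on the forward strand of the contig; it is only
    populated for ORF-called records.
    """

    id: str
    seq: str
    description: str = ""
    source: str = "annotated_input"  # or "orf_called"
    coords: tuple[str, int, int, str] | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class UsageTable:
    """The 64-row per-codon statistics payload written to CSV."""

    rows: pd.DataFrame  # columns: codon, amino_acid, count, rscu, nrscu, fb
    input_id: str = ""
    n_hegs_used: int = 0
    n_codons_counted: int = 0
    table_id: int = 11

    def __post_init__(self):
        assert list(self.rows["codon"]) == list(ALL_CODONS), \
            "usage table must have one row per codon in lexicographic order"


def read_fasta(path: str | Path) -> list[CdsRecord]:
    """Parse a (possibly line-wrapped) multi-record nucleotide FASTA.

    Sequences are uppercased; CRLF endings and blank lines are tolerated.

    Raises
    ------
    FastaParseError
        On an empty file, a file not starting with ``>``, a duplicate or
        empty record id, or a non-ACGTN character — each with the line
        number where the problem was found.
    """
    path = Path(path)
    records: list[CdsRecord] = []
    seen: set[str] = set()
    header_line = 0
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []

    def flush():
        if cur_id is None:
            return
        records.append(CdsRecord(id=cur_id, seq="".join(chunks),
                                 description=cur_desc))

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                header = line[1:].strip()
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
                cur_id, _, cur_desc = header.partition(" ")
                if cur_id in seen:
                    raise FastaParseError(
                        f"duplicate record id {cur_id!r}", lineno)
                seen.add(cur_id)
                header_line = lineno
            else:
                if cur_id is None:
                    raise FastaParseError(
                        "expected '>' header before sequence data", lineno)
                seq = line.strip().upper()
                bad = set(seq) - _NUCLEOTIDES
                if bad:
                    raise FastaParseError(
                        f"non-nucleotide character(s) {sorted(bad)} in "
                        f"record {cur_id!r}", lineno)
                chunks.append(seq)
        if lineno == 0:
            raise FastaParseError(f"empty FASTA file: {path}", 1)
        flush()
    if not records:
        raise FastaParseError(f"no FASTA records in {path}", header_line or 1)
    return records


def write_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA (via Biopython)."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        _seqio_write(seqrecs, fh, "fasta")


def write_heg_fasta(hits: "list[HegHit]", cds_index: dict[str, CdsRecord],
                    path: str | Path) -> None:
    """Write the retained HEG nucleotide sequences, one per family.

    Header contract: ``><family_id>|<cds_id>|score=<bitscore>``, records
    in family-id order, sequence wrapped at 60 columns.
    """
    hits = sorted(hits, key=lambda h: h.family_id)
    if not hits:
        raise ValueError("refusing to write an empty HEG FASTA")
    seqrecs = []
    for h in hits:
        label = f"{h.family_id}|{h.cds_id}|score={h.bitscore:.1f}"
        seqrecs.append(SeqRecord(Seq(cds_index[h.cds_id].seq),
                                 id=label, description=""))
    with open(path, "w", encoding="utf-8") as fh:
        _seqio_write(seqrecs, fh, "fasta")


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.6f}"


def write_usage_csv(table: UsageTable, path: str | Path) -> None:
    """Write the per-codon statistics CSV.

    Header is exactly ``codon,amino_acid,count,rscu,nrscu,fb``; 64 data
    rows in lexicographic codon order; floats with six decimal places;
    missing statistics (unobserved families, stop codons) as empty fields.
    LF line endings, no quoting — the payload contains no commas.
    """
    df = table.rows.copy()
    for col in ("rscu", "nrscu", "fb"):
        df[col] = df[col].map(_fmt)
    df.to_csv(path, index=False, lineterminator="\n")


def read_usage_csv(path: str | Path) -> UsageTable:
    """Re-load a usage CSV written by :func:`write_usage_csv`."""
    df = pd.read_csv(path, dtype={"codon": str, "amino_acid": str})
    if list(df.columns) != ["codon", "amino_acid", "count", "rscu",
                            "nrscu", "fb"]:
        raise FastaParseError(f"unexpected usage CSV columns in {path}", 1)
    if len(df) != 64:
        raise FastaParseError(
            f"usage CSV must have 64 data rows, found {len(df)}", 1)
    return UsageTable(rows=df, input_id=str(path),
                      n_codons_counted=int(
                          df.loc[~df["rscu"].isna(), "count"].sum()))


def usage_table_from_profile(profile, code: GeneticCode, *,
                             input_id: str = "",
                             n_hegs_used: int = 0) -> UsageTable:
    """Assemble the CSV payload from a computed usage profile."""
    rows = []
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        rows.append({
            "codon": codon,
            "amino_acid": aa,
            "count": profile.counts.counts[codon],
            "rscu": profile.rscu[codon],
            "nrscu": profile.nrscu[codon],
            "fb": profile.fb[codon],
        })
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "count",
                                     "rscu", "nrscu", "fb"])
    return UsageTable(rows=df, input_id=input_id, n_hegs_used=n_hegs_used,
                      n_codons_counted=profile.counts.n_codons,
                      table_id=code.table_id)


def zip_outputs(paths: Iterable[str | Path], zip_path: str | Path) -> None:
    """Bundle output files into a zip archive (flat layout)."""
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for p in paths:
            zf.write(p, arcname=Path(p).name)
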