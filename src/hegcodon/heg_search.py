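"""Translated homology search: find the best CDS for each HEG family.

Each input CDS is translated and aligned (Smith-Waterman, affine gaps,
BLOSUM62) against every reference protein; for every HEG family the
single best-scoring (CDS, reference) pair is kept, subject to an E-value
cutoff.  An adapter ingests 12-column tabular output from an external
aligner so users can substitute a faster search tool for the built-in
one without changing anything downstream.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ExternalHitsError, ReferenceDbError
from .genetic_code import GeneticCode, translate
from .io_seq import CdsRecord

logger = logging.getLogger(__name__)


def load_families(path: str | Path | None = None) -> list[str]:
    """The configured HEG family identifiers (shipped default: 40 ids,
    ribosomal proteins plus translation factors)."""
    if path is None:
        from importlib.resources import files
        text = (files("hegcodon") / "data" / "families.txt").read_text()
    else:
        text = Path(path).read_text()
    fams = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(set(fams)) != len(fams):
        raise ReferenceDbError("duplicate ids in family list")
    return fams


#: Karlin-Altschul parameters for gapped BLOSUM62, open 11 / extend 1.
LAMBDA = 0.267
K = 0.041

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_EVALUE_MAX = 1e-5

_AA20 = set("ARNDCQEGHILKMFPSTWYV")
_FAMILY_RE = re.compile(r"family=(\S+)")


@dataclass(frozen=True)
class ReferenceDbEntry:
    protein_id: str
    family_id: str
    seq: str


@dataclass
class ReferenceDB:
    """Reference proteins, each tagged with its HEG family."""

    entries: list[ReferenceDbEntry]

    @property
    def families(self) -> set[str]:
        return {e.family_id for e in self.entries}

    @property
    def total_residues(self) -> int:
        return sum(len(e.seq) for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class HegHit:
    """Best-scoring CDS for one HEG family."""

    family_id: str
    cds_id: str
    raw_score: int
    bitscore: float
    evalue: float
    aligned_fraction: float


def read_reference_db(path: str | Path,
                      allowed_families: set[str] | None = None) -> ReferenceDB:
    """Load a protein FASTA whose headers carry ``family=<id>`` tags.

    Raises
    ------
    ReferenceDbError
        On an empty file, a record without a family tag, a duplicate
        protein id, or (if ``allowed_families`` is given) an unknown tag.
    """
    entries = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _FAMILY_RE.search(rec.description)
        if not m:
            raise ReferenceDbError(
                f"record {rec.id!r} lacks a family=<id> tag")
        family = m.group(1)
        if allowed_families is not None and family not in allowed_families:
            raise ReferenceDbError(
                f"record {rec.id!r} has unknown family {family!r}")
        if rec.id in seen:
            raise ReferenceDbError(f"duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ReferenceDbError(f"record {rec.id!r} has empty sequence")
        entries.append(ReferenceDbEntry(rec.id, family, seq))
    if not entries:
        raise ReferenceDbError(f"no records in reference database {path}")
    return ReferenceDB(entries=entries)


def _make_matrix():
    """BLOSUM62 with the X and * rows/columns zeroed, so unknown residues
    are scored neutrally rather than penalised."""
    m = substitution_matrices.load("BLOSUM62")
    arr = m.copy()
    for ch in ("X", "*"):
        i = m.alphabet.index(ch)
        arr[i, :] = 0
        arr[:, i] = 0
    return arr


_MATRIX = _make_matrix()


def _make_aligner(gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    # BLAST convention: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner(DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)


def sanitize_protein(seq: str) -> str:
    """Uppercase and map any non-standard residue (U, O, J, B, Z, *) to X."""
    return "".join(c if c in _AA20 else "X" for c in seq.upper())


def sw_align(query: str, subject: str, *,
             gap_open: int = DEFAULT_GAP_OPEN,
             gap_extend: int = DEFAULT_GAP_EXTEND) -> int:
    """Optimal local-alignment raw score under affine gaps and BLOSUM62.

    ``X`` scores zero against everything.  Raises ``ValueError`` on an
    empty sequence.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    if (gap_open, gap_extend) == (DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND):
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(gap_open, gap_extend)
    return int(aligner.score(sanitize_protein(query),
                             sanitize_protein(subject)))


def evalue(raw_score: int, query_len: int,
           db_residues: int) -> tuple[float, float]:
    """Karlin-Altschul bitscore and E-value for a raw alignment score.

    bitscore = (lambda * S - ln K) / ln 2 with the gapped BLOSUM62
    constants; E = m * n * 2 ** (-bitscore).
    """
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    bits = (LAMBDA * raw_score - math.log(K)) / math.log(2)
    ev = query_len * db_residues * 2.0 ** (-bits)
    return bits, ev


def _aligned_fraction(query: str, subject: str) -> float:
    """Fraction of query residues inside the optimal local alignment."""
    aln = _DEFAULT_ALIGNER.align(sanitize_protein(query),
                                 sanitize_protein(subject))[0]
    blocks = aln.aligned[0]
    covered = sum(int(e - s) for s, e in blocks)
    return min(1.0, covered / len(query))


def find_hegs(cds: list[CdsRecord], db: ReferenceDB, code: GeneticCode,
              evalue_max: float = DEFAULT_EVALUE_MAX) -> list[HegHit]:
    """Select, per HEG family, the best-matching CDS below the E-value cut.

    Every CDS is translated (ORF-called records render their start codon
    as M) and exhaustively aligned against every reference entry.  Ties
    in score go to the lexicographically smaller CDS id.  A CDS may win
    several families; this is logged as a warning since it usually means
    the reference families overlap.
    """
    if not cds:
        raise ValueError("empty CDS list")
    if not db.entries:
        raise ReferenceDbError("empty reference database")

    proteins: dict[str, str] = {}
    for rec in cds:
        try:
            aa = translate(rec.seq, code,
                           orf_start=(rec.source == "orf_called"),
                           record_id=rec.id)
        except Exception as exc:  # frame errors: skip, keep searching
            logger.warning("skipping %s: %s", rec.id, exc)
            continue
        if aa:
            proteins[rec.id] = sanitize_protein(aa)
    if not proteins:
        return []

    db_res = db.total_residues
    # best per family: (raw_score, cds_id, entry)
    best: dict[str, tuple[int, str, ReferenceDbEntry]] = {}
    for cds_id in sorted(proteins):
        q = proteins[cds_id]
        for entry in db.entries:
            s = sw_align(q, entry.seq)
            cur = best.get(entry.family_id)
            if cur is None or s > cur[0]:
                best[entry.family_id] = (s, cds_id, entry)
            # equal score: earlier (lexicographically smaller) cds_id kept

    hits = []
    winners: dict[str, list[str]] = {}
    for family in sorted(best):
        raw, cds_id, entry = best[family]
        bits, ev = evalue(raw, len(proteins[cds_id]), db_res)
        if ev > evalue_max:
            continue
        frac = _aligned_fraction(proteins[cds_id], entry.seq)
        hits.append(HegHit(family_id=family, cds_id=cds_id, raw_score=raw,
                           bitscore=bits, evalue=ev, aligned_fraction=frac))
        winners.setdefault(cds_id, []).append(family)
    for cds_id, fams in winners.items():
        if len(fams) > 1:
            logger.warning("CDS %s is the top hit for multiple families: %s",
                           cds_id, ", ".join(fams))
    return hits


def read_external_hits(path: str | Path, db: ReferenceDB,
                       evalue_max: float | None = None) -> list[HegHit]:
    """Ingest 12-column tabular hits from an external aligner.

    Columns (tab-separated, no header): query id, subject id, pident,
    length, mismatches, gapopen, qstart, qend, sstart, send, evalue,
    bitscore.  Rows are mapped to families through the subject's tag in
    ``db`` and reduced to the single best bitscore per family.
    """
    by_subject = {e.protein_id: e for e in db.entries}
    best: dict[str, HegHit] = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 12:
                raise ExternalHitsError(
                    f"expected 12 columns, found {len(row)} (line {lineno})")
            n_rows += 1
            qid, sid = row[0], row[1]
            entry = by_subject.get(sid)
            if entry is None:
                raise ExternalHitsError(
                    f"subject id {sid!r} not in reference database "
                    f"(line {lineno})")
            try:
                aln_len = int(row[3])
                ev = float(row[10])
                bits = float(row[11])
            except ValueError as exc:
                raise ExternalHitsError(
                    f"malformed numeric field (line {lineno}): {exc}")
            if evalue_max is not None and ev > evalue_max:
                continue
            raw = int(round((bits * math.log(2) + math.log(K)) / LAMBDA))
            hit = HegHit(
                family_id=entry.family_id, cds_id=qid, raw_score=raw,
                bitscore=bits, evalue=ev,
                aligned_fraction=min(1.0, aln_len / len(entry.seq)))
            cur = best.get(entry.family_id)
            if (cur is None or hit.bitscore > cur.bitscore
                    or (hit.bitscore == cur.bitscore
                        and hit.cds_id < cur.cds_id)):
                best[entry.family_id] = hit
    if n_rows == 0:
        logger.warning("external hits file %s is empty", path)
        return []
    return [best[f] for f in sorted(best)]
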