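"""Deterministic six-frame ORF scan for unannotated genomes.

This is the fallback coding-region finder for the unannotated branch of
the pipeline.  It trades the statistical model of a real gene finder for
a simple, fully deterministic rule: within every stop-to-stop segment of
every frame, the most upstream in-frame start codon opens at most one
ORF, which runs to and including the stop.  Spurious calls are tolerable
because the downstream homology search keeps only strong HEG matches;
sensitivity is what matters here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .io_seq import CdsRecord

_STARTS_DEFAULT = frozenset({"ATG", "GTG", "TTG"})
_STOPS_T11 = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfParams:
    """Tuning knobs of the ORF scan.

    ``min_len_nt`` counts start through stop inclusive; 90 nt (30 codons)
    discards most random open frames while keeping short real genes.
    """

    min_len_nt: int = 90
    start_codons: frozenset[str] = _STARTS_DEFAULT
    table_id: int = 11

    def __post_init__(self):
        if self.min_len_nt < 6 or self.min_len_nt % 3 != 0:
            raise ValueError("min_len_nt must be >= 6 and divisible by 3")


def _scan_strand(seq: str, starts: frozenset[str],
                 stops: frozenset[str], min_len: int):
    """Yield (start, end) 0-based half-open ORFs on this strand's forward
    reading.  Codons containing N never match a start or a stop."""
    n = len(seq)
    for frame in range(3):
        seg_start = frame  # first codon after the previous stop
        first_start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in stops:
                if first_start is not None:
                    end = i + 3
                    if end - first_start >= min_len:
                        yield first_start, end
                seg_start = i + 3
                first_start = None
            elif first_start is None and codon in starts:
                first_start = i
        # segment running off the contig end (no stop) is discarded


def find_orfs(genome: list[tuple[str, str]],
              params: OrfParams = OrfParams()) -> list[CdsRecord]:
    """Call ORFs in all six frames of each contig.

    Reverse-strand ORFs are reported as the reverse complement of the
    forward contig, with 0-based half-open forward coordinates and
    strand ``'-'``.  Records are sorted by (contig, start) and assigned
    sequential ids ``<contig>_orf<k>``.
    """
    stops = _STOPS_T11
    found: list[tuple[str, int, int, str, str]] = []
    for contig_id, raw in genome:
        seq = raw.upper()
        rc = reverse_complement(seq)
        L = len(seq)
        for s, e in _scan_strand(seq, params.start_codons, stops,
                                 params.min_len_nt):
            found.append((contig_id, s, e, "+", seq[s:e]))
        for s, e in _scan_strand(rc, params.start_codons, stops,
                                 params.min_len_nt):
            # map coordinates on the reverse strand back to forward
            found.append((contig_id, L - e, L - s, "-", rc[s:e]))
    found.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    records = []
    for k, (contig, s, e, strand, cds) in enumerate(found, start=1):
        records.append(CdsRecord(
            id=f"{contig}_orf{k}",
            seq=cds,
            description=f"# {contig}:{s}-{e}({strand})",
            source="orf_called",
            coords=(contig, s, e, strand),
        ))
    return records
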