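"""Genetic-code tables and the synonymous-family structure.

Every statistic downstream (RSCU, NRSCU, frequency bias) is defined over
the partition of the 61 sense codons into synonymous families, so that
partition is materialised once here and shared.  Tables are sourced from
Biopython's NCBI codon-table catalogue; the default is table 11
(bacteria/archaea), with table 1 (standard) also supported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _CodonTable

from .errors import FrameError, UnsupportedTableError

SUPPORTED_TABLES = (1, 11)

#: All 64 DNA codons in lexicographic order.
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)

_AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass(frozen=True)
class GeneticCode:
    """A translation table plus its synonymous-codon family partition.

    Attributes
    ----------
    table_id:
        NCBI translation-table number.
    codon_to_aa:
        Total map over the 64 codons; stop codons map to ``'*'``.
    start_codons, stop_codons:
        Codon sets from the NCBI table.
    families:
        Amino-acid letter -> ordered (lexicographic) list of its
        synonymous sense codons.  Families partition the sense codons.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]
    families: dict[str, list[str]] = field(repr=False)

    @property
    def sense_codons(self) -> list[str]:
        return [c for c in ALL_CODONS if c not in self.stop_codons]

    def degeneracy(self, aa: str) -> int:
        """Number of synonymous codons encoding amino acid ``aa``."""
        return len(self.families[aa])

    def family_of(self, codon: str) -> list[str]:
        """The synonymous family containing ``codon`` (sense codons only)."""
        return self.families[self.codon_to_aa[codon]]


def load_code(table_id: int = 11) -> GeneticCode:
    """Build a :class:`GeneticCode` for an NCBI translation table.

    Raises
    ------
    UnsupportedTableError
        If ``table_id`` is not one of :data:`SUPPORTED_TABLES`.
    """
    if table_id not in SUPPORTED_TABLES:
        raise UnsupportedTableError(
            f"translation table {table_id!r} not supported; "
            f"choose one of {SUPPORTED_TABLES}"
        )
    ncbi = _CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = {c: ncbi.forward_table.get(c, "*") for c in ALL_CODONS}
    stop = frozenset(ncbi.stop_codons)
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa[codon]
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(ncbi.start_codons),
        stop_codons=stop,
        families=families,
    )


def translate(cds: str, code: GeneticCode, *, orf_start: bool = False,
              record_id: str = "<sequence>") -> str:
    """Translate a coding sequence codon by codon.

    The terminal stop codon (if present) is dropped; internal stops render
    as ``'*'``; any codon containing an ambiguity character renders as
    ``'X'``.  With ``orf_start=True`` the first codon is rendered ``'M'``
    when it is a start codon of the table, matching gene-caller convention
    for alternative starts (GTG/TTG); otherwise codons translate by their
    table identity.

    Raises
    ------
    FrameError
        If the length is not a multiple of three.
    """
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise FrameError(
            f"length of {record_id} ({len(seq)} nt) is not a multiple of 3"
        )
    aas = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if any(ch in _AMBIGUOUS for ch in codon):
            aas.append("X")
            continue
        aa = code.codon_to_aa[codon]
        if i == 0 and orf_start and codon in code.start_codons:
            aa = "M"
        if aa == "*" and i == n_codons - 1:
            break  # trailing stop is not part of the protein
        aas.append(aa)
    return "".join(aas)
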