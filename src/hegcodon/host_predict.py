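"""Phage-host comparison by Pearson correlation of RSCU vectors.

A phage's coding regions tend to mirror the codon usage of the host
machinery that translates them.  Given the RSCU profile of each
candidate host's highly expressed genes, every phage gene (and the
pooled set of all genes) is scored by the Pearson correlation between
its RSCU vector and each host's, over the codons comparable in both;
each gene is assigned to the host with the highest r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .codon_metrics import UsageProfile, profile_from_cds
from .errors import ConstantVectorError, InsufficientOverlapError
from .genetic_code import ALL_CODONS, GeneticCode
from .io_seq import CdsRecord

logger = logging.getLogger(__name__)

MIN_COMPARABLE_CODONS = 10


@dataclass(frozen=True)
class RscuVector:
    """An ordered RSCU vector over a shared codon set (no NA entries)."""

    values: tuple[float, ...]
    codon_ids: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self):
        assert len(self.values) == len(self.codon_ids)


@dataclass
class GeneAssignment:
    gene_id: str
    r_by_host: dict[str, float]
    assigned_host: str | None  # None on an exact tie


@dataclass
class HostComparison:
    """Per-gene and collective comparison of a phage against hosts."""

    per_gene: list[GeneAssignment]
    collective: dict[str, float]
    tally: dict[str, int]
    skipped_genes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def best_collective_host(self) -> str:
        return max(self.collective, key=self.collective.get)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Raises
    ------
    ConstantVectorError
        If either vector is constant (correlation undefined).
    ValueError
        On mismatched lengths or fewer than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for constant vector")
    return float(stats.pearsonr(x, y).statistic)


def comparable_rscu(profile_a: UsageProfile, profile_b: UsageProfile,
                    code: GeneticCode,
                    labels: tuple[str, str] = ("a", "b"),
                    ) -> tuple[RscuVector, RscuVector]:
    """Align two profiles onto the codons comparable in both.

    The comparable set is restricted to sense codons of families with
    degeneracy >= 2 (single-codon families carry RSCU = 1 identically and
    no signal), dropping any codon that is NA on either side.  Both
    vectors use the same lexicographic codon order.
    """
    multi = {c for fam in code.families.values() if len(fam) >= 2
             for c in fam}
    codons = [c for c in ALL_CODONS
              if c in multi
              and profile_a.rscu[c] is not None
              and profile_b.rscu[c] is not None]
    if len(codons) < MIN_COMPARABLE_CODONS:
        raise InsufficientOverlapError(
            f"only {len(codons)} comparable codons (need "
            f">= {MIN_COMPARABLE_CODONS})")
    va = RscuVector(tuple(profile_a.rscu[c] for c in codons),
                    tuple(codons), labels[0])
    vb = RscuVector(tuple(profile_b.rscu[c] for c in codons),
                    tuple(codons), labels[1])
    return va, vb


def _correlate(profile: UsageProfile, hosts, code) -> dict[str, float]:
    out = {}
    for label, host_profile in hosts:
        va, vb = comparable_rscu(profile, host_profile, code,
                                 labels=("query", label))
        out[label] = pearson(va.values, vb.values)
    return out


def predict_host(phage_cds: list[CdsRecord],
                 hosts: list[tuple[str, UsageProfile]],
                 code: GeneticCode) -> HostComparison:
    """Score each phage gene, and the pooled gene set, against every host.

    Per gene, RSCU is computed from that gene's codons alone; genes with
    fewer than 10 comparable codons against any host, or a constant RSCU
    vector, are skipped and reported.  A gene whose best correlation is
    an exact tie between hosts is left unassigned and excluded from the
    tally.  "Collective" pools counts over all phage genes.
    """
    if not phage_cds:
        raise ValueError("empty phage CDS list")
    if len(hosts) < 2:
        raise ValueError("need at least 2 host profiles")

    per_gene: list[GeneAssignment] = []
    tally = {label: 0 for label, _ in hosts}
    skipped: list[tuple[str, str]] = []
    for rec in phage_cds:
        try:
            gene_profile = profile_from_cds([rec], code)
            r_by_host = _correlate(gene_profile, hosts, code)
        except (InsufficientOverlapError, ConstantVectorError,
                ValueError) as exc:
            skipped.append((rec.id, str(exc)))
            continue
        best_r = max(r_by_host.values())
        winners = [h for h, r in r_by_host.items() if r == best_r]
        assigned = winners[0] if len(winners) == 1 else None
        if assigned is None:
            logger.warning("gene %s tied between hosts %s; left unassigned",
                           rec.id, winners)
        else:
            tally[assigned] += 1
        per_gene.append(GeneAssignment(rec.id, r_by_host, assigned))

    pooled = profile_from_cds(phage_cds, code)
    collective = _correlate(pooled, hosts, code)
    return HostComparison(per_gene=per_gene, collective=collective,
                          tally=tally, skipped_genes=skipped)
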