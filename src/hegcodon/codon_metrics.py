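"""Codon counting and the three usage-bias statistics.

For a set of genes with observed codon counts x_c, the statistics are
computed per synonymous family a (degeneracy n_a):

* RSCU_c  = x_c * n_a / sum_{c' in a} x_{c'} — observed over expected
  under equal synonymous usage; 1 means no bias, n_a means exclusive use.
* NRSCU_c = RSCU_c / max_{c' in a} RSCU_{c'} — the relative-adaptiveness
  rescaling (the w_c of the CAI literature): the preferred codon of each
  family scores 1.
* FB_c    = x_c / n_codons — the codon's overall frequency among all
  sense codons counted in the gene set ("frequency bias").

Families with zero observations yield the NA sentinel (None), which
propagates to the CSV as an empty field; stop codons are always NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import HegcodonError
from .genetic_code import ALL_CODONS, GeneticCode
from .io_seq import CdsRecord

logger = logging.getLogger(__name__)

Stat = dict[str, float | None]


@dataclass
class CodonCounts:
    """Aggregated codon counts for a gene set.

    ``n_codons`` totals sense codons only; terminal stops are excluded
    entirely, internal stops appear in ``counts`` but not in
    ``n_codons``, and codons containing ambiguity characters are tallied
    in ``skipped_codons``.
    """

    counts: dict[str, int]
    n_codons: int
    n_genes: int
    skipped_codons: int = 0
    skipped_genes: int = 0


@dataclass
class UsageProfile:
    """RSCU / NRSCU / FB over the 64 codons, plus the underlying counts."""

    rscu: Stat
    nrscu: Stat
    fb: Stat
    counts: CodonCounts


def count_codons(cds: list[CdsRecord], code: GeneticCode) -> CodonCounts:
    """Count codons in frame 0 across a gene set.

    Records whose length is not a multiple of three are skipped with a
    warning (truncating would silently shift frame).  The terminal stop
    codon of each gene is not counted at all; internal stops land in the
    stop rows; N-containing codons are skipped and tallied.
    """
    if not cds:
        raise ValueError("empty CDS list")
    counts = {c: 0 for c in ALL_CODONS}
    n_sense = 0
    n_genes = 0
    skipped_codons = 0
    skipped_genes = 0
    for rec in cds:
        seq = rec.seq.upper()
        if len(seq) % 3 != 0:
            logger.warning("skipping %s: length %d not divisible by 3",
                           rec.id, len(seq))
            skipped_genes += 1
            continue
        n_genes += 1
        n_cod = len(seq) // 3
        for i in range(n_cod):
            codon = seq[3 * i : 3 * i + 3]
            if codon not in counts:  # contains N or other ambiguity
                skipped_codons += 1
                continue
            if codon in code.stop_codons:
                if i == n_cod - 1:
                    continue  # terminal stop: excluded from everything
                counts[codon] += 1  # internal stop: recorded, not sense
                continue
            counts[codon] += 1
            n_sense += 1
    return CodonCounts(counts=counts, n_codons=n_sense, n_genes=n_genes,
                       skipped_codons=skipped_codons,
                       skipped_genes=skipped_genes)


def rscu(counts: CodonCounts, code: GeneticCode) -> Stat:
    """Relative synonymous codon usage per codon (None where undefined)."""
    out: Stat = {c: None for c in ALL_CODONS}
    for aa, family in code.families.items():
        total = sum(counts.counts[c] for c in family)
        if total == 0:
            continue  # unobserved family stays NA
        n_a = len(family)
        for c in family:
            out[c] = counts.counts[c] * n_a / total
    return out


def nrscu(rscu_map: Stat, code: GeneticCode, *, form: str = "max") -> Stat:
    """Normalised RSCU.

    ``form="max"`` (default) rescales so the most-used codon of each
    family scores 1 (relative adaptiveness).  ``form="sum"`` divides by
    the family sum instead (within-family frequency).  NA propagates.
    """
    if form not in ("max", "sum"):
        raise ValueError(f"unknown NRSCU form {form!r}")
    out: Stat = {c: None for c in ALL_CODONS}
    for family in code.families.values():
        vals = [rscu_map[c] for c in family]
        if any(v is None for v in vals):
            continue
        denom = max(vals) if form == "max" else sum(vals)
        if denom == 0:
            continue
        for c in family:
            out[c] = rscu_map[c] / denom
    return out


def fb(counts: CodonCounts, code: GeneticCode, *,
       form: str = "overall") -> Stat:
    """Frequency bias.

    ``form="overall"`` (default): each sense codon's share of all sense
    codons counted; sums to 1 over the gene set.  ``form="within_family"``:
    each codon's share within its own synonymous family.
    """
    if form not in ("overall", "within_family"):
        raise ValueError(f"unknown FB form {form!r}")
    if counts.n_codons == 0:
        raise HegcodonError("no sense codons counted; FB undefined")
    out: Stat = {c: None for c in ALL_CODONS}
    for family in code.families.values():
        total = sum(counts.counts[c] for c in family)
        if total == 0:
            continue  # unobserved family: NA, like RSCU
        for c in family:
            out[c] = (counts.counts[c] / counts.n_codons
                      if form == "overall"
                      else counts.counts[c] / total)
    return out


def profile_from_counts(counts: CodonCounts, code: GeneticCode) -> UsageProfile:
    """Compute all three statistics from aggregated counts."""
    r = rscu(counts, code)
    return UsageProfile(rscu=r, nrscu=nrscu(r, code), fb=fb(counts, code),
                        counts=counts)


def profile_from_cds(cds: list[CdsRecord], code: GeneticCode) -> UsageProfile:
    """Convenience: counts plus statistics for a plain gene set."""
    return profile_from_counts(count_codons(cds, code), code)


def profile_from_hegs(hits, cds_index: dict[str, CdsRecord],
                      code: GeneticCode) -> UsageProfile:
    """Aggregate over the unique CDS referenced by HEG hits.

    A CDS that is the top hit for two families is counted once.
    """
    if not hits:
        raise ValueError("empty hit list")
    unique_ids: list[str] = []
    seen = set()
    for h in hits:
        if h.cds_id not in seen:
            seen.add(h.cds_id)
            unique_ids.append(h.cds_id)
    try:
        records = [cds_index[i] for i in unique_ids]
    except KeyError as exc:
        raise KeyError(f"hit references unknown CDS id {exc.args[0]!r}")
    return profile_from_cds(records, code)
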