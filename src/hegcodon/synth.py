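"""Synthetic CDS sets, genomes and reference databases.

Everything downstream of the FASTA parsers can be exercised without any
external data by generating gene sets whose codon usage follows known
per-amino-acid weight distributions.  Back-translation samples each site
independently, so within-family codon frequencies of a generated set
converge to the weights at the binomial rate — which is what makes the
parameter-recovery tolerances in the tests computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetic_code import GeneticCode, load_code
from .heg_search import ReferenceDB, ReferenceDbEntry
from .io_seq import CdsRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: 13-nt cassette with a stop codon in all six reading frames and no
#: start codon in any frame; placed around planted genes so the ORF
#: caller's stop-to-stop segments end exactly at gene boundaries.
STOP_CASSETTE = "CTAGTTAGTTAGT"


@dataclass
class UsageSpec:
    """Generating distribution for a synthetic CDS set.

    ``weights`` maps each amino-acid letter to a probability vector over
    its synonymous codons, in the family's lexicographic codon order.
    """

    weights: dict[str, np.ndarray]
    seed: int = 0
    gene_len_aa: int = 300
    n_genes: int = 100
    code: GeneticCode = field(default_factory=load_code)

    def __post_init__(self):
        for aa, fam in self.code.families.items():
            w = np.asarray(self.weights[aa], dtype=float)
            if w.shape != (len(fam),):
                raise ValueError(
                    f"weight vector for {aa} has arity {w.shape}, "
                    f"family has {len(fam)} codons")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"weights for {aa} must be a distribution")
            self.weights[aa] = w / w.sum()


def uniform_spec(code: GeneticCode | None = None, **kw) -> UsageSpec:
    """Equal weight on every synonymous codon (no bias)."""
    code = code or load_code()
    w = {aa: np.full(len(fam), 1.0 / len(fam))
         for aa, fam in code.families.items()}
    return UsageSpec(weights=w, code=code, **kw)


def _third_base_biased_spec(code: GeneticCode, favored: str,
                            beta: float, **kw) -> UsageSpec:
    w = {}
    for aa, fam in code.families.items():
        raw = np.array([np.exp(beta * (c[2] in favored)) for c in fam])
        w[aa] = raw / raw.sum()
    return UsageSpec(weights=w, code=code, **kw)


def dominant_codon_spec(code: GeneticCode | None = None,
                        preferred_weight: float = 0.9,
                        **kw) -> UsageSpec:
    """Strong translational-selection archetype: the first codon of each
    family carries ``preferred_weight``, the rest share the remainder.

    With weights this far from 1/2, a sampled set of 200 genes x 300
    codons pins each within-family frequency to its weight well inside
    +/-0.02 (>= 3 binomial standard errors), which is what the
    parameter-recovery checks rely on.
    """
    code = code or load_code()
    w = {}
    for aa, fam in code.families.items():
        n = len(fam)
        if n == 1:
            w[aa] = np.array([1.0])
        else:
            rest = (1.0 - preferred_weight) / (n - 1)
            w[aa] = np.array([preferred_weight] + [rest] * (n - 1))
    return UsageSpec(weights=w, code=code, **kw)


def gc3_rich_spec(code: GeneticCode | None = None, beta: float = 2.5,
                  **kw) -> UsageSpec:
    """Host archetype preferring G/C in the third codon position."""
    return _third_base_biased_spec(code or load_code(), "GC", beta, **kw)


def at3_rich_spec(code: GeneticCode | None = None, beta: float = 2.5,
                  **kw) -> UsageSpec:
    """Host archetype preferring A/T in the third codon position."""
    return _third_base_biased_spec(code or load_code(), "AT", beta, **kw)


def back_translate(protein: str, spec: UsageSpec,
                   rng: np.random.Generator) -> str:
    """Sample one codon per residue from the spec's family weights."""
    code = spec.code
    codons = []
    for aa in protein:
        fam = code.families[aa]
        codons.append(fam[rng.choice(len(fam), p=spec.weights[aa])])
    return "".join(codons)


def sample_cds(spec: UsageSpec, protein: str | None = None,
               id_prefix: str = "gene") -> list[CdsRecord]:
    """Generate ``spec.n_genes`` coding sequences.

    Each gene's amino-acid sequence is either ``protein`` (for planted
    homologs) or drawn uniformly over the 20 amino acids; every residue
    is back-translated by sampling its family's weights.  ATG is
    prepended and TAA appended.  Deterministic for a fixed seed.
    """
    if protein is not None and ("*" in protein or
                                set(protein) - set(_AA20)):
        raise ValueError("protein must use the 20 standard amino acids")
    rng = np.random.default_rng(spec.seed)
    records = []
    for g in range(spec.n_genes):
        if protein is None:
            aa_idx = rng.integers(0, 20, size=spec.gene_len_aa)
            aa_seq = "".join(_AA20[i] for i in aa_idx)
        else:
            aa_seq = protein
        seq = "ATG" + back_translate(aa_seq, spec, rng) + "TAA"
        records.append(CdsRecord(id=f"{id_prefix}{g + 1:04d}", seq=seq,
                                 source="annotated_input"))
    return records


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _spacer(n: int, rng: np.random.Generator) -> str:
    """Intergenic filler: random core flanked by stop cassettes when
    there is room, so adjacent genes sit in stop-bounded segments."""
    cl = len(STOP_CASSETTE)
    if n >= 2 * cl:
        core = "".join(rng.choice(list("ACGT"), size=n - 2 * cl))
        return STOP_CASSETTE + core + STOP_CASSETTE
    if n >= cl:
        return STOP_CASSETTE + "".join(rng.choice(list("ACGT"),
                                                  size=n - cl))
    return "".join(rng.choice(list("ACGT"), size=n))


def plant_genome(spec: UsageSpec, intergenic_len: int = 100,
                 seed: int = 0, contig_id: str = "synthcontig1",
                 proteins: list[str] | None = None,
                 ) -> tuple[list[tuple[str, str]], list[dict]]:
    """Embed sampled genes in a single contig with intergenic spacers.

    Each gene is placed on a random strand.  Returns the genome as
    ``[(contig_id, seq)]`` plus a truth table of dicts with keys
    gene_id, contig, start, end, strand, cds (forward 0-based half-open
    coordinates; ``cds`` is the coding-strand sequence).
    """
    if intergenic_len < 0:
        raise ValueError("intergenic_len must be >= 0")
    rng = np.random.default_rng(seed)
    if proteins is None:
        genes = sample_cds(spec)
    else:
        genes = []
        for k, prot in enumerate(proteins):
            one = UsageSpec(weights=dict(spec.weights), code=spec.code,
                            seed=int(rng.integers(0, 2**31 - 1)),
                            n_genes=1, gene_len_aa=len(prot))
            rec = sample_cds(one, protein=prot,
                             id_prefix=f"planted{k + 1:02d}_")[0]
            genes.append(rec)
    parts = [_spacer(intergenic_len, rng)]
    pos = len(parts[0])
    truth = []
    for rec in genes:
        strand = "+" if rng.random() < 0.5 else "-"
        insert = rec.seq if strand == "+" else _revcomp(rec.seq)
        truth.append({"gene_id": rec.id, "contig": contig_id,
                      "start": pos, "end": pos + len(insert),
                      "strand": strand, "cds": rec.seq})
        parts.append(insert)
        pos += len(insert)
        sp = _spacer(intergenic_len, rng)
        parts.append(sp)
        pos += len(sp)
    return [(contig_id, "".join(parts))], truth


def make_reference_db(n_families: int, per_family: int, seed: int,
                      family_ids: list[str] | None = None,
                      len_range: tuple[int, int] = (150, 400),
                      mutation_rate: float = 0.10) -> ReferenceDB:
    """Build a synthetic HEG reference database.

    Per family: one master protein (seeded random, length drawn from
    ``len_range``) plus ``per_family - 1`` copies with ``mutation_rate``
    of positions substituted — a stand-in for a curated database of
    family representatives drawn from real proteomes.
    """
    from .heg_search import load_families  # local import avoids cycle
    if family_ids is None:
        family_ids = load_families()
    if n_families > len(family_ids):
        raise ValueError(f"at most {len(family_ids)} families available")
    rng = np.random.default_rng(seed)
    entries = []
    for family in family_ids[:n_families]:
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        master = "".join(_AA20[i] for i in rng.integers(0, 20, size=length))
        entries.append(ReferenceDbEntry(f"{family}_1", family, master))
        for k in range(2, per_family + 1):
            seq = list(master)
            n_mut = int(round(mutation_rate * length))
            sites = rng.choice(length, size=n_mut, replace=False)
            for s in sites:
                choices = _AA20.replace(seq[s], "")
                seq[s] = choices[rng.integers(0, len(choices))]
            entries.append(ReferenceDbEntry(f"{family}_{k}", family,
                                            "".join(seq)))
    return ReferenceDB(entries=entries)


def write_reference_fasta(db: ReferenceDB, path: str | Path) -> None:
    """Write a reference database with ``family=`` header tags."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in db.entries:
            fh.write(f">{e.protein_id} family={e.family_id}\n")
            for i in range(0, len(e.seq), 60):
                fh.write(e.seq[i : i + 60] + "\n")


def write_truth_table(truth: list[dict], path: str | Path) -> None:
    """Write the planted-gene coordinates as TSV."""
    cols = ["gene_id", "contig", "start", "end", "strand", "cds"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
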