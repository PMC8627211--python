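# Methods

## Genetic code and counting conventions

All statistics are defined over NCBI translation table 11
(bacteria/archaea); table 1 is also supported and the table is
selectable everywhere a `GeneticCode` is accepted. The 61 sense codons
partition into synonymous families of degeneracy 1–6; the two
single-codon families of table 11 (ATG/Met, TGG/Trp) carry RSCU = 1
identically and are excluded from correlation vectors.

Codons are read in frame from position 0 of each CDS. The terminal stop
codon is excluded from all counts; an internal in-frame stop is recorded
in the stop rows of the usage table but never enters sense-codon totals;
codons containing ambiguity characters (N etc.) are skipped and tallied
separately. A record whose length is not a multiple of three is skipped
with a warning rather than truncated — truncation would silently shift
the reading frame of everything downstream.

Alternative start codons (GTG, TTG) translate by their table identity
inside genes; only position 1 of an ORF called by this package is
rendered as M, matching standard gene-caller convention.

## Statistics

With $x_c$ the count of codon $c$ in family $a$ (degeneracy $n_a$) and
$N$ the total sense-codon count:

- RSCU$_c = x_c n_a / \sum_{c'\in a} x_{c'}$. Family sums equal $n_a$
  by construction; this conservation is asserted to 1e-9 in the tests.
- NRSCU$_c$ = RSCU$_c$ / max over the family — the relative-adaptiveness
  form ($w_c$ of the CAI literature). A family-sum normalisation is
  available via `nrscu(..., form="sum")`.
- FB$_c = x_c / N$ — the codon's overall frequency in the HEG set. A
  within-family form is available via `fb(..., form="within_family")`.

NRSCU and FB have no universally fixed definition in the codon-usage
literature; the defaults here were chosen because the max-normalised
form is the standard "normalised RSCU" and the overall-frequency form is
non-redundant with RSCU (a within-family frequency would equal
RSCU$/n_a$). Both alternatives are kept as switches.

Families with zero observations yield an NA sentinel for all three
statistics (empty field in the CSV), deliberately distinct from 0, which
means "family observed, codon unused".

## ORF calling

The unannotated branch uses a deterministic six-frame scan: within each
stop-to-stop segment of each frame, the most upstream in-frame start
codon (ATG/GTG/TTG) opens at most one ORF, which runs to and including
the stop; ORFs shorter than 90 nt, and segments that run off a contig
end without a stop, are discarded. N-containing codons never match a
start or stop. This trades the precision of a statistical gene finder
for determinism and zero external dependencies; precision is recovered
downstream because only CDS with strong translated homology to an HEG
family are ever counted. The cost is sensitivity at contig edges and
for genes whose true start lies downstream of an earlier in-frame start.

## HEG search

Each translated CDS is aligned locally (Smith–Waterman, affine gaps)
against every reference protein; per family the single best-scoring
(CDS, entry) pair is kept. Scoring is BLOSUM62 with gap open 11 /
extend 1 (a gap of length L costs 11 + L), the de-facto default of
protein search tools; X scores 0 against everything. Significance uses
the Karlin–Altschul transform with the gapped BLOSUM62 constants
λ = 0.267, K = 0.041: bits = (λS − ln K)/ln 2 and
E = m·n·2^(−bits) with m the query length and n the total residues in
the reference database. The default cutoff E ≤ 1e-5 is deliberately
stringent: a missed borderline HEG costs little (39 families remain),
while a spurious one contaminates the statistics. Score ties between
CDS go to the lexicographically smaller id; a CDS winning several
families is allowed but logged.

The exhaustive dynamic program is the only search mode: at the problem
sizes this package targets (hundreds of candidate ORFs against ~10²
reference proteins) it completes in seconds, so no heuristic seeding
layer is included. A 12-column tabular adapter
(`read_external_hits`) lets users substitute any external aligner that
emits BLAST-style output.

The 40 HEG family identifiers shipped in `data/families.txt` (large- and
small-subunit ribosomal proteins plus the translation factors fusA,
tufA, tsf) are configuration, not data: the reference *sequences* are
user-supplied, and `synth.make_reference_db` builds a synthetic
stand-in database for testing.

## Host prediction

Per phage gene, RSCU is computed from that gene's codons alone and
correlated (sample Pearson r) against each host profile over the
comparable codon set: sense codons of families with degeneracy ≥ 2,
excluding any codon NA in either profile (59 codons when both profiles
are complete). Genes with fewer than 10 comparable codons, or a
constant RSCU vector, are skipped and reported. A gene is assigned to
the host with the highest r; an exact tie leaves it unassigned rather
than defaulting to the first host. "Collective" means RSCU over the
pooled counts of all phage genes — pooling, not averaging per-gene RSCU,
because that is how the host HEG profiles themselves are built.

## Synthetic data

`UsageSpec` holds per-family codon weight vectors; genes are generated
by drawing amino acids uniformly (or taking a supplied protein) and
back-translating each site independently from the family weights, with
ATG prepended and TAA appended. Independence across sites makes
recovery tolerances computable from binomial error. Three archetypes
ship as constructors: `uniform_spec` (no bias), `gc3_rich_spec` /
`at3_rich_spec` (third-position bias with weight ∝ exp(β·[third base
favored]), β = 2.5, mimicking divergent mutational/selectional regimes),
and `dominant_codon_spec` (0.9 of the mass on one codon per family,
mimicking strong translational selection).

Parameter-recovery checks use the dominant-codon spec at 200 genes ×
300 aa: with weights this extreme the binomial standard error of every
within-family frequency is ≤ 0.0056, so the asserted ±0.02 tolerance is
a ≥ 3σ bound. With near-uniform weights the same tolerance would sit at
~2σ and fail a substantial fraction of seeds; uniform-weight recovery is
therefore asserted at an explicit 3.5-SE binomial bound instead.

`plant_genome` concatenates genes (random strand each) with random
spacers whose ends carry a fixed 13-nt cassette (`CTAGTTAGTTAGT`)
containing a stop codon in all six reading frames and no start codon in
any frame. The cassette guarantees that each planted gene's
stop-bounded segment begins at the gene's own start codon, so the ORF
caller recovers planted genes exactly rather than extended through an
upstream in-frame start in random spacer sequence.

What the generator does **not** emulate: realistic intergenic
composition, operon structure, codon autocorrelation within genes,
amino-acid composition of real proteins, overlapping genes, and
sequencing artifacts. Passing tests therefore demonstrate correctness
of the computations and recoverability under the stated generative
model, not performance on real draft assemblies.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated
data: the full-pipeline check plants all 40 families (~37 kb genome,
~400 candidate ORFs against 80 reference proteins), the null check
searches 100 random ORFs, and the host study uses 90 phage genes of 220
codons against two 40-gene host profiles. All generators take explicit
seeds; identical inputs and configuration produce byte-identical CSV
and FASTA outputs (no timestamps in payload files).

## Known limitations

- E-value constants are hard-coded for BLOSUM62 11/1; other scoring
  schemes would need user-supplied λ and K.
- The ORF caller discards ORFs without an in-frame stop on the contig,
  losing genes truncated by contig ends.
- Host prediction assumes candidate host profiles are comparable in
  completeness; a host profile with many unobserved families shrinks
  the comparable codon set for every gene.
- The shipped family list is configuration; results depend on the
  user-supplied reference database actually containing representative
  homologs for those families.
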