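"""Compute RSCU / NRSCU / frequency bias for a small gene set.

Generates 30 synthetic genes whose codon usage strongly prefers the
first codon of every synonymous family, then prints the three statistics
for the lysine family (AAA/AAG) and the most-used codons overall.
"""

from hegcodon import load_code
from hegcodon.codon_metrics import profile_from_cds
from hegcodon.synth import dominant_codon_spec, sample_cds

code = load_code(11)
genes = sample_cds(dominant_codon_spec(seed=42, n_genes=30,
                                       gene_len_aa=200))
prof = profile_from_cds(genes, code)

print(f"genes: {len(genes)}, sense codons counted: "
      f"{prof.counts.n_codons}")
print("codon  aa  count   RSCU   NRSCU      FB")
for codon in ("AAA", "AAG", "GCA", "GCT"):
    aa = code.codon_to_aa[codon]
    print(f"{codon}    {aa}  {prof.counts.counts[codon]:6d} "
          f"{prof.rscu[codon]:6.3f}  {prof.nrscu[codon]:6.3f} "
          f"{prof.fb[codon]:7.4f}")

# RSCU ~ degeneracy for the preferred codon and ~0 for the others marks
# a strongly biased family; NRSCU rescales so the preferred codon is 1;
# FB is each codon's share of all counted sense codons.
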