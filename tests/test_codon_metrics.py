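import numpy as np
import pytest

from hegcodon.codon_metrics import (CodonCounts, count_codons, fb, nrscu,
                                    profile_from_cds, profile_from_hegs,
                                    rscu)
from hegcodon.genetic_code import ALL_CODONS
from hegcodon.heg_search import HegHit
from hegcodon.io_seq import CdsRecord
from hegcodon.synth import UsageSpec, sample_cds, uniform_spec


def _counts(code, **codon_counts):
    counts = {c: 0 for c in ALL_CODONS}
    counts.update(codon_counts)
    n_sense = sum(v for c, v in counts.items()
                  if c not in code.stop_codons)
    return CodonCounts(counts=counts, n_codons=n_sense, n_genes=1)


class TestCountCodons:
    def test_single_gene_example(self, code):
        cc = count_codons([CdsRecord(id="g", seq="ATGGCTGCTTAA")], code)
        assert cc.counts["ATG"] == 1 and cc.counts["GCT"] == 2
        assert cc.counts["TAA"] == 0  # terminal stop excluded entirely
        assert cc.n_codons == 3
        assert cc.n_genes == 1

    def test_frame_violation_skipped(self, code):
        cc = count_codons([CdsRecord(id="bad", seq="ATGGC"),
                           CdsRecord(id="ok", seq="ATGTAA")], code)
        assert cc.n_genes == 1 and cc.skipped_genes == 1

    def test_internal_stop_and_ambiguity(self, code):
        cc = count_codons([CdsRecord(id="g", seq="ATGTAANNNGCTTAA")],
                          code)
        assert cc.counts["TAA"] == 1       # internal stop recorded
        assert cc.n_codons == 2            # ATG + GCT only
        assert cc.skipped_codons == 1      # the NNN codon

    def test_empty_input_error(self, code):
        with pytest.raises(ValueError):
            count_codons([], code)

    def test_uniform_sampling_frequencies(self, code):
        """Codons of genes sampled uniformly over sense codons appear at
        frequency 1/61 within binomial error."""
        rng = np.random.default_rng(7)
        sense = code.sense_codons
        genes = []
        n_codons_per_gene = 200
        for g in range(1000):
            idx = rng.integers(0, 61, size=n_codons_per_gene)
            genes.append(CdsRecord(id=f"g{g}",
                                   seq="".join(sense[i] for i in idx)))
        cc = count_codons(genes, code)
        n = cc.n_codons
        p = 1 / 61
        se = np.sqrt(p * (1 - p) / n)
        for c in sense:
            assert abs(cc.counts[c] / n - p) < 3.5 * se


class TestRscu:
    def test_exclusive_codon(self, code):
        r = rscu(_counts(code, GCT=2), code)
        assert r["GCT"] == pytest.approx(4.0)
        assert r["GCC"] == r["GCA"] == r["GCG"] == 0.0

    def test_lysine_hand_example(self, code):
        r = rscu(_counts(code, AAA=3, AAG=1), code)
        assert r["AAA"] == pytest.approx(1.5)   # 3 * 2 / 4
        assert r["AAG"] == pytest.approx(0.5)   # 1 * 2 / 4

    def test_uniform_counts_give_one(self, code):
        counts = _counts(code, **{c: 5 for c in code.sense_codons})
        r = rscu(counts, code)
        for c in code.sense_codons:
            assert r[c] == pytest.approx(1.0)

    def test_na_for_unobserved_and_stops(self, code):
        r = rscu(_counts(code, AAA=1), code)
        assert r["GCT"] is None and r["TAA"] is None
        assert r["ATG"] is None  # single-codon family unobserved

    def test_single_codon_family_observed(self, code):
        r = rscu(_counts(code, ATG=10), code)
        assert r["ATG"] == pytest.approx(1.0)

    def test_family_sums_equal_degeneracy(self, code):
        rng = np.random.default_rng(3)
        counts = _counts(code, **{c: int(rng.integers(0, 50))
                                  for c in code.sense_codons})
        r = rscu(counts, code)
        for aa, fam in code.families.items():
            vals = [r[c] for c in fam]
            if all(v is not None for v in vals):
                assert sum(vals) == pytest.approx(len(fam), abs=1e-9)


class TestNrscuFb:
    def test_lysine_nrscu(self, code):
        r = rscu(_counts(code, AAA=3, AAG=1), code)
        n = nrscu(r, code)
        assert n["AAA"] == pytest.approx(1.0)
        assert n["AAG"] == pytest.approx(1 / 3)

    def test_nrscu_max_is_one_and_na_propagates(self, code):
        rng = np.random.default_rng(5)
        counts = _counts(code, **{c: int(rng.integers(1, 50))
                                  for c in code.sense_codons})
        n = nrscu(rscu(counts, code), code)
        for fam in code.families.values():
            assert max(n[c] for c in fam) == pytest.approx(1.0)
        n2 = nrscu(rscu(_counts(code, AAA=1), code), code)
        assert n2["GCT"] is None

    def test_nrscu_sum_form(self, code):
        r = rscu(_counts(code, AAA=3, AAG=1), code)
        n = nrscu(r, code, form="sum")
        assert n["AAA"] == pytest.approx(0.75)

    def test_fb_hand_example(self, code):
        f = fb(_counts(code, ATG=1, GCT=2), code)
        assert f["GCT"] == pytest.approx(2 / 3)
        assert f["ATG"] == pytest.approx(1 / 3)
        assert f["TAA"] is None

    def test_fb_sums_to_one(self, code):
        rng = np.random.default_rng(6)
        counts = _counts(code, **{c: int(rng.integers(0, 30))
                                  for c in code.sense_codons})
        f = fb(counts, code)
        assert sum(v for v in f.values() if v is not None) == \
            pytest.approx(1.0)

    def test_fb_within_family_form(self, code):
        f = fb(_counts(code, AAA=3, AAG=1), code, form="within_family")
        assert f["AAA"] == pytest.approx(0.75)


class TestProfiles:
    def test_permutation_and_duplication_invariance(self, code):
        spec = uniform_spec(seed=8, n_genes=12, gene_len_aa=60)
        genes = sample_cds(spec)
        p1 = profile_from_cds(genes, code)
        p2 = profile_from_cds(genes[::-1], code)
        p3 = profile_from_cds(genes + genes, code)
        assert p1.rscu == p2.rscu
        assert p1.rscu == pytest.approx(p3.rscu)
        assert p1.fb == pytest.approx(p3.fb)

    def test_profile_from_hegs_dedup(self, code):
        rec = CdsRecord(id="g1", seq="ATGGCTGCTTAA")
        index = {"g1": rec}
        one = profile_from_hegs([HegHit("rplA", "g1", 10, 20.0, 1e-9, 1.0)],
                                index, code)
        two = profile_from_hegs(
            [HegHit("rplA", "g1", 10, 20.0, 1e-9, 1.0),
             HegHit("rpsB", "g1", 10, 20.0, 1e-9, 1.0)], index, code)
        assert one.counts.counts == two.counts.counts
        assert one.fb["GCT"] == pytest.approx(2 / 3)

    def test_unknown_cds_id_error(self, code):
        with pytest.raises(KeyError, match="ghost"):
            profile_from_hegs([HegHit("rplA", "ghost", 1, 1.0, 1.0, 1.0)],
                              {}, code)

    def test_parameter_recovery_from_known_weights(self, code):
        """Within-family frequencies of a gene set generated under a
        strongly biased (dominant-codon) spec land within +/-0.02 of the
        generating weights — a >= 3-sigma binomial bound at this size."""
        from hegcodon.synth import dominant_codon_spec
        spec = dominant_codon_spec(seed=11, n_genes=200, gene_len_aa=300)
        prof = profile_from_cds(sample_cds(spec), code)
        for aa, fam in code.families.items():
            total = sum(prof.counts.counts[c] for c in fam)
            for c, w in zip(fam, spec.weights[aa]):
                assert abs(prof.counts.counts[c] / total - w) < 0.02
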