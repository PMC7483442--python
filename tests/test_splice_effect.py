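"""Splice-acceptor consequence prediction, translation and domain reporting."""

import numpy as np
import pytest

from dwarfmap import splice_effect as se

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_first_stop(transcript):
    """Independent oracle: scan codon positions for the first in-frame stop."""
    for i in range(0, len(transcript) - 2, 3):
        if transcript[i:i + 3] in STOPS:
            return i // 3, (i + 1, i + 3)
    return None, None


class TestExampleGene:
    def test_layout(self, example_gene):
        model, variant = example_gene
        assert len(model.sequence) == 1_257
        assert model.exons == [(1, 503), (627, 1_257)]
        assert model.introns == [(504, 626)]
        assert model.intron_is_canonical(0)
        assert (variant.pos, variant.ref_base, variant.alt_base) == (626, "G", "A")

    def test_canonical_protein(self, example_gene):
        model, _ = example_gene
        canon = se.canonical_isoform(model)
        assert canon.protein_length == 377
        assert canon.stop_codon_span == (1_132, 1_134)
        assert canon.domains_retained == {"Fe2OG dioxygenase": "retained"}

    def test_acceptor_variant_isoforms(self, example_gene):
        model, variant = example_gene
        isoforms = {r.label: r for r in se.enumerate_isoforms(model, variant)}
        assert set(isoforms) == {"intron_retention", "cryptic_acceptor"}
        retention = isoforms["intron_retention"]
        assert retention.stop_codon_span == (505, 507)
        assert retention.transcript[504:507] == "TAG"
        assert retention.protein_length == 168
        assert retention.cds_delta == 123  # intron length
        cryptic = isoforms["cryptic_acceptor"]
        assert cryptic.cds_delta == -13
        assert cryptic.stop_codon_span == (520, 522)
        assert cryptic.transcript[519:522] == "TGA"
        assert cryptic.protein_length == 173
        # both truncations precede the catalytic domain: it is lost
        assert retention.domains_retained == {"Fe2OG dioxygenase": "lost"}
        assert cryptic.domains_retained == {"Fe2OG dioxygenase": "lost"}

    def test_enumeration_is_deterministic_and_idempotent(self, example_gene):
        model, variant = example_gene
        a = se.enumerate_isoforms(model, variant)
        b = se.enumerate_isoforms(model, variant)
        assert [(r.label, r.transcript, r.cds_delta) for r in a] == \
               [(r.label, r.transcript, r.cds_delta) for r in b]
        rebuilt, _ = se.build_example_gene()
        assert rebuilt.sequence == model.sequence


class TestClassification:
    def test_acceptor_terminal_g(self, example_gene):
        model, variant = example_gene
        assert se.classify_splice_variant(model, variant) == "acceptor_disruption"

    def test_acceptor_penultimate_base(self, example_gene):
        model, _ = example_gene
        v = se.Variant(pos=625, ref_base=model.sequence[624], alt_base="C")
        assert se.classify_splice_variant(model, v) == "acceptor_disruption"

    def test_donor_disruption(self, example_gene):
        model, _ = example_gene
        v = se.Variant(pos=504, ref_base="G", alt_base="A")  # GT -> AT
        assert se.classify_splice_variant(model, v) == "donor_disruption"

    def test_exonic_and_intronic_other(self, example_gene):
        model, _ = example_gene
        mid_exon = se.Variant(pos=250, ref_base=model.sequence[249], alt_base="A"
                              if model.sequence[249] != "A" else "C")
        assert se.classify_splice_variant(model, mid_exon) == "exonic"
        mid_intron = se.Variant(pos=560, ref_base=model.sequence[559], alt_base="A"
                                if model.sequence[559] != "A" else "C")
        assert se.classify_splice_variant(model, mid_intron) == "intronic_other"

    def test_reference_mismatch_rejected(self, example_gene):
        model, _ = example_gene
        wrong = "A" if model.sequence[625] != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            se.classify_splice_variant(model, se.Variant(626, wrong, "T"))

    def test_non_acceptor_variant_rejected_by_enumeration(self, example_gene):
        model, _ = example_gene
        v = se.Variant(pos=250, ref_base=model.sequence[249],
                       alt_base="A" if model.sequence[249] != "A" else "C")
        with pytest.raises(ValueError, match="canonical"):
            se.enumerate_isoforms(model, v)


class TestTranslation:
    def test_minimal_transcript(self):
        # one Met codon, then the stop: protein "M", stop at nt 4-6
        protein, span = se.translate_first_orf("ATGTAA")
        assert protein == "M" and span == (4, 6)
        assert 3 * len(protein) + 3 == span[1]

    @pytest.mark.parametrize("stop_start,expected_len", [(505, 168), (520, 173)])
    def test_stop_position_to_length_arithmetic(self, stop_start, expected_len):
        # a transcript with its first in-frame stop at a given position
        rng = np.random.default_rng(stop_start)
        codons = ["ATG"] + [c for c in ("GCA", "TGC", "CTT") for _ in range(200)]
        body = "".join(codons[i] for i in range((stop_start - 1) // 3))
        transcript = body + "TAG" + "CCC"
        protein, span = se.translate_first_orf(transcript)
        assert span == (stop_start, stop_start + 2)
        assert len(protein) == expected_len

    def test_open_ended_frame(self):
        protein, span = se.translate_first_orf("ATGGCAGCA")
        assert span is None and protein == "MAA"

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="ATG"):
            se.translate_first_orf("TTGAAA")
        with pytest.raises(ValueError, match="A,C,G,T"):
            se.translate_first_orf("ATGNNN")

    def test_agrees_with_bruteforce_stop_scan(self):
        """1,000 random ATG-prefixed sequences against the codon-scan oracle."""
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGT"))
        for _ in range(1_000):
            n = int(rng.integers(3, 120))
            transcript = "ATG" + "".join(rng.choice(bases, size=n))
            protein, span = se.translate_first_orf(transcript)
            n_aa, expected_span = brute_force_first_stop(transcript)
            assert span == expected_span
            if span is not None:
                assert len(protein) == n_aa
                # frame conservation: 3*protein_length + 3 = stop end
                assert 3 * len(protein) + 3 == span[1]
                assert span[0] % 3 == 1


class TestCrypticScan:
    def test_cds_delta_matches_acceptor_shift(self):
        # tiny genes with the first exon-2 AG at a controlled offset
        for exon2, expected_delta in [("CCAGGCTAA", -4), ("CACCAGTTTTAA", -6)]:
            exon1, intron = "ATG", "GTCCCCCCAG"
            seq = exon1 + intron + exon2
            model = se.GeneModel(sequence=seq, exons=[(1, 3), (14, 13 + len(exon2))])
            v = se.Variant(pos=13, ref_base="G", alt_base="T")
            isoforms = {r.label: r for r in se.enumerate_isoforms(model, v)}
            assert isoforms["cryptic_acceptor"].cds_delta == expected_delta

    def test_no_downstream_ag_gives_retention_only(self):
        model = se.GeneModel(sequence="ATG" + "GTCCCCCCAG" + "CCCCCCTAA",
                             exons=[(1, 3), (14, 22)])
        v = se.Variant(pos=13, ref_base="G", alt_base="T")
        isoforms = se.enumerate_isoforms(model, v)
        assert [r.label for r in isoforms] == ["intron_retention"]


class TestDomainReport:
    @pytest.mark.parametrize("domain,length,expected", [
        ((200, 350), 168, "lost"),
        ((200, 350), 377, "retained"),
        ((100, 200), 168, "truncated"),
    ])
    def test_domain_status(self, domain, length, expected):
        model = se.GeneModel(sequence="ATG" + "GTCCCCCCAG" + "CCCCCCTAA",
                             exons=[(1, 3), (14, 22)],
                             domain_intervals={"d": domain})
        result = se.IsoformResult(label="x", transcript="", cds_delta=0,
                                  stop_codon_span=None, protein="M" * length)
        assert se.domain_report(result, model) == {"d": expected}


class TestGeneModelValidation:
    def test_rejects_bad_models(self):
        with pytest.raises(ValueError, match="ATG"):
            se.GeneModel(sequence="CCCTAA", exons=[(1, 6)])
        with pytest.raises(ValueError, match="divisible"):
            se.GeneModel(sequence="ATGCTAA", exons=[(1, 7)])
        with pytest.raises(ValueError, match="stop"):
            se.GeneModel(sequence="ATGCCC", exons=[(1, 6)])
        with pytest.raises(ValueError, match="sorted"):
            se.GeneModel(sequence="ATGCCCTAA", exons=[(4, 9), (1, 3)])

    def test_non_canonical_intron_is_flagged_not_rejected(self):
        model = se.GeneModel(sequence="ATG" + "CTCCCCCCAC" + "CCCCCCTAA",
                             exons=[(1, 3), (14, 22)])
        assert not model.intron_is_canonical(0)
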