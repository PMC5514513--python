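"""Variant application, peptide enumeration, fusions, and database assembly."""

import pytest

from conftest import brute_force_digest
from protevar.proteome import PeptideIndex, ProteinRecord
from protevar.variants import (
    FusionEvent,
    VariantApplicationError,
    VariantPeptide,
    VariantRecord,
    apply_variant,
    build_search_database,
    collapse_duplicates,
    enumerate_variant_peptides,
    fusion_peptides,
    parse_variant_header,
    read_fusion_table,
    read_variant_table,
    write_fusion_table,
    write_variant_table,
)


def _variant(cls, pos, ref, alt, vid="v1", acc="P1"):
    return VariantRecord(
        variant_id=vid,
        gene="G1",
        protein_accession=acc,
        variant_class=cls,
        position=pos,
        ref_seq=ref,
        alt_seq=alt,
        provenance=frozenset({"cosmic"}),
    )


@pytest.fixture
def base() -> ProteinRecord:
    return ProteinRecord("P1", "", "MKTAYR", "uniprot_canonical")


class TestApplyVariant:
    def test_sav(self, base):
        mutated, span = apply_variant(base, _variant("sav", 4, "A", "V"))
        assert mutated.sequence == "MKTVYR"
        assert span == (4, 4)

    def test_deletion_span_is_junction_pair(self, base):
        mutated, span = apply_variant(base, _variant("deletion", 3, "TA", ""))
        assert mutated.sequence == "MKYR"
        assert span == (2, 3)

    def test_insertion_span_includes_flanks(self, base):
        mutated, span = apply_variant(base, _variant("insertion", 3, "", "GG"))
        assert mutated.sequence == "MKGGTAYR"
        assert span == (2, 5)  # inserted run (3..4) plus one flank each side

    def test_stop_loss_truncate_and_append(self, base):
        mutated, span = apply_variant(base, _variant("stop_loss", 6, "", "RGGW"))
        assert mutated.sequence == "MKTAYRGGW"
        assert span == (6, 9)

    def test_frameshift_replaces_c_terminus(self, base):
        mutated, span = apply_variant(base, _variant("frameshift", 3, "", "WWK"))
        assert mutated.sequence == "MKWWK"
        assert span == (3, 5)

    def test_reference_mismatch_names_variant(self, base):
        with pytest.raises(VariantApplicationError, match="v1"):
            apply_variant(base, _variant("sav", 4, "Y", "V"))

    def test_position_beyond_sequence(self, base):
        with pytest.raises(VariantApplicationError):
            apply_variant(base, _variant("insertion", 99, "", "G"))


class TestEnumerateVariantPeptides:
    def test_internal_sav_yields_six_peptides(self, unfiltered_spec):
        # cleavage-neutral substitution deep inside a protein: one peptide at
        # 0 missed cleavages, two at 1, three at 2
        seq = "MAAAKCCCDKEEEFKGGGHKIIIMKNNNQKSSSTK"
        protein = ProteinRecord("P1", "", seq, "uniprot_canonical")
        variant = _variant("sav", 17, "G", "W")
        mutated, span = apply_variant(protein, variant)
        peptides = enumerate_variant_peptides(mutated, span, unfiltered_spec, None, "v1")
        assert len(peptides) == 6
        by_mc = sorted(p.missed_cleavages for p in peptides)
        assert by_mc == [0, 1, 1, 2, 2, 2]
        # every peptide covers the substituted residue
        for pep in peptides:
            s, e = pep.mutated_span
            assert pep.sequence[s - 1 : e] == "W"

    def test_cleavage_site_sav_matches_brute_force(self, unfiltered_spec):
        seq = "MAAAKCCCDKEEEFKGGGHKIIIMKNNNQKSSSTK"
        protein = ProteinRecord("P1", "", seq, "uniprot_canonical")
        variant = _variant("sav", 15, "K", "A")  # destroys a cleavage site
        mutated, span = apply_variant(protein, variant)
        got = {(p.sequence, p.missed_cleavages) for p in
               enumerate_variant_peptides(mutated, span, unfiltered_spec, None, "v1")}
        oracle = {
            (s, mc)
            for (s, start, end, mc) in brute_force_digest(mutated.sequence, unfiltered_spec)
            if start <= span[1] and end >= span[0]
        }
        assert got == oracle
        # the destroyed site merges two tryptic segments into one peptide
        assert any("EEEFAGGGHK" == s for s, _ in got)

    def test_reference_matching_peptides_excluded(self, unfiltered_spec):
        protein = ProteinRecord("P1", "", "MKTIYRGGK", "uniprot_canonical")
        # reference contains the L-form of the mutated peptide
        reference = [ProteinRecord("R1", "", "MKTLYRGGK", "uniprot_canonical")]
        index = PeptideIndex.build([reference], unfiltered_spec)
        variant = _variant("sav", 4, "I", "L")
        mutated, span = apply_variant(protein, variant)
        assert enumerate_variant_peptides(mutated, span, unfiltered_spec, index, "v1") == []


class TestFusionPeptides:
    def test_in_frame_junction_peptides(self, unfiltered_spec):
        # 5' = ATG AAA -> MK ; 3' = CGT GGA TGG TAA -> RGW*
        event = FusionEvent("f1", "ATGAAA", "CGTGGATGGTAA", "in_frame", "rnaseq")
        peptides = fusion_peptides(event, unfiltered_spec, None)
        seqs = {p.sequence for p in peptides}
        # translation is MKRGW; junction lies between residues 2 and 3, so
        # junction-spanning tryptic peptides are those covering both K and R
        assert seqs == {"MKR", "MKRGW"}
        for pep in peptides:
            s, e = pep.mutated_span
            assert pep.sequence[s - 1 : e] == "KR"

    def test_frame_with_immediate_stop_contributes_nothing(self, unfiltered_spec):
        # frame 0 hits TAA immediately after the first codon
        event = FusionEvent("f1", "ATGTAA", "AAACGTGGA", "three_frame", "cosmic")
        peptides = fusion_peptides(event, unfiltered_spec, None)
        assert all(p.sequence != "M" for p in peptides)
        frames_with_peptides = {p for p in peptides}
        # remaining frames may still contribute junction peptides
        for pep in frames_with_peptides:
            assert "*" not in pep.sequence

    def test_peptides_not_crossing_junction_excluded(self, unfiltered_spec):
        # 5' encodes MKAAAK; a peptide entirely 5' of the junction (MK) must
        # never be returned
        event = FusionEvent("f1", "ATGAAAGCTGCTGCTAAA", "CGTGGATGG", "in_frame", "rnaseq")
        peptides = fusion_peptides(event, unfiltered_spec, None)
        assert peptides
        junction_nt = len(event.five_prime_nt)
        for pep in peptides:
            assert pep.sequence not in ("MK", "AAAK")  # wholly 5' peptides

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            FusionEvent("f1", "ATGQQQ", "CGT", "in_frame", "rnaseq")

    def test_in_frame_requires_divisible_five_prime(self):
        with pytest.raises(ValueError, match="divisible"):
            FusionEvent("f1", "ATGA", "CGT", "in_frame", "rnaseq")


def _vp(seq, vid, tags, span=(1, 1), mc=0):
    return VariantPeptide(
        sequence=seq,
        variant_ids=frozenset({vid}),
        mutated_span=span,
        missed_cleavages=mc,
        database_tags=frozenset(tags),
    )


class TestCollapseDuplicates:
    def test_merges_ids_and_tags(self):
        collapsed = collapse_duplicates(
            [_vp("MKTAYR", "v1", {"dbsnp"}), _vp("MKTAYR", "v2", {"cosmic"})]
        )
        assert len(collapsed) == 1
        assert collapsed[0].variant_ids == frozenset({"v1", "v2"})
        assert collapsed[0].database_tags == frozenset({"dbsnp", "cosmic"})

    def test_disjoint_sequences_unchanged_and_sorted(self):
        collapsed = collapse_duplicates([_vp("ZZZ", "v1", {"dbsnp"}), _vp("AAA", "v2", {"cosmic"})])
        assert [p.sequence for p in collapsed] == ["AAA", "ZZZ"]

    def test_idempotent(self):
        once = collapse_duplicates(
            [_vp("MK", "v1", {"dbsnp"}), _vp("MK", "v2", {"cosmic"}), _vp("AR", "v3", {"exome"})]
        )
        assert collapse_duplicates(once) == once

    def test_conserves_sequence_provenance_pairs(self):
        peptides = [
            _vp("MK", "v1", {"dbsnp"}),
            _vp("MK", "v2", {"cosmic", "exome"}),
            _vp("AR", "v3", {"exome"}),
        ]
        before = {(p.sequence, tag) for p in peptides for tag in p.database_tags}
        after = {(p.sequence, tag) for p in collapse_duplicates(peptides) for tag in p.database_tags}
        assert before == after


class TestBuildSearchDatabase:
    @pytest.fixture
    def db(self):
        reference = [
            ProteinRecord("P1", "", "MKTAYR", "uniprot_canonical"),
            ProteinRecord("P2", "", "GGGKWW", "uniprot_canonical"),
            ProteinRecord("P3", "", "CCCR", "uniprot_canonical"),
        ]
        peptides = [_vp("MKTVYR", "v1", {"cosmic"}, span=(4, 4)), _vp("WWWK", "v2", {"dbsnp"}, span=(2, 2))]
        return build_search_database(reference, peptides)

    def test_class_counts(self, db):
        assert db.class_counts() == {
            "reference_target": 3,
            "variant_target": 2,
            "reference_decoy": 3,
            "variant_decoy": 2,
        }

    def test_decoys_are_exact_reversals(self, db):
        targets = {e.header: e.sequence for e in db.entries if e.db_class.endswith("_target")}
        decoys = {e.header: e.sequence for e in db.entries if e.db_class.endswith("_decoy")}
        assert len(decoys) == len(targets)
        for header, seq in decoys.items():
            assert header.startswith("rev_")
            target_seq = targets[header.removeprefix("rev_")]
            assert seq == target_seq[::-1]
            assert sorted(seq) == sorted(target_seq)  # composition preserved

    def test_reversal_involution(self, db):
        for entry in db.entries:
            if entry.db_class.endswith("_decoy"):
                assert entry.sequence[::-1][::-1] == entry.sequence

    def test_variant_headers_parse_back(self, db):
        for entry in db.by_class("variant_target"):
            parsed = parse_variant_header(entry.header)
            assert parsed["variant_ids"] <= {"v1", "v2"}

    def test_no_variant_target_in_reference_index(self, unfiltered_spec):
        reference = [ProteinRecord("P1", "", "MAAAKCCCDKEEEFKGGGHK", "uniprot_canonical")]
        index = PeptideIndex.build([reference], unfiltered_spec)
        variant = _variant("sav", 7, "C", "W")
        mutated, span = apply_variant(reference[0], variant)
        peptides = enumerate_variant_peptides(mutated, span, unfiltered_spec, index, "v1", {"cosmic"})
        db = build_search_database(reference, peptides)
        for entry in db.by_class("variant_target"):
            assert entry.sequence not in index

    def test_header_collision_rejected(self):
        reference = [ProteinRecord("P1", "", "MKTAYR", "uniprot_canonical")]
        with pytest.raises(ValueError, match="duplicate"):
            build_search_database(reference + reference, [])


class TestTables:
    def test_variant_table_round_trip(self, tmp_path):
        variants = [
            _variant("sav", 4, "A", "V", vid="v1"),
            _variant("deletion", 2, "KT", "", vid="v2"),
            _variant("insertion", 3, "", "GG", vid="v3"),
        ]
        path = tmp_path / "variants.tsv"
        write_variant_table(variants, path)
        assert read_variant_table(path) == variants

    def test_fusion_table_round_trip(self, tmp_path):
        fusions = [FusionEvent("f1", "ATGAAA", "CGTGGA", "in_frame", "rnaseq")]
        path = tmp_path / "fusions.tsv"
        write_fusion_table(fusions, path)
        assert read_fusion_table(path) == fusions

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("variant_id\tgene\nv1\tG1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_variant_table(path)
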