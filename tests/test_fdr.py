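"""PSM parsing, best-per-spectrum selection, and split target-decoy FDR."""

import pytest

from protevar.fdr import (
    PSM,
    PsmSchemaError,
    assign_q_values,
    classify_database_class,
    parse_psm_table,
    pooled_fdr,
    select_best_psm_per_spectrum,
    split_fdr,
    write_psm_table,
)


def _psm(score, db_class="variant_target", charge=2, scan=1, peptide="PEPTIDEK", engine="tandem"):
    acc = "var|v1|G1|sav|cosmic|1-1" if db_class.startswith("variant") else "P1"
    if db_class.endswith("_decoy"):
        acc = "rev_" + acc
    return PSM("f.raw", scan, peptide, charge, engine, score, db_class, frozenset({acc}))


class TestClassify:
    @pytest.mark.parametrize(
        "accessions, expected",
        [
            ({"P1"}, "reference_target"),
            ({"rev_P1"}, "reference_decoy"),
            ({"var|v1|G|sav|cosmic|1-1"}, "variant_target"),
            ({"rev_var|v1|G|sav|cosmic|1-1"}, "variant_decoy"),
            ({"P1", "var|v1|G|sav|cosmic|1-1"}, "variant_target"),  # variant marker wins
            ({"rev_P1", "P2"}, "reference_target"),  # any target accession -> target
        ],
    )
    def test_classification(self, accessions, expected):
        assert classify_database_class(accessions) == expected


class TestParsePsmTable:
    HEADER = "raw_file\tscan_id\tpeptide\tcharge\te_value\tprotein_accessions\n"

    def test_well_formed_rows(self, tmp_path):
        rows = "".join(
            f"f.raw\t{i}\tPEPTIDEK\t2\t1e-4\tP1\n" for i in range(1, 6)
        )
        path = tmp_path / "psms.tsv"
        path.write_text(self.HEADER + rows)
        psms = parse_psm_table(path, "tandem")
        assert len(psms) == 5
        assert all(p.engine == "tandem" for p in psms)

    def test_evalue_negated_log_transform(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(self.HEADER + "f.raw\t1\tPEPTIDEK\t2\t1e-6\tP1\n")
        assert parse_psm_table(path, "msgf")[0].score == pytest.approx(6.0)

    def test_charge_zero_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(self.HEADER + "f.raw\t1\tPEPTIDEK\t0\t1e-6\tP1\n")
        with pytest.raises(PsmSchemaError, match="line 2"):
            parse_psm_table(path, "comet")

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text("raw_file\tscan_id\tpeptide\te_value\tprotein_accessions\nf\t1\tPEP\t1e-3\tP1\n")
        with pytest.raises(PsmSchemaError, match="charge"):
            parse_psm_table(path, "tandem")

    def test_non_numeric_score_rejected(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(self.HEADER + "f.raw\t1\tPEPTIDEK\t2\tnot_a_number\tP1\n")
        with pytest.raises(PsmSchemaError, match="line 2"):
            parse_psm_table(path, "tandem")

    def test_round_trip(self, tmp_path):
        psms = [_psm(7.5, scan=1), _psm(3.25, "reference_decoy", scan=2)]
        path = tmp_path / "out.tsv"
        write_psm_table(psms, path)
        back = parse_psm_table(path, "tandem")
        assert len(back) == 2
        assert back[0].score == pytest.approx(7.5)
        assert back[0].database_class == "variant_target"
        assert back[1].database_class == "reference_decoy"


class TestBestPerSpectrum:
    def test_highest_score_survives(self):
        a, b = _psm(8.0, scan=7), _psm(9.0, scan=7)
        assert select_best_psm_per_spectrum([a, b]) == [b]

    def test_tie_prefers_reference(self):
        v = _psm(8.0, "variant_target", scan=7, peptide="AAAA")
        r = _psm(8.0, "reference_target", scan=7, peptide="AAAA")
        assert select_best_psm_per_spectrum([v, r]) == [r]

    def test_tie_breaks_lexicographically_first(self):
        a = _psm(8.0, scan=7, peptide="AAAA")
        z = _psm(8.0, "reference_target", scan=7, peptide="ZZZZ")
        assert select_best_psm_per_spectrum([a, z]) == [a]

    def test_distinct_scans_untouched(self):
        psms = [_psm(8.0, scan=1), _psm(9.0, scan=2)]
        assert sorted(p.scan_id for p in select_best_psm_per_spectrum(psms)) == [1, 2]


class TestSplitFdr:
    def test_worked_example_uncorrected(self):
        """Targets {9,7,5} vs decoy {6}: FDR sequence 0, 0, 1/3."""
        psms = [
            _psm(9.0),
            _psm(7.0, scan=2),
            _psm(5.0, scan=3),
            _psm(6.0, "variant_decoy", scan=4),
        ]
        qvalued = assign_q_values(psms, conservative=False)
        by_score = {q.psm.score: q.q_value for q in qvalued}
        assert by_score[9.0] == 0.0
        assert by_score[7.0] == 0.0
        assert by_score[5.0] == pytest.approx(1 / 3)
        accepted = split_fdr(psms, threshold=0.01, conservative=False)
        assert sorted(q.psm.score for q in accepted) == [7.0, 9.0]

    def test_conservative_estimator_adds_one_decoy(self):
        psms = [_psm(9.0), _psm(7.0, scan=2), _psm(5.0, scan=3), _psm(6.0, "variant_decoy", scan=4)]
        by_score = {q.psm.score: q.q_value for q in assign_q_values(psms, conservative=True)}
        assert by_score[9.0] == pytest.approx(1 / 2)  # monotonized (D+1)/T
        assert by_score[5.0] == pytest.approx(2 / 3)

    def test_no_decoys_all_accepted_uncorrected(self):
        psms = [_psm(s, scan=i) for i, s in enumerate([9.0, 7.0, 5.0], 1)]
        accepted = split_fdr(psms, conservative=False)
        assert len(accepted) == 3
        assert all(q.q_value == 0.0 for q in accepted)

    def test_charge_strata_are_independent(self):
        base = [_psm(9.0, scan=1), _psm(7.0, scan=2), _psm(6.0, "variant_decoy", scan=3)]
        dup = [_psm(p.score, p.database_class, charge=3, scan=p.scan_id + 10) for p in base]
        qvalued = assign_q_values(base + dup, conservative=False)
        by_stratum = {}
        for q in qvalued:
            by_stratum.setdefault(q.stratum, []).append(q.q_value)
        assert sorted(by_stratum[("variant", 2)]) == sorted(by_stratum[("variant", 3)])

    def test_stratum_isolation_under_permutation(self):
        variant = [_psm(9.0, scan=1), _psm(6.0, "variant_decoy", scan=2)]
        reference = [_psm(4.0, "reference_target", scan=3), _psm(8.0, "reference_target", scan=4)]
        q_before = {q.psm.scan_id: q.q_value for q in assign_q_values(variant + reference)}
        q_after = {q.psm.scan_id: q.q_value for q in assign_q_values(reference[::-1] + variant)}
        assert q_before == q_after

    def test_threshold_monotonicity(self):
        psms = [_psm(float(s), scan=s) for s in range(3, 30)] + [
            _psm(float(s) + 0.5, "variant_decoy", scan=100 + s) for s in range(3, 9)
        ]
        accepted_ids = {}
        for threshold in (0.001, 0.01, 0.05, 0.2, 0.5):
            accepted_ids[threshold] = {q.psm.scan_id for q in split_fdr(psms, threshold=threshold)}
        thresholds = sorted(accepted_ids)
        for lo, hi in zip(thresholds, thresholds[1:]):
            assert accepted_ids[lo] <= accepted_ids[hi]

    def test_pooled_mixes_partitions(self):
        # one variant decoy cannot penalize reference targets under the split
        # estimate, but does contribute to the pooled one
        psms = [
            _psm(9.0, "reference_target", scan=1),
            _psm(8.0, "reference_target", scan=2),
            _psm(8.5, "variant_decoy", scan=3),
        ]
        split_q = {q.psm.scan_id: q.q_value for q in assign_q_values(psms, conservative=False)}
        pooled_q = {q.psm.scan_id: q.q_value for q in assign_q_values(psms, split=False, conservative=False)}
        assert split_q[2] == 0.0
        assert pooled_q[2] == pytest.approx(1 / 2)

    def test_empty_stratum_warns_and_skips(self):
        psms = [_psm(6.0, "variant_decoy", scan=1)]
        with pytest.warns(UserWarning, match="no target"):
            assert assign_q_values(psms) == []

    def test_merge_below_pools_small_charge_strata(self):
        psms = [_psm(9.0, charge=2, scan=1), _psm(8.0, charge=3, scan=2), _psm(7.0, charge=4, scan=3)]
        merged = assign_q_values(psms, merge_below=10)
        assert {q.stratum for q in merged} == {("variant", 0)}
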