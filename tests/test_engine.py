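"""Engine phases: structure validation, duplicate scan, record cycle with
acceptance criteria, external sort, post-record batching, full runs."""

import csv
import random

import pytest

from registryqc import (
    detect_perfect_duplicates,
    external_sort,
    load_protocol,
    run_validation,
    validate_file_structure,
)
from registryqc.engine import (
    acceptable_temp_path,
    run_post_record_cycle,
    run_record_cycle,
)
from registryqc.rules_core import ParsedRecord, parse_record


def write_file(path, protocol, rows):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=";")
        writer.writerow(protocol.variable_names)
        writer.writerows(rows)
    return path


class TestStructure:
    def test_empty_file_is_blocking(self, tmp_path, inc_protocol):
        path = tmp_path / "empty.csv"
        path.write_text("")
        messages = validate_file_structure(path, inc_protocol)
        assert [m.code for m in messages] == ["C-EMPT"]
        assert messages[0].severity == "critical"

    def test_single_valid_record_passes(self, tmp_path, inc_protocol,
                                        make_row):
        path = write_file(tmp_path / "one.csv", inc_protocol, [make_row()])
        assert validate_file_structure(path, inc_protocol) == []

    def test_header_mismatch(self, tmp_path, inc_protocol, make_row):
        path = tmp_path / "bad_header.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=";")
            writer.writerow(["a", "b", "c"])
            writer.writerow(make_row())
        assert [m.code for m in
                validate_file_structure(path, inc_protocol)] == ["C-HEAD"]

    def test_short_row_is_flagged_with_its_line(self, tmp_path, inc_protocol,
                                                make_row):
        path = tmp_path / "short.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=";")
            writer.writerow(inc_protocol.variable_names)
            writer.writerow(make_row())
            writer.writerow(make_row()[:-3])  # N-3 fields
        messages = validate_file_structure(path, inc_protocol)
        assert [(m.code, m.line_no) for m in messages] == [("C-NCOL", 3)]

    def test_missing_file_is_io_error(self, tmp_path, inc_protocol):
        with pytest.raises(OSError):
            validate_file_structure(tmp_path / "nope.csv", inc_protocol)


def key_record(line_no, pat, tum):
    return ParsedRecord(line_no=line_no, values={"Pat": pat, "Tum": tum},
                        parsed={}, status={}, pat_id=pat, tum_id=tum)


class TestDuplicates:
    def test_second_occurrence_flagged(self):
        messages = detect_perfect_duplicates(
            [key_record(2, "P1", "T1"), key_record(3, "P1", "T1")])
        assert [(m.code, m.line_no) for m in messages] == [("E-DUPL", 3)]

    def test_same_patient_different_tumour_is_fine(self):
        assert detect_perfect_duplicates(
            [key_record(2, "P1", "T1"), key_record(3, "P1", "T2")]) == []

    def test_matches_pairwise_oracle_on_random_keys(self):
        rng = random.Random(5)
        records = [key_record(i + 2, f"P{rng.randint(1, 120)}",
                              f"T{rng.randint(1, 4)}") for i in range(1000)]
        got = {m.line_no for m in detect_perfect_duplicates(records)}
        # O(n^2) oracle: a record is a duplicate iff any earlier record
        # carries the same key
        expected = set()
        for i, rec in enumerate(records):
            for prev in records[:i]:
                if (prev.pat_id, prev.tum_id) == (rec.pat_id, rec.tum_id):
                    expected.add(rec.line_no)
                    break
        assert got == expected


class TestAcceptanceSemantics:
    def run_cycle(self, tmp_path, inc_protocol, tables, rows):
        records = (parse_record(row, inc_protocol, tables, i + 2)
                   for i, row in enumerate(rows))
        return run_record_cycle(records, inc_protocol, tables, tmp_path)

    def read_temp_lines(self, tmp_path):
        temp = acceptable_temp_path(tmp_path, "MPT")
        with open(temp, newline="") as fh:
            return [int(row[0]) for row in csv.reader(fh, delimiter=";")]

    def test_missing_yoi_excludes_record_from_mpt_file(
            self, tmp_path, inc_protocol, tables, make_row):
        result = self.run_cycle(tmp_path, inc_protocol, tables,
                                [make_row(YoI=""), make_row()])
        assert [m.code for m in result.messages] == ["E-MISS"]
        assert self.read_temp_lines(tmp_path) == [3]  # only the clean record

    def test_missing_stage_keeps_record_in_mpt_file(
            self, tmp_path, inc_protocol, tables, make_row):
        result = self.run_cycle(tmp_path, inc_protocol, tables,
                                [make_row(Stage=""), make_row()])
        assert [m.code for m in result.messages] == ["E-MISS"]
        assert self.read_temp_lines(tmp_path) == [2, 3]

    def test_clean_record_in_every_rule_file_with_no_messages(
            self, tmp_path, inc_protocol, tables, make_row):
        result = self.run_cycle(tmp_path, inc_protocol, tables, [make_row()])
        assert result.messages == []
        assert self.read_temp_lines(tmp_path) == [2]


class TestExternalSort:
    def write_temp(self, tmp_path, rows):
        temp = tmp_path / "qcs_acceptable_by_rule_MPT.csv"
        with open(temp, "w", newline="") as fh:
            csv.writer(fh, delimiter=";").writerows(rows)
        return temp

    def temp_rows(self, make_row, keys):
        return [[str(i + 2)] + make_row(Pat=pat, Tum=tum)
                for i, (pat, tum) in enumerate(keys)]

    def test_equals_in_memory_stable_sort(self, tmp_path, inc_protocol,
                                          make_row):
        rng = random.Random(3)
        keys = [(f"P{rng.randint(1, 30):03d}", f"T{i}") for i in range(200)]
        rows = self.temp_rows(make_row, keys)
        temp = self.write_temp(tmp_path, rows)
        out = external_sort(temp, "Pat", inc_protocol, chunk_size=16)
        assert out.name == "qcs_acceptable_by_rule_MPT-by-PAT.csv"
        with open(out, newline="") as fh:
            got = list(csv.reader(fh, delimiter=";"))
        pat_idx = inc_protocol.by_name["Pat"].position
        assert got == sorted(rows, key=lambda r: (r[pat_idx], int(r[0])))

    def test_already_sorted_input_is_unchanged(self, tmp_path, inc_protocol,
                                               make_row):
        keys = [("P001", "T1"), ("P001", "T2"), ("P002", "T1")]
        rows = self.temp_rows(make_row, keys)
        temp = self.write_temp(tmp_path, rows)
        out = external_sort(temp, "Pat", inc_protocol, chunk_size=2)
        with open(out, newline="") as fh:
            assert list(csv.reader(fh, delimiter=";")) == rows

    def test_chunk_size_independence(self, tmp_path, inc_protocol, make_row):
        rng = random.Random(9)
        keys = [(f"P{rng.randint(1, 5)}", f"T{i}") for i in range(10)]
        rows = self.temp_rows(make_row, keys)
        temp = self.write_temp(tmp_path, rows)
        small = external_sort(temp, "Pat", inc_protocol, chunk_size=2)
        small_bytes = small.read_bytes()
        big = external_sort(temp, "Pat", inc_protocol, chunk_size=1000)
        assert small_bytes == big.read_bytes()


class TestPostRecord:
    def sorted_file(self, tmp_path, make_row, patients, name="sorted.csv"):
        """patients: list of (pat, tum, topo, morpho, beh), pre-sorted."""
        temp = tmp_path / name
        with open(temp, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=";")
            for i, (pat, tum, topo, morpho, beh) in enumerate(patients):
                writer.writerow(
                    [str(i + 2)] + make_row(
                        Pat=pat, Tum=tum, Topo=topo, Morpho=morpho, Beh=beh,
                        Stage="X", pT="", pN="", pM="", BoD="7"))
        return temp

    def test_same_primary_pair_warns(self, tmp_path, inc_protocol, tables,
                                     make_row):
        path = self.sorted_file(tmp_path, make_row, [
            ("P1", "T1", "C502", "8500", "3"),
            ("P1", "T2", "C509", "8140", "3")])
        result = run_post_record_cycle({"MPT": path}, inc_protocol, tables)
        assert [m.code for m in result.messages] == ["W-MULP"]
        assert result.mpt_clusters == 1

    def test_singleton_patients_are_silent(self, tmp_path, inc_protocol,
                                           tables, make_row):
        path = self.sorted_file(tmp_path, make_row, [
            ("P1", "T1", "C509", "8500", "3"),
            ("P2", "T1", "C619", "8140", "3")])
        result = run_post_record_cycle({"MPT": path}, inc_protocol, tables)
        assert result.messages == []

    def test_batch_isolation(self, tmp_path, inc_protocol, tables, make_row):
        """A patient's verdicts do not depend on surrounding patients."""
        trio = [("P5", "T1", "C502", "8500", "3"),
                ("P5", "T2", "C509", "8140", "3"),
                ("P5", "T3", "C504", "8520", "3")]
        alone = self.sorted_file(tmp_path, make_row, trio, name="alone.csv")
        result_alone = run_post_record_cycle({"MPT": alone}, inc_protocol,
                                             tables)
        surrounded = self.sorted_file(tmp_path, make_row, [
            ("P1", "T1", "C619", "8140", "3")] + trio + [
            ("P9", "T1", "C679", "8120", "3")])
        result_surrounded = run_post_record_cycle({"MPT": surrounded},
                                                  inc_protocol, tables)
        def pairs(result):
            return sorted(m.values[0] for m in result.messages)
        assert pairs(result_alone) == pairs(result_surrounded)
        assert len(result_alone.messages) == 3

    def test_unsorted_input_is_an_internal_error(self, tmp_path, inc_protocol,
                                                 tables, make_row):
        path = self.sorted_file(tmp_path, make_row, [
            ("P2", "T1", "C509", "8500", "3"),
            ("P1", "T1", "C619", "8140", "3")])
        with pytest.raises(RuntimeError, match="not sorted"):
            run_post_record_cycle({"MPT": path}, inc_protocol, tables)


class TestFullRun:
    def test_empty_file_blocks_and_writes_no_reports(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        result = run_validation(path, "incidence-2020",
                                output_dir=tmp_path / "out")
        assert result.blocking_failure
        assert "csv" not in result.output_paths
        assert result.messages_by_code == {"C-EMPT": 1}

    def test_structural_error_continue_mode_skips_bad_rows(
            self, tmp_path, inc_protocol, make_row):
        path = tmp_path / "mixed.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=";")
            writer.writerow(inc_protocol.variable_names)
            writer.writerow(make_row())
            writer.writerow(["too", "short"])
            writer.writerow(make_row(Pat="P000002"))
        aborted = run_validation(path, "incidence-2020",
                                 output_dir=tmp_path / "out1")
        assert aborted.blocking_failure
        result = run_validation(path, "incidence-2020",
                                output_dir=tmp_path / "out2",
                                on_structural_error="continue")
        assert result.blocking_failure is None
        assert result.total_records == 2
        assert result.messages_by_code == {"C-NCOL": 1}

    def test_aggregate_protocol_round(self, tmp_path):
        protocol = load_protocol(None, "lifetable-2020")
        path = write_file(tmp_path / "lt.csv", protocol, [
            ["2018", "1", "60", "AREA01", "Registry area 1", "0.012"],
            ["2018", "2", "60", "AREA01", "Registry area 1", "1.5"],
        ])
        result = run_validation(path, "lifetable-2020",
                                output_dir=tmp_path / "out")
        # the out-of-[0,1] death probability is the only finding
        assert result.messages_by_code == {"E-OUTR": 1}

    def test_message_cap_aborts(self, tmp_path, inc_protocol, make_row):
        path = write_file(tmp_path / "many.csv", inc_protocol,
                          [make_row(Sex="5", Pat=f"P{i:06d}")
                           for i in range(20)])
        result = run_validation(path, "incidence-2020",
                                output_dir=tmp_path / "out", message_cap=5)
        assert result.blocking_failure == "message cap exceeded"
        assert result.messages_by_code.get("C-CAP") == 1
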