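import pytest

from registryqc import load_protocol, load_reference_tables, parse_record

# A clean breast-carcinoma record under the 39-variable incidence layout:
# pathological T3 N1 M0 maps to stage IIIA in the bundled grouping table.
BASE_ROW = {
    "Pat": "P000001", "Tum": "T01", "Sex": "2",
    "DoB": "1950-04-01", "DoI": "2018-06-15", "YoI": "2018", "Age": "68",
    "BoD": "7", "Topo": "C509", "Morpho": "8500", "Beh": "3", "Grade": "2",
    "Stage": "IIIA", "TNMEdition": "7",
    "cT": "", "cN": "", "cM": "", "pT": "3", "pN": "1", "pM": "0",
    "VitalStatus": "1", "DoF": "2019-01-10",
}


@pytest.fixture(scope="session")
def tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def inc_protocol():
    return load_protocol(None, "incidence-2020")


@pytest.fixture(scope="session")
def make_record(inc_protocol, tables):
    """Factory: ParsedRecord from the clean baseline plus overrides."""

    def _make(line_no=2, **overrides):
        row = {name: "" for name in inc_protocol.variable_names}
        row.update(BASE_ROW)
        row.update(overrides)
        fields = [row[name] for name in inc_protocol.variable_names]
        return parse_record(fields, inc_protocol, tables, line_no)

    return _make


@pytest.fixture(scope="session")
def make_row(inc_protocol):
    """Factory: raw field list (protocol order) from baseline + overrides."""

    def _make(**overrides):
        row = {name: "" for name in inc_protocol.variable_names}
        row.update(BASE_ROW)
        row.update(overrides)
        return [row[name] for name in inc_protocol.variable_names]

    return _make
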