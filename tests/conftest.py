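import csv

import pytest

from synoptex import OracleBackend, load_default_schema, load_schema

TOY_HEADER = ["section", "subsection", "field_id", "label", "value_kind",
              "options", "numeric_template", "synonyms"]


def write_toy_csv(path, rows):
    """Write a minimal schema CSV; rows are dicts over the schema columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=TOY_HEADER)
        w.writeheader()
        for row in rows:
            w.writerow({k: row.get(k, "") for k in TOY_HEADER})
    return path


TOY_ROWS = [
    {"section": "specimen", "subsection": "Procedure", "field_id": "procedure",
     "label": "Procedure", "value_kind": "categorical",
     "options": "Core needle biopsy|Total mastectomy|Other (specify)",
     "synonyms": "Total mastectomy=>Simple mastectomy"},
    {"section": "specimen", "subsection": "Procedure", "field_id": "procedure_note",
     "label": "Procedure note", "value_kind": "free_text"},
    {"section": "tumor", "subsection": "Tumor size", "field_id": "size_mm",
     "label": "Greatest dimension", "value_kind": "numeric_template",
     "options": "Greatest dimension: — mm",
     "numeric_template": "Greatest dimension: — mm"},
    {"section": "comments", "subsection": "Comment", "field_id": "comment",
     "label": "Comment", "value_kind": "free_text"},
]


@pytest.fixture(scope="session")
def schema():
    return load_default_schema()


@pytest.fixture
def toy_schema(tmp_path):
    path = write_toy_csv(tmp_path / "toy.csv", TOY_ROWS)
    return load_schema([path])


@pytest.fixture(scope="session")
def oracle(schema):
    return OracleBackend(schema)
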