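import pytest

from instarkit import clean_larval_table, load_larval_table, load_pupal_table


@pytest.fixture()
def larvae():
    """Cleaned bundled larval table (fresh copy per test)."""
    records, report = clean_larval_table(load_larval_table("larvae"))
    return records, report


@pytest.fixture()
def larvae_records(larvae):
    return larvae[0]


@pytest.fixture()
def pupae_records():
    return load_pupal_table("pupae")


@pytest.fixture()
def fossil_widths(larvae_records):
    return [
        r.value("head_width")
        for r in larvae_records
        if r.value("head_width") is not None
    ]
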