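import pandas as pd
import pytest
from hypothesis import settings

from pvsignal.faers_io import ParsedTable
from pvsignal.synthetic_data import SyntheticConfig, simulate_store

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def write_table(path, header, rows):
    """Write a '$'-delimited table file from a header list and row lists."""
    lines = ["$".join(header)] + ["$".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def frame(header, rows):
    """A parsed-table frame from literal rows ('' -> missing)."""
    f = pd.DataFrame([list(map(str, r)) for r in rows], columns=header, dtype=object)
    return f.mask(f == "")


def parsed(table_name, header, rows):
    return ParsedTable(table_name=table_name, frame=frame(header, rows))


@pytest.fixture(scope="session")
def small_config():
    """A fast synthetic corpus with two injected signals."""
    return SyntheticConfig(
        n_reports=4000,
        injected_signals=(("PT_001", 8.0), ("PT_002", 4.0)),
        duplicate_rate=0.15,
        start_quarter="2022Q1",
        end_quarter="2023Q4",
        seed=42,
    )


@pytest.fixture(scope="session")
def small_store(small_config):
    store, truth = simulate_store(small_config)
    return store, truth
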