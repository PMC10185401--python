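import io

import hypothesis
import numpy as np
import pytest

from busz import BusHeader, bus_io

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=100
)
hypothesis.settings.load_profile("deterministic")


def make_records(rows):
    """Array from (barcode, umi, ec[, count[, flags]]) tuples."""
    return bus_io.records_from_tuples(rows)


def bus_bytes(records, header=None):
    """Serialize records to in-memory BUS file bytes."""
    header = header or BusHeader(bc_len=16, umi_len=12)
    buf = io.BytesIO()
    bus_io.write_bus(header, records, buf)
    return buf.getvalue()


@pytest.fixture
def small_sorted_records():
    return make_records(
        [
            (3, 10, 0, 1, 0),
            (3, 10, 4, 2, 0),
            (3, 12, 1, 1, 0),
            (7, 2, 9, 1, 1),
            (7, 5, 0, 6, 0),
            (9, 0, 2, 1, 0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
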