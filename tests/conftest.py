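import numpy as np
import pytest

from segext.classify import (InsertSizeModel, build_irs, classify_pairs,
                             compute_coverage)
from segext.mapping import build_reference_index, map_reads
from segext.read_index import build_read_index
from segext.simulate import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def model():
    return InsertSizeModel(mu=200.0, sigma=25.0)


@pytest.fixture(scope="session")
def small_ds():
    """Error-free dataset: 120 kb reference, two 500 bp unique insertions."""
    spec = SimulationSpec(reference_length=120_000, n_insertions=2,
                          category="case1_unique", insert_size_mean=500,
                          insert_size_sd=50, error_rate=0.0, seed=7)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_pipeline(small_ds, model):
    """Mapping table, labels, coverage, IRS and read index for small_ds."""
    ds = small_ds
    ref_index = build_reference_index(ds.reference)
    table = map_reads(ref_index, ds.reads.reads1, ds.reads.reads2, d=2)
    labels = classify_pairs(table, model)
    profile = compute_coverage(table, len(ds.reference), seed=7)
    irs = build_irs(labels, profile, seed=7)
    ridx = build_read_index(ds.reads.reads1, ds.reads.reads2, irs, seed=7)
    return {"table": table, "labels": labels, "profile": profile,
            "irs": irs, "ridx": ridx, "ref_index": ref_index}


def naive_hamming_scan(ref_codes: np.ndarray, pat: np.ndarray, d: int):
    """Independent sliding-window oracle: (position, mismatches) pairs."""
    n = len(ref_codes) - len(pat) + 1
    out = []
    for i in range(n):
        win = ref_codes[i : i + len(pat)]
        mm = int(np.count_nonzero((win != pat) | (win >= 4) | (pat >= 4)))
        if mm <= d:
            out.append((i, mm))
    return out
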