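import numpy as np
import pandas as pd
import pytest

from cnvrpipe.core_io import CNVR, CNVCall, GenomeLayout, ReadCountMatrix


@pytest.fixture
def layout_2mb() -> GenomeLayout:
    return GenomeLayout(("chr1",), (2_000_000,), window_length=1000)


@pytest.fixture
def layout_two_chroms() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (100_000, 50_000), window_length=1000)


def make_call(start, end, cn, sample="S1", chrom="chr1", dataset=""):
    return CNVCall(
        sample_id=sample, chrom=chrom, start=start, end=end, cn=cn, dataset_id=dataset
    )


def make_cnvr(members, cnvr_id="r1"):
    return CNVR(
        cnvr_id=cnvr_id,
        chrom=members[0].chrom,
        start=min(c.start for c in members),
        end=max(c.end for c in members),
        members=list(members),
    )


@pytest.fixture
def small_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(1, 7)],
            "breed": ["HER", "HER", "HER", "SIM", "SIM", "SIM"],
            "dataset_id": "A",
            "coverage": 10.0,
        }
    )


@pytest.fixture
def flat_counts(layout_two_chroms) -> ReadCountMatrix:
    n = layout_two_chroms.total_windows
    counts = np.full((n, 4), 100, dtype=int)
    return ReadCountMatrix(layout_two_chroms, ("S1", "S2", "S3", "S4"), counts)
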