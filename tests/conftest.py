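import numpy as np
import pandas as pd
import pytest

from rsnpscan.io_formats import ASSAYS, HISTONE_MARKS


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_counts(rows):
    """Counts frame from (snp, individual, assay, target, ref, alt) tuples."""
    return pd.DataFrame(
        rows,
        columns=["snp_id", "individual", "assay", "alignment_target",
                 "ref_reads", "alt_reads"],
    )


def dual_site(snp, individual, assay, ref_counts, alt_counts):
    """One site observed on both alignment targets."""
    (r1, a1), (r2, a2) = ref_counts, alt_counts
    return [
        (snp, individual, assay, "reference", r1, a1),
        (snp, individual, assay, "alternative", r2, a2),
    ]
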