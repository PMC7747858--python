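import numpy as np
import pandas as pd
import pytest

from pairedexome.io import VARIANT_COLUMNS
from pairedexome.synthetic_cohort import Cohort, CohortConfig, generate_cohort


def make_variant(
    sample="S",
    chrom="chr1",
    pos=100,
    ref="C",
    alt="A",
    depth=100,
    alt_reads=40,
    qphred=60.0,
    vclass="SNV",
    gene="G00001",
    consequence="missense",
    pop_freq=np.nan,
    context5="A",
    context3="G",
):
    return dict(
        sample=sample, chrom=chrom, pos=pos, ref=ref, alt=alt, depth=depth,
        alt_reads=alt_reads, qphred=qphred, vclass=vclass, gene=gene,
        consequence=consequence, pop_freq=pop_freq, context5=context5,
        context3=context3,
    )


def variant_frame(rows):
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Two-patient cohort with modest counts; shared across tests."""
    return generate_cohort(
        CohortConfig(
            n_patients=2,
            n_truncal=50,
            n_primary_private=10,
            n_met_private=10,
            n_germline=40,
            n_bins=80,
            planted_segments=[("chr1", 20, 49, 0.6)],
            n_recurrent_patients=2,
            seed=11,
        )
    )
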