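import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ruffinv.qpcr_quant import (
    AmpliconSpec,
    collapse_replicates,
    relative_abundance_table,
)
from ruffinv.synthetic_data import GenerativeConfig, simulate_qpcr_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def default_gen() -> GenerativeConfig:
    return GenerativeConfig()


@pytest.fixture
def cohort_ra(default_gen):
    """Relative-abundance table of a default simulated cohort (seed 7)."""
    records, truth = simulate_qpcr_cohort(default_gen, seed=7)
    collapsed = collapse_replicates(records)
    ra = relative_abundance_table(
        collapsed, default_gen.amplicon_specs(), ["GAPDH", "RPL30"]
    )
    return ra, truth


def make_ra_frame(rows):
    """Hand-built RelAbundanceTable from (sample, morph, tissue, gene, klass, ra)."""
    return pd.DataFrame(
        rows,
        columns=["sample_id", "morph", "tissue", "gene", "amplicon_class", "ra"],
    )


@pytest.fixture
def spec_e2():
    return AmpliconSpec(gene="g", amplicon_class="common", efficiency=2.0,
                        efficiency_source="assumed_two")


@pytest.fixture
def ref_specs_e2():
    return [
        AmpliconSpec(gene=f"ref{i}", amplicon_class="reference", efficiency=2.0,
                     efficiency_source="assumed_two")
        for i in (1, 2)
    ]
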