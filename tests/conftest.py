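import numpy as np
import pandas as pd
import pytest

import mrith
from mrith.synthetic import build_sample_sheet, generate_mutations


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort at generator defaults."""
    return mrith.generate_cohort(mrith.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def mutation_stage():
    """Mutation/neoantigen stage only (fast to regenerate)."""
    config = mrith.CohortConfig(seed=11)
    sheet = build_sample_sheet(config)
    return config, sheet, generate_mutations(config, sheet)


@pytest.fixture
def two_region_sheet():
    return pd.DataFrame(
        {
            "patient": ["PA", "PA"],
            "region": ["R1", "R2"],
            "timepoint": ["untreated", "untreated"],
            "tissue": ["tumor", "tumor"],
            "purity": [0.5, 0.5],
        },
        index=pd.Index(["PA_R1", "PA_R2"], name="sample"),
    )


def make_sheet(rows):
    """rows: (sample, patient, region, timepoint, tissue, purity)."""
    df = pd.DataFrame(
        rows, columns=["sample", "patient", "region", "timepoint", "tissue",
                       "purity"])
    return df.set_index("sample")


def make_clonotype_table(repertoires):
    """repertoires: {sample: {cdr3: count}} with a fixed V/J label."""
    rows = []
    for sample, counts in repertoires.items():
        for cdr3, n in counts.items():
            rows.append((sample, cdr3, "TRBV1", "TRBJ1-1", n))
    return pd.DataFrame(rows, columns=["sample_id", "cdr3_aa", "v_call",
                                       "j_call", "duplicate_count"])
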