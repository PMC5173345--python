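import numpy as np
import pandas as pd
import pytest

from gangliomics import annotation, quantify, simulate


@pytest.fixture(scope="session")
def peak_table():
    """Default-preset synthetic SRM table plus its realised truth."""
    table, truth = simulate.generate_peak_table(
        simulate.GeneratorConfig(seed=0), return_truth=True)
    return table, truth


@pytest.fixture(scope="session")
def subject_table(peak_table):
    table, _ = peak_table
    flagged = annotation.flag_detection(table)
    props = quantify.species_proportions(flagged)
    subj, means = quantify.average_replicates(props)
    return subj, means


def make_peak_records(rows):
    """Small peak table from (tissue, subject, injection, gclass, species,
    area, snr) tuples."""
    return pd.DataFrame(
        rows, columns=["tissue", "subject", "injection", "gclass", "species",
                       "area", "snr"])
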