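import numpy as np
import pandas as pd
import pytest

from fluidert.exprio import ExpressionDataset


def make_dataset(values, stages, patients=None, scale="log2", gene_ids=None,
                 protocols=None, outcomes=None, gene_lengths=None):
    """Build a small ExpressionDataset from an array and stage labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n_genes)]
    sample_ids = [f"s{i+1}" for i in range(n_samples)]
    patients = patients or [f"p{i+1}" for i in range(n_samples)]
    day = {"PR": "LH+5", "RE": "LH+7", "PO": "LH+9"}
    meta = pd.DataFrame({
        "patient_id": patients,
        "day": [day.get(s, "transfer") for s in stages],
        "stage": list(stages),
        "protocol": protocols or ["natural"] * n_samples,
        "outcome": outcomes or ["unknown"] * n_samples,
    }, index=pd.Index(sample_ids, name="sample_id"))
    lengths = None
    if gene_lengths is not None:
        lengths = pd.Series(gene_lengths, index=gene_ids, dtype=float)
    return ExpressionDataset(pd.DataFrame(values, index=gene_ids, columns=sample_ids),
                             meta, scale, lengths)


def balanced_stages(n_per_stage):
    return ["PR"] * n_per_stage + ["RE"] * n_per_stage + ["PO"] * n_per_stage


@pytest.fixture()
def rng():
    # fresh deterministic stream per test: results do not depend on the
    # order in which tests consume random numbers
    return np.random.default_rng(20240917)
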