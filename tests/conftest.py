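import numpy as np
import pandas as pd
import pytest

from rbpcompendium.io import ExpressionMatrix


@pytest.fixture
def tiny_registry() -> pd.DataFrame:
    rows = [
        ("G1", "rrm-1", "protein_coding", "live"),
        ("G2", "kh-1", "protein_coding", "live"),
        ("G3", "dead-1", "protein_coding", "dead"),
        ("G4", "tn-1", "protein_coding", "transposon"),
        ("G5", "lin-1", "protein_coding", "live"),
        ("G6", "rrn-1", "other", "live"),
    ]
    return pd.DataFrame(rows, columns=["gene_id", "public_name", "biotype", "status"])


def hits_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["gene_id", "protein_id", "domain_accession", "domain_name", "source_db"]
    )


@pytest.fixture
def expr_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[10.0, 5.0, 0.0], [5.0, 5.0, 5.0], [0.0, 0.0, 10.0]],
        index=pd.Index(["G1", "G2", "G3"], name="gene_id"),
        columns=["ctA", "ctB", "ctC"],
    )
    return ExpressionMatrix(values=values, unit="TPM", condition_kind="cell_type")
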