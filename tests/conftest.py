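import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_variants():
    """Six-variant table exercising confidence and evidence edge cases."""
    return pd.DataFrame({
        "patient_id": ["P1", "P1", "P1", "P2", "P2", "P2"],
        "gene": ["KRAS", "TP53", "APC", "KRAS", "BRCA1", "G0001"],
        "chrom": ["12", "17", "5", "12", "17", "1"],
        "pos": [25398284, 7577121, 112175240, 25398284, 41245466, 1000],
        "ref": ["C", "G", "C", "C", "A", "T"],
        "alt": ["T", "A", "T", "A", "G", "C"],
        "variant_class": ["missense", "missense", "stop_gained",
                          "missense", "frameshift", "other"],
        "confidence": [9, 8, 7, 10, 8, 9],
        "protein_change": ["p.G12D", "p.R273H", "p.R1450*", "p.G12V",
                           "p.K654S", "p.A1B"],
        "ev_pathogenicity": [1.0, 1.0, 1.0, 0.0, 1.0, 0.0],
        "ev_cancer": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        "ev_clinical": [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],
        "ev_expression": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
    })


@pytest.fixture
def counts_matrix():
    """Five-gene, six-sample count matrix with known expression patterns."""
    return pd.DataFrame(
        {
            "s1": [10, 10, 0, 50, 0],
            "s2": [10, 10, 0, 50, 0],
            "s3": [10, 10, 0, 50, 0],
            "s4": [10, 10, 0, 50, 0],
            "s5": [10, 0, 0, 50, 0],
            "s6": [0, 0, 9, 50, 0],
        },
        index=["expressed5", "expressed4", "low", "high", "zero"],
    )
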