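import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scpbench.io import ProteinRecord, ProteomeDB, QuantMatrix, QuantReport

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


@pytest.fixture
def tiny_db() -> ProteomeDB:
    return ProteomeDB(
        [
            ProteinRecord("P00001_HUMAN", "MAAKGGRCCDELKK", description="protein one"),
            ProteinRecord("P00002_HUMAN", "ACDKPGGRWWK", description="protein two"),
            ProteinRecord("P00003_YEAST", "KRPKRP", description="all fixed residues"),
        ]
    )


@pytest.fixture
def small_report() -> QuantReport:
    rows = []
    for cond, rep, scale in [("a", 1, 1.0), ("a", 2, 1.1), ("b", 1, 2.0), ("b", 2, 2.2)]:
        for i, q in enumerate([100.0, 200.0, 400.0]):
            rows.append(
                {
                    "run_id": f"{cond}_r{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "protein_group": f"P{i:05d}_HUMAN",
                    "quantity": q * scale,
                    "n_peptides": i + 1,
                }
            )
    return QuantReport(pd.DataFrame(rows))


def make_matrix(values: np.ndarray, conditions: list[str], protein_ids=None,
                **sample_cols) -> QuantMatrix:
    """Build a QuantMatrix from a 2D array with one column per sample."""
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    sample_ids = [f"s{i}" for i in range(n_samp)]
    protein_ids = protein_ids or [f"P{i:05d}_HUMAN" for i in range(n_prot)]
    meta = pd.DataFrame({"condition": conditions, **sample_cols},
                        index=pd.Index(sample_ids, name="sample_id"))
    reps = meta.groupby("condition").cumcount() + 1
    meta["replicate"] = reps
    return QuantMatrix(
        values=pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                            columns=meta.index),
        sample_meta=meta,
    )
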