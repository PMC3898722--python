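import pandas as pd
import pytest

from mirmeth import CohortSimParams, RunConfig, simulate_cohort


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort, shared across tests."""
    params = CohortSimParams(seed=11)
    ct_table, meta, truth = simulate_cohort(params)
    return ct_table, meta, truth


@pytest.fixture
def tiny_ct_csv(tmp_path):
    """2 samples x 2 assays x 3 replicates, well formed."""
    rows = []
    for sample in ("S1", "S2"):
        for assay, base in (("miR-29a", 28.0), ("RNU66", 24.0)):
            for rep in (1, 2, 3):
                rows.append((sample, assay, rep, base + 0.1 * rep))
    path = tmp_path / "ct.csv"
    pd.DataFrame(rows, columns=["sample_id", "assay_id", "replicate", "ct"]).to_csv(
        path, index=False
    )
    return path


@pytest.fixture
def study_metadata_csv(tmp_path):
    """Metadata mirroring the study design: 70 tumors + 18 normals."""
    rows = []
    for prefix, subtype, n in (
        ("LA", "luminal_A", 36),
        ("LB", "luminal_B", 13),
        ("H", "her2_enriched", 5),
        ("B", "basal_like", 16),
    ):
        rows += [(f"{prefix}{i:02d}", subtype, "tumor") for i in range(1, n + 1)]
    rows += [(f"N{i:02d}", "normal", "calibrator") for i in range(1, 19)]
    path = tmp_path / "metadata.csv"
    pd.DataFrame(rows, columns=["sample_id", "subtype", "role"]).to_csv(
        path, index=False
    )
    return path
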