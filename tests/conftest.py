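import numpy as np
import pandas as pd
import pytest

from rainplot import (
    AssociationGrid,
    AssociationRecord,
    MetaboliteAnnotation,
    ModelSpec,
    SyntheticDesign,
    build_grid,
    generate_study,
    preprocess_pipeline,
)


def make_grid(betas, ps, mz=None, outcomes=None, families=None):
    """Hand-build a complete grid from beta and P matrices (lists of rows)."""
    betas = np.asarray(betas, dtype=float)
    ps = np.asarray(ps, dtype=float)
    n, k = betas.shape
    ids = [f"M{i + 1:04d}" for i in range(n)]
    if outcomes is None:
        outcomes = [f"out{j + 1}" for j in range(k)]
    if families is None:
        families = ["linear"] * k
    if mz is None:
        mz = 300.0 + 10.0 * np.arange(n)
    panel = [
        ModelSpec(outcome=o, family=f, display_index=j)
        for j, (o, f) in enumerate(zip(outcomes, families))
    ]
    annotations = [MetaboliteAnnotation(i, float(z)) for i, z in zip(ids, mz)]
    records = [
        AssociationRecord(ids[i], outcomes[j], betas[i, j], 0.1, ps[i, j])
        for i in range(n)
        for j in range(k)
    ]
    return AssociationGrid(records, annotations, panel)


@pytest.fixture
def small_grid():
    """3 metabolites x 2 outcomes with distinct betas and P values."""
    return make_grid(
        betas=[[0.5, -0.2], [-1.0, 0.3], [0.0, 0.8]],
        ps=[[0.20, 0.50], [0.01, 0.90], [0.05, 0.30]],
        mz=[400.1, 250.2, 649.9],
    )


@pytest.fixture(scope="session")
def tiny_study():
    """Seeded synthetic study small enough for fast end-to-end tests."""
    design = SyntheticDesign(
        n_samples=150,
        n_metabolites=12,
        missing_rate=0.1,
        planted_effects=[
            ("M0001", "age", 4.0),
            ("M0002", "female_sex", 1.2),
            ("M0003", "body_mass_index", 2.0),
        ],
        seed=42,
    )
    return generate_study(design)


@pytest.fixture(scope="session")
def tiny_grid(tiny_study):
    abundance, phenotypes, annotations, _ = tiny_study
    std, _ = preprocess_pipeline(abundance)
    return build_grid(std, phenotypes, annotations=annotations)
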