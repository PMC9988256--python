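import numpy as np
import pandas as pd
import pytest

from myoatlas import preprocess as pp
from myoatlas import synthetic as syn


@pytest.fixture(scope="session")
def small_design():
    return syn.StudyDesign(n_individuals=10)


@pytest.fixture(scope="session")
def default_dataset():
    """Generator-default-structure dataset at reduced gene count, shared by
    read-only tests."""
    design = syn.StudyDesign()
    params = syn.GenerativeParams(
        n_genes=700, seed=42,
        planted_modules=((80, 0.8), (70, 0.8), (60, 0.8), (50, 0.8), (40, 0.8)))
    counts, meta, truth = syn.simulate_bulk_counts(design, params)
    return {"design": design, "params": params, "counts": counts,
            "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def default_expr(default_dataset):
    counts = pp.filter_low_expressed(default_dataset["counts"])
    factors = pp.tmm_norm_factors(counts)
    return pp.cpm_log(counts, factors)


def make_paired_metadata(n_individuals: int, muscles=("A", "B")) -> pd.DataFrame:
    rows = [(f"I{i:02d}_{m}", f"I{i:02d}", m, "B1")
            for i in range(n_individuals) for m in muscles]
    meta = pd.DataFrame(rows, columns=["sample", "individual", "muscle", "batch"])
    return meta.set_index("sample", drop=False)


@pytest.fixture
def paired_meta():
    return make_paired_metadata(20)


@pytest.fixture(scope="session")
def atlas_meta():
    """Complete 10-individual x 7-muscle metadata (no missingness)."""
    rows = [(f"I{i:02d}_{m}", f"I{i:02d}", m, f"B{(i + j) % 2 + 1}")
            for i in range(10) for j, m in enumerate(syn.DEFAULT_MUSCLES)]
    meta = pd.DataFrame(rows, columns=["sample", "individual", "muscle", "batch"])
    return meta.set_index("sample", drop=False)
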