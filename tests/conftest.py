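import numpy as np
import pandas as pd
import pytest

from diaprm.io import LayoutEntry, SampleLayout
from diaprm.preprocess import ProteinMatrix
from diaprm.synth import FixtureSpec, make_dia_fixture, make_prm_fixture


def make_layout(groups=("A", "B"), replicates=2) -> SampleLayout:
    entries = [
        LayoutEntry(f"run_{g}_{r}", f"{g}_R{r}", g, r)
        for g in groups
        for r in range(1, replicates + 1)
    ]
    return SampleLayout(entries=entries, group_order=list(groups))


def matrix_from_frame(ab: pd.DataFrame, layout: SampleLayout) -> ProteinMatrix:
    """Wrap an abundance frame (proteins x samples, NaN = missing)."""
    upep = ab.notna().astype(int) * 2
    genes = pd.Series(
        [f"G_{p}" for p in ab.index], index=ab.index, name="gene"
    )
    return ProteinMatrix(abundance=ab, unique_peptides=upep, genes=genes, layout=layout)


@pytest.fixture
def two_group_layout():
    return make_layout(("A", "B"), 3)


@pytest.fixture(scope="session")
def dia_fixture(tmp_path_factory):
    """Small two-group DIA fixture shared across read-only tests."""
    spec = FixtureSpec(
        groups=("A", "B"), replicates=4, n_proteins=40, replicate_cv=10.0, seed=11
    )
    out = tmp_path_factory.mktemp("dia_fix")
    report, skyline, layout, gt = make_dia_fixture(spec, out)
    return {"report": report, "skyline": skyline, "layout": layout, "truth": gt, "spec": spec}


@pytest.fixture(scope="session")
def prm_fixture(tmp_path_factory):
    """Three-group heavy-label PRM fixture with 10% ratio noise."""
    spec = FixtureSpec(
        groups=("D0", "D2", "D4"), replicates=3, ratio_cv=10.0, seed=7
    )
    out = tmp_path_factory.mktemp("prm_fix")
    csv, params, layout, gt = make_prm_fixture(spec, out, n_proteins=6)
    return {"csv": csv, "params": params, "layout": layout, "truth": gt, "spec": spec}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
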