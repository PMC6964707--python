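import numpy as np
import pytest

from toxdeconv.core_data import (
    CompoundDataset,
    DoseLevel,
    ExpressionMatrix,
    SampleMeta,
    System,
)
from toxdeconv.deconvolution import NMFConfig
from toxdeconv.pipeline import run_simulation, run_verification
from toxdeconv.synthetic import SyntheticConfig, generate_study


def make_expr(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(
        gene_ids or [f"g{i}" for i in range(m)],
        sample_ids or [f"s{j}" for j in range(n)],
        values,
    )


def make_meta(sample_id, compound, system=System.IN_VIVO_SINGLE, control=False, replicate=1):
    return SampleMeta(
        sample_id=sample_id,
        compound=compound,
        system=system,
        dose_level=DoseLevel.CONTROL if control else DoseLevel.HIGH,
        time_label="24h",
        replicate=replicate,
        is_control=control,
    )


def make_compound_dataset(treated, controls, compound="cmpA", system=System.IN_VIVO_SINGLE):
    t = make_expr(treated, sample_ids=[f"{compound}_t{j}" for j in range(np.shape(treated)[1])])
    c = ExpressionMatrix(
        t.gene_ids,
        [f"{compound}_c{j}" for j in range(np.shape(controls)[1])],
        controls,
    )
    return CompoundDataset(compound=compound, treated=t, controls=c, system=system)


SMALL_STUDY_CONFIG = SyntheticConfig(
    n_genes=600, n_compounds=4, frac_de_genes=0.1, seed=11
)
SMALL_NMF = NMFConfig(k=2, restarts=5, repeats=2, seed=11)
SMALL_G = 60


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SMALL_STUDY_CONFIG)


@pytest.fixture(scope="session")
def small_verification(small_study):
    s = small_study
    return run_verification(
        s.expr_invivo, s.meta_invivo, s.expr_invitro, s.meta_invitro,
        nmf=SMALL_NMF, g=SMALL_G,
    )


@pytest.fixture(scope="session")
def small_simulation(small_verification):
    return run_simulation(small_verification, g=SMALL_G)
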