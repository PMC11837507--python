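import numpy as np
import pandas as pd
import pytest

from qsip15n.datatypes import (
    GradientFraction,
    SampleMeta,
    TaxonAbundanceMatrix,
    TubeGradient,
)
from qsip15n.pipeline import NitrogenQsip, PipelineConfig
from qsip15n.simulate import SimulationConfig, simulate_study


@pytest.fixture()
def two_tubes():
    """Two small tubes with in-window densities."""
    def frac(tube, k, d, c):
        return GradientFraction(f"{tube}:F{k}", d, c)

    t1 = TubeGradient(
        "T1", "S1", tuple(frac("T1", k, d, c) for k, (d, c) in
                          enumerate(zip([1.68, 1.70, 1.72], [100.0, 300.0, 200.0])))
    )
    t2 = TubeGradient(
        "T2", "S2", tuple(frac("T2", k, d, c) for k, (d, c) in
                          enumerate(zip([1.68, 1.70, 1.72], [150.0, 250.0, 100.0])))
    )
    return [t1, t2]


@pytest.fixture()
def small_matrix(two_tubes):
    cols = [fid for t in two_tubes for fid in t.fraction_ids]
    counts = pd.DataFrame(
        np.array(
            [
                [10, 20, 5, 8, 15, 3],
                [0, 5, 10, 1, 4, 12],
                [2, 2, 2, 2, 2, 2],
                [0, 0, 0, 0, 0, 0],
            ],
            dtype=float,
        ),
        index=["A1", "A2", "A3", "A4"],
        columns=cols,
    )
    taxonomy = pd.Series(
        {
            "A1": "d__Bacteria;p__P1;c__C1;o__O1;f__F1;g__G1",
            "A2": "d__Bacteria;p__P1;c__C1;o__O1;f__F1;g__G1",
            "A3": "d__Bacteria;p__P1;c__C1;o__O1;f__Oxalobacteraceae",
            "A4": "d__Bacteria;p__P2;c__C2;o__O2;f__F2;g__G2",
        },
        name="taxonomy",
    )
    f2t = {fid: t.tube_id for t in two_tubes for fid in t.fraction_ids}
    return TaxonAbundanceMatrix(counts=counts, taxonomy=taxonomy, fraction_to_tube=f2t)


@pytest.fixture()
def full_design_metas():
    metas = []
    for site in ("Valley", "Ridge"):
        for plot in range(1, 8):
            metas.append(SampleMeta(f"{site}_p{plot}_pre", site, "pre", plot, "unlabeled"))
            for method in ("field", "lab"):
                metas.append(
                    SampleMeta(f"{site}_p{plot}_{method}", site, method, plot, "labeled")
                )
    return metas


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study shared by pipeline-level tests."""
    cfg = SimulationConfig(n_taxa=40, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_results(small_study):
    tubes, matrix, metas, _ = small_study
    return NitrogenQsip(tubes, matrix, metas).fit()
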