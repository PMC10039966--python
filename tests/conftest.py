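import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dosagescope.io import ExpressionMatrix, GeneAnnotation, Karyotype, SampleSheet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_sheet(strains: dict[str, int]) -> SampleSheet:
    """Sample sheet with the given number of replicates per strain."""
    rows = [
        (f"{s}_r{r}", s, r)
        for s, n in strains.items()
        for r in range(1, n + 1)
    ]
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "strain_id", "replicate"]))


def make_matrix(values: dict[str, list[float]], genes: list[str] | None = None) -> ExpressionMatrix:
    df = pd.DataFrame(values)
    df.index = genes or [f"g{i+1}" for i in range(len(df))]
    return ExpressionMatrix(df)


@pytest.fixture
def two_strain_data():
    """Four genes, two strains x two replicates, exact means by construction."""
    sheet = make_sheet({"TRI": 2, "WT": 2})
    matrix = make_matrix(
        {
            "TRI_r1": [14.0, 10.0, 0.0, 5.0],
            "TRI_r2": [16.0, 10.0, 0.0, 7.0],
            "WT_r1": [9.0, 10.0, 4.0, 6.0],
            "WT_r2": [11.0, 10.0, 6.0, 6.0],
        }
    )
    return matrix, sheet


@pytest.fixture
def annotation12():
    """120 genes spread evenly over 12 chromosomes."""
    mapping = {f"g{i+1:03d}": str(i % 12 + 1) for i in range(120)}
    return GeneAnnotation(mapping, chromosomes=[str(c) for c in range(1, 13)])


@pytest.fixture
def trisomy11():
    return Karyotype("T11-P", frozenset({"11"}))


def pure_sim_config(multiplier_class: str, side: str, n_genes: int = 200,
                    noise: float = 0.0, seed: int = 0, **kw):
    """One trisomic strain + WT where every cis (or trans) gene carries a
    single response class; the other side is left unchanged."""
    from dosagescope.simulate import SimulationConfig, StrainSpec

    cis = {"dosage_effect": 0.0, "compensated": 0.0, "intermediate": 0.0}
    trans = {"inverse": 0.0, "unchanged": 0.0, "direct": 0.0, "extreme": 0.0}
    if side == "cis":
        cis[multiplier_class] = 1.0
        trans["unchanged"] = 1.0
    else:
        trans[multiplier_class] = 1.0
        cis["compensated"] = 1.0
    wt_trans = dict.fromkeys(trans, 0.0) | {"unchanged": 1.0}
    return SimulationConfig(
        n_genes=n_genes,
        replicate_noise_sd=noise,
        strains=[
            StrainSpec("WT", (), trans_mixture=wt_trans),
            StrainSpec("TRI", ("11",), cis_mixture=cis, trans_mixture=trans),
        ],
        seed=seed,
        **kw,
    )
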