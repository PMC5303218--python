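"""Shared fixtures: canonical pedigrees and small simulated datasets."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famassoc.pedigree import Individual, Pedigree, kinship
from famassoc.phenotype import PhenotypeTable
from famassoc.relatedness import RelatednessMatrix
from famassoc.simulate import SimulationConfig, simulate_families, simulate_traits


def make_pedigree(rows: list[tuple]) -> Pedigree:
    """Build a pedigree from (fid, iid, father, mother) tuples."""
    return Pedigree(
        [Individual(iid, fid, father, mother, "unknown") for fid, iid, father, mother in rows]
    )


def cousin_pedigree(degree: int) -> tuple[Pedigree, str, str]:
    """A pedigree containing a pair of ``degree``-th cousins.

    Two founder sibs each found a lineage through unrelated spouses; after
    ``degree`` generations the lineage tips are degree-th cousins.
    """
    rows = [
        ("F", "A", None, None),
        ("F", "B", None, None),
        ("F", "L0", "A", "B"),
        ("F", "R0", "A", "B"),
    ]
    left, right = "L0", "R0"
    for g in range(1, degree + 1):
        rows += [
            ("F", f"LS{g}", None, None),
            ("F", f"RS{g}", None, None),
            ("F", f"L{g}", left, f"LS{g}"),
            ("F", f"R{g}", right, f"RS{g}"),
        ]
        left, right = f"L{g}", f"R{g}"
    return make_pedigree(rows), left, right


@pytest.fixture(scope="session")
def three_gen_pedigree() -> Pedigree:
    return simulate_families(1)


@pytest.fixture(scope="session")
def small_families():
    """25 three-generation families with a moderately heritable trait and a
    causal predictor explaining 5% of variance."""
    config = SimulationConfig(
        n_families=25, h2=0.4, predictor_variance_fraction=0.05,
        n_predictors=3, seed=11,
    )
    ped = simulate_families(config)
    rel = kinship(ped)
    responses, predictors = simulate_traits(ped, config)
    return ped, rel, responses, predictors


@pytest.fixture()
def identity_dataset():
    """60 mutually unrelated individuals with pure-noise data."""
    rng = np.random.default_rng(7)
    n = 60
    ids = [f"i{k}" for k in range(n)]
    rel = RelatednessMatrix(ids=ids, values=np.eye(n), source="gsm")
    responses = PhenotypeTable(
        pd.DataFrame({"y": rng.standard_normal(n)}, index=ids)
    )
    predictors = PhenotypeTable(
        pd.DataFrame(
            rng.standard_normal((n, 4)), index=ids,
            columns=[f"x{k}" for k in range(4)],
        )
    )
    return rel, responses, predictors
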