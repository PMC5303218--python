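"""Synthetic family data: pedigrees, polygenic traits and test oracles.

The canonical simulated unit is a three-generation family of eight:
maternal and paternal grandparent couples (four founders), their two
children who marry, and two full-sib offspring. Traits follow the standard
additive polygenic Gaussian model — per family, polygenic effects are drawn
with covariance ``2*Phi * sigma2_a`` through the family's Cholesky factor,
plus i.i.d. environmental noise — so a simulated trait has exactly the
narrow-sense heritability requested and (optionally) one causal predictor
explaining a requested fraction of variance.

Gene-dropping utilities (Monte-Carlo transmission of founder alleles down
the pedigree) serve as independent oracles: an empirical kinship estimate
for checking the exact recursion, and simulated genotypes from which an
allelic-correlation GRM can be built to mirror marker-based analyses.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, kinship
from .phenotype import PhenotypeTable
from .relatedness import RelatednessMatrix

__all__ = [
    "SimulationConfig",
    "simulate_families",
    "simulate_traits",
    "simulate_dataset",
    "simulate_polygenic",
    "gene_drop_kinship",
    "gene_drop_genotypes",
    "allelic_correlation_grm",
    "write_ped",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``h2`` is the narrow-sense heritability of every simulated response;
    ``predictor_variance_fraction`` the trait variance explained by the
    first (causal) predictor — the implied slope on the unit-variance
    predictor is ``sqrt(predictor_variance_fraction)``; ``beta`` overrides
    the slope directly when the fraction is 0. Remaining predictors are
    null. Missingness is completely at random at ``missing_rate``, unless
    ``n_shared_masks`` assigns predictors to that many shared missingness
    patterns (exercising missingness clustering).
    """

    n_families: int = 125
    family_structure: str = "three_generation_8"
    h2: float = 0.4
    beta: float = 0.0
    predictor_variance_fraction: float = 0.0
    n_predictors: int = 1
    n_responses: int = 1
    missing_rate: float = 0.0
    n_shared_masks: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        if not (0 <= self.predictor_variance_fraction < 1):
            raise ValueError("predictor_variance_fraction must lie in [0, 1)")
        if self.h2 + self.predictor_variance_fraction >= 1:
            raise ValueError(
                "h2 + predictor_variance_fraction must be < 1 "
                "(environmental variance would be non-positive)"
            )

    @property
    def slope(self) -> float:
        """Effective slope of the causal predictor."""
        if self.predictor_variance_fraction > 0:
            return float(np.sqrt(self.predictor_variance_fraction))
        return self.beta


def simulate_families(config: SimulationConfig | int) -> Pedigree:
    """``n_families`` independent three-generation families of eight.

    Each family: two grandparental couples (founders), one parent from each
    couple, and two full-sib offspring of the parental couple.
    """
    if isinstance(config, int):
        config = SimulationConfig(n_families=config)
    if config.n_families < 1:
        raise ValueError("need at least one family")
    if config.family_structure != "three_generation_8":
        raise ValueError(f"unknown family structure {config.family_structure!r}")
    individuals: list[Individual] = []
    for f in range(1, config.n_families + 1):
        fid = f"F{f}"

        def iid(tag: str) -> str:
            return f"{fid}_{tag}"

        individuals += [
            Individual(iid("gpf"), fid, None, None, "male"),
            Individual(iid("gmf"), fid, None, None, "female"),
            Individual(iid("gpm"), fid, None, None, "male"),
            Individual(iid("gmm"), fid, None, None, "female"),
            Individual(iid("fa"), fid, iid("gpf"), iid("gmf"), "male"),
            Individual(iid("mo"), fid, iid("gpm"), iid("gmm"), "female"),
            Individual(iid("o1"), fid, iid("fa"), iid("mo"), "male"),
            Individual(iid("o2"), fid, iid("fa"), iid("mo"), "female"),
        ]
    return Pedigree(individuals)


def _family_chol_factors(rel: RelatednessMatrix) -> list[tuple[slice, np.ndarray]]:
    factors = []
    for start, stop in rel.family_blocks:
        block = rel.values[start:stop, start:stop]
        factors.append((slice(start, stop), np.linalg.cholesky(block)))
    return factors


def simulate_polygenic(
    rel: RelatednessMatrix, sigma2_a: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw polygenic effect vectors with covariance ``sigma2_a * 2*Phi``.

    Returns an (n, size) matrix aligned to ``rel.ids``; uses per-family
    Cholesky factors of the block-diagonal relatedness.
    """
    n = rel.n
    g = np.empty((n, size))
    if rel.family_blocks is None:
        L = np.linalg.cholesky(rel.values + 1e-12 * np.eye(n))
        g[:] = L @ rng.standard_normal((n, size))
    else:
        for sl, L in _family_chol_factors(rel):
            g[sl] = L @ rng.standard_normal((sl.stop - sl.start, size))
    return np.sqrt(sigma2_a) * g


def simulate_traits(
    ped: Pedigree, config: SimulationConfig
) -> tuple[PhenotypeTable, PhenotypeTable]:
    """Simulate responses and predictors on a pedigree.

    Every response is ``slope * p1 + g + e`` with ``g`` polygenic
    (variance ``h2``), ``e`` i.i.d. normal sized so the total variance is
    1, and ``p1`` the shared standard-normal causal predictor; predictors
    beyond the first are null. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rel = kinship(ped)
    ids = rel.ids
    n = rel.n
    slope = config.slope
    var_pred = slope**2
    sigma2_e = 1.0 - config.h2 - (var_pred if config.predictor_variance_fraction > 0 else 0.0)
    if sigma2_e <= 0:
        raise ValueError("variance fractions sum to >= 1")
    predictors = rng.standard_normal((n, config.n_predictors))
    g = simulate_polygenic(rel, config.h2, rng, size=config.n_responses)
    e = np.sqrt(sigma2_e) * rng.standard_normal((n, config.n_responses))
    responses = g + e
    if slope != 0.0 and config.n_predictors >= 1:
        responses = responses + slope * predictors[:, [0]]

    resp_df = pd.DataFrame(
        responses, index=ids, columns=[f"resp{j + 1}" for j in range(config.n_responses)]
    )
    pred_df = pd.DataFrame(
        predictors, index=ids, columns=[f"pred{j + 1}" for j in range(config.n_predictors)]
    )
    if config.missing_rate > 0:
        if config.n_shared_masks:
            masks = rng.random((n, config.n_shared_masks)) < config.missing_rate
            assign = rng.integers(0, config.n_shared_masks, config.n_predictors)
            for j in range(config.n_predictors):
                pred_df.iloc[masks[:, assign[j]], j] = np.nan
        else:
            pred_df[rng.random(pred_df.shape) < config.missing_rate] = np.nan
        resp_df[rng.random(resp_df.shape) < config.missing_rate] = np.nan
    return PhenotypeTable(resp_df), PhenotypeTable(pred_df)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Pedigree, PhenotypeTable, PhenotypeTable]:
    ped = simulate_families(config)
    responses, predictors = simulate_traits(ped, config)
    return ped, responses, predictors


# --------------------------------------------------------------------------
# gene-dropping oracles
# --------------------------------------------------------------------------

def _dropping_order(
    ped: Pedigree,
) -> tuple[list[tuple[int, int | None, int | None]], list[str]]:
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    rows = []
    for iid in order:
        ind = ped[iid]
        if ind.is_founder:
            rows.append((pos[iid], None, None))
        else:
            rows.append((pos[iid], pos[ind.father], pos[ind.mother]))
    return rows, order


def gene_drop_kinship(
    ped: Pedigree, n_drops: int = 100_000, rng: np.random.Generator | None = None
) -> tuple[RelatednessMatrix, np.ndarray]:
    """Monte-Carlo estimate of the relatedness matrix by gene dropping.

    Founders receive unique allele labels; alleles are transmitted down the
    pedigree with independent fair Mendelian draws, ``n_drops`` times. The
    kinship of (i, j) is estimated as the probability that a random allele
    of i is identical by descent to a random allele of j. Returns the
    estimated 2*phi matrix (ids in topological order) and the per-entry
    Monte-Carlo standard errors.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows, order = _dropping_order(ped)
    n = len(order)
    pat = np.empty((n, n_drops), dtype=np.int32)
    mat = np.empty((n, n_drops), dtype=np.int32)
    label = 0
    for k, (i, f, m) in enumerate(rows):
        if f is None:
            pat[i] = 2 * label
            mat[i] = 2 * label + 1
            label += 1
        else:
            pick_f = rng.integers(0, 2, n_drops, dtype=np.int8)
            pick_m = rng.integers(0, 2, n_drops, dtype=np.int8)
            pat[i] = np.where(pick_f == 0, pat[f], mat[f])
            mat[i] = np.where(pick_m == 0, pat[m], mat[m])
    est = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            # P(random allele of i IBD to random allele of j), averaged
            share = (
                (pat[i] == pat[j]).astype(float)
                + (pat[i] == mat[j])
                + (mat[i] == pat[j])
                + (mat[i] == mat[j])
            ) / 4.0
            phi_hat = share.mean()
            est[i, j] = est[j, i] = 2.0 * phi_hat
            se[i, j] = se[j, i] = 2.0 * share.std(ddof=1) / np.sqrt(n_drops)
    rel = RelatednessMatrix(ids=order, values=est, source="pedigree", psd=None)
    return rel, se


def gene_drop_genotypes(
    ped: Pedigree,
    n_snps: int = 500,
    rng: np.random.Generator | None = None,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate unlinked biallelic genotypes by gene dropping.

    Founder alleles are Bernoulli draws at per-SNP allele frequencies
    uniform on ``maf_range``; transmission is Mendelian and independent
    across SNPs. Returns a (individuals x SNPs) dosage frame (0/1/2) and
    the true allele frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows, order = _dropping_order(ped)
    n = len(order)
    freqs = rng.uniform(*maf_range, n_snps)
    pat = np.empty((n, n_snps), dtype=np.int8)
    mat = np.empty((n, n_snps), dtype=np.int8)
    for i, f, m in rows:
        if f is None:
            pat[i] = rng.random(n_snps) < freqs
            mat[i] = rng.random(n_snps) < freqs
        else:
            pick_f = rng.integers(0, 2, n_snps, dtype=np.int8)
            pick_m = rng.integers(0, 2, n_snps, dtype=np.int8)
            pat[i] = np.where(pick_f == 0, pat[f], mat[f])
            mat[i] = np.where(pick_m == 0, pat[m], mat[m])
    dosage = (pat + mat).astype(float)
    return pd.DataFrame(dosage, index=order), freqs


def allelic_correlation_grm(
    genotypes: pd.DataFrame, freqs: np.ndarray | None = None
) -> RelatednessMatrix:
    """Allelic-correlation GRM from a dosage matrix (reference formula).

    ``A = Z Z' / m`` with ``z_ik = (g_ik - 2 p_k) / sqrt(2 p_k (1 - p_k))``;
    the realized-relatedness analogue of the expected 2*phi matrix. Intended
    as an in-repo reference for pipelines and tests, not a replacement for
    dedicated GRM software.
    """
    G = genotypes.to_numpy(dtype=float)
    if freqs is None:
        freqs = G.mean(axis=0) / 2.0
    keep = (freqs > 0) & (freqs < 1)
    G = G[:, keep]
    p = np.asarray(freqs)[keep]
    Z = (G - 2 * p) / np.sqrt(2 * p * (1 - p))
    values = (Z @ Z.T) / Z.shape[1]
    values = 0.5 * (values + values.T)
    return RelatednessMatrix(
        ids=[str(i) for i in genotypes.index],
        values=values,
        source="gsm",
        psd=None,
        family_blocks=None,
    )


# --------------------------------------------------------------------------
# file emission
# --------------------------------------------------------------------------

def write_ped(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree as a whitespace-delimited PED file."""
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                f"{ind.fid}\t{ind.iid}\t{ind.father or '0'}\t"
                f"{ind.mother or '0'}\t{sex_code[ind.sex]}\n"
            )


def write_dataset(
    out_dir: str | Path,
    config: SimulationConfig,
    with_map: bool = False,
) -> dict[str, Path]:
    """Simulate a dataset and write PED, phenotype and predictor tables
    (plus an optional map with synthetic positions). Byte-deterministic
    given the config seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ped, responses, predictors = simulate_dataset(config)
    paths = {
        "ped": out_dir / "families.ped",
        "responses": out_dir / "responses.tsv",
        "predictors": out_dir / "predictors.tsv",
    }
    write_ped(ped, paths["ped"])
    responses.write(paths["responses"])
    predictors.write(paths["predictors"])
    if with_map:
        paths["map"] = out_dir / "predictors.map"
        with open(paths["map"], "w") as fh:
            fh.write("name\tchrom\tposition\n")
            for k, name in enumerate(predictors.variables):
                fh.write(f"{name}\t1\t{1000 * (k + 1)}\n")
    return paths
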