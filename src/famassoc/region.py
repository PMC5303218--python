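"""Region-based testing: sliding windows summarized by a first principal
component.

When predictors can be ordered in space (CpG loci, expression probes with a
genomic anchor, ...), consecutive predictors are gathered into sliding
windows and each window's member values are replaced by their first
principal component, which by construction captures as much of the joint
variability of the region as a single composite variable can. The composite
is then tested exactly like an ordinary predictor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotype import PhenotypeTable
from .relatedness import RelatednessMatrix
from .vc import AssocOptions, AssociationResult, run_association_scan

__all__ = ["RegionWindow", "build_windows", "summarize_window", "run_region_scan"]


@dataclass
class RegionWindow:
    """A genomic window of consecutive predictors."""

    chrom: str
    start: int
    end: int  # 1-based, inclusive
    predictor_ids: list[str]
    pc1_scores: pd.Series | None = field(default=None, repr=False)
    variance_explained: float | None = None

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def build_windows(
    map_df: pd.DataFrame,
    size: int,
    unit: str = "predictors",
    step: int = 1,
) -> list[RegionWindow]:
    """Window skeletons over position-ordered predictors.

    ``map_df`` is indexed by predictor name with columns ``chrom`` and
    ``position`` (1-based), sorted by position within each chromosome.
    ``unit="predictors"``: each window holds ``size`` consecutive predictors
    advancing by ``step`` (a shorter trailing window is kept).
    ``unit="bases"``: half-open genomic intervals ``[s, s + size)`` starting
    at the chromosome's first mapped position, advancing by ``step``;
    windows with no members are dropped. Windows never span chromosomes.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    if step < 1:
        raise ValueError("window step must be >= 1")
    if unit not in ("predictors", "bases"):
        raise ValueError(f"unknown window unit {unit!r}")
    windows: list[RegionWindow] = []
    for chrom in map_df["chrom"].unique():
        sub = map_df[map_df["chrom"] == chrom]
        pos = sub["position"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(
                f"map positions on chromosome {chrom} are not sorted; "
                "sort the map file by position within each chromosome"
            )
        names = list(sub.index)
        if unit == "predictors":
            for start_i in range(0, len(names), step):
                members = names[start_i : start_i + size]
                windows.append(
                    RegionWindow(
                        chrom=str(chrom),
                        start=int(pos[start_i]),
                        end=int(pos[min(start_i + size, len(names)) - 1]),
                        predictor_ids=members,
                    )
                )
                if start_i + size >= len(names):
                    break
        else:
            for s in range(int(pos[0]), int(pos[-1]) + 1, step):
                lo = int(np.searchsorted(pos, s, side="left"))
                hi = int(np.searchsorted(pos, s + size, side="left"))
                if hi > lo:
                    windows.append(
                        RegionWindow(
                            chrom=str(chrom),
                            start=s,
                            end=s + size - 1,
                            predictor_ids=names[lo:hi],
                        )
                    )
                if s + step > pos[-1]:
                    break
    return windows


def summarize_window(
    values: pd.DataFrame, impute: str = "complete_case"
) -> tuple[pd.Series, float]:
    """First-principal-component summary of a window's member values.

    Columns are centered and scaled to unit variance (correlation-based
    PCA); individuals missing any member value are dropped (complete-case).
    The component sign is fixed so the loading largest in absolute value is
    positive, making the summary independent of member input order; scores
    are rescaled to unit sample variance. ``variance_explained`` is the
    leading eigenvalue of the correlation matrix divided by the number of
    retained members.
    """
    if impute != "complete_case":
        raise ValueError(f"unknown missing-data policy {impute!r}")
    if values.shape[1] < 1:
        raise ValueError("window has no members")
    complete = values.dropna(axis=0)
    Z = complete.to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=1) if Z.shape[0] > 1 else np.zeros(Z.shape[1])
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(values.columns, keep) if not k]
        warnings.warn(
            f"dropping zero-variance window member(s): {dropped}", stacklevel=2
        )
    if not keep.any():
        raise ValueError("all window members have zero variance")
    Z = (Z[:, keep] - Z[:, keep].mean(axis=0)) / sd[keep]
    m = Z.shape[1]
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvals[-1]
    v = eigvecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    scores = Z @ v
    s = scores.std(ddof=1)
    if s > 0:
        scores = scores / s
    return (
        pd.Series(scores, index=complete.index),
        float(lead / m),
    )


def run_region_scan(
    responses: PhenotypeTable,
    predictors: PhenotypeTable,
    map_df: pd.DataFrame,
    rel: RelatednessMatrix,
    size: int,
    unit: str = "predictors",
    step: int = 1,
    covariates: PhenotypeTable | None = None,
    options: AssocOptions | None = None,
) -> tuple[list[AssociationResult], list[RegionWindow]]:
    """Association scan of window first principal components.

    Builds windows from ``map_df`` over mapped predictors, summarizes each
    window on its complete-case individuals, and scans the composite
    predictors with :func:`famassoc.vc.run_association_scan`.
    """
    mapped = [p for p in map_df.index if p in predictors.data.columns]
    windows = build_windows(map_df.loc[mapped], size, unit=unit, step=step)
    comp = {}
    positions = []
    kept: list[RegionWindow] = []
    for w in windows:
        try:
            scores, varexp = summarize_window(predictors.data[w.predictor_ids])
        except ValueError:
            continue
        w.pc1_scores = scores
        w.variance_explained = varexp
        comp[w.name] = scores
        positions.append(
            {"name": w.name, "chrom": w.chrom, "position": (w.start + w.end) // 2}
        )
        kept.append(w)
    if not comp:
        raise ValueError("no usable windows (all empty or zero-variance)")
    comp_table = PhenotypeTable(
        pd.DataFrame(comp).reindex(predictors.data.index),
        positions=pd.DataFrame(positions).set_index("name"),
    )
    results = run_association_scan(
        responses, comp_table, rel, covariates=covariates, options=options
    )
    return results, kept
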