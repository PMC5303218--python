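"""Genetic similarity matrix (GRM) input and conditioning.

GRMs are computed externally (e.g. by PLINK, GCTA or LDAK) and read here in
the GCTA binary and gzipped-text dialects or as a plain square matrix.
Marker-based matrices are not guaranteed positive semi-definite; a bending
step (eigenvalue clipping) repairs them, and an unrelatedness threshold can
zero near-zero off-diagonal entries to sparsify the covariance structure.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .relatedness import RelatednessMatrix

__all__ = [
    "GsmConditioningReport",
    "read_grm",
    "bend_to_psd",
    "threshold_unrelated",
    "UNRELATED_PRESETS",
]

#: Unrelatedness cutoffs on the 2*phi scale.
UNRELATED_PRESETS = {
    "second_cousin": 0.03125,   # 2 * 1/64
    "third_cousin": 0.0078125,  # 2 * 1/256
}

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class GsmConditioningReport:
    """What bending/thresholding did to a GSM."""

    original_min_eigenvalue: float
    bent: bool
    n_negative_eigenvalues: int
    threshold_applied: float | None = None
    n_entries_zeroed: int = 0


def _read_grm_ids(prefix: Path) -> tuple[list[str], list[str]]:
    id_path = Path(str(prefix) + ".grm.id")
    if not id_path.exists():
        raise FileNotFoundError(f"GRM id file not found: {id_path}")
    ids_df = pd.read_csv(id_path, sep=r"\s+", header=None, dtype=str)
    return ids_df.iloc[:, 1].tolist(), ids_df.iloc[:, 0].tolist()


def read_grm(prefix: str | Path, dialect: str = "gcta_bin") -> RelatednessMatrix:
    """Read an externally computed GRM.

    Dialects: ``gcta_bin`` (``prefix.grm.bin``: float32 lower triangle with
    diagonal, row-major, plus ``prefix.grm.id``), ``gcta_gz_text``
    (``prefix.grm.gz``: lines ``i j n_snps value`` with 1-based indices), or
    ``plain_matrix`` (tab-delimited square matrix with id header row and
    column at ``prefix``).
    """
    prefix = Path(prefix)
    if dialect == "plain_matrix":
        df = pd.read_csv(prefix, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("plain matrix row and column ids differ")
        values = df.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=1e-8, rtol=0):
            raise ValueError("plain GRM is not symmetric (beyond 1e-8)")
        values = 0.5 * (values + values.T)
        ids = list(df.index)
    elif dialect in ("gcta_bin", "gcta_gz_text"):
        ids, _fids = _read_grm_ids(prefix)
        n = len(ids)
        n_tri = n * (n + 1) // 2
        values = np.zeros((n, n))
        tril = np.tril_indices(n)
        if dialect == "gcta_bin":
            raw = np.fromfile(str(prefix) + ".grm.bin", dtype="<f4")
            if raw.size != n_tri:
                raise ValueError(
                    f"GRM size mismatch: id file lists {n} individuals "
                    f"({n_tri} lower-triangle entries) but .grm.bin holds "
                    f"{raw.size} values"
                )
            values[tril] = raw.astype(float)
        else:
            with gzip.open(str(prefix) + ".grm.gz", "rt") as fh:
                rows = np.loadtxt(fh, ndmin=2)
            if rows.shape[0] != n_tri:
                raise ValueError(
                    f"GRM size mismatch: id file lists {n} individuals "
                    f"({n_tri} lower-triangle entries) but .grm.gz holds "
                    f"{rows.shape[0]} lines"
                )
            i = rows[:, 0].astype(int) - 1
            j = rows[:, 1].astype(int) - 1
            values[i, j] = rows[:, 3]
        values = values + np.tril(values, -1).T
    else:
        raise ValueError(f"unknown GRM dialect {dialect!r}")

    rel = RelatednessMatrix(ids=ids, values=values, source="gsm", family_blocks=None)
    rel.psd = bool(rel.min_eigenvalue() >= -_PSD_TOL)
    return rel


def write_grm(
    rel: RelatednessMatrix, prefix: str | Path, dialect: str = "gcta_bin"
) -> None:
    """Write a GRM in a GCTA dialect (round-trip support for pipelines)."""
    prefix = Path(prefix)
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in rel.ids:
            fh.write(f"F_{iid}\t{iid}\n")
    tril = np.tril_indices(rel.n)
    if dialect == "gcta_bin":
        rel.values[tril].astype("<f4").tofile(str(prefix) + ".grm.bin")
    elif dialect == "gcta_gz_text":
        with gzip.open(str(prefix) + ".grm.gz", "wt") as fh:
            for i, j in zip(*tril):
                fh.write(f"{i + 1}\t{j + 1}\t1\t{rel.values[i, j]:.10g}\n")
    else:
        raise ValueError(f"unknown GRM dialect {dialect!r}")


def bend_to_psd(
    rel: RelatednessMatrix, epsilon: float = 1e-6
) -> tuple[RelatednessMatrix, GsmConditioningReport]:
    """Repair a non-PSD matrix by clipping eigenvalues below ``epsilon``.

    Eigenvalues smaller than ``epsilon`` are replaced by ``epsilon`` and the
    matrix reconstructed; an input whose minimum eigenvalue already reaches
    ``epsilon`` (within tolerance) is returned unchanged with ``bent=False``.
    """
    w, v = np.linalg.eigh(rel.values)
    min_eig = float(w[0])
    n_neg = int(np.sum(w < 0))
    if min_eig >= epsilon - _PSD_TOL:
        report = GsmConditioningReport(min_eig, False, n_neg)
        out = RelatednessMatrix(
            ids=list(rel.ids),
            values=rel.values,
            source=rel.source,
            psd=True,
            fids=rel.fids,
            family_blocks=rel.family_blocks,
        )
        return out, report
    w_bent = np.maximum(w, epsilon)
    values = (v * w_bent) @ v.T
    values = 0.5 * (values + values.T)
    out = RelatednessMatrix(
        ids=list(rel.ids),
        values=values,
        source=rel.source,
        psd=True,
        fids=rel.fids,
        family_blocks=rel.family_blocks,
    )
    return out, GsmConditioningReport(min_eig, True, n_neg)


def threshold_unrelated(
    rel: RelatednessMatrix, cutoff: float | str
) -> tuple[RelatednessMatrix, GsmConditioningReport]:
    """Zero off-diagonal entries below an unrelatedness cutoff.

    ``cutoff`` is a non-negative value on the 2*phi scale, or one of the
    presets ``"second_cousin"`` (0.03125) / ``"third_cousin"`` (0.0078125):
    pairs less related than the preset degree are treated as unrelated.
    """
    if isinstance(cutoff, str):
        try:
            cutoff_value = UNRELATED_PRESETS[cutoff]
        except KeyError:
            raise ValueError(
                f"unknown preset {cutoff!r}; use one of {sorted(UNRELATED_PRESETS)}"
            ) from None
    else:
        cutoff_value = float(cutoff)
        if cutoff_value < 0:
            raise ValueError("unrelatedness cutoff must be non-negative")
    values = rel.values.copy()
    off = ~np.eye(rel.n, dtype=bool)
    zero = off & (np.abs(values) < cutoff_value)
    values[zero] = 0.0
    out = RelatednessMatrix(
        ids=list(rel.ids),
        values=values,
        source=rel.source,
        psd=None,
        fids=rel.fids,
        family_blocks=rel.family_blocks,
    )
    report = GsmConditioningReport(
        original_min_eigenvalue=float(np.linalg.eigvalsh(rel.values)[0]),
        bent=False,
        n_negative_eigenvalues=0,
        threshold_applied=cutoff_value,
        n_entries_zeroed=int(zero.sum()),
    )
    return out, report
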