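"""Relatedness matrices on the 2*phi (GRM) scale.

A single container is shared by pedigree-derived expected relatedness and
marker-derived genetic similarity matrices (GSM/GRM). All relatedness in
this package lives on the 2*phi scale — twice the kinship coefficient, the
scale on which GRMs are conventionally reported — and is converted nowhere
else.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RelatednessMatrix"]

_SYMMETRY_TOL = 1e-12


@dataclass
class RelatednessMatrix:
    """Symmetric n x n expected or realized relatedness between individuals.

    Parameters
    ----------
    ids
        Ordered individual identifiers, one per row/column.
    values
        Symmetric matrix of relatedness coefficients on the 2*phi scale
        (diagonal 1 + F for pedigree sources, ~1 for GRMs).
    source
        ``"pedigree"`` for expected relatedness from a genealogy,
        ``"gsm"`` for a marker-based genetic similarity matrix.
    fids
        Optional family label per individual (pedigree sources).
    family_blocks
        Optional ``(start, stop)`` index ranges when the matrix is
        block-diagonal by family.
    """

    ids: list[str]
    values: np.ndarray
    source: str = "pedigree"
    psd: bool | None = None
    fids: list[str] | None = None
    family_blocks: list[tuple[int, int]] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("relatedness matrix is not symmetric")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in relatedness matrix")
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def indices(self, ids: list[str]) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in relatedness matrix") from None

    def get(self, a: str, b: str) -> float:
        """Relatedness (2*phi) between individuals ``a`` and ``b``."""
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids: list[str]) -> "RelatednessMatrix":
        """Restrict to ``ids`` (in the given order)."""
        idx = self.indices(ids)
        fids = [self.fids[k] for k in idx] if self.fids is not None else None
        return RelatednessMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            source=self.source,
            psd=None,
            fids=fids,
            family_blocks=None,
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])
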