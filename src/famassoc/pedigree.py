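"""Pedigree parsing, validation and expected-relatedness computation.

Pedigrees are read from whitespace-delimited PED/FAM files (columns: family
id, individual id, father, mother, sex; extra columns ignored). The expected
relatedness matrix is computed by the classical tabular kinship recursion
with founders assumed unrelated and full support for inbreeding; entries are
dyadic rationals and therefore exact in binary floating point.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .relatedness import RelatednessMatrix

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "parse_pedigree",
    "kinship",
    "is_ancestor",
    "read_mz_pairs",
    "apply_mz_pairs",
]

DEFAULT_MISSING_CODES = ("0", "")

_SEX_MAP = {
    "1": "male",
    "2": "female",
    "0": "unknown",
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
    "unknown": "unknown",
}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicates, cycles, bad parents)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``father``/``mother`` are ``None`` for founders."""

    iid: str
    fid: str
    father: str | None
    mother: str | None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father is None


@dataclass
class Pedigree:
    """A validated collection of individuals partitioned into families."""

    individuals: list[Individual]
    _by_iid: dict[str, Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_iid = {ind.iid: ind for ind in self.individuals}
        if len(self._by_iid) != len(self.individuals):
            raise PedigreeError("duplicate individual ids in pedigree")

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.individuals]

    @property
    def n(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_iid

    def __getitem__(self, iid: str) -> Individual:
        return self._by_iid[iid]

    @property
    def families(self) -> dict[str, list[str]]:
        """Family id -> member iids, in input order."""
        fams: dict[str, list[str]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.fid, []).append(ind.iid)
        return fams

    def founders(self) -> list[str]:
        return [ind.iid for ind in self.individuals if ind.is_founder]

    def topological_order(self, members: list[str] | None = None) -> list[str]:
        """Members ordered parents-before-children (Kahn's algorithm)."""
        pool = self.ids if members is None else members
        pool_set = set(pool)
        n_parents = {}
        children: dict[str, list[str]] = {i: [] for i in pool}
        for iid in pool:
            ind = self._by_iid[iid]
            parents = [p for p in (ind.father, ind.mother) if p in pool_set]
            n_parents[iid] = len(parents)
            for p in parents:
                children[p].append(iid)
        queue = [i for i in pool if n_parents[i] == 0]
        order: list[str] = []
        while queue:
            iid = queue.pop()
            order.append(iid)
            for c in children[iid]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    queue.append(c)
        if len(order) != len(pool):
            cyclic = sorted(set(pool) - set(order))
            raise PedigreeError(f"cyclic parentage involving {cyclic}")
        return order


def _normalize_sex(token: str) -> str:
    return _SEX_MAP.get(token.strip().lower(), "unknown")


def parse_pedigree(
    path: str | Path,
    dialect: str = "ped",
    missing_code: str | tuple[str, ...] = DEFAULT_MISSING_CODES,
) -> Pedigree:
    """Parse and validate a PED/FAM-style pedigree file.

    Individuals referenced only as parents are added as founders with a
    warning. Raises :class:`PedigreeError` on duplicates, cycles,
    half-specified parentage, or an empty file.
    """
    if dialect not in ("ped", "fam"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    missing = (
        (missing_code,) if isinstance(missing_code, str) else tuple(missing_code)
    )
    rows: list[tuple[str, str, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 5:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected >=5 columns "
                    f"(fid iid father mother sex), got {len(tok)}"
                )
            rows.append((tok[0], tok[1], tok[2], tok[3], tok[4]))
    if not rows:
        raise PedigreeError(f"{path}: no individuals")

    seen: set[tuple[str, str]] = set()
    individuals: list[Individual] = []
    named: set[str] = set()
    for fid, iid, father, mother, sex in rows:
        if (fid, iid) in seen:
            raise PedigreeError(f"duplicate individual ({fid}, {iid})")
        seen.add((fid, iid))
        f = None if father in missing else father
        m = None if mother in missing else mother
        if (f is None) != (m is None):
            raise PedigreeError(
                f"individual {iid}: half-specified parentage "
                f"(father={father!r}, mother={mother!r})"
            )
        individuals.append(Individual(iid, fid, f, m, _normalize_sex(sex)))
        named.add(iid)

    # parents referenced but never listed become implicit founders
    implicit: list[Individual] = []
    for ind in individuals:
        for parent, sex in ((ind.father, "male"), (ind.mother, "female")):
            if parent is not None and parent not in named:
                implicit.append(Individual(parent, ind.fid, None, None, sex))
                named.add(parent)
    if implicit:
        warnings.warn(
            f"{len(implicit)} parent(s) not listed as individuals; "
            f"added as implicit founders: {[i.iid for i in implicit]}",
            stacklevel=2,
        )

    ped = Pedigree(individuals + implicit)
    ped.topological_order()  # raises on cycles
    for ind in ped.individuals:
        if ind.iid in (ind.father, ind.mother):
            raise PedigreeError(f"individual {ind.iid} is its own parent")
    return ped


def is_ancestor(ped: Pedigree, a: str, b: str) -> bool:
    """True iff ``a`` is a proper ancestor of ``b``."""
    for iid in (a, b):
        if iid not in ped:
            raise KeyError(f"unknown individual {iid!r}")
    stack = [b]
    seen: set[str] = set()
    while stack:
        cur = ped[stack.pop()]
        for p in (cur.father, cur.mother):
            if p is not None and p not in seen:
                if p == a:
                    return True
                seen.add(p)
                stack.append(p)
    return False


def kinship(ped: Pedigree) -> RelatednessMatrix:
    """Expected relatedness (2*phi) by the tabular kinship recursion.

    phi(i,i) = (1 + phi(father_i, mother_i)) / 2 and, for j processed before
    i, phi(i,j) = (phi(father_i, j) + phi(mother_i, j)) / 2, with phi = 0
    between founders. Individuals are processed in topological order within
    each family; families are mutually unrelated, so the result is
    block-diagonal with one block per family.
    """
    order: list[str] = []
    blocks: list[tuple[int, int]] = []
    fams = ped.families
    for fid, members in fams.items():
        start = len(order)
        order.extend(ped.topological_order(members))
        blocks.append((start, len(order)))
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for start, stop in blocks:
        for iid in order[start:stop]:
            i = pos[iid]
            ind = ped[iid]
            if ind.is_founder:
                phi[i, i] = 0.5
                continue
            fpos, mpos = pos[ind.father], pos[ind.mother]
            phi[i, i] = 0.5 * (1.0 + phi[fpos, mpos])
            for j in range(start, i):
                phi[i, j] = phi[j, i] = 0.5 * (phi[fpos, j] + phi[mpos, j])

    # reorder: input order, grouped by family (first-appearance order)
    final_ids: list[str] = []
    final_fids: list[str] = []
    final_blocks: list[tuple[int, int]] = []
    for fid, members in fams.items():
        start = len(final_ids)
        final_ids.extend(members)
        final_fids.extend([fid] * len(members))
        final_blocks.append((start, len(final_ids)))
    idx = np.array([pos[i] for i in final_ids])
    values = 2.0 * phi[np.ix_(idx, idx)]
    return RelatednessMatrix(
        ids=final_ids,
        values=values,
        source="pedigree",
        psd=True,
        fids=final_fids,
        family_blocks=final_blocks,
    )


def read_mz_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column tab/whitespace-delimited file of MZ twin iid pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 2:
                raise PedigreeError(f"MZ pair file: malformed line {line!r}")
            pairs.append((tok[0], tok[1]))
    return pairs


def apply_mz_pairs(
    rel: RelatednessMatrix, pairs: list[tuple[str, str]]
) -> RelatednessMatrix:
    """Set the mutual relatedness of monozygotic twin pairs to the diagonal
    value (2*phi = 1 + F), making the pair genetically identical in the model.
    """
    values = rel.values.copy()
    for a, b in pairs:
        ia, ib = rel.indices([a, b])
        if not np.isclose(values[ia, ia], values[ib, ib]):
            raise PedigreeError(
                f"MZ pair ({a}, {b}) has unequal inbreeding coefficients"
            )
        values[ia, ib] = values[ib, ia] = values[ia, ia]
    return RelatednessMatrix(
        ids=list(rel.ids),
        values=values,
        source=rel.source,
        psd=None,
        fids=list(rel.fids) if rel.fids is not None else None,
        family_blocks=rel.family_blocks,
    )
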