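"""Multiple-testing adjustment, family diagnostics and summary plots.

Because the pedigree covariance is block-diagonal by family, the model
log-likelihood decomposes into a sum of per-family terms; the association
chi-square statistic therefore splits into per-family contributions. A test
driven by a uniform signal shows many families contributing positively and
a low Gini coefficient over the contributions, while a single outlying
family produces a high Gini — a useful screen against spurious hits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .relatedness import RelatednessMatrix

__all__ = [
    "FamilyDiagnostics",
    "bh_fdr",
    "gini",
    "family_contributions",
    "qq_plot",
    "manhattan_plot",
    "write_results",
    "RESULT_COLUMNS",
]

_LOG2PI = math.log(2.0 * math.pi)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control).

    Sorting ascending, ``q_i = min_{j >= i} (m * p_j / j)`` capped at 1,
    returned in the original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector.

    ``G = sum_ij |x_i - x_j| / (2 n^2 xbar)``; 0 for perfectly equal
    contributions, bounded above by ``1 - 1/n``. Undefined (raises) when
    all values are zero.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("Gini coefficient requires non-negative values")
    total = x.sum()
    if total <= 0:
        raise ValueError("undefined Gini: values sum to zero")
    n = x.size
    xs = np.sort(x)
    # mean absolute difference via the sorted-order identity
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * xs) - (n + 1) * total) / (n * total))


@dataclass
class FamilyDiagnostics:
    """Per-family decomposition of one association chi-square statistic."""

    family_ids: list[str]
    contributions: np.ndarray  # sums to the total LRT
    pct_positive: float
    gini: float


def _family_loglik_terms(fit, rel: RelatednessMatrix) -> dict[str, float]:
    """Per-family Gaussian log-likelihood terms at the fit's own estimates."""
    fid_by_id = dict(zip(rel.ids, rel.fids))
    fids = [fid_by_id[i] for i in fit.individuals]
    resid = fit.spec.y - fit.spec.X @ fit.coef
    idx = rel.indices(fit.individuals)
    K = rel.values[np.ix_(idx, idx)]
    terms: dict[str, float] = {}
    seen: list[str] = []
    for f in fids:
        if f not in terms:
            terms[f] = 0.0
            seen.append(f)
    fids_arr = np.array(fids, dtype=object)
    for f in seen:
        j = np.flatnonzero(fids_arr == f)
        omega = fit.sigma2_a * K[np.ix_(j, j)] + fit.sigma2_e * np.eye(j.size)
        r = resid[j]
        sign, logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"family {f}: singular within-family covariance"
            )
        quad = float(r @ np.linalg.solve(omega, r))
        terms[f] = -0.5 * (j.size * _LOG2PI + logdet + quad)
    return terms


def family_contributions(null_fit, alt_fit, rel: RelatednessMatrix) -> FamilyDiagnostics:
    """Decompose the LRT into per-family contributions.

    Requires a pedigree (block-diagonal) relatedness source and fits on the
    same individuals. ``contribution_f = 2 * (ll_alt,f - ll_null,f)`` with
    each model evaluated at its own fitted parameters, so the contributions
    sum exactly to the total statistic. The Gini coefficient is computed on
    contributions clamped at zero; the percentage positive uses raw signs.
    """
    if rel.source != "pedigree" or rel.fids is None:
        raise ValueError(
            "family diagnostics require a pedigree-derived relatedness matrix"
        )
    if null_fit.individuals != alt_fit.individuals:
        raise ValueError("fits use different individuals")
    null_terms = _family_loglik_terms(null_fit, rel)
    alt_terms = _family_loglik_terms(alt_fit, rel)
    fams = list(null_terms)
    contrib = np.array([2.0 * (alt_terms[f] - null_terms[f]) for f in fams])
    pct_positive = 100.0 * float(np.mean(contrib > 0))
    clamped = np.maximum(contrib, 0.0)
    g = gini(clamped) if clamped.sum() > 0 else 0.0
    if len(fams) == 1:
        g = 0.0
    return FamilyDiagnostics(
        family_ids=fams,
        contributions=contrib,
        pct_positive=pct_positive,
        gini=g,
    )


# --------------------------------------------------------------------------
# plots
# --------------------------------------------------------------------------

def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-inflation factor lambda: median observed chi-square over the
    chi-square(1) median."""
    from scipy.stats import chi2

    p = np.asarray(pvalues, dtype=float)
    stats = chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return float(np.median(stats) / chi2.ppf(0.5, 1))


def qq_plot(pvalues: np.ndarray, path: str) -> str:
    """Quantile-quantile plot of observed vs expected -log10 p-values.

    Expected quantiles are ``(i - 0.5) / m`` under uniformity; the identity
    line is drawn and the genomic-inflation factor lambda annotated.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size < 1:
        raise ValueError("need at least one p-value")
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    lam = genomic_inflation(p)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(expected, observed, "o", ms=3, color="#355f8d", alpha=0.7)
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], "-", color="grey", lw=1)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.text(0.05, 0.95, rf"$\lambda$ = {lam:.3f}", transform=ax.transAxes, va="top")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def manhattan_plot(
    results,
    path: str,
    fdr_threshold: float | None = None,
) -> str:
    """Manhattan plot of -log10 p by genomic position.

    ``results`` are AssociationResults carrying ``chrom``/``position``
    (supply a map file to the scan to populate them); chromosomes are
    alternately shaded and an optional BH-threshold line drawn at the
    largest raw p with adjusted p below ``fdr_threshold``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [
        r for r in results if not r.skipped and r.position is not None and r.p is not None
    ]
    if not rows:
        raise ValueError(
            "no results with genomic positions; supply a map file assigning "
            "chromosome and position to predictors"
        )
    chroms: list[str] = []
    for r in rows:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    offset = 0
    xs, ys, colors = [], [], []
    bounds = []
    palette = ("#355f8d", "#c96f2a")
    for ci, chrom in enumerate(chroms):
        sub = sorted((r for r in rows if r.chrom == chrom), key=lambda r: r.position)
        span = max(r.position for r in sub)
        for r in sub:
            xs.append(offset + r.position)
            ys.append(-np.log10(max(r.p, 1e-300)))
            colors.append(palette[ci % 2])
        bounds.append((offset, offset + span, chrom))
        offset += span + max(span // 20, 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    for (lo, hi, chrom), ci in zip(bounds, range(len(bounds))):
        if ci % 2 == 1:
            ax.axvspan(lo, hi, color="0.93", zorder=0)
    ax.scatter(xs, ys, c=colors, s=8, zorder=2)
    ax.set_xticks([(lo + hi) / 2 for lo, hi, _ in bounds])
    ax.set_xticklabels([c for _, _, c in bounds])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if fdr_threshold is not None:
        p_raw = np.array([r.p for r in rows])
        adj = bh_fdr(p_raw)
        passing = p_raw[adj <= fdr_threshold]
        if passing.size:
            ax.axhline(-np.log10(passing.max()), color="red", lw=1, ls="--")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


# --------------------------------------------------------------------------
# results table
# --------------------------------------------------------------------------

RESULT_COLUMNS = (
    "response",
    "predictor",
    "chr",
    "position",
    "n",
    "beta",
    "se",
    "lrt",
    "p",
    "h2_null",
    "empirical_p",
    "n_perms",
    "pct_families_positive",
    "gini",
    "fdr_bh",
    "flags",
)


def write_results(results, path: str) -> None:
    """Write the scan results as a tab-delimited table (fixed column order,
    missing values as NA). BH-adjusted p-values are computed over the
    non-skipped tests."""
    tested = [r for r in results if not r.skipped and r.p is not None]
    adj = bh_fdr(np.array([r.p for r in tested])) if tested else np.empty(0)
    fdr_map = {id(r): q for r, q in zip(tested, adj)}

    def fmt(x, nd=6):
        if x is None:
            return "NA"
        if isinstance(x, float):
            return f"{x:.{nd}g}"
        return str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            diag = r.family_diag
            flags = list(r.flags)
            if r.skip_reason is not None:
                flags.append(f"skipped:{r.skip_reason}")
            fh.write(
                "\t".join(
                    [
                        r.response,
                        r.predictor,
                        fmt(r.chrom),
                        fmt(r.position),
                        str(r.n),
                        fmt(r.beta),
                        fmt(r.se_beta),
                        fmt(r.lrt),
                        fmt(r.p),
                        fmt(r.h2_null),
                        fmt(r.empirical_p),
                        fmt(r.n_permutations),
                        fmt(diag.pct_positive if diag else None),
                        fmt(diag.gini if diag else None),
                        fmt(fdr_map.get(id(r))),
                        ";".join(flags) if flags else "NA",
                    ]
                )
                + "\n"
            )
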