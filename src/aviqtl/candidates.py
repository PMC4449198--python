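"""Candidate quantitative-trait-gene prioritisation.

Two phases: (1) overlap trait-QTL support intervals with cis-eQTL support
intervals; (2) test the association between probeset expression and the
trait (body weight, and optionally egg production, as covariates), with a
Bonferroni correction by the number of uncorrelated cis-eQTL in the QTL
interval.  Interval merging used for genomic region counts lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Cross, ExpressionSet, GenomicInterval

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# interval calculus


def _check_units(intervals) -> str | None:
    units = {iv.unit for iv in intervals}
    if len(units) > 1:
        raise ValueError(f"mixed interval units: {sorted(units)}; convert first")
    return units.pop() if units else None


def overlap_pairs(
    qtl: list[GenomicInterval], eqtl: list[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All same-chromosome pairs with closed-interval overlap (touching
    endpoints count)."""
    _check_units(list(qtl) + list(eqtl))
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in eqtl:
        by_chrom.setdefault(e.chrom, []).append(e)
    out = []
    for q in qtl:
        for e in by_chrom.get(q.chrom, []):
            if q.start <= e.end and e.start <= q.end:
                out.append((q, e))
    return out


def merge_regions(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping-or-touching intervals into maximal disjoint regions
    per chromosome."""
    unit = _check_units(intervals)
    if not intervals:
        return []
    merged: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        labels = [ivs[0].label]
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # touching counts
                cur_end = max(cur_end, iv.end)
                labels.append(iv.label)
            else:
                merged.append(
                    GenomicInterval(chrom, cur_start, cur_end, unit, "qtl", ";".join(labels))
                )
                cur_start, cur_end, labels = iv.start, iv.end, [iv.label]
        merged.append(GenomicInterval(chrom, cur_start, cur_end, unit, "qtl", ";".join(labels)))
    return merged


# ---------------------------------------------------------------------------
# association testing


def association_test(
    cross: Cross,
    expr: ExpressionSet,
    trait: str,
    probeset: str,
    covariates: list[str] | None = None,
    min_cases: int = 10,
) -> tuple[float, float]:
    """Least-squares ``trait ~ expression + covariates``.

    Returns (two-sided p-value of the expression coefficient, coefficient).
    """
    covariates = covariates if covariates is not None else ["body_weight"]
    common = expr.individuals.intersection(cross.individuals)
    df = pd.DataFrame(
        {"y": cross.phenotypes[trait].reindex(common).astype(float),
         "expr": expr.matrix.loc[probeset].reindex(common).astype(float)}
    )
    source = pd.concat([cross.covariates, cross.phenotypes], axis=1)
    for c in covariates:
        df[c] = pd.to_numeric(source[c].reindex(common), errors="coerce")
    df = df.dropna()
    if len(df) < min_cases:
        raise ValueError(
            f"association test {trait} ~ {probeset}: only {len(df)} complete cases "
            f"(minimum {min_cases})"
        )
    D = np.column_stack(
        [np.ones(len(df)), df["expr"].to_numpy()] + [df[c].to_numpy() for c in covariates]
    )
    y = df["y"].to_numpy()
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    dof = len(df) - D.shape[1]
    rss = float(resid @ resid)
    if rss <= np.finfo(float).tiny * len(df):
        return float(np.finfo(float).tiny), float(beta[1])
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.pinv(D.T @ D)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), dof))
    p = max(p, float(np.finfo(float).tiny))
    return p, float(beta[1])


def count_uncorrelated(
    expr: ExpressionSet,
    probesets: list[str],
    alpha: float = 0.05,
    method: str = "components",
    individuals: pd.Index | None = None,
) -> int:
    """Number of uncorrelated cis-eQTL genes in an interval.

    Genes are linked when the pairwise correlation test has p <= ``alpha``;
    with ``method='components'`` (default) m is the number of connected
    components of the link graph; with ``method='isolated'`` m is the count
    of genes uncorrelated with every other gene (floored at 1).
    """
    if not probesets:
        raise ValueError("count_uncorrelated requires at least one probeset")
    ids = list(dict.fromkeys(probesets))
    k = len(ids)
    if k == 1:
        return 1
    cols = individuals if individuals is not None else expr.individuals
    M = expr.matrix.loc[ids, list(cols)].to_numpy(dtype=float)
    linked = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~(np.isnan(M[i]) | np.isnan(M[j]))
            if ok.sum() < 3:
                continue
            _, p = stats.pearsonr(M[i, ok], M[j, ok])
            if p <= alpha:
                linked[i, j] = linked[j, i] = True
    if method == "isolated":
        isolated = int((~linked.any(axis=1)).sum())
        return max(isolated, 1)
    # union-find over the link graph
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if linked[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(k)})


# ---------------------------------------------------------------------------
# candidate calling


@dataclass
class CandidateGene:
    trait: str
    probeset: str
    qtl: GenomicInterval
    eqtl: GenomicInterval
    eqtl_lod: float | None
    raw_p: float
    coefficient: float
    m: int
    adjusted_p: float
    passed: bool


def call_candidates(
    pairs: list[tuple[GenomicInterval, GenomicInterval]],
    cross: Cross,
    expr: ExpressionSet,
    alpha: float = 0.05,
    covariates_for_trait=None,
    corr_method: str = "components",
) -> list[CandidateGene]:
    """Association-filter overlapping (QTL, eQTL) pairs into candidates.

    ``covariates_for_trait`` maps a trait name to the covariate list of its
    association regression (default ``["body_weight"]``; add the egg column
    for QTL detected with the fecundity covariate).
    """
    covariates_for_trait = covariates_for_trait or {}
    # cis genes per QTL interval (for the Bonferroni denominator)
    genes_in_qtl: dict[int, list[str]] = {}
    for q, e in pairs:
        genes_in_qtl.setdefault(id(q), []).append(e.label)

    out: list[CandidateGene] = []
    for q, e in pairs:
        trait, probeset = q.label, e.label
        covs = covariates_for_trait.get(trait, ["body_weight"])
        try:
            raw_p, coef = association_test(cross, expr, trait, probeset, covariates=covs)
        except (KeyError, ValueError) as err:
            log.warning("candidate %s/%s skipped: %s", trait, probeset, err)
            continue
        m = count_uncorrelated(expr, genes_in_qtl[id(q)], method=corr_method)
        adj = min(1.0, raw_p * m)
        out.append(
            CandidateGene(
                trait=trait,
                probeset=probeset,
                qtl=q,
                eqtl=e,
                eqtl_lod=e.peak_lod,
                raw_p=raw_p,
                coefficient=coef,
                m=m,
                adjusted_p=adj,
                passed=bool(adj < alpha),
            )
        )
    out.sort(key=lambda c: (c.trait, _chrom_key(c.qtl.chrom), c.eqtl.start))
    return out


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def candidate_table(candidates: list[CandidateGene]) -> pd.DataFrame:
    """Output schema: trait, gene, chromosome, position, eQTL LOD, p-values."""
    rows = []
    for c in candidates:
        pos = 0.5 * (c.eqtl.start + c.eqtl.end)
        rows.append(
            {
                "trait": c.trait,
                "gene": c.probeset,
                "chromosome": c.qtl.chrom,
                "position_Mb" if c.eqtl.unit == "Mb" else "position_cM": round(pos),
                "eqtl_lod": c.eqtl_lod,
                "p_value": c.raw_p,
                "m": c.m,
                "p_adjusted": c.adjusted_p,
                "pass": c.passed,
            }
        )
    return pd.DataFrame(rows)
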