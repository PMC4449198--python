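"""Phenotype QTL scans: single- and two-locus Haley-Knott regression,
permutation thresholds, genotype-PCA covariates, the egg-covariate decision
rule, forward-selected multi-QTL models and LOD-drop support intervals."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._hk import check_full_rank, hk_scan_core, ols_rss
from .genoprob import GenoProbs
from .io_formats import Cross, GeneticMap, GenomicInterval

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# covariate handling


def build_covariate_matrix(
    cross: Cross,
    covariates: list[str],
    extra: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Numeric design block for the named covariates (plus intercept).

    Categorical columns (``sex``, ``batch`` or any non-numeric dtype) are
    dummy-coded dropping the first level.  Returns (matrix, column names,
    complete-row mask); rows with any missing covariate are masked out.
    """
    frames = [pd.Series(1.0, index=cross.individuals, name="intercept")]
    source = pd.concat([cross.covariates, cross.phenotypes], axis=1)
    if extra is not None:
        source = pd.concat([source, extra], axis=1)
        covariates = list(covariates) + [c for c in extra.columns if c not in covariates]
    for name in covariates:
        if name not in source.columns:
            raise KeyError(f"covariate {name!r} not found")
        col = source[name]
        if col.dtype == object or name in {"sex", "batch"}:
            dummies = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True)
            dummies = dummies.astype(float)
            # preserve missingness: rows that were NaN become NaN in dummies
            dummies[col.isna()] = np.nan
            frames.append(dummies)
        else:
            frames.append(col.astype(float))
    design = pd.concat(frames, axis=1)
    mask = ~design.isna().any(axis=1)
    return design.to_numpy(dtype=float), list(design.columns), mask.to_numpy()


def _prepare(
    probs: GenoProbs,
    cross: Cross,
    trait: str,
    covariates: list[str],
    extra_covar: pd.DataFrame | None = None,
):
    if trait not in cross.phenotypes.columns:
        raise KeyError(f"trait {trait!r} not found")
    y_all = cross.phenotypes[trait].to_numpy(dtype=float)
    C_all, names, cov_ok = build_covariate_matrix(cross, covariates, extra=extra_covar)
    keep = cov_ok & ~np.isnan(y_all)
    y = y_all[keep]
    if len(y) == 0:
        raise ValueError(f"no complete cases for trait {trait!r}")
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait!r} is constant on the retained individuals")
    C = C_all[keep]
    check_full_rank(C, names)
    X = probs.x[keep]
    Z = probs.z[keep]
    return y, C, names, X, Z, keep


@dataclass
class ScanResult:
    """Genome scan of one response: LOD per evaluated position."""

    response: str
    table: pd.DataFrame  # chrom, pos_cM, name, is_marker, lod
    covariate_names: list[str]
    n_used: int
    perfect: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self) -> tuple[str, float]:
        """Genome-wide peak; ties broken toward the lowest position."""
        lod = self.lod
        i = int(np.flatnonzero(lod == lod.max())[0])
        row = self.table.iloc[i]
        return str(row["chrom"]), float(row["pos_cM"])


def scanone(
    probs: GenoProbs,
    cross: Cross,
    trait: str,
    covariates: list[str] | None = None,
    extra_covar: pd.DataFrame | None = None,
) -> ScanResult:
    """Single-locus Haley-Knott scan of ``trait`` with listwise deletion.

    At each position the model ``trait ~ covariates + x + z`` is compared to
    the covariates-only null: LOD = (n/2) log10(RSS0/RSS1).
    """
    covariates = covariates or []
    y, C, names, X, Z, keep = _prepare(probs, cross, trait, covariates, extra_covar)
    lod, perfect = hk_scan_core(y[:, None], C, X, Z)
    table = probs.positions.copy()
    table["lod"] = lod[0]
    if perfect[0].any():
        log.warning("trait %s: perfect fit capped at %d position(s)", trait, perfect[0].sum())
    return ScanResult(trait, table, names, int(keep.sum()), perfect[0])


@dataclass
class PairScanResult:
    """Two-locus scan: full, additive and interaction LOD per locus pair."""

    response: str
    table: pd.DataFrame  # chrom1, pos1, chrom2, pos2, lod_full, lod_add, lod_int
    covariate_names: list[str]
    n_used: int

    def max_int(self) -> tuple[float, pd.Series]:
        i = int(self.table["lod_int"].idxmax())
        return float(self.table.loc[i, "lod_int"]), self.table.loc[i]


def _pair_designs(C, x1, z1, x2, z2):
    add = np.column_stack([C, x1, z1, x2, z2])
    full = np.column_stack([add, x1 * x2, x1 * z2, z1 * x2, z1 * z2])
    return add, full


def scantwo(
    probs: GenoProbs,
    cross: Cross,
    trait: str,
    covariates: list[str] | None = None,
    position_step: int = 1,
) -> PairScanResult:
    """Exhaustive two-locus scan over the position grid.

    ``position_step`` thins the grid (every k-th position) to bound the
    quadratic cost.  Same-position pairs are excluded.
    """
    covariates = covariates or []
    y, C, names, X, Z, keep = _prepare(probs, cross, trait, covariates)
    n = len(y)
    idx = np.arange(0, probs.n_positions, position_step)
    pos_tab = probs.positions.iloc[idx].reset_index(drop=True)
    rss0 = ols_rss(y, C)
    rows = []
    for ai in range(len(idx)):
        for bi in range(ai + 1, len(idx)):
            ja, jb = idx[ai], idx[bi]
            add, full = _pair_designs(C, X[:, ja], Z[:, ja], X[:, jb], Z[:, jb])
            rss_add = ols_rss(y, add)
            rss_full = ols_rss(y, full)
            rss_full = max(rss_full, rss0 * 1e-16)
            rss_add = max(rss_add, rss0 * 1e-16)
            lod_full = (n / 2.0) * np.log10(rss0 / rss_full)
            lod_add = (n / 2.0) * np.log10(rss0 / rss_add)
            rows.append(
                (
                    pos_tab["chrom"].iloc[ai],
                    pos_tab["pos_cM"].iloc[ai],
                    pos_tab["chrom"].iloc[bi],
                    pos_tab["pos_cM"].iloc[bi],
                    lod_full,
                    lod_add,
                    lod_full - lod_add,
                )
            )
    table = pd.DataFrame(
        rows, columns=["chrom1", "pos1", "chrom2", "pos2", "lod_full", "lod_add", "lod_int"]
    )
    return PairScanResult(trait, table, names, n)


# ---------------------------------------------------------------------------
# permutation thresholds


def permutation_maxima(
    probs: GenoProbs,
    cross: Cross,
    trait: str,
    covariates: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Genome-wide max LOD for each permutation.

    Trait and covariates are shuffled as a block against the genotypes,
    preserving both the trait-covariate structure and genotype LD.
    """
    covariates = covariates or []
    y, C, names, X, Z, keep = _prepare(probs, cross, trait, covariates)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(y)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n)
        lod, _ = hk_scan_core(y[idx][:, None], C[idx], X, Z)
        maxima[b] = lod.max()
    return maxima


def permutation_threshold(
    probs: GenoProbs,
    cross: Cross,
    trait: str,
    covariates: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical (1 - alpha) quantile of the permutation max-LOD distribution."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    maxima = permutation_maxima(probs, cross, trait, covariates, n_perm, seed)
    return float(np.quantile(maxima, 1.0 - alpha))


def scantwo_permutation_maxima(
    probs: GenoProbs,
    cross: Cross,
    trait: str,
    covariates: list[str] | None = None,
    n_perm: int = 250,
    position_step: int = 2,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Max interaction LOD per permutation (for the epistasis threshold)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covariates = covariates or []
    y, C, names, X, Z, keep = _prepare(probs, cross, trait, covariates)
    n = len(y)
    idx_pos = np.arange(0, probs.n_positions, position_step)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        yp, Cp = y[perm], C[perm]
        best = 0.0
        for ai in range(len(idx_pos)):
            for bi in range(ai + 1, len(idx_pos)):
                ja, jb = idx_pos[ai], idx_pos[bi]
                add, full = _pair_designs(Cp, X[:, ja], Z[:, ja], X[:, jb], Z[:, jb])
                rss_add = ols_rss(yp, add)
                rss_full = max(ols_rss(yp, full), 1e-300)
                li = (n / 2.0) * np.log10(max(rss_add, 1e-300) / rss_full)
                best = max(best, li)
        maxima[b] = best
    return maxima


# ---------------------------------------------------------------------------
# covariate construction rules


def pca_covariates(cross: Cross, k: int) -> pd.DataFrame:
    """First ``k`` genotype principal-component scores as covariates.

    Genotypes are coded -1/0/1 and mean-imputed per marker before the PCA.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return pd.DataFrame(index=cross.individuals)
    if k >= cross.n_individuals:
        raise ValueError(f"k = {k} must be < number of individuals ({cross.n_individuals})")
    from sklearn.decomposition import PCA

    G = cross.geno.to_numpy(dtype=float) - 1.0
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    G = np.where(np.isnan(G), col_mean[None, :], G)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(G)
    return pd.DataFrame(
        scores, index=cross.individuals, columns=[f"PC{i + 1}" for i in range(k)]
    )


def default_n_pcs(cross: Cross, min_var_frac: float = 0.01, cap: int = 10) -> int:
    """Heuristic PC count: components explaining > ``min_var_frac`` of variance."""
    from sklearn.decomposition import PCA

    G = cross.geno.to_numpy(dtype=float) - 1.0
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    G = np.where(np.isnan(G), col_mean[None, :], G)
    pca = PCA(n_components=min(cap, min(G.shape) - 1), svd_solver="full").fit(G)
    return int(np.sum(pca.explained_variance_ratio_ > min_var_frac))


@dataclass
class EggCovariateDecision:
    include: bool
    pvalue: float
    covariates: list[str]


def select_egg_covariate(
    cross: Cross,
    trait: str,
    egg_column: str = "eggs",
    alpha: float = 0.05,
    adjust_body_weight: bool = True,
) -> EggCovariateDecision:
    """Decide whether the egg-production covariate enters the model for a
    female trait: include it iff trait ~ eggs shows p < ``alpha``."""
    sexes = set(cross.covariates["sex"].dropna())
    if sexes - {"F"}:
        raise ValueError("egg covariate decision applies to female-only subsets")
    if egg_column not in cross.covariates.columns:
        raise KeyError(f"egg column {egg_column!r} not present")
    y = cross.phenotypes[trait].astype(float)
    eggs = cross.covariates[egg_column].astype(float)
    frames = {"eggs": eggs}
    if adjust_body_weight and "body_weight" in cross.covariates.columns:
        frames["body_weight"] = cross.covariates["body_weight"].astype(float)
    df = pd.DataFrame(frames)
    df["y"] = y
    df = df.dropna()
    if df["eggs"].count() == 0 or len(df) < 3:
        log.warning("egg covariate skipped for %s: no usable egg records", trait)
        return EggCovariateDecision(False, float("nan"), [])
    D = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in frames])
    yv = df["y"].to_numpy()
    beta, _, _, _ = np.linalg.lstsq(D, yv, rcond=None)
    resid = yv - D @ beta
    dof = len(df) - D.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(D.T @ D)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * stats.t.sf(abs(t), dof)
    include = bool(p < alpha)
    log.info("egg covariate for %s: p = %.4g -> %s", trait, p, "included" if include else "omitted")
    return EggCovariateDecision(include, float(p), [egg_column] if include else [])


# ---------------------------------------------------------------------------
# multi-QTL forward selection


@dataclass
class QtlModel:
    """Fitted multi-QTL model with variance decomposition."""

    trait: str
    loci: list[dict]  # chrom, pos_cM, name, a, d, pve
    pairs: list[dict]  # idx1, idx2, lod_int, pve
    covariate_names: list[str]
    lod: float
    pve: float
    n_used: int

    def refit(self, probs: GenoProbs, cross: Cross, covariates: list[str]) -> float:
        """Recompute the model LOD on the stated data (reproducibility check)."""
        fitted = _fit_model(probs, cross, self.trait, covariates, self.loci, self.pairs)
        return fitted["lod"]


def _position_index(probs: GenoProbs, chrom: str, pos: float) -> int:
    tab = probs.positions
    hits = np.flatnonzero(
        (tab["chrom"].to_numpy() == chrom) & np.isclose(tab["pos_cM"].to_numpy(), pos)
    )
    if len(hits) == 0:
        raise KeyError(f"position {chrom}:{pos} not on the scan grid")
    return int(hits[0])


def _fit_model(probs, cross, trait, covariates, loci, pairs):
    y, C, names, X, Z, keep = _prepare(probs, cross, trait, covariates or [])
    n = len(y)
    cols = [C]
    for q in loci:
        j = _position_index(probs, q["chrom"], q["pos_cM"])
        cols.append(np.column_stack([X[:, j], Z[:, j]]))
    for pr in pairs:
        j1 = _position_index(probs, loci[pr["idx1"]]["chrom"], loci[pr["idx1"]]["pos_cM"])
        j2 = _position_index(probs, loci[pr["idx2"]]["chrom"], loci[pr["idx2"]]["pos_cM"])
        cols.append(
            np.column_stack(
                [
                    X[:, j1] * X[:, j2],
                    X[:, j1] * Z[:, j2],
                    Z[:, j1] * X[:, j2],
                    Z[:, j1] * Z[:, j2],
                ]
            )
        )
    D = np.column_stack(cols)
    rss0 = ols_rss(y, C)
    rss1 = max(ols_rss(y, D), rss0 * 1e-16)
    tss = float(np.sum((y - y.mean()) ** 2))
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    r2_full = 1 - rss1 / tss
    r2_cov = 1 - rss0 / tss
    # per-term variance: R^2 drop when the term is removed
    term_pve = []
    c0 = C.shape[1]
    widths = [2] * len(loci) + [4] * len(pairs)
    offs = np.cumsum([c0] + widths)
    for t in range(len(widths)):
        keep_cols = np.ones(D.shape[1], bool)
        keep_cols[offs[t] : offs[t] + widths[t]] = False
        rss_wo = ols_rss(y, D[:, keep_cols])
        term_pve.append(100.0 * (rss_wo - rss1) / tss)
    # effect estimates from the full design
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    return {
        "lod": float(lod),
        "pve": float(100.0 * (r2_full - r2_cov)),
        "term_pve": term_pve,
        "beta": beta,
        "c0": c0,
        "n": n,
    }


def forward_select(
    probs: GenoProbs,
    cross: Cross,
    trait: str,
    covariates: list[str] | None = None,
    threshold: float = 3.5,
    pair_threshold: float | None = None,
    max_qtl: int = 10,
) -> QtlModel:
    """Forward selection of a multi-QTL model.

    Repeatedly adds the position with the highest conditional LOD (given the
    loci already in the model as covariates) while it exceeds ``threshold``;
    afterwards tests every pair of selected loci for interaction and keeps
    pairs whose interaction LOD exceeds ``pair_threshold``.
    """
    covariates = covariates or []
    loci: list[dict] = []
    while len(loci) < max_qtl:
        extra = _loci_covariates(probs, cross, loci)
        scan = scanone(probs, cross, trait, covariates, extra_covar=extra)
        best = scan.max_lod()
        if best < threshold:
            break
        chrom, pos = scan.peak()
        name = scan.table.iloc[int(np.flatnonzero(scan.lod == best)[0])]["name"]
        loci.append({"chrom": chrom, "pos_cM": float(pos), "name": str(name)})
        log.info("forward_select %s: added %s:%.1f (conditional LOD %.2f)", trait, chrom, pos, best)

    pairs: list[dict] = []
    if pair_threshold is not None and len(loci) >= 2:
        y, C, names, X, Z, keep = _prepare(probs, cross, trait, covariates)
        n = len(y)
        base_cols = [C] + [
            np.column_stack(
                [X[:, _position_index(probs, q["chrom"], q["pos_cM"])],
                 Z[:, _position_index(probs, q["chrom"], q["pos_cM"])]]
            )
            for q in loci
        ]
        D_add = np.column_stack(base_cols)
        rss_add = ols_rss(y, D_add)
        for i1 in range(len(loci)):
            for i2 in range(i1 + 1, len(loci)):
                j1 = _position_index(probs, loci[i1]["chrom"], loci[i1]["pos_cM"])
                j2 = _position_index(probs, loci[i2]["chrom"], loci[i2]["pos_cM"])
                inter = np.column_stack(
                    [X[:, j1] * X[:, j2], X[:, j1] * Z[:, j2], Z[:, j1] * X[:, j2], Z[:, j1] * Z[:, j2]]
                )
                rss_full = max(ols_rss(y, np.column_stack([D_add, inter])), 1e-300)
                lod_int = (n / 2.0) * np.log10(max(rss_add, 1e-300) / rss_full)
                if lod_int > pair_threshold:
                    pairs.append({"idx1": i1, "idx2": i2, "lod_int": float(lod_int)})
                    log.info(
                        "forward_select %s: epistatic pair %d-%d (LOD_int %.2f)",
                        trait, i1, i2, lod_int,
                    )

    fit = _fit_model(probs, cross, trait, covariates, loci, pairs)
    beta, c0 = fit["beta"], fit["c0"]
    for t, q in enumerate(loci):
        q["a"] = float(beta[c0 + 2 * t])
        q["d"] = float(beta[c0 + 2 * t + 1])
        q["pve"] = fit["term_pve"][t]
    for t, pr in enumerate(pairs):
        pr["pve"] = fit["term_pve"][len(loci) + t]
    y_used = fit["n"]
    return QtlModel(
        trait=trait,
        loci=loci,
        pairs=pairs,
        covariate_names=covariates,
        lod=fit["lod"],
        pve=fit["pve"],
        n_used=y_used,
    )


def _loci_covariates(probs: GenoProbs, cross: Cross, loci: list[dict]) -> pd.DataFrame | None:
    if not loci:
        return None
    cols = {}
    for t, q in enumerate(loci):
        j = _position_index(probs, q["chrom"], q["pos_cM"])
        cols[f"qtl{t}_x"] = probs.x[:, j]
        cols[f"qtl{t}_z"] = probs.z[:, j]
    return pd.DataFrame(cols, index=cross.individuals)


# ---------------------------------------------------------------------------
# support intervals


@dataclass
class SupportInterval:
    """LOD-drop support interval around a scan peak (cM coordinates)."""

    interval: GenomicInterval
    drop: float
    peak_pos: float
    peak_lod: float
    expanded_to_markers: bool
    truncated_left: bool = False
    truncated_right: bool = False
    degenerate: bool = False


def lod_support_interval(
    scan: ScanResult,
    gmap: GeneticMap,
    peak: tuple[str, float] | None = None,
    drop: float = 1.8,
    expand_to_markers: bool = True,
    source_kind: str = "qtl",
) -> SupportInterval:
    """Support interval: smallest contiguous run around the peak with
    LOD >= peak - drop, expanded outward to the closest flanking markers."""
    if peak is None:
        peak = scan.peak()
    chrom, peak_pos = peak
    tab = scan.table[scan.table["chrom"] == chrom].reset_index(drop=True)
    if len(tab) == 0:
        raise KeyError(f"chromosome {chrom!r} not in scan")
    pos = tab["pos_cM"].to_numpy()
    lod = tab["lod"].to_numpy()
    pk = int(np.argmin(np.abs(pos - peak_pos)))
    peak_lod = float(lod[pk])
    cut = peak_lod - drop
    lo = pk
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = pk
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    left, right = float(pos[lo]), float(pos[hi])
    degenerate = lo == 0 and hi == len(lod) - 1 and np.ptp(lod) < 1e-12

    # truncated: the LOD never dropped below the cut before the chromosome end
    truncated_left = lo == 0
    truncated_right = hi == len(lod) - 1
    if expand_to_markers:
        mpos = gmap.chrom_table(chrom)["pos_cM"].to_numpy(dtype=float)
        lower = mpos[mpos <= left + 1e-9]
        upper = mpos[mpos >= right - 1e-9]
        if len(lower):
            left = float(lower.max())
        if len(upper):
            right = float(upper.min())

    iv = GenomicInterval(
        chrom=chrom,
        start=left,
        end=right,
        unit="cM",
        source_kind=source_kind,
        label=scan.response,
        peak_lod=peak_lod,
    )
    return SupportInterval(
        interval=iv,
        drop=drop,
        peak_pos=float(pos[pk]),
        peak_lod=peak_lod,
        expanded_to_markers=expand_to_markers,
        truncated_left=truncated_left,
        truncated_right=truncated_right,
        degenerate=bool(degenerate),
    )
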