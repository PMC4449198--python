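"""Expression QTL mapping.

Local (cis) eQTL are mapped inside a 100 cM window centred on the probe
position, expanded to the closest flanking markers spanning at least 50 cM
in each direction; distal (trans) eQTL are mapped genome-wide outside that
window against a higher threshold.  Both thresholds come from a permutation
scheme that resamples individual identities and subsamples probesets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._hk import hk_scan_core
from .genoprob import GenoProbs
from .io_formats import Cross, ExpressionSet, GeneticMap, GenomicInterval
from .scan import ScanResult, lod_support_interval

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coordinate conversion


def coordinate_convert(
    value: float | np.ndarray,
    gmap: GeneticMap,
    chrom: str,
    direction: str,
) -> float | np.ndarray:
    """Piecewise-linear cM<->Mb conversion through the anchor markers.

    Beyond the terminal anchors the nearest segment's slope is extrapolated.
    Requires >= 2 markers with both coordinates on the chromosome.
    """
    if direction not in {"cM->Mb", "Mb->cM"}:
        raise ValueError("direction must be 'cM->Mb' or 'Mb->cM'")
    tab = gmap.chrom_table(str(chrom))
    if "pos_Mb" not in tab.columns:
        raise ValueError(f"chromosome {chrom}: no physical positions on the map")
    tab = tab.dropna(subset=["pos_Mb"])
    if len(tab) < 2:
        raise ValueError(f"chromosome {chrom}: need >= 2 anchor markers, have {len(tab)}")
    cm = tab["pos_cM"].to_numpy(dtype=float)
    mb = tab["pos_Mb"].to_numpy(dtype=float)
    src, dst = (cm, mb) if direction == "cM->Mb" else (mb, cm)
    # collapse duplicate source coordinates (flat segments are not invertible)
    src, uniq = np.unique(src, return_index=True)
    dst = dst[uniq]
    v = np.asarray(value, dtype=float)
    out = np.interp(v, src, dst)
    # linear extrapolation with the terminal segment slopes
    lo_slope = (dst[1] - dst[0]) / (src[1] - src[0])
    hi_slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
    out = np.where(v < src[0], dst[0] + (v - src[0]) * lo_slope, out)
    out = np.where(v > src[-1], dst[-1] + (v - src[-1]) * hi_slope, out)
    return float(out) if np.isscalar(value) or np.ndim(value) == 0 else out


def convert_interval(iv: GenomicInterval, gmap: GeneticMap, to_unit: str) -> GenomicInterval:
    """Convert an interval between cM and Mb through the anchor markers."""
    if iv.unit == to_unit:
        return iv
    direction = "cM->Mb" if to_unit == "Mb" else "Mb->cM"
    start = coordinate_convert(iv.start, gmap, iv.chrom, direction)
    end = coordinate_convert(iv.end, gmap, iv.chrom, direction)
    lo, hi = (start, end) if start <= end else (end, start)
    return GenomicInterval(iv.chrom, lo, hi, to_unit, iv.source_kind, iv.label, iv.peak_lod)


# ---------------------------------------------------------------------------
# local windows


@dataclass
class LocalWindow:
    """Cis-test window around a probe position."""

    probeset: str
    chrom: str
    start: float
    end: float
    truncated_start: bool = False
    truncated_end: bool = False

    def contains(self, chrom: str, pos_cM: float) -> bool:
        return chrom == self.chrom and self.start <= pos_cM <= self.end


def build_local_window(
    probeset: str,
    chrom: str,
    pos_cM: float,
    gmap: GeneticMap,
    half_width_cM: float = 50.0,
) -> LocalWindow | None:
    """Window [pos-50, pos+50] cM expanded outward to the closest markers at
    distance >= 50 cM; truncated (and flagged) at chromosome ends."""
    chrom = str(chrom)
    if chrom not in gmap.chromosomes:
        log.info("probeset %s: chromosome %s not on the map; no window", probeset, chrom)
        return None
    mpos = gmap.chrom_table(chrom)["pos_cM"].to_numpy(dtype=float)
    lo_target = pos_cM - half_width_cM
    hi_target = pos_cM + half_width_cM
    below = mpos[mpos <= lo_target + 1e-9]
    above = mpos[mpos >= hi_target - 1e-9]
    truncated_start = len(below) == 0
    truncated_end = len(above) == 0
    start = float(below.max()) if len(below) else 0.0
    end = float(above.min()) if len(above) else float(mpos.max())
    return LocalWindow(probeset, chrom, start, end, truncated_start, truncated_end)


def probe_window(
    probeset: str, expr: ExpressionSet, gmap: GeneticMap, half_width_cM: float = 50.0
) -> LocalWindow | None:
    """Window from the annotation table, deriving cM from Mb when needed."""
    if probeset not in expr.annotation.index:
        return None
    ann = expr.annotation.loc[probeset]
    chrom = str(ann["chrom"])
    if "pos_cM" in expr.annotation.columns and pd.notna(ann.get("pos_cM")):
        pos_cm = float(ann["pos_cM"])
    else:
        if chrom not in gmap.chromosomes:
            return None
        pos_cm = float(coordinate_convert(float(ann["pos_Mb"]), gmap, chrom, "Mb->cM"))
    return build_local_window(probeset, chrom, pos_cm, gmap, half_width_cM)


# ---------------------------------------------------------------------------
# scanning


@dataclass
class EqtlRecord:
    probeset: str
    kind: str  # cis | trans
    chrom: str
    pos_cM: float
    lod: float
    interval: GenomicInterval


def _align(cross: Cross, expr: ExpressionSet) -> tuple[pd.Index, np.ndarray]:
    common = expr.individuals.intersection(cross.individuals)
    if len(common) == 0:
        raise ValueError("no shared individuals between expression set and cross")
    Y = expr.matrix[list(common)].to_numpy(dtype=float).T  # n x q
    return pd.Index(common), Y


def _expr_lod_matrix(probs: GenoProbs, cross: Cross, expr: ExpressionSet) -> tuple[np.ndarray, pd.Index]:
    """LOD for every probeset x position (intercept-only model)."""
    common, Y = _align(cross, expr)
    row_idx = [cross.individuals.get_loc(i) for i in common]
    X = probs.x[row_idx]
    Z = probs.z[row_idx]
    C = np.ones((len(common), 1))
    lod, _ = hk_scan_core(Y, C, X, Z)
    return lod, common


def _window_mask(probs: GenoProbs, window: LocalWindow | None) -> np.ndarray:
    """Boolean per position: inside the probe's local window."""
    if window is None:
        return np.zeros(probs.n_positions, dtype=bool)
    chrom = probs.positions["chrom"].to_numpy()
    pos = probs.positions["pos_cM"].to_numpy()
    return (chrom == window.chrom) & (pos >= window.start - 1e-9) & (pos <= window.end + 1e-9)


def eqtl_scan(
    probs: GenoProbs,
    cross: Cross,
    expr: ExpressionSet,
    cis_threshold: float,
    trans_threshold: float,
    half_width_cM: float = 50.0,
    drop: float = 1.8,
) -> list[EqtlRecord]:
    """Scan every probeset and classify significant peaks.

    A probeset gets a cis record when its LOD passes ``cis_threshold`` at
    any position inside its local window, and a trans record when it passes
    ``trans_threshold`` at a peak outside the window (best peak per
    chromosome).  Intervals are 1.8-LOD-drop, expanded to closest markers.
    """
    lod_mat, common = _expr_lod_matrix(probs, cross, expr)
    records: list[EqtlRecord] = []
    positions = probs.positions
    chrom_arr = positions["chrom"].to_numpy()
    pos_arr = positions["pos_cM"].to_numpy()

    for qi, probeset in enumerate(expr.probesets):
        lod = lod_mat[qi]
        window = probe_window(probeset, expr, cross.gmap, half_width_cM)
        if window is None:
            log.info("probeset %s has no mappable annotation; trans-only scan", probeset)
        inside = _window_mask(probs, window)

        scan = ScanResult(
            response=str(probeset),
            table=positions.assign(lod=lod),
            covariate_names=["intercept"],
            n_used=len(common),
        )

        if window is not None and inside.any():
            li = lod.copy()
            li[~inside] = -np.inf
            if li.max() >= cis_threshold:
                j = int(np.flatnonzero(li == li.max())[0])
                si = lod_support_interval(
                    scan, cross.gmap, peak=(str(chrom_arr[j]), float(pos_arr[j])),
                    drop=drop, source_kind="eqtl",
                )
                records.append(
                    EqtlRecord(
                        probeset=str(probeset), kind="cis", chrom=str(chrom_arr[j]),
                        pos_cM=float(pos_arr[j]), lod=float(lod[j]), interval=si.interval,
                    )
                )

        out = lod.copy()
        out[inside] = -np.inf
        for chrom in dict.fromkeys(chrom_arr):
            sel = chrom_arr == chrom
            if not np.any(out[sel] >= trans_threshold):
                continue
            local = np.where(sel, out, -np.inf)
            j = int(np.flatnonzero(local == local.max())[0])
            si = lod_support_interval(
                scan, cross.gmap, peak=(str(chrom), float(pos_arr[j])),
                drop=drop, source_kind="eqtl",
            )
            records.append(
                EqtlRecord(
                    probeset=str(probeset), kind="trans", chrom=str(chrom),
                    pos_cM=float(pos_arr[j]), lod=float(lod[j]), interval=si.interval,
                )
            )
    return records


def eqtl_permutation_threshold(
    probs: GenoProbs,
    cross: Cross,
    expr: ExpressionSet,
    scope: str,
    n_iter: int = 1000,
    n_subsample: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    half_width_cM: float = 50.0,
    return_maxima: bool = False,
):
    """Permutation threshold for cis or trans eQTL calls.

    Each iteration permutes the expression-to-genotype individual mapping,
    draws ``n_subsample`` probesets without replacement, scans each (within
    its window for scope='cis', genome-wide for scope='trans') and saves the
    maximum LOD over the subsample; the (1 - alpha) percentile over
    iterations is the threshold.
    """
    if scope not in {"cis", "trans"}:
        raise ValueError("scope must be 'cis' or 'trans'")
    if n_subsample > len(expr.probesets):
        raise ValueError(
            f"n_subsample ({n_subsample}) exceeds probeset count ({len(expr.probesets)})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    common, Y = _align(cross, expr)
    row_idx = [cross.individuals.get_loc(i) for i in common]
    X = probs.x[row_idx]
    Z = probs.z[row_idx]
    C = np.ones((len(common), 1))

    masks = None
    if scope == "cis":
        masks = np.zeros((len(expr.probesets), probs.n_positions), dtype=bool)
        for qi, probeset in enumerate(expr.probesets):
            w = probe_window(probeset, expr, cross.gmap, half_width_cM)
            masks[qi] = _window_mask(probs, w)

    n = len(common)
    maxima = np.empty(n_iter)
    for b in range(n_iter):
        perm = rng.permutation(n)
        sub = rng.choice(len(expr.probesets), size=n_subsample, replace=False)
        lod, _ = hk_scan_core(Y[perm][:, sub], C, X, Z)
        if scope == "cis":
            msk = masks[sub]
            vals = np.where(msk, lod, -np.inf)
            per_probe = vals.max(axis=1)
            per_probe = per_probe[np.isfinite(per_probe)]
            maxima[b] = per_probe.max() if len(per_probe) else 0.0
        else:
            maxima[b] = lod.max()
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    if return_maxima:
        return threshold, maxima
    return threshold


def eqtl_table(records: list[EqtlRecord], gmap: GeneticMap) -> pd.DataFrame:
    """Flat output table with interval bounds in both cM and Mb."""
    rows = []
    for r in records:
        try:
            mb = convert_interval(r.interval, gmap, "Mb")
            start_mb, end_mb = mb.start, mb.end
        except ValueError:
            start_mb = end_mb = np.nan
        rows.append(
            {
                "probeset": r.probeset,
                "kind": r.kind,
                "chromosome": r.chrom,
                "peak_cM": r.pos_cM,
                "lod": r.lod,
                "start_cM": r.interval.start,
                "end_cM": r.interval.end,
                "start_Mb": start_mb,
                "end_Mb": end_mb,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probeset", "kind", "chromosome", "peak_cM", "lod",
            "start_cM", "end_cM", "start_Mb", "end_Mb",
        ],
    )
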