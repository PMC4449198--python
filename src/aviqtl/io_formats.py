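"""Readers and writers for cross, expression, annotation and interval tables.

The cross format is the rotated-header CSV dialect used by R/qtl: the first
row holds column names (phenotypes and covariates first, then markers), the
second row the chromosome of each marker column (blank for non-genotype
columns), the third row the genetic position in cM, and each subsequent row
one individual.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: numeric genotype codes used throughout the package
GENO_AA, GENO_AB, GENO_BB = 0.0, 1.0, 2.0

DEFAULT_GENO_CODES: Mapping[str, float] = {"A": GENO_AA, "H": GENO_AB, "B": GENO_BB}
DEFAULT_MISSING_CODES = ("", "-", "NA", "na")

#: covariate columns recognised when splitting a cross phenotype block
DEFAULT_COVARIATE_COLUMNS = ("sex", "batch", "body_weight", "eggs")


class MapOrderError(ValueError):
    """Raised when marker positions violate map monotonicity."""


class GenotypeCodeError(ValueError):
    """Raised when a genotype cell holds an unrecognised code."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map.

    ``table`` has columns ``marker``, ``chrom``, ``pos_cM`` and optionally
    ``pos_Mb``; rows are ordered by chromosome then position.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "pos_cM"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker ids: {dups}")
        if (t["pos_cM"] < 0).any():
            raise ValueError("negative cM positions in map")
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cM"].to_numpy()
            # coincident markers are tolerated (r = 0); decreases are not
            if np.any(np.diff(pos) < 0):
                i = int(np.argmax(np.diff(pos) < 0))
                raise MapOrderError(
                    f"chromosome {chrom}: marker {sub['marker'].iloc[i + 1]!r} at "
                    f"{pos[i + 1]} cM does not increase past "
                    f"{sub['marker'].iloc[i]!r} at {pos[i]} cM"
                )
            if "pos_Mb" in sub.columns:
                mb = sub["pos_Mb"].to_numpy(dtype=float)
                ok = ~np.isnan(mb)
                if ok.sum() >= 2 and np.any(np.diff(mb[ok]) < 0):
                    raise MapOrderError(
                        f"chromosome {chrom}: physical positions decrease with "
                        "genetic position"
                    )

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"].to_numpy(), name="marker")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def chrom_length(self, chrom: str) -> float:
        return float(self.chrom_table(chrom)["pos_cM"].max())

    def expand(self, factor: float) -> "GeneticMap":
        """Multiply all genetic positions by ``factor`` (map expansion)."""
        if factor < 1:
            raise ValueError("expansion factor must be >= 1")
        t = self.table.copy()
        t["pos_cM"] = t["pos_cM"] * factor
        return GeneticMap(t)


@dataclass
class Cross:
    """Genotypes, phenotypes and covariates for one mapping population.

    ``geno`` is an individuals x markers frame of numeric codes
    (0 = AA, 1 = AB, 2 = BB, NaN = missing) whose column order matches the
    map.  ``phenotypes`` and ``covariates`` share the genotype row index.
    """

    gmap: GeneticMap
    geno: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.geno.columns) != list(self.gmap.markers):
            raise ValueError("genotype columns do not match map marker order")
        self.geno.columns = pd.Index(list(self.geno.columns), name="marker")
        for name, frame in (("phenotypes", self.phenotypes), ("covariates", self.covariates)):
            if not frame.index.equals(self.geno.index):
                raise ValueError(f"{name} rows not keyed to genotype rows")
        vals = self.geno.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, [GENO_AA, GENO_AB, GENO_BB]))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise GenotypeCodeError(
                f"invalid genotype code {vals[i, j]!r} for individual "
                f"{self.geno.index[i]!r} at marker {self.geno.columns[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.geno)

    @property
    def individuals(self) -> pd.Index:
        return self.geno.index

    def subset(self, individuals: Sequence) -> "Cross":
        idx = pd.Index(individuals)
        return Cross(
            self.gmap,
            self.geno.loc[idx],
            self.phenotypes.loc[idx],
            self.covariates.loc[idx],
        )

    def subset_sex(self, sex: str) -> "Cross":
        if sex not in {"F", "M"}:
            raise ValueError("sex filter must be 'F' or 'M'")
        keep = self.covariates.index[self.covariates["sex"] == sex]
        return self.subset(keep)


@dataclass
class ExpressionSet:
    """Probesets x individuals expression matrix with probe annotation.

    ``annotation`` is indexed by probeset id with columns ``chrom``,
    ``pos_Mb`` and optionally ``pos_cM``; probesets without annotation are
    permitted (they can only be scanned genome-wide).
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.annotation.index.name is None:
            self.annotation.index.name = "probeset"

    @property
    def probesets(self) -> pd.Index:
        return self.matrix.index

    @property
    def individuals(self) -> pd.Index:
        return self.matrix.columns

    def values_for(self, probeset: str, individuals: Sequence) -> np.ndarray:
        return self.matrix.loc[probeset, list(individuals)].to_numpy(dtype=float)


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome interval in an explicit coordinate unit."""

    chrom: str
    start: float
    end: float
    unit: str  # "cM" or "Mb"
    source_kind: str = "qtl"  # qtl | eqtl | f2_qtl
    label: str = ""
    peak_lod: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} ({self.chrom}, {self.label!r})"
            )
        if self.unit not in {"cM", "Mb"}:
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def length(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Closed-interval overlap; touching endpoints count."""
        if self.unit != other.unit:
            raise ValueError(f"cannot compare {self.unit} with {other.unit} intervals")
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


# ---------------------------------------------------------------------------
# cross CSV


def read_rqtl_csv(
    path,
    geno_codes: Mapping[str, float] = DEFAULT_GENO_CODES,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
    covariate_columns: Iterable[str] = DEFAULT_COVARIATE_COLUMNS,
) -> Cross:
    """Read a rotated-header cross CSV into a validated :class:`Cross`.

    Phenotype/covariate columns are auto-detected as those with a blank
    chromosome cell in header row two.  A phenotype column named ``id`` is
    used as the individual index.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError(f"{path}: not a cross CSV (needs 3 header rows + data)")
    names, chrom_row, pos_row = rows[0], rows[1], rows[2]
    ncol = len(names)
    chrom_row = (chrom_row + [""] * ncol)[:ncol]
    pos_row = (pos_row + [""] * ncol)[:ncol]
    is_marker = [c.strip() != "" for c in chrom_row]

    map_rows = []
    for j, flag in enumerate(is_marker):
        if flag:
            map_rows.append(
                {
                    "marker": names[j],
                    "chrom": chrom_row[j].strip(),
                    "pos_cM": float(pos_row[j]),
                }
            )
    gmap = GeneticMap(pd.DataFrame(map_rows))

    missing = set(missing_codes)
    data = rows[3:]
    pheno_cols = [j for j, flag in enumerate(is_marker) if not flag]
    marker_cols = [j for j, flag in enumerate(is_marker) if flag]

    pheno_records, geno_records = [], []
    for i, row in enumerate(data):
        row = (row + [""] * ncol)[:ncol]
        pheno_records.append([row[j] for j in pheno_cols])
        codes = []
        for j in marker_cols:
            cell = row[j].strip()
            if cell in missing:
                codes.append(np.nan)
            elif cell in geno_codes:
                codes.append(geno_codes[cell])
            else:
                raise GenotypeCodeError(
                    f"{path}: unknown genotype code {cell!r} in data row {i + 1}, "
                    f"column {names[j]!r}"
                )
        geno_records.append(codes)

    pheno = pd.DataFrame(pheno_records, columns=[names[j] for j in pheno_cols])
    if "id" in pheno.columns:
        pheno = pheno.set_index("id")
        pheno.index.name = "id"
    with pd.option_context("future.no_silent_downcasting", True):
        pheno = pheno.replace(list(missing), np.nan)
    for col in pheno.columns:
        if col not in {"sex", "batch"}:
            try:
                pheno[col] = pd.to_numeric(pheno[col])
            except (ValueError, TypeError):
                pass

    geno = pd.DataFrame(geno_records, columns=[names[j] for j in marker_cols], index=pheno.index)

    covar_names = [c for c in covariate_columns if c in pheno.columns]
    covariates = pheno[covar_names]
    phenotypes = pheno.drop(columns=covar_names)
    return Cross(gmap, geno, phenotypes, covariates)


def write_rqtl_csv(cross: Cross, path, geno_codes: Mapping[str, float] = DEFAULT_GENO_CODES) -> None:
    """Write a :class:`Cross` in the rotated-header CSV dialect."""
    inverse = {v: k for k, v in geno_codes.items()}
    pheno = pd.concat([cross.phenotypes, cross.covariates], axis=1)
    pheno_names = ["id"] + list(pheno.columns)
    markers = list(cross.gmap.markers)
    mtab = cross.gmap.table.set_index("marker")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(pheno_names + markers)
        w.writerow([""] * len(pheno_names) + [str(mtab.loc[m, "chrom"]) for m in markers])
        w.writerow([""] * len(pheno_names) + [repr(float(mtab.loc[m, "pos_cM"])) for m in markers])
        geno = cross.geno.to_numpy(dtype=float)
        for i, ind in enumerate(cross.individuals):
            cells = [str(ind)]
            for col in pheno.columns:
                v = pheno.iloc[i][col]
                if pd.isna(v):
                    cells.append("")
                elif isinstance(v, (float, np.floating)):
                    cells.append(repr(float(v)))
                else:
                    cells.append(str(v))
            for g in geno[i]:
                cells.append("" if np.isnan(g) else inverse[g])
            w.writerow(cells)


# ---------------------------------------------------------------------------
# interval tables

DEFAULT_INTERVAL_COLUMNS = {
    "chrom": "chromosome",
    "start": "start",
    "end": "end",
    "label": "label",
    "peak_lod": "peak_lod",
}


def read_interval_table(
    path,
    unit: str,
    kind: str = "qtl",
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[GenomicInterval]:
    """Read a delimited interval table into unit-tagged intervals.

    ``columns`` maps the logical names ``chrom``, ``start``, ``end``,
    ``label`` and (optionally) ``peak_lod`` to the file's header names.
    """
    colmap = dict(DEFAULT_INTERVAL_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep)
    for logical in ("chrom", "start", "end", "label"):
        if colmap[logical] not in df.columns:
            raise ValueError(
                f"{path}: required column {colmap[logical]!r} (for {logical}) not found; "
                f"available: {list(df.columns)}"
            )
    has_lod = colmap.get("peak_lod") in df.columns
    out = []
    for i, row in df.iterrows():
        start, end = float(row[colmap["start"]]), float(row[colmap["end"]])
        if start > end:
            raise ValueError(f"{path}: row {i + 1}: start {start} > end {end}")
        lod = float(row[colmap["peak_lod"]]) if has_lod and pd.notna(row[colmap["peak_lod"]]) else None
        out.append(
            GenomicInterval(
                chrom=str(row[colmap["chrom"]]),
                start=start,
                end=end,
                unit=unit,
                source_kind=kind,
                label=str(row[colmap["label"]]),
                peak_lod=lod,
            )
        )
    return out


def write_interval_table(intervals: Sequence[GenomicInterval], path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "chromosome": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "label": [iv.label for iv in intervals],
            "peak_lod": [iv.peak_lod for iv in intervals],
            "unit": [iv.unit for iv in intervals],
            "kind": [iv.source_kind for iv in intervals],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    """Write Mb-unit intervals as BED (0-based, half-open, bp)."""
    for iv in intervals:
        if iv.unit != "Mb":
            raise ValueError(
                f"write_bed requires Mb-unit intervals; got {iv.unit} for {iv.label!r} "
                "(convert with coordinate_convert first)"
            )
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.peak_lod is None else f"{iv.peak_lod:g}"
            fh.write(
                f"{iv.chrom}\t{round(iv.start * 1e6)}\t{round(iv.end * 1e6)}"
                f"\t{iv.label or '.'}\t{score}\n"
            )


# ---------------------------------------------------------------------------
# expression matrix + annotation


def read_expression(path, sep: str = "\t") -> pd.DataFrame:
    """Probesets x individuals matrix; first column is the probeset id."""
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    df.index.name = "probeset"
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, index_label="probeset")


def read_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Probe annotation with columns probeset, chrom, pos_Mb [, pos_cM]."""
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    df = df.set_index("probeset")
    return df


def write_annotation(annotation: pd.DataFrame, path, sep: str = "\t") -> None:
    annotation.to_csv(path, sep=sep, index_label="probeset")
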