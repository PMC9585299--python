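"""Domain types, CSV I/O, validation, and trait derivation.

The analysis consumes four inputs:

* a plot x taxon abundance matrix (integer counts of woody individuals
  per plot),
* a per-taxon trait table of specific leaf area (SLA, mm^2/mg), leaf
  thickness (LT, mm) and wood density (WD, g/cm^3) — optionally derived
  here from raw specimen measurements,
* a rooted phylogeny covering the taxa (handled in :mod:`divgrad.phylo`),
* a per-plot environment table (region, latitude, temperature seasonality,
  annual precipitation, soil pH, soil bulk density).

Taxon sets rarely coincide across inputs (some taxa lack trait records or
tree tips); :func:`align_inputs` computes, per diversity attribute, the
usable taxon subset of each plot with renormalised relative abundances and
emits a coverage report rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "SpecimenTraitRecord",
    "TraitTable",
    "EnvTable",
    "read_community",
    "write_community",
    "read_traits",
    "write_traits",
    "read_specimens",
    "derive_traits",
    "read_env",
    "write_env",
    "align_inputs",
    "AlignedBundle",
]

TRAIT_COLUMNS = ("SLA", "LT", "WD")
ENV_COLUMNS = (
    "region", "latitude", "temp_seasonality", "annual_precip",
    "soil_pH", "bulk_density",
)


# ---------------------------------------------------------------------------
# community matrix

@dataclass(frozen=True)
class CommunityMatrix:
    """Plot x taxon matrix of non-negative integer counts.

    Every plot must contain at least one individual; taxon identifiers are
    unique, whitespace-trimmed opaque strings.
    """

    plots: tuple
    taxa: tuple
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.plots), len(self.taxa)):
            raise ValueError("counts shape does not match plots x taxa")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at plot {self.plots[i]!r}, taxon {self.taxa[j]!r}"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if tuple(self.taxa).count(t) > 1})
            raise ValueError(f"duplicate taxon identifiers: {dupes}")
        if len(set(self.plots)) != len(self.plots):
            raise ValueError("duplicate plot identifiers")
        totals = counts.sum(axis=1)
        if np.any(totals == 0):
            bad = self.plots[int(np.argmax(totals == 0))]
            raise ValueError(f"plot {bad!r} has zero total abundance")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "plots", tuple(self.plots))
        object.__setattr__(self, "taxa", tuple(self.taxa))

    def row(self, plot) -> np.ndarray:
        return self.counts[self.plots.index(plot)]

    def relative_abundances(self, plot) -> np.ndarray:
        row = self.row(plot).astype(float)
        return row / row.sum()

    def plot_taxa(self, plot) -> list:
        row = self.row(plot)
        return [t for t, c in zip(self.taxa, row) if c > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.plots),
                            columns=list(self.taxa))


def read_community(path) -> CommunityMatrix:
    """Read a community matrix CSV: first column plot ids, header taxa."""
    header = pd.read_csv(path, header=None, nrows=1).iloc[0]
    raw_names = [str(c).strip() for c in header[1:]]
    if len(set(raw_names)) != len(raw_names):
        dupes = sorted({t for t in raw_names if raw_names.count(t) > 1})
        raise ValueError(f"duplicate taxon columns: {dupes}")
    df = pd.read_csv(path, index_col=0)
    taxa = raw_names
    plots = [str(i).strip() for i in df.index]
    arr = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(np.argmax(vals.isna().to_numpy()))
            raise ValueError(
                f"non-numeric count at plot {plots[i]!r}, taxon {taxa[j]!r}"
            )
        arr[:, j] = vals.to_numpy()
        if not np.allclose(df[col].to_numpy(dtype=float), arr[:, j]):
            raise ValueError(f"non-integer count in column {taxa[j]!r}")
    return CommunityMatrix(tuple(plots), tuple(taxa), arr)


def write_community(cm: CommunityMatrix, path) -> None:
    cm.to_frame().to_csv(path, index_label="plot")


# ---------------------------------------------------------------------------
# traits

@dataclass(frozen=True)
class SpecimenTraitRecord:
    """Raw field/lab measurements for one collected individual.

    Leaf area (mm^2) and leaf dry mass (mg) yield SLA; branch dry mass (g)
    over branch fresh volume (cm^3) yields WD; leaf thickness (mm) is
    measured directly.  Missing measurements are ``None``.
    """

    taxon: str
    leaf_area: float | None = None
    leaf_dry_mass: float | None = None
    leaf_thickness: float | None = None
    branch_dry_mass: float | None = None
    branch_fresh_volume: float | None = None

    def __post_init__(self):
        for name in ("leaf_area", "leaf_dry_mass", "leaf_thickness",
                     "branch_dry_mass", "branch_fresh_volume"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")

    @property
    def sla(self) -> float | None:
        if self.leaf_area is None or self.leaf_dry_mass is None:
            return None
        return self.leaf_area / self.leaf_dry_mass

    @property
    def wd(self) -> float | None:
        if self.branch_dry_mass is None or self.branch_fresh_volume is None:
            return None
        return self.branch_dry_mass / self.branch_fresh_volume

    @property
    def complete(self) -> bool:
        return (self.sla is not None and self.leaf_thickness is not None
                and self.wd is not None)


@dataclass(frozen=True)
class TraitTable:
    """Per-taxon mean SLA, LT, WD; all three strictly positive."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.table
        missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        df = df.loc[:, list(TRAIT_COLUMNS)].astype(float)
        if df.isna().any().any() or (df <= 0).any().any():
            raise ValueError("trait values must be present and strictly positive")
        if df.index.has_duplicates:
            raise ValueError("duplicate taxa in trait table")
        df.index = df.index.astype(str).str.strip()
        object.__setattr__(self, "table", df)

    @property
    def taxa(self) -> tuple:
        return tuple(self.table.index)

    def subset(self, taxa: Sequence[str]) -> "TraitTable":
        return TraitTable(self.table.loc[list(taxa)])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def derive_traits(records: Iterable[SpecimenTraitRecord]) -> TraitTable:
    """Per-taxon arithmetic trait means over complete specimens.

    Specimens lacking any of SLA, LT or WD are dropped (only individuals
    with records for all three traits contribute); taxa with no complete
    specimen are excluded with a warning giving the count.
    """
    rows: dict[str, list] = {}
    n_dropped = 0
    incomplete_taxa = set()
    for rec in records:
        if not rec.complete:
            n_dropped += 1
            incomplete_taxa.add(rec.taxon.strip())
            continue
        rows.setdefault(rec.taxon.strip(), []).append(
            (rec.sla, rec.leaf_thickness, rec.wd)
        )
    excluded = sorted(incomplete_taxa - set(rows))
    if excluded:
        warnings.warn(
            f"{len(excluded)} taxa excluded (no specimen with all three traits); "
            f"{n_dropped} incomplete specimens dropped"
        )
    if not rows:
        raise ValueError("no taxon has a complete specimen record")
    data = {
        taxon: np.mean(np.asarray(vals, dtype=float), axis=0)
        for taxon, vals in sorted(rows.items())
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(TRAIT_COLUMNS))
    df.index.name = "taxon"
    return TraitTable(df)


def read_traits(path) -> TraitTable:
    return TraitTable(pd.read_csv(path, index_col=0))


def write_traits(tt: TraitTable, path) -> None:
    tt.table.to_csv(path, index_label="taxon", float_format="%.10g")


_SPECIMEN_FIELDS = ("leaf_area", "leaf_dry_mass", "leaf_thickness",
                    "branch_dry_mass", "branch_fresh_volume")


def read_specimens(path) -> list[SpecimenTraitRecord]:
    """Read raw specimen measurements: columns taxon + any of
    leaf_area, leaf_dry_mass, leaf_thickness, branch_dry_mass,
    branch_fresh_volume (blank = missing)."""
    df = pd.read_csv(path)
    if "taxon" not in df.columns:
        raise ValueError("specimen CSV must have a 'taxon' column")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in _SPECIMEN_FIELDS:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = float(row[f])
        records.append(SpecimenTraitRecord(taxon=str(row["taxon"]), **kwargs))
    return records


# ---------------------------------------------------------------------------
# environment

@dataclass(frozen=True)
class EnvTable:
    """Per-plot environment: region, latitude (signed decimal degrees),
    temperature seasonality (degC), annual precipitation (mm/yr), soil pH,
    soil bulk density (g/cm^3)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.table
        missing = [c for c in ENV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"environment table missing columns: {missing}")
        df = df.loc[:, list(ENV_COLUMNS)].copy()
        df.index = df.index.astype(str).str.strip()
        df["region"] = df["region"].astype(str)
        for c in ENV_COLUMNS[1:]:
            df[c] = pd.to_numeric(df[c])
        if df.index.has_duplicates:
            raise ValueError("duplicate plot identifiers in environment table")
        object.__setattr__(self, "table", df)

    @property
    def plots(self) -> tuple:
        return tuple(self.table.index)

    def check_covers(self, cm: CommunityMatrix) -> None:
        missing = sorted(set(cm.plots) - set(self.plots))
        if missing:
            raise ValueError(f"plots without environment rows: {missing}")

    def check_regions(self, min_plots: int = 2) -> None:
        sizes = self.table.groupby("region").size()
        small = sizes[sizes < min_plots]
        if len(small):
            raise ValueError(
                f"regions with fewer than {min_plots} plots: {list(small.index)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def read_env(path) -> EnvTable:
    return EnvTable(pd.read_csv(path, index_col=0))


def write_env(env: EnvTable, path) -> None:
    env.table.to_csv(path, index_label="plot", float_format="%.10g")


# ---------------------------------------------------------------------------
# alignment

@dataclass(frozen=True)
class AlignedBundle:
    """Per-attribute usable taxa and renormalised abundances per plot.

    ``per_plot[attribute][plot]`` is a (taxa, p) pair with p summing to 1,
    or ``None`` when the plot has < 2 usable taxa for that attribute (the
    cell is flagged missing in the coverage report, not fatal).
    Counts in the community matrix are never altered.
    """

    cm: CommunityMatrix
    per_plot: Mapping[str, Mapping[str, tuple | None]]
    coverage: pd.DataFrame = field(repr=False)


def align_inputs(cm: CommunityMatrix, tt: TraitTable | None = None,
                 tree=None, env: EnvTable | None = None) -> AlignedBundle:
    """Intersect taxon sets per attribute and renormalise abundances.

    TD uses all taxa of each plot; FD the plot's taxa with complete trait
    records; PD the plot's taxa present as tree tips.  For FD/PD the
    relative abundances are renormalised over the usable subset.
    """
    from .phylo import tip_labels  # local import to avoid a cycle

    if env is not None:
        env.check_covers(cm)
    usable = {"TD": set(cm.taxa)}
    if tt is not None:
        usable["FD"] = set(cm.taxa) & set(tt.taxa)
    if tree is not None:
        usable["PD"] = set(cm.taxa) & set(tip_labels(tree))

    taxon_idx = {t: j for j, t in enumerate(cm.taxa)}
    per_plot: dict[str, dict] = {}
    cov_rows = []
    for attr, ok in usable.items():
        per_plot[attr] = {}
        for plot in cm.plots:
            present = cm.plot_taxa(plot)
            sub = [t for t in present if t in ok]
            if len(sub) < (1 if attr == "TD" else 2):
                per_plot[attr][plot] = None
            else:
                row = cm.row(plot)
                counts = np.array([row[taxon_idx[t]] for t in sub], float)
                per_plot[attr][plot] = (tuple(sub), counts / counts.sum())
            cov_rows.append({
                "plot": plot, "attribute": attr,
                "n_present": len(present), "n_usable": len(sub),
                "usable": per_plot[attr][plot] is not None,
            })
    coverage = pd.DataFrame(cov_rows)
    return AlignedBundle(cm=cm, per_plot=per_plot, coverage=coverage)
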