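"""Occurrence-table input/output and temporal binning.

The pipeline's raw input is a long-format table of taxon detections: one row
per (site, sample, taxon), where every sample carries a calibrated age in
years before present (BP) and every site has geographic coordinates. Samples
are binned into fixed-width time intervals (default 500 years); within a bin,
all samples of one site are pooled by set union into a *community*, and the
communities of one bin form a *metacommunity slice* — the unit on which all
diversity metrics operate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeBin",
    "BinnedCommunity",
    "MetacommunitySlice",
    "OccurrenceTable",
    "SchemaError",
    "ValidationError",
    "read_occurrences",
    "bin_communities",
    "write_long_table",
]


class SchemaError(ValueError):
    """A required column is missing or the input schema cannot be resolved."""


class ValidationError(ValueError):
    """The table content violates an occurrence-data invariant."""


@dataclass(frozen=True, order=True)
class TimeBin:
    """Half-open age interval [lower, upper) in years BP.

    ``lower`` is the young edge, ``upper`` the old edge; a sample of age *a*
    falls in the bin with ``lower <= a < upper``. Bins are anchored at 0 BP,
    so an age exactly on an edge belongs to the older bin.
    """

    lower: float
    upper: float

    @property
    def label(self) -> float:
        """Bin midpoint in years BP, used as the bin's age coordinate."""
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper

    def is_adjacent_older(self, other: "TimeBin") -> bool:
        """True if ``other`` is the bin immediately older than this one."""
        return np.isclose(other.lower, self.upper)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lower:g},{self.upper:g})"


@dataclass
class BinnedCommunity:
    """One site's community in one time bin.

    ``taxa`` is the union of the taxon sets of all of the site's samples in
    the bin; the per-sample sets are retained because alpha diversity is
    defined per sediment sample, not per pooled community.
    """

    site_id: str
    bin: TimeBin
    taxa: frozenset
    n_samples: int
    sample_taxa: dict = field(default_factory=dict)  # sample_id -> frozenset

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"community {self.site_id} {self.bin}: n_samples < 1")
        if self.sample_taxa:
            union = frozenset().union(*self.sample_taxa.values())
            if union != self.taxa:
                raise ValidationError(
                    f"community {self.site_id} {self.bin}: taxa != union of samples"
                )

    @property
    def richness(self) -> int:
        return len(self.taxa)

    @property
    def sample_richness(self) -> list:
        """Per-sample taxon counts (alpha diversity observations)."""
        if self.sample_taxa:
            return [len(s) for s in self.sample_taxa.values()]
        return [len(self.taxa)] * self.n_samples


@dataclass
class MetacommunitySlice:
    """All communities of one time bin: the unit for gamma, beta and zeta.

    Slices with fewer than the configured minimum number of communities are
    kept but flagged ``excluded`` so downstream stages can skip them without
    silently losing data.
    """

    bin: TimeBin
    communities: list
    excluded: bool = False

    def __post_init__(self) -> None:
        sites = [c.site_id for c in self.communities]
        if len(sites) != len(set(sites)):
            raise ValidationError(f"slice {self.bin}: duplicate site communities")

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @property
    def site_ids(self) -> list:
        return [c.site_id for c in self.communities]

    def union(self) -> frozenset:
        """Pooled (gamma-level) taxon set of the slice."""
        if not self.communities:
            return frozenset()
        return frozenset().union(*(c.taxa for c in self.communities))

    def community(self, site_id: str):
        for c in self.communities:
            if c.site_id == site_id:
                return c
        return None

    def taxon_sets(self) -> list:
        return [c.taxa for c in self.communities]


@dataclass
class OccurrenceTable:
    """Long-format presence/absence detections with site coordinates.

    ``records`` has columns ``site``, ``sample``, ``age``, ``taxon`` (one row
    per detection, deduplicated); ``sites`` maps site_id to (lon, lat) in
    decimal degrees and may be empty when no spatial analysis is intended.
    """

    records: pd.DataFrame
    sites: dict = field(default_factory=dict)
    provenance: str = ""

    REQUIRED = ("site", "sample", "age", "taxon")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing columns: {missing}")
        df = self.records.loc[:, list(self.REQUIRED)].copy()
        df["site"] = df["site"].astype(str)
        df["sample"] = df["sample"].astype(str)
        df["taxon"] = df["taxon"].astype(str)
        df["age"] = pd.to_numeric(df["age"])
        if (df["age"] < 0).any():
            bad = df.loc[df["age"] < 0, "sample"].unique()[:5]
            raise ValidationError(f"negative ages for samples {list(bad)}")
        df = df.drop_duplicates(subset=["site", "sample", "taxon"], ignore_index=True)
        # each sample must resolve to exactly one site and one age
        per_sample = df.groupby("sample").agg(
            n_sites=("site", "nunique"), n_ages=("age", "nunique")
        )
        bad_site = per_sample.index[per_sample["n_sites"] > 1].tolist()
        bad_age = per_sample.index[per_sample["n_ages"] > 1].tolist()
        if bad_site:
            raise ValidationError(f"samples mapped to several sites: {bad_site[:10]}")
        if bad_age:
            raise ValidationError(f"samples with conflicting ages: {bad_age[:10]}")
        if self.sites:
            unknown = sorted(set(df["site"]) - set(self.sites))
            if unknown:
                raise ValidationError(f"sites without coordinates: {unknown}")
        object.__setattr__(self, "records", df)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_samples(self) -> int:
        return self.records["sample"].nunique()

    @property
    def n_sites(self) -> int:
        return self.records["site"].nunique()

    @property
    def n_taxa(self) -> int:
        return self.records["taxon"].nunique()

    def site_taxa(self, site_id: str) -> frozenset:
        sub = self.records[self.records["site"] == site_id]
        return frozenset(sub["taxon"])

    def subset_ages(self, older: float, younger: float, include_younger: bool = False):
        """Rows with younger < age <= older (or >= younger when inclusive)."""
        a = self.records["age"]
        mask = (a <= older) & ((a >= younger) if include_younger else (a > younger))
        return OccurrenceTable(self.records[mask], sites=self.sites, provenance=self.provenance)


def _resolve(df: pd.DataFrame, wanted: str, given: str | None) -> str:
    if given is not None:
        if given not in df.columns:
            raise SchemaError(f"column {given!r} (for {wanted}) not in file")
        return given
    lower = {c.lower(): c for c in df.columns}
    for cand in (wanted, wanted + "_id", wanted + "_name"):
        if cand in lower:
            return lower[cand]
    raise SchemaError(f"cannot resolve a column for {wanted!r}; have {list(df.columns)}")


def read_occurrences(
    path,
    *,
    site_col: str | None = None,
    sample_col: str | None = None,
    age_col: str | None = None,
    taxon_col: str | None = None,
    sep: str | None = None,
    ages_in_ka: bool = False,
    coords_path=None,
    lon_col: str = "lon",
    lat_col: str = "lat",
) -> OccurrenceTable:
    """Read a long-format occurrence file into a validated table.

    Column names are resolved case-insensitively (``site``/``site_id`` etc.)
    or given explicitly. ``ages_in_ka=True`` converts kiloyears to years at
    read time so the in-memory unit is always years BP. Duplicated
    (site, sample, taxon) rows are collapsed to one detection. Coordinates
    come either from a separate ``coords_path`` CSV (site, lon, lat) or from
    ``lon``/``lat`` columns of the main file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = {
        "site": _resolve(df, "site", site_col),
        "sample": _resolve(df, "sample", sample_col),
        "age": _resolve(df, "age", age_col),
        "taxon": _resolve(df, "taxon", taxon_col),
    }
    out = df.rename(columns={v: k for k, v in cols.items()})
    if ages_in_ka:
        out["age"] = pd.to_numeric(out["age"]) * 1000.0
    sites: dict = {}
    if coords_path is not None:
        cdf = pd.read_csv(coords_path)
        csite = _resolve(cdf, "site", None)
        sites = {
            str(r[csite]): (float(r[lon_col]), float(r[lat_col]))
            for _, r in cdf.iterrows()
        }
    elif lon_col in df.columns and lat_col in df.columns:
        for _, r in out.drop_duplicates("site").iterrows():
            row = df.loc[r.name]
            sites[str(r["site"])] = (float(row[lon_col]), float(row[lat_col]))
    return OccurrenceTable(out, sites=sites, provenance=f"read from {path.name}")


def bin_communities(
    tab: OccurrenceTable, width: float = 500.0, min_communities: int = 2
) -> list:
    """Bin samples into communities and metacommunity slices.

    Each sample goes to the half-open bin [k*width, (k+1)*width) containing
    its age; per site and bin, taxa are pooled by union across the site's
    samples while per-sample sets are retained for alpha diversity. Slices
    are returned oldest first; slices with fewer than ``min_communities``
    communities are flagged ``excluded`` rather than dropped.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    df = tab.records
    if df.empty:
        return []
    k = np.floor(df["age"].to_numpy() / width).astype(int)
    df = df.assign(_bin=k)
    slices = []
    for bin_k, bdf in df.groupby("_bin"):
        tb = TimeBin(lower=bin_k * width, upper=(bin_k + 1) * width)
        comms = []
        for site, sdf in bdf.groupby("site"):
            sample_taxa = {
                str(s): frozenset(g["taxon"]) for s, g in sdf.groupby("sample")
            }
            comms.append(
                BinnedCommunity(
                    site_id=str(site),
                    bin=tb,
                    taxa=frozenset(bdf.loc[bdf["site"] == site, "taxon"]),
                    n_samples=len(sample_taxa),
                    sample_taxa=sample_taxa,
                )
            )
        comms.sort(key=lambda c: c.site_id)
        slices.append(
            MetacommunitySlice(
                bin=tb, communities=comms, excluded=len(comms) < min_communities
            )
        )
    slices.sort(key=lambda s: -s.bin.lower)  # oldest first
    return slices


def write_long_table(rows, path) -> None:
    """Write any tabular result as TSV (or CSV by extension) with a header.

    Accepts a DataFrame, a list of dataclass records, or a list of dicts;
    an empty input yields a header-only file when columns are known.
    """
    if rows is None:
        raise ValueError("rows must not be None")
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        dicts = []
        for r in rows:
            if dataclasses.is_dataclass(r):
                d = dataclasses.asdict(r)
                for key in list(d):
                    if isinstance(d[key], TimeBin) or (
                        isinstance(d[key], dict) and {"lower", "upper"} <= set(d[key])
                    ):
                        tb = d.pop(key)
                        lo = tb["lower"] if isinstance(tb, dict) else tb.lower
                        up = tb["upper"] if isinstance(tb, dict) else tb.upper
                        d[f"{key}_lower"] = lo
                        d[f"{key}_upper"] = up
                        d[f"{key}_mid"] = 0.5 * (lo + up)
                dicts.append(d)
            else:
                dicts.append(dict(r))
        df = pd.DataFrame(dicts)
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
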