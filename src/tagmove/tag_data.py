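"""Study frame, tagging tables, and CSV input/output.

A tag-recovery study releases batches of tagged fish into spatial management
units and records terminal recoveries from a commercial fishery. The raw
material is four tables: releases by (tag year, tag region, length class),
recoveries by (tag year, tag region, length class, recovery year, recovery
region), fixed tag-reporting rates by (year, region), and an age-length
sample of aged fish by (length class, age). This module defines the in-memory
containers for those tables, validates them against a common study frame, and
reads/writes them as plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StudyFrame",
    "TagDataset",
    "ReportingRates",
    "AgeLengthSample",
    "read_tag_tables",
    "read_reporting_rates",
    "read_age_length_sample",
    "write_tag_tables",
    "write_reporting_rates",
    "write_age_length_sample",
    "lake_erie_frame",
    "lake_erie_dataset",
    "lake_erie_reporting_rates",
]


@dataclass(frozen=True)
class StudyFrame:
    """Index frame shared by every array in a study.

    Parameters
    ----------
    years : contiguous calendar years covered by releases and recoveries.
    regions : ordered region (management unit) labels.
    n_ages : number of age classes; the last is an absorbing plus-group.
    length_classes : ordered, non-overlapping length-class labels.
    """

    years: tuple[int, ...]
    regions: tuple[str, ...]
    n_ages: int
    length_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "regions", tuple(str(r) for r in self.regions))
        object.__setattr__(
            self, "length_classes", tuple(str(c) for c in self.length_classes)
        )
        if len(years) == 0:
            raise ValueError("frame needs at least one year")
        if list(years) != list(range(years[0], years[-1] + 1)):
            raise ValueError(f"years must be contiguous, got {years}")
        if len(self.regions) < 1:
            raise ValueError("frame needs at least one region")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region labels")
        if self.n_ages < 2:
            raise ValueError("need at least two age classes (last is a plus-group)")
        if len(self.length_classes) == 0:
            raise ValueError("frame needs at least one length class")
        if len(set(self.length_classes)) != len(self.length_classes):
            raise ValueError("duplicate length-class labels")

    # Sizes -----------------------------------------------------------------
    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_lengths(self) -> int:
        return len(self.length_classes)

    @property
    def ages(self) -> np.ndarray:
        """Age-class values 1..n_ages (the last read as ``n_ages``+)."""
        return np.arange(1, self.n_ages + 1)

    # Label resolution ------------------------------------------------------
    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in frame {self.years[0]}..{self.years[-1]}")

    def region_index(self, region: str) -> int:
        wanted = str(region).strip().lower()
        for i, r in enumerate(self.regions):
            if r.lower() == wanted:
                return i
        raise KeyError(f"region {region!r} not in frame regions {self.regions}")

    def length_index(self, length_class: str) -> int:
        wanted = str(length_class).strip().lower()
        for i, c in enumerate(self.length_classes):
            if c.lower() == wanted:
                return i
        raise KeyError(
            f"length class {length_class!r} not in frame classes {self.length_classes}"
        )


@dataclass
class TagDataset:
    """Releases, recoveries and the derived never-recovered (at-large) counts.

    Arrays are indexed on the frame: ``releases[ty, tk, l]``,
    ``recoveries[ty, tk, l, fy, fk]`` and ``at_large[ty, tk, l]``, with
    ``at_large = releases - recoveries.sum over (fy, fk)`` by construction.
    """

    frame: StudyFrame
    releases: np.ndarray
    recoveries: np.ndarray
    at_large: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        f = self.frame
        self.releases = np.asarray(self.releases, dtype=np.int64)
        self.recoveries = np.asarray(self.recoveries, dtype=np.int64)
        shape_rel = (f.n_years, f.n_regions, f.n_lengths)
        shape_rec = shape_rel + (f.n_years, f.n_regions)
        if self.releases.shape != shape_rel:
            raise ValueError(f"releases shape {self.releases.shape} != {shape_rel}")
        if self.recoveries.shape != shape_rec:
            raise ValueError(f"recoveries shape {self.recoveries.shape} != {shape_rec}")
        if (self.releases < 0).any() or (self.recoveries < 0).any():
            raise ValueError("counts must be non-negative")
        # recoveries cannot precede the tag year
        ty = np.arange(f.n_years)[:, None, None, None, None]
        fy = np.arange(f.n_years)[None, None, None, :, None]
        before = np.broadcast_to(fy < ty, self.recoveries.shape)
        if (self.recoveries[before] > 0).any():
            raise ValueError("recovery before tag year")
        recovered = self.recoveries.sum(axis=(3, 4))
        # recoveries from strata with no releases are impossible
        if ((recovered > 0) & (self.releases == 0)).any():
            bad = np.argwhere((recovered > 0) & (self.releases == 0))[0]
            raise ValueError(
                f"recoveries recorded for stratum with zero releases at "
                f"(year={f.years[bad[0]]}, region={f.regions[bad[1]]}, "
                f"length={f.length_classes[bad[2]]})"
            )
        self.at_large = self.releases - recovered
        if (self.at_large < 0).any():
            raise ValueError("more recoveries than releases in some stratum")

    @property
    def total_releases(self) -> int:
        return int(self.releases.sum())

    @property
    def total_recoveries(self) -> int:
        return int(self.recoveries.sum())

    @property
    def total_at_large(self) -> int:
        return int(self.at_large.sum())


@dataclass
class ReportingRates:
    """Fixed probabilities that a harvested tagged fish is scanned and reported.

    ``lam[fy, k]`` is treated as a known quantity (no prior): in the Lake Erie
    study it is the proportion of the commercial catch scanned for tags.
    """

    frame: StudyFrame
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        shape = (self.frame.n_years, self.frame.n_regions)
        if self.lam.shape != shape:
            raise ValueError(f"lam shape {self.lam.shape} != {shape}")
        if not np.isfinite(self.lam).all():
            raise ValueError("reporting rates must be finite")
        if (self.lam < 0).any() or (self.lam > 1).any():
            raise ValueError("reporting rates must lie in [0, 1]")


@dataclass
class AgeLengthSample:
    """Counts of aged fish per length class and age class.

    ``n[l, a]`` with row totals ``N[l]``; drives the multinomial likelihood of
    the age-composition state variables.
    """

    frame: StudyFrame
    n: np.ndarray
    N: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        shape = (self.frame.n_lengths, self.frame.n_ages)
        if self.n.shape != shape:
            raise ValueError(f"age-length counts shape {self.n.shape} != {shape}")
        if (self.n < 0).any():
            raise ValueError("age-length counts must be non-negative")
        self.N = self.n.sum(axis=1)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_tag_tables(release_path, recovery_path, frame: StudyFrame) -> TagDataset:
    """Read release and recovery CSVs into a validated :class:`TagDataset`.

    Duplicate rows for the same stratum are summed, so a one-row-per-fish long
    format works as well as pre-aggregated counts. An empty recovery file (or
    one with only a header) is valid: every released fish is then at large.
    """
    f = frame
    rel = pd.read_csv(release_path)
    _require_columns(rel, ["tag_year", "tag_region", "length_class", "count"], release_path)
    releases = np.zeros((f.n_years, f.n_regions, f.n_lengths), dtype=np.int64)
    for row in rel.itertuples(index=False):
        c = int(row.count)
        if c < 0:
            raise ValueError(f"{release_path}: negative count {c}")
        releases[
            f.year_index(row.tag_year),
            f.region_index(row.tag_region),
            f.length_index(row.length_class),
        ] += c

    recoveries = np.zeros(
        (f.n_years, f.n_regions, f.n_lengths, f.n_years, f.n_regions), dtype=np.int64
    )
    rec = pd.read_csv(recovery_path)
    if len(rec):
        _require_columns(
            rec,
            ["tag_year", "tag_region", "length_class", "recovery_year", "recovery_region", "count"],
            recovery_path,
        )
        for row in rec.itertuples(index=False):
            c = int(row.count)
            if c < 0:
                raise ValueError(f"{recovery_path}: negative count {c}")
            ty = f.year_index(row.tag_year)
            fy = f.year_index(row.recovery_year)
            if fy < ty and c > 0:
                raise ValueError(
                    f"{recovery_path}: recovery year {row.recovery_year} precedes "
                    f"tag year {row.tag_year}"
                )
            recoveries[
                ty,
                f.region_index(row.tag_region),
                f.length_index(row.length_class),
                fy,
                f.region_index(row.recovery_region),
            ] += c
    return TagDataset(frame=f, releases=releases, recoveries=recoveries)


def read_reporting_rates(path, frame: StudyFrame) -> ReportingRates:
    """Read the year x region reporting-rate table; every cell must be present."""
    f = frame
    df = pd.read_csv(path)
    _require_columns(df, ["year", "region", "rate"], path)
    lam = np.full((f.n_years, f.n_regions), np.nan)
    for row in df.itertuples(index=False):
        rate = float(row.rate)
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{path}: rate {rate} outside [0, 1]")
        lam[f.year_index(row.year), f.region_index(row.region)] = rate
    if np.isnan(lam).any():
        bad = np.argwhere(np.isnan(lam))[0]
        raise ValueError(
            f"{path}: missing reporting rate for "
            f"(year={f.years[bad[0]]}, region={f.regions[bad[1]]})"
        )
    return ReportingRates(frame=f, lam=lam)


def read_age_length_sample(path, frame: StudyFrame) -> AgeLengthSample:
    """Read aged-fish counts; unobserved (length, age) cells are zero."""
    f = frame
    df = pd.read_csv(path)
    _require_columns(df, ["length_class", "age", "count"], path)
    n = np.zeros((f.n_lengths, f.n_ages), dtype=np.int64)
    for row in df.itertuples(index=False):
        a = int(row.age)
        if not 1 <= a <= f.n_ages:
            raise ValueError(f"{path}: age {a} outside 1..{f.n_ages}")
        c = int(row.count)
        if c < 0:
            raise ValueError(f"{path}: negative count {c}")
        n[f.length_index(row.length_class), a - 1] += c
    return AgeLengthSample(frame=f, n=n)


# ---------------------------------------------------------------------------
# Writers (exact round-trip with the readers)
# ---------------------------------------------------------------------------

def write_tag_tables(dataset: TagDataset, release_path, recovery_path) -> None:
    f = dataset.frame
    rel_rows = []
    for (iy, ik, il), c in np.ndenumerate(dataset.releases):
        if c:
            rel_rows.append((f.years[iy], f.regions[ik], f.length_classes[il], int(c)))
    pd.DataFrame(
        rel_rows, columns=["tag_year", "tag_region", "length_class", "count"]
    ).to_csv(release_path, index=False)

    rec_rows = []
    for (iy, ik, il, jy, jk), c in np.ndenumerate(dataset.recoveries):
        if c:
            rec_rows.append(
                (f.years[iy], f.regions[ik], f.length_classes[il],
                 f.years[jy], f.regions[jk], int(c))
            )
    pd.DataFrame(
        rec_rows,
        columns=["tag_year", "tag_region", "length_class",
                 "recovery_year", "recovery_region", "count"],
    ).to_csv(recovery_path, index=False)


def write_reporting_rates(rates: ReportingRates, path) -> None:
    f = rates.frame
    rows = [
        (f.years[iy], f.regions[ik], rates.lam[iy, ik])
        for iy in range(f.n_years)
        for ik in range(f.n_regions)
    ]
    pd.DataFrame(rows, columns=["year", "region", "rate"]).to_csv(path, index=False)


def write_age_length_sample(sample: AgeLengthSample, path) -> None:
    f = sample.frame
    rows = []
    for (il, ia), c in np.ndenumerate(sample.n):
        if c:
            rows.append((f.length_classes[il], ia + 1, int(c)))
    pd.DataFrame(rows, columns=["length_class", "age", "count"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged Lake Erie fixtures (printed release/recovery and scanning tables)
# ---------------------------------------------------------------------------

def _fixture_path(name: str) -> Path:
    return Path(resources.files("tagmove") / "fixtures" / name)


def lake_erie_frame() -> StudyFrame:
    """Frame of the Lake Erie yellow perch study: 2009-2015, MU1-MU3, ages 1-6+.

    The packaged tables aggregate over length, so the frame carries a single
    pooled length class.
    """
    return StudyFrame(
        years=tuple(range(2009, 2016)),
        regions=("MU1", "MU2", "MU3"),
        n_ages=6,
        length_classes=("ALL",),
    )


def lake_erie_dataset() -> TagDataset:
    """The published Lake Erie release/recovery counts (13,694 releases)."""
    frame = lake_erie_frame()
    return read_tag_tables(
        _fixture_path("lake_erie_releases.csv"),
        _fixture_path("lake_erie_recoveries.csv"),
        frame,
    )


def lake_erie_reporting_rates() -> ReportingRates:
    """Scanned proportions of the Ontario commercial catch by year and MU."""
    return read_reporting_rates(
        _fixture_path("lake_erie_reporting_rates.csv"), lake_erie_frame()
    )
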