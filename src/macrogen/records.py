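"""Population-diversity records: data model, validation and CSV I/O.

One record is one sampled population of one species under one genetic marker,
carrying a diversity value in [0, 1] (expected heterozygosity H_E for nuclear
markers, haplotype diversity h for mitochondrial ones), the population's
coordinates and bioregion, and the per-population sample size n.  Records are
grouped by ``dataID`` — one study x marker combination — which is the unit of
within-study standardisation and of the minimum-populations filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MARKER_CATEGORIES = (
    "mtDNA_sequence",
    "mtDNA_restriction",
    "allozyme",
    "microsatellite",
    "nuclear_sequence",
    "other",
)

RANKS = ("class", "order", "family", "genus", "species")

#: canonical CSV column names, in file order
COLUMNS = (
    "dataID",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "marker",
    "lat",
    "lon",
    "region",
    "n",
    "H",
)

MIN_SAMPLE_SIZE = 5


class ValidationError(ValueError):
    """Raised when rows violate record invariants; carries row diagnostics."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


class ConfigurationError(ValueError):
    """Raised for malformed input configuration (e.g. missing columns)."""


@dataclass(frozen=True)
class PopulationRecord:
    """A single population's diversity observation.

    ``species_path`` orders the Linnaean labels class, order, family, genus,
    species.  ``diversity`` is H_E or h on [0, 1]; ``sample_size`` is the
    number of individuals genotyped (study inclusion requires n >= 5).
    """

    data_id: str
    species_path: tuple[str, str, str, str, str]
    marker_category: str
    latitude: float
    longitude: float
    region_id: str
    sample_size: int
    diversity: float

    def __post_init__(self) -> None:
        if self.marker_category not in MARKER_CATEGORIES:
            raise ValidationError(
                f"unknown marker category {self.marker_category!r}; "
                f"expected one of {MARKER_CATEGORIES}"
            )
        if not (0.0 <= self.diversity <= 1.0):
            raise ValidationError(f"diversity {self.diversity} outside [0, 1]")
        if self.sample_size < MIN_SAMPLE_SIZE:
            raise ValidationError(
                f"sample size {self.sample_size} below minimum {MIN_SAMPLE_SIZE}"
            )
        if len(self.species_path) != 5 or any(not s for s in self.species_path):
            raise ValidationError("species_path must have all five ranks non-empty")

    @property
    def species(self) -> str:
        return self.species_path[-1]


@dataclass
class DiversityDataset:
    """A validated table of population records with deterministic indices.

    ``regions``, ``species`` and ``data_ids`` are the sorted unique labels;
    sorting makes every downstream design matrix reproducible.
    """

    df: pd.DataFrame
    regions: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    data_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.regions = sorted(self.df["region"].astype(str).unique())
        self.species = sorted(self.df["species"].unique())
        self.data_ids = sorted(self.df["dataID"].unique())

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[PopulationRecord]:
        cols = self.df[list(COLUMNS)]
        out = []
        for did, cls, order, family, genus, sp, marker, lat, lon, region, n, h in (
            cols.itertuples(index=False, name=None)
        ):
            out.append(
                PopulationRecord(
                    data_id=str(did),
                    species_path=(cls, order, family, genus, sp),
                    marker_category=marker,
                    latitude=float(lat),
                    longitude=float(lon),
                    region_id=str(region),
                    sample_size=int(n),
                    diversity=float(h),
                )
            )
        return out

    def species_paths(self) -> list[tuple[str, str, str, str, str]]:
        """One (class, order, family, genus, species) path per unique species."""
        sub = self.df.drop_duplicates("species").sort_values("species")
        return [
            (r["class"], r["order"], r["family"], r["genus"], r["species"])
            for _, r in sub.iterrows()
        ]

    def manifest(self) -> dict:
        """Counts per region / species / marker, for provenance output."""
        return {
            "n_records": int(len(self.df)),
            "n_regions": len(self.regions),
            "n_species": len(self.species),
            "n_data_ids": len(self.data_ids),
            "records_per_region": self.df.groupby("region").size().to_dict(),
            "records_per_marker": self.df.groupby("marker").size().to_dict(),
            "records_per_species": self.df.groupby("species").size().to_dict(),
        }


def _validate_frame(df: pd.DataFrame) -> None:
    bad: dict[str, list[int]] = {}
    h = df["H"].astype(float)
    rows = df.index[(h < 0) | (h > 1) | h.isna()].tolist()
    if rows:
        bad["diversity outside [0, 1]"] = rows
    n = df["n"].astype(float)
    rows = df.index[(n < MIN_SAMPLE_SIZE) | n.isna()].tolist()
    if rows:
        bad[f"sample size below {MIN_SAMPLE_SIZE}"] = rows
    rows = df.index[~df["marker"].isin(MARKER_CATEGORIES)].tolist()
    if rows:
        bad["unknown marker category"] = rows
    for rank in RANKS:
        col = df[rank].astype(str)
        rows = df.index[(col == "") | (col == "nan")].tolist()
        if rows:
            bad.setdefault("empty taxonomic rank", []).extend(rows)
    if bad:
        msgs = [f"{k}: rows {sorted(set(v))}" for k, v in bad.items()]
        all_rows = sorted({r for v in bad.values() for r in v})
        raise ValidationError("invalid records — " + "; ".join(msgs), rows=all_rows)


def read_dataset(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> DiversityDataset:
    """Read a population-records CSV into a validated :class:`DiversityDataset`.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row, one row per population.
    dialect : mapping, optional
        Maps the file's column names to the canonical names in
        :data:`COLUMNS` (e.g. ``{"latitude": "lat"}``).

    Raises
    ------
    ConfigurationError
        If a required column is missing after renaming.
    ValidationError
        If any row violates the record invariants; the error message lists
        the offending 0-based row numbers.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")
    df = df[list(COLUMNS)].copy()
    df["region"] = df["region"].astype(str)
    df["dataID"] = df["dataID"].astype(str)
    _validate_frame(df)
    df["n"] = df["n"].astype(int)
    return DiversityDataset(df)


def write_dataset(ds: DiversityDataset, path: str | Path, manifest: bool = True) -> None:
    """Write the dataset CSV; optionally a JSON manifest next to it."""
    path = Path(path)
    ds.df[list(COLUMNS)].to_csv(path, index=False)
    if manifest:
        with open(path.with_suffix(".manifest.json"), "w") as fh:
            json.dump(ds.manifest(), fh, indent=2, default=int)


def from_frame(df: pd.DataFrame) -> DiversityDataset:
    """Build a validated dataset from an in-memory frame (canonical columns)."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")
    df = df[list(COLUMNS)].copy()
    df["region"] = df["region"].astype(str)
    df["dataID"] = df["dataID"].astype(str)
    _validate_frame(df)
    df["n"] = df["n"].astype(int)
    return DiversityDataset(df)


def filter_regions(
    ds: DiversityDataset,
    keep: Iterable[str],
    min_pops_per_data_id: int = 3,
) -> DiversityDataset:
    """Restrict to a set of regions, then drop under-sampled dataIDs.

    The coastal-only analysis keeps only coastal regions and then requires
    every dataID to retain at least ``min_pops_per_data_id`` populations
    (default 3, the study-inclusion minimum); dataIDs falling below the
    threshold after the regional cut are removed entirely.
    """
    keep = {str(k) for k in keep}
    if not keep:
        raise ValueError("keep must be a non-empty set of region ids")
    sub = ds.df[ds.df["region"].isin(keep)]
    counts = sub.groupby("dataID").size()
    good = counts.index[counts >= min_pops_per_data_id]
    sub = sub[sub["dataID"].isin(good)]
    if len(sub) == 0:
        raise ValueError("no records remain after region filtering")
    return DiversityDataset(sub.copy())


def squeeze_unit_interval(y: float | np.ndarray, n: int | np.ndarray):
    """Map diversity from [0, 1] into the open interval (0, 1).

    Uses the standard compression ``(y * (n - 1) + 0.5) / n`` so the beta
    likelihood (support on the open interval) can absorb boundary values of
    exactly 0 or 1 without discarding them.  Monotone in ``y`` for fixed
    ``n``; 0.5 is a fixed point; interior values move by at most 1/(2n).
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    out = (y * (n - 1.0) + 0.5) / n
    return float(out) if out.ndim == 0 else out
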