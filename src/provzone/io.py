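"""Core data containers and plain-text I/O.

The pipeline's universal genetic input is a binary band-state matrix
(individuals x loci, dominant markers scored 0/1), carried together with
population labels.  Sites are point coordinates in decimal degrees; climate
variables are one numeric row per site.  All tables round-trip through
delimited text (comma or tab, auto-detected), so every artefact the pipeline
reads or writes is human-inspectable.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # internal sentinel for a missing band call
EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cell cannot be interpreted."""


# ---------------------------------------------------------------------------
# MarkerMatrix


@dataclasses.dataclass
class MarkerMatrix:
    """Binary band states per individual x locus with population labels.

    ``bands`` holds 0 (band absent), 1 (band present) or :data:`MISSING`.
    Row order is meaningful and preserved through I/O.
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    bands: np.ndarray  # int8, shape (n_individuals, n_loci)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.int8)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.population_labels = [str(p) for p in self.population_labels]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.bands.shape
        if len(self.individual_ids) != n or len(self.population_labels) != n:
            raise ValidationError("row labels do not match matrix height")
        if len(self.locus_ids) != m:
            raise ValidationError("locus ids do not match matrix width")
        if m == 0:
            raise ValidationError("matrix has no loci")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.locus_ids)) != m:
            raise ValidationError("duplicate locus ids")
        ok = np.isin(self.bands, (0, 1, MISSING))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"invalid band state {self.bands[i, j]} at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        pops = self.populations()
        if len(pops) < 2:
            raise ValidationError("need at least 2 populations")
        labels = np.asarray(self.population_labels)
        for p in pops:
            rows = self.bands[labels == p]
            if (rows != MISSING).any(axis=1).sum() < 2:
                raise ValidationError(f"population {p!r} has <2 scored individuals")

    # -- convenience ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.bands.shape[0]

    @property
    def n_loci(self) -> int:
        return self.bands.shape[1]

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    def population_rows(self, pop: str) -> np.ndarray:
        mask = np.asarray(self.population_labels) == pop
        if not mask.any():
            raise KeyError(pop)
        return self.bands[mask]

    def has_missing(self) -> bool:
        return bool((self.bands == MISSING).any())

    def subset_loci(self, loci: Sequence[str]) -> "MarkerMatrix":
        """Restrict to the listed loci, preserving the given order."""
        loci = list(loci)
        if not loci:
            raise ValidationError("empty locus subset")
        index = {l: j for j, l in enumerate(self.locus_ids)}
        try:
            cols = [index[l] for l in loci]
        except KeyError as exc:
            raise ValidationError(f"unknown locus id {exc.args[0]!r}") from None
        return MarkerMatrix(
            list(self.individual_ids),
            list(self.population_labels),
            loci,
            self.bands[:, cols],
        )

    def subset_populations(self, pops: Sequence[str]) -> "MarkerMatrix":
        pops = set(pops)
        mask = np.asarray([p in pops for p in self.population_labels])
        return MarkerMatrix(
            [i for i, k in zip(self.individual_ids, mask) if k],
            [p for p, k in zip(self.population_labels, mask) if k],
            list(self.locus_ids),
            self.bands[mask],
        )

    def drop_missing(self, max_fraction: float = 0.05) -> "MarkerMatrix":
        """Drop loci, then individuals, whose missingness exceeds ``max_fraction``.

        Any residual missing entries after the two passes are rejected:
        downstream statistics require complete data.
        """
        miss = self.bands == MISSING
        keep_loci = miss.mean(axis=0) <= max_fraction
        bands = self.bands[:, keep_loci]
        keep_ind = (bands == MISSING).mean(axis=1) <= max_fraction
        m = MarkerMatrix(
            [i for i, k in zip(self.individual_ids, keep_ind) if k],
            [p for p, k in zip(self.population_labels, keep_ind) if k],
            [l for l, k in zip(self.locus_ids, keep_loci) if k],
            bands[keep_ind],
        )
        if m.has_missing():
            raise ValidationError(
                "missing entries remain after filtering; raise max_fraction "
                "or clean the input"
            )
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.population_labels == other.population_labels
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.bands, other.bands)
        )


# ---------------------------------------------------------------------------
# SiteTable / ClimateTable


@dataclasses.dataclass
class SiteTable:
    """One row per population: decimal-degree latitude and longitude."""

    table: pd.DataFrame  # columns population, latitude, longitude

    def __post_init__(self) -> None:
        t = self.table
        required = ["population", "latitude", "longitude"]
        if list(t.columns[:3]) != required:
            raise ValidationError(f"site table must start with columns {required}")
        if t["population"].duplicated().any():
            raise ValidationError("duplicate population ids in site table")
        if t[["latitude", "longitude"]].isna().any().any():
            raise ValidationError("missing coordinate values")
        lat, lon = t["latitude"].to_numpy(float), t["longitude"].to_numpy(float)
        if (np.abs(lat) > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        if (np.abs(lon) > 180).any():
            raise ValidationError("longitude outside [-180, 180]")
        self.table = t.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return [str(p) for p in self.table["population"]]

    def coordinates(self) -> np.ndarray:
        return self.table[["latitude", "longitude"]].to_numpy(float)

    def cross_check(self, m: MarkerMatrix) -> None:
        known = set(self.populations)
        unknown = sorted(set(m.populations()) - known)
        if unknown:
            raise ValidationError(f"populations missing from site table: {unknown}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteTable):
            return NotImplemented
        return self.table.equals(other.table)


@dataclasses.dataclass
class ClimateTable:
    """One row per population: named numeric climate variables."""

    table: pd.DataFrame  # column 'population' + one column per variable

    def __post_init__(self) -> None:
        t = self.table
        if t.columns[0] != "population":
            raise ValidationError("climate table must start with 'population'")
        if t.shape[1] < 2:
            raise ValidationError("climate table needs at least one variable")
        if t["population"].duplicated().any():
            raise ValidationError("duplicate population ids in climate table")
        if t.iloc[:, 1:].isna().any().any():
            raise ValidationError("missing climate values")
        self.table = t.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return [str(p) for p in self.table["population"]]

    @property
    def variables(self) -> list[str]:
        return [str(c) for c in self.table.columns[1:]]

    def values(self) -> np.ndarray:
        return self.table.iloc[:, 1:].to_numpy(float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClimateTable):
            return NotImplemented
        return self.table.equals(other.table)


# ---------------------------------------------------------------------------
# DistMatrix


@dataclasses.dataclass
class DistMatrix:
    """Square symmetric dissimilarity matrix with entity labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(l) for l in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("label count does not match matrix dimension")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValidationError("diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("negative dissimilarities")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy 'condensed' (row-major) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistMatrix":
        idx = [self.labels.index(str(l)) for l in labels]
        return DistMatrix([self.labels[i] for i in idx], self.values[np.ix_(idx, idx)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistMatrix):
            return NotImplemented
        return self.labels == other.labels and np.allclose(self.values, other.values)


# ---------------------------------------------------------------------------
# Geographic distance


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of mean Earth radius."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_distance_matrix(sites: SiteTable) -> DistMatrix:
    """Pairwise great-circle distances (km) between all sites."""
    coords = sites.coordinates()
    if coords.shape[0] < 2:
        raise ValidationError("need at least 2 sites")
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    d = haversine_km(lat, lon, lat.T, lon.T)
    np.fill_diagonal(d, 0.0)
    return DistMatrix(sites.populations, d)


# ---------------------------------------------------------------------------
# Delimited-text I/O (comma or tab auto-detected from the header line)


def _sniff_sep(path: Path) -> str:
    header = Path(path).read_text(encoding="utf-8").splitlines()[0]
    return "\t" if "\t" in header else ","


def read_marker_matrix(path, missing_code: str = "NA") -> MarkerMatrix:
    """Read a genotype table: individual, population, then one 0/1 column per locus."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ParseError("genotype file needs individual, population and >=1 locus column")
    locus_ids = [str(c) for c in df.columns[2:]]
    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    bands = np.empty(raw.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell == missing_code:
            bands[i, j] = MISSING
        elif cell in ("0", "1"):
            bands[i, j] = int(cell)
        else:
            raise ParseError(
                f"invalid band value {cell!r} at row {i + 2} (individual "
                f"{df.iloc[i, 0]!r}), column {locus_ids[j]!r}"
            )
    return MarkerMatrix(
        list(df.iloc[:, 0].astype(str)), list(df.iloc[:, 1].astype(str)), locus_ids, bands
    )


def write_marker_matrix(m: MarkerMatrix, path, missing_code: str = "NA") -> Path:
    m.validate()
    path = Path(path)
    cells = m.bands.astype(object)
    cells[m.bands == MISSING] = missing_code
    df = pd.DataFrame(cells, columns=m.locus_ids)
    df.insert(0, "population", m.population_labels)
    df.insert(0, "individual", m.individual_ids)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_site_table(path) -> SiteTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [str(c).strip() for c in df.columns]
    df["population"] = df["population"].astype(str)
    return SiteTable(df)


def write_site_table(s: SiteTable, path) -> Path:
    path = Path(path)
    s.table.to_csv(path, index=False, lineterminator="\n")
    return path


def read_climate_table(path) -> ClimateTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [str(c).strip() for c in df.columns]
    df["population"] = df["population"].astype(str)
    return ClimateTable(df)


def write_climate_table(c: ClimateTable, path) -> Path:
    path = Path(path)
    c.table.to_csv(path, index=False, lineterminator="\n")
    return path


def read_dist_matrix(path) -> DistMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    return DistMatrix([str(c) for c in df.columns], df.to_numpy(float))


def write_dist_matrix(d: DistMatrix, path) -> Path:
    path = Path(path)
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(
        path, lineterminator="\n"
    )
    return path
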