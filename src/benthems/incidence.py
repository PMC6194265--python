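"""Binary site-by-species incidence matrices: data model, validation, I/O.

The incidence matrix is the universal currency of the analysis: rows are
sampling sites, columns are species, cells are 0/1 occurrence. Site and
species metadata travel in separate tables keyed on the row/column labels.
Cross-period comparisons additionally need taxonomic harmonization, handled
here by a static synonym table (recorded name -> accepted name) so the
pipeline never depends on a live taxonomy service.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "SiteRecord",
    "SpeciesRecord",
    "DegenerateMatrixError",
    "read_incidence",
    "write_incidence",
    "read_site_records",
    "read_species_records",
    "read_synonym_table",
    "harmonize",
    "shared_species",
    "drop_empty",
]

TAXON_GROUPS = (
    "Polychaeta",
    "Peracarida",
    "Bivalvia",
    "Gastropoda",
    "Decapoda",
    "Echinodermata",
    "Other",
)
SIZE_CLASSES = ("S", "M", "L")
POSITION_CLASSES = ("emergent_semiemergent", "infauna")


class DegenerateMatrixError(ValueError):
    """Raised when an operation would leave zero sites or zero species."""


@dataclass(frozen=True)
class SiteRecord:
    """One sampling site: label, water depth (m, > 0), period label."""

    site_id: str
    depth_m: float
    period: str = ""
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if not self.depth_m > 0:
            raise ValueError(f"site {self.site_id!r}: depth_m must be > 0, got {self.depth_m}")


@dataclass(frozen=True)
class SpeciesRecord:
    """Species-level traits used by the trawling-sensitivity cross-tabulations."""

    species_id: str
    taxon_group: str = "Other"
    size_class: str = "M"
    position_class: str = "infauna"

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon_group {self.taxon_group!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size_class {self.size_class!r}")
        if self.position_class not in POSITION_CLASSES:
            raise ValueError(f"unknown position_class {self.position_class!r}")


@dataclass
class IncidenceMatrix:
    """Validated binary sites x species occurrence table.

    ``values[i, j]`` is 1 when species ``species_ids[j]`` was recorded at
    site ``site_ids[i]``. Labels are unique and order is meaningful (it is
    the tie-break everywhere downstream).
    """

    site_ids: list[str]
    species_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if not np.isin(v, (0, 1)).all():
            bad = v[~np.isin(v, (0, 1))][0]
            raise ValueError(f"non-binary cell value {bad!r}")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site labels")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species labels")
        self.values = v.astype(np.int8)

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total_presences(self) -> int:
        return int(self.values.sum())

    def site_richness(self) -> np.ndarray:
        """Row sums: species count per site."""
        return self.values.sum(axis=1)

    def species_prevalence(self) -> np.ndarray:
        """Column sums: occupied-site count per species."""
        return self.values.sum(axis=0)

    def present_species(self) -> set[str]:
        """Species recorded at at least one site."""
        keep = self.values.sum(axis=0) > 0
        return {s for s, k in zip(self.species_ids, keep) if k}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.site_ids, name="site_id"), columns=self.species_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IncidenceMatrix":
        return cls(
            site_ids=[str(i) for i in frame.index],
            species_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(),
        )

    def subset_sites(self, site_ids: Sequence[str]) -> "IncidenceMatrix":
        idx = {s: i for i, s in enumerate(self.site_ids)}
        rows = [idx[s] for s in site_ids]
        return IncidenceMatrix(list(site_ids), list(self.species_ids), self.values[rows])

    def copy(self) -> "IncidenceMatrix":
        return IncidenceMatrix(list(self.site_ids), list(self.species_ids), self.values.copy())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_incidence(
    path: str | Path, site_meta_path: str | Path | None = None
) -> IncidenceMatrix | tuple[IncidenceMatrix, list[SiteRecord]]:
    """Read a wide incidence CSV (header = species, first column = site ids).

    Cell values must be 0 or 1; anything else is an error. If
    ``site_meta_path`` is given, the site metadata CSV is read alongside and
    must cover every site in the matrix; a ``(matrix, records)`` pair is
    returned (records in matrix row order).
    """
    frame = pd.read_csv(path, index_col=0)
    matrix = IncidenceMatrix.from_frame(frame)
    if site_meta_path is None:
        return matrix
    records = read_site_records(site_meta_path)
    by_id = {r.site_id: r for r in records}
    missing = [s for s in matrix.site_ids if s not in by_id]
    if missing:
        raise ValueError(f"site metadata missing for sites: {missing}")
    return matrix, [by_id[s] for s in matrix.site_ids]


def write_incidence(matrix: IncidenceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def read_site_records(path: str | Path) -> list[SiteRecord]:
    """Site metadata CSV: site_id, depth_m, period[, lat, lon]."""
    df = pd.read_csv(path, dtype={"site_id": str})
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SiteRecord(
                site_id=str(d["site_id"]),
                depth_m=float(d["depth_m"]),
                period=str(d.get("period", "") or ""),
                lat=float(d["lat"]) if "lat" in d and pd.notna(d["lat"]) else None,
                lon=float(d["lon"]) if "lon" in d and pd.notna(d["lon"]) else None,
            )
        )
    seen: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.period, r.site_id)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] > 1:
            raise ValueError(f"duplicate site {r.site_id!r} within period {r.period!r}")
    return records


def read_species_records(path: str | Path) -> list[SpeciesRecord]:
    """Species metadata CSV: species_id, taxon_group, size_class, position_class."""
    df = pd.read_csv(path, dtype=str)
    return [
        SpeciesRecord(
            species_id=str(r["species_id"]),
            taxon_group=str(r.get("taxon_group", "Other")),
            size_class=str(r.get("size_class", "M")),
            position_class=str(r.get("position_class", "infauna")),
        )
        for r in df.to_dict("records")
    ]


def read_synonym_table(path: str | Path) -> dict[str, str]:
    """Synonym CSV (recorded_name, accepted_name) -> mapping dict.

    The mapping must be a function: a recorded name may appear only once.
    """
    df = pd.read_csv(path, dtype=str)
    if df["recorded_name"].duplicated().any():
        dup = df["recorded_name"][df["recorded_name"].duplicated()].iloc[0]
        raise ValueError(f"recorded name {dup!r} mapped more than once")
    return dict(zip(df["recorded_name"], df["accepted_name"]))


# ---------------------------------------------------------------------------
# Harmonization and species accounting
# ---------------------------------------------------------------------------

def harmonize(matrix: IncidenceMatrix, synonyms: Mapping[str, str]) -> IncidenceMatrix:
    """Rename species per the synonym table and OR-merge columns that collapse
    onto the same accepted name. Names absent from the table pass through.
    Output species order: first appearance of each accepted name.
    """
    accepted = [synonyms.get(s, s) for s in matrix.species_ids]
    order: list[str] = []
    cols: dict[str, np.ndarray] = {}
    for name, col in zip(accepted, matrix.values.T):
        if name in cols:
            cols[name] = cols[name] | col
        else:
            order.append(name)
            cols[name] = col.copy()
    values = np.column_stack([cols[n] for n in order]) if order else np.zeros((matrix.n_sites, 0), np.int8)
    return IncidenceMatrix(list(matrix.site_ids), order, values)


def shared_species(
    matrix_old: IncidenceMatrix, *matrices_recent: IncidenceMatrix
) -> dict[str, object]:
    """Species overlap between an old-period matrix and recent matrices.

    A species counts as present in a matrix only if it occupies >= 1 site.
    ``shared`` is present in old AND in at least one recent matrix;
    turnover = 1 - |shared| / |union of old and recent|.
    """
    old = matrix_old.present_species()
    recent: set[str] = set()
    for m in matrices_recent:
        recent |= m.present_species()
    shared = old & recent
    union = old | recent
    return {
        "shared": shared,
        "old_only": old - recent,
        "recent_only": recent - old,
        "n_old": len(old),
        "n_recent": len(recent),
        "n_shared": len(shared),
        "n_union": len(union),
        "turnover": 1.0 - len(shared) / len(union) if union else 0.0,
    }


def drop_empty(
    matrix: IncidenceMatrix, which: Literal["species", "sites", "both"] = "species"
) -> IncidenceMatrix:
    """Remove all-zero columns and/or rows, preserving survivor order.

    Raises :class:`DegenerateMatrixError` if nothing survives on a dropped
    axis.
    """
    values = matrix.values
    site_ids, species_ids = matrix.site_ids, matrix.species_ids
    if which in ("species", "both"):
        keep = values.sum(axis=0) > 0
        if not keep.any():
            raise DegenerateMatrixError("no non-empty species remain")
        values = values[:, keep]
        species_ids = [s for s, k in zip(species_ids, keep) if k]
    if which in ("sites", "both"):
        keep = values.sum(axis=1) > 0
        if not keep.any():
            raise DegenerateMatrixError("no non-empty sites remain")
        values = values[keep]
        site_ids = [s for s, k in zip(site_ids, keep) if k]
    return IncidenceMatrix(list(site_ids), list(species_ids), values)


def restrict_to_species(matrix: IncidenceMatrix, species: Iterable[str]) -> IncidenceMatrix:
    """Column subset in matrix order; silently ignores unknown names."""
    wanted = set(species)
    keep = [j for j, s in enumerate(matrix.species_ids) if s in wanted]
    return IncidenceMatrix(
        list(matrix.site_ids), [matrix.species_ids[j] for j in keep], matrix.values[:, keep]
    )
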