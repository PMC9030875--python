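"""Reference table of plankton cell sizes and suspension densities.

The package ships a literature-derived table of representative marine
phytoplankton and heterotrophic bacterioplankton taxa: for each habitat class
(oligotrophic, mesotrophic, eutrophic, or within a phytoplankton colony) it
records a taxon, its metabolism, a representative cell radius in µm and a cell
suspension density in cells m⁻³. Densities are kept in cells m⁻³ everywhere;
conversion to cells mm⁻³ happens only inside computations, which avoids silent
10⁹-fold unit mistakes.

Duplicate taxon × habitat rows coming from different literature sources are
retained as distinct records, disambiguated by ``source_citation``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "HABITATS",
    "METABOLISMS",
    "TaxonRecord",
    "Community",
    "load_builtin_table",
    "read_community",
    "write_community",
]

HABITATS = ("oligotrophic", "mesotrophic", "eutrophic", "colony")
METABOLISMS = ("phototroph", "heterotroph")

# Common shorthand found in the source literature.
_METABOLISM_ALIASES = {
    "phyto": "phototroph",
    "phototroph": "phototroph",
    "hetero": "heterotroph",
    "heterotroph": "heterotroph",
}

_CSV_COLUMNS = ["habitat", "taxon", "metabolism", "cells_per_m3", "cell_radius_um", "citation"]


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon × habitat entry of the reference table.

    Parameters
    ----------
    taxon_name
        Taxon label (need not be unique across records).
    habitat
        One of :data:`HABITATS`.
    metabolism
        ``"phototroph"`` (net H₂O₂ source) or ``"heterotroph"`` (net sink).
    cell_radius_um
        Cell radius in µm; must be positive.
    cells_per_m3
        Suspension density in cells m⁻³; must be positive.
    source_citation
        Free-text source label; distinguishes duplicate rows.
    """

    taxon_name: str
    habitat: str
    metabolism: str
    cell_radius_um: float
    cells_per_m3: float
    source_citation: str = ""

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValidationError(f"unknown habitat {self.habitat!r}; expected one of {HABITATS}")
        if self.metabolism not in METABOLISMS:
            raise ValidationError(
                f"unknown metabolism {self.metabolism!r}; expected one of {METABOLISMS}"
            )
        if not (self.cell_radius_um > 0 and math.isfinite(self.cell_radius_um)):
            raise ValidationError(f"cell_radius_um must be positive, got {self.cell_radius_um}")
        if not (self.cells_per_m3 > 0 and math.isfinite(self.cells_per_m3)):
            raise ValidationError(f"cells_per_m3 must be positive, got {self.cells_per_m3}")


@dataclass
class Community:
    """Ordered collection of :class:`TaxonRecord`; may be empty."""

    records: list[TaxonRecord] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> TaxonRecord:
        return self.records[i]

    def filter(
        self,
        habitat: str | None = None,
        metabolism: str | None = None,
        taxon: str | None = None,
    ) -> "Community":
        """Return the sub-community matching all given criteria."""
        recs = [
            r
            for r in self.records
            if (habitat is None or r.habitat == habitat)
            and (metabolism is None or r.metabolism == metabolism)
            and (taxon is None or r.taxon_name == taxon)
        ]
        parts = [p for p in (self.label, habitat, metabolism, taxon) if p]
        return Community(recs, label="/".join(parts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "habitat": [r.habitat for r in self.records],
                "taxon": [r.taxon_name for r in self.records],
                "metabolism": [r.metabolism for r in self.records],
                "cells_per_m3": [r.cells_per_m3 for r in self.records],
                "cell_radius_um": [r.cell_radius_um for r in self.records],
                "citation": [r.source_citation for r in self.records],
            }
        )


def _records_from_frame(df: pd.DataFrame, source: str) -> list[TaxonRecord]:
    missing = [c for c in _CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        metabolism = _METABOLISM_ALIASES.get(str(row.metabolism).strip().lower())
        if metabolism is None:
            raise ValidationError(f"{source}, row {i}: unknown metabolism {row.metabolism!r}")
        try:
            records.append(
                TaxonRecord(
                    taxon_name=str(row.taxon),
                    habitat=str(row.habitat).strip().lower(),
                    metabolism=metabolism,
                    cell_radius_um=float(row.cell_radius_um),
                    cells_per_m3=float(row.cells_per_m3),
                    source_citation="" if not hasattr(row, "citation") else str(row.citation),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{source}, row {i}: {err}") from err
    return records


def load_builtin_table() -> Community:
    """Load the packaged reference table of taxa × habitat parameters."""
    with resources.files("rosphere.data").joinpath("reference_communities.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"citation": str})
    return Community(_records_from_frame(df, "builtin table"), label="builtin")


def read_community(path: str | Path, format: str = "csv") -> Community:
    """Read a community table from a CSV with the packaged schema.

    The header must contain ``habitat, taxon, metabolism, cells_per_m3,
    cell_radius_um`` (a ``citation`` column is optional). Scientific notation
    is accepted for the numeric fields.
    """
    if format != "csv":
        raise ValidationError(f"unsupported format {format!r}; only 'csv' is available")
    path = Path(path)
    df = pd.read_csv(path, dtype={"citation": str}, keep_default_na=False)
    return Community(_records_from_frame(df, str(path)), label=path.stem)


def write_community(community: Community, path: str | Path) -> None:
    """Write a community to CSV; :func:`read_community` inverts it."""
    community.to_frame().to_csv(path, index=False)


def with_density(record: TaxonRecord, cells_per_m3: float) -> TaxonRecord:
    """Copy of ``record`` at a different suspension density."""
    return replace(record, cells_per_m3=cells_per_m3)
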