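"""Domain types and I/O for presence–absence biogeography data.

The package works from a single binary species × geographic-unit matrix
(Operational Taxonomic Units × Operational Geographical Units).  Sites are
compared over species (Q-mode) and species over sites (R-mode) by
transposition at the analysis layer; species are always the canonical rows
here.

Packaged fixtures hold the Venezuelan marsupial study data: the 33-species ×
15-sub-region presence–absence matrix and the four climatic/altitudinal
variables (MA, MDP, TR, ME) per sub-region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import Dendrogram

__all__ = [
    "PresenceAbsenceTable",
    "EnvironmentTable",
    "ENV_VARIABLES",
    "read_presence_absence",
    "read_environment",
    "write_presence_absence",
    "load_fixture",
    "FIXTURES",
    "to_newick",
    "write_newick",
]

#: Environmental variables: mean altitude (m), mean precipitation of the
#: driest month (mm), temperature range (°C), mean evapotranspiration (mm).
ENV_VARIABLES = ("MA", "MDP", "TR", "ME")

FIXTURES = ("venezuela_marsupials_pa", "venezuela_env")


class TableValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass(frozen=True)
class PresenceAbsenceTable:
    """Binary species × geographic-unit matrix with labels.

    Parameters
    ----------
    species_labels : tuple of str
        Row labels (taxa).  Must be unique.
    unit_labels : tuple of str
        Column labels (geographic units).  Must be unique.
    cells : ndarray of shape (n_species, n_units)
        0/1 occurrence matrix.

    Notes
    -----
    A species recorded nowhere (all-zero row) is rejected: similarity of two
    empty occurrence vectors is undefined under the Baroni-Urbani & Buser
    index.  An all-zero unit column is allowed with a warning — a unit may
    simply lack the taxon group, and similarity with ``c = 0`` is well
    defined (zero).
    """

    species_labels: tuple[str, ...]
    unit_labels: tuple[str, ...]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int8)
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "species_labels", tuple(self.species_labels))
        object.__setattr__(self, "unit_labels", tuple(self.unit_labels))
        if cells.ndim != 2 or cells.shape != (len(self.species_labels), len(self.unit_labels)):
            raise TableValidationError(
                f"cell matrix shape {cells.shape} does not match "
                f"{len(self.species_labels)} species x {len(self.unit_labels)} units"
            )
        if not np.isin(cells, (0, 1)).all():
            raise TableValidationError("cells must be exactly 0 or 1")
        for kind, labels in (("species", self.species_labels), ("unit", self.unit_labels)):
            if len(set(labels)) != len(labels):
                dupes = sorted({l for l in labels if list(labels).count(l) > 1})
                raise TableValidationError(f"duplicate {kind} labels: {dupes}")
        zero_rows = np.flatnonzero(cells.sum(axis=1) == 0)
        if zero_rows.size:
            names = [self.species_labels[i] for i in zero_rows]
            raise TableValidationError(
                f"species with no recorded presence are not allowed: {names}"
            )
        zero_cols = np.flatnonzero(cells.sum(axis=0) == 0)
        if zero_cols.size:
            names = [self.unit_labels[i] for i in zero_cols]
            warnings.warn(f"units with no recorded species: {names}", stacklevel=3)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    @property
    def n_units(self) -> int:
        return len(self.unit_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells.copy(), index=list(self.species_labels), columns=list(self.unit_labels)
        )

    def column_sums(self) -> pd.Series:
        """Species richness per geographic unit."""
        return self.to_frame().sum(axis=0)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceAbsenceTable":
        return cls(
            species_labels=tuple(str(i) for i in frame.index),
            unit_labels=tuple(str(c) for c in frame.columns),
            cells=frame.to_numpy(),
        )


@dataclass(frozen=True)
class EnvironmentTable:
    """Geographic units × environmental variables (MA, MDP, TR, ME)."""

    unit_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    variables: tuple[str, ...] = ENV_VARIABLES

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "unit_labels", tuple(self.unit_labels))
        object.__setattr__(self, "variables", tuple(self.variables))
        if vals.shape != (len(self.unit_labels), len(self.variables)):
            raise TableValidationError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(self.unit_labels)} units x {len(self.variables)} variables"
            )
        if len(set(self.unit_labels)) != len(self.unit_labels):
            raise TableValidationError("duplicate unit labels")
        if not np.isfinite(vals).all():
            raise TableValidationError("environmental values must be finite")
        if (vals < 0).any():
            raise TableValidationError("environmental values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.unit_labels), columns=list(self.variables)
        )

    def aligned_to(self, unit_labels: Iterable[str]) -> "EnvironmentTable":
        """Reorder rows to match ``unit_labels``; labels must agree as sets."""
        wanted = list(unit_labels)
        if set(wanted) != set(self.unit_labels):
            missing = sorted(set(wanted) - set(self.unit_labels))
            extra = sorted(set(self.unit_labels) - set(wanted))
            raise TableValidationError(
                f"unit labels do not match (missing={missing}, extra={extra})"
            )
        frame = self.to_frame().loc[wanted]
        return EnvironmentTable(tuple(wanted), frame.to_numpy(), self.variables)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EnvironmentTable":
        return cls(
            unit_labels=tuple(str(i) for i in frame.index),
            values=frame.to_numpy(dtype=float),
            variables=tuple(str(c) for c in frame.columns),
        )


def read_presence_absence(path, orientation: str = "species_rows") -> PresenceAbsenceTable:
    """Read a labelled binary CSV matrix.

    The first row holds column labels and the first column row labels.  With
    ``orientation="units_rows"`` the matrix is transposed after reading so
    species end up as rows.
    """
    if orientation not in ("species_rows", "units_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    frame = pd.read_csv(path, index_col=0)
    for col in frame.columns:
        bad = frame.index[~frame[col].isin((0, 1))]
        if len(bad):
            raise TableValidationError(
                f"non-binary cell at row {bad[0]!r}, column {col!r}: "
                f"{frame.loc[bad[0], col]!r}"
            )
    if orientation == "units_rows":
        frame = frame.T
    return PresenceAbsenceTable.from_frame(frame)


def write_presence_absence(table: PresenceAbsenceTable, path) -> None:
    table.to_frame().to_csv(path, index_label="species")


def read_environment(path) -> EnvironmentTable:
    frame = pd.read_csv(path, index_col=0)
    return EnvironmentTable.from_frame(frame)


def load_fixture(name: str) -> PresenceAbsenceTable | EnvironmentTable:
    """Load a packaged study table.

    ``venezuela_marsupials_pa`` — presence/absence of 33 marsupial species in
    15 Venezuelan physiographical sub-regions.  ``venezuela_env`` — the four
    environmental variables for the same sub-regions.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = resources.files("chorotypes.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        if name == "venezuela_marsupials_pa":
            return read_presence_absence(path)
        return read_environment(path)


def _quote(label: str) -> str:
    if any(ch in label for ch in " \t(),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: "Dendrogram") -> str:
    """Serialize a dendrogram so leaf-to-node path lengths equal cophenetic
    heights (root-to-leaf distance = root merge height)."""
    if not tree.nodes:
        return _quote(tree.leaves[0]) + ";"

    leaf_ids = {i: lab for i, lab in enumerate(tree.leaves)}
    nodes = {n.id: n for n in tree.nodes}

    def render(node_id: int, parent_height: float) -> str:
        if node_id in leaf_ids:
            return f"{_quote(leaf_ids[node_id])}:{parent_height:.10g}"
        node = nodes[node_id]
        inner = ",".join(render(c, node.height) for c in (node.left, node.right))
        return f"({inner}):{parent_height - node.height:.10g}"

    root = tree.nodes[-1]
    inner = ",".join(render(c, root.height) for c in (root.left, root.right))
    return f"({inner});"


def write_newick(tree: "Dendrogram", path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree) + "\n")
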