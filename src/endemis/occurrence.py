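"""Site-by-taxon occurrence matrices, grid utilities and dataset refinement.

The elementary spatial unit (operational geographic unit, OGU) is a grid
cell; in the intended use these are Quarter Degree Squares (QDS), 15' x 15'
longitude-latitude cells identified by a degree-square code plus two
quadrant letters, e.g. ``3318CB``. Taxon range size is the number of cells a
taxon occupies in the *full* input matrix; ranges are computed once, when
the matrix is read, and deliberately never recomputed after cells are
dropped, because range-size weighting must reflect full ranges.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ParseError, ValidationError

__all__ = [
    "OccurrenceMatrix",
    "CellGrid",
    "RefinementReport",
    "read_occurrence",
    "write_occurrence",
    "read_adjacency",
    "write_adjacency",
    "parse_qds",
    "qds_centroid",
    "qds_adjacency",
    "refine_cells",
    "flag_clustering_taxa",
]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceMatrix:
    """Binary incidence of taxa over cells, with full-range metadata.

    ``range_sizes`` maps every taxon to its occupancy in the full input
    matrix; on a freshly read matrix it equals the column sums, and it is
    carried unchanged through any later subsetting.
    """

    cells: list
    taxa: list
    incidence: np.ndarray
    range_sizes: dict

    def __post_init__(self) -> None:
        self.cells = [str(c) for c in self.cells]
        self.taxa = [str(t) for t in self.taxa]
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.cells), len(self.taxa)):
            raise ValidationError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.cells)} cells x {len(self.taxa)} taxa"
            )
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        self.incidence = self.incidence.astype(np.int8)
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon ids")
        missing = [t for t in self.taxa if t not in self.range_sizes]
        if missing:
            raise ValidationError(f"range_sizes missing for taxa: {missing[:5]}")
        bad = [t for t in self.taxa if self.range_sizes[t] < 1]
        if bad:
            raise ValidationError(f"taxa with range < 1: {bad[:5]}")
        self._cell_index = {c: i for i, c in enumerate(self.cells)}
        self._taxon_index = {t: j for j, t in enumerate(self.taxa)}

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_incidence(cls, cells: Sequence, taxa: Sequence, incidence) -> "OccurrenceMatrix":
        """Build from a full matrix; ranges are the column sums."""
        incidence = np.asarray(incidence)
        ranges = {str(t): int(s) for t, s in zip(taxa, incidence.sum(axis=0))}
        empty = [t for t, s in ranges.items() if s == 0]
        if empty:
            raise ValidationError(f"taxa with no occurrences: {empty[:5]}")
        return cls(list(cells), list(taxa), incidence, ranges)

    @classmethod
    def from_records(cls, pairs: Iterable[tuple]) -> "OccurrenceMatrix":
        """Build from (cell, taxon) pairs; duplicates are collapsed."""
        seen = set()
        uniq = []
        for cell, taxon in pairs:
            cell, taxon = str(cell), str(taxon)
            if (cell, taxon) in seen:
                continue
            seen.add((cell, taxon))
            uniq.append((cell, taxon))
        cells = list(dict.fromkeys(c for c, _ in uniq))
        taxa = list(dict.fromkeys(t for _, t in uniq))
        ci = {c: i for i, c in enumerate(cells)}
        ti = {t: j for j, t in enumerate(taxa)}
        inc = np.zeros((len(cells), len(taxa)), dtype=np.int8)
        for cell, taxon in uniq:
            inc[ci[cell], ti[taxon]] = 1
        return cls.from_incidence(cells, taxa, inc)

    # -- accessors ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.incidence.shape

    def cell_row(self, cell: str) -> np.ndarray:
        try:
            return self.incidence[self._cell_index[cell]]
        except KeyError:
            raise ValidationError(f"unknown cell: {cell!r}") from None

    def taxa_of_cell(self, cell: str) -> set:
        row = self.cell_row(cell)
        return {self.taxa[j] for j in np.flatnonzero(row)}

    def cells_of_taxon(self, taxon: str) -> set:
        try:
            col = self.incidence[:, self._taxon_index[taxon]]
        except KeyError:
            raise ValidationError(f"unknown taxon: {taxon!r}") from None
        return {self.cells[i] for i in np.flatnonzero(col)}

    def range_vector(self) -> np.ndarray:
        """Full range sizes in taxon order."""
        return np.array([self.range_sizes[t] for t in self.taxa])

    def subset(self, cells: Optional[Sequence] = None,
               taxa: Optional[Sequence] = None) -> "OccurrenceMatrix":
        """Restrict to the given cells/taxa, keeping *full* range sizes."""
        cell_keep = self.cells if cells is None else [c for c in self.cells if c in set(map(str, cells))]
        taxon_keep = self.taxa if taxa is None else [t for t in self.taxa if t in set(map(str, taxa))]
        ri = [self._cell_index[c] for c in cell_keep]
        cj = [self._taxon_index[t] for t in taxon_keep]
        inc = self.incidence[np.ix_(ri, cj)]
        ranges = {t: self.range_sizes[t] for t in taxon_keep}
        return OccurrenceMatrix(cell_keep, taxon_keep, inc, ranges)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=pd.Index(self.cells, name="cell"),
                            columns=self.taxa)


@dataclass
class CellGrid:
    """Spatial neighbourhood of cells.

    ``adjacency`` is symmetric and irreflexive; ``coordinates`` optionally
    gives (lon, lat) cell centroids.
    """

    adjacency: dict
    coordinates: Optional[dict] = None

    def __post_init__(self) -> None:
        for a, nbrs in self.adjacency.items():
            if a in nbrs:
                raise ValidationError(f"cell {a!r} adjacent to itself")
            for b in nbrs:
                if a not in self.adjacency.get(b, set()):
                    raise ValidationError(f"asymmetric adjacency: {a!r} -> {b!r}")

    def neighbours(self, cell: str) -> set:
        return set(self.adjacency.get(cell, set()))


@dataclass
class RefinementReport:
    """Outcome of the dataset refinement filters.

    ``dropped_cells`` maps each dropped cell to a tuple of reason codes;
    ``singleton_taxa`` (range 1) are flagged for exclusion from weighting
    and clustering but are retained in the matrix for endemism accounting.
    """

    kept_cells: set = field(default_factory=set)
    dropped_cells: dict = field(default_factory=dict)
    clustering_taxa: set = field(default_factory=set)
    singleton_taxa: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# File I/O (wide CSV is canonical; long CSV accepted)
# ---------------------------------------------------------------------------

def read_occurrence(path, format: str = "wide") -> OccurrenceMatrix:
    """Read a binary site-by-taxon matrix from CSV.

    Wide format: first column ``cell``, remaining headers are taxon ids and
    the body is 0/1. Long format: two columns ``cell,taxon``, one record per
    occurrence (duplicates collapsed). Ranges are column sums of the matrix
    as read.
    """
    path = Path(path)
    if format == "wide":
        df = pd.read_csv(path, dtype={0: str})
        if df.shape[1] < 2:
            raise ParseError(f"{path}: wide matrix needs a cell column plus taxa")
        df = df.set_index(df.columns[0])
        body = df.to_numpy()
        bad = ~np.isin(body, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"{path}: non-binary value {body[i, j]!r} at line {i + 2}, "
                f"column {df.columns[j]!r}"
            )
        return OccurrenceMatrix.from_incidence(list(df.index), list(df.columns), body)
    if format == "long":
        df = pd.read_csv(path, dtype=str)
        cols = [c.strip().lower() for c in df.columns]
        if cols[:2] != ["cell", "taxon"]:
            raise ParseError(f"{path}: long format needs headers 'cell,taxon'")
        bad = df.index[df.iloc[:, 0].isna() | df.iloc[:, 1].isna()]
        if len(bad):
            raise ParseError(f"{path}: malformed row at line {bad[0] + 2}")
        return OccurrenceMatrix.from_records(
            zip(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist()))
    raise ConfigurationError(f"unknown format {format!r}; use 'wide' or 'long'")


def write_occurrence(m: OccurrenceMatrix, path, format: str = "wide") -> None:
    path = Path(path)
    if format == "wide":
        m.to_dataframe().to_csv(path)
    elif format == "long":
        rows = [(c, t) for c in m.cells for t in sorted(m.taxa_of_cell(c))]
        pd.DataFrame(rows, columns=["cell", "taxon"]).to_csv(path, index=False)
    else:
        raise ConfigurationError(f"unknown format {format!r}; use 'wide' or 'long'")


def read_adjacency(path, coordinates: Optional[dict] = None) -> CellGrid:
    """Read an undirected adjacency CSV with headers ``cell_a,cell_b``."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["cell_a", "cell_b"]:
        raise ParseError(f"{path}: adjacency CSV needs headers 'cell_a,cell_b'")
    adj: dict = {}
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = str(a), str(b)
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return CellGrid(adjacency=adj, coordinates=coordinates)


def write_adjacency(grid: CellGrid, path) -> None:
    rows = []
    for a in sorted(grid.adjacency):
        for b in sorted(grid.adjacency[a]):
            if a < b:
                rows.append((a, b))
    pd.DataFrame(rows, columns=["cell_a", "cell_b"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QDS grid utilities
# ---------------------------------------------------------------------------

_QDS_RE = re.compile(r"^(\d{2})(\d{2})([A-D])([A-D])$")

# quadrant letters: A=NW, B=NE, C=SW, D=SE, applied twice (half-degree, then
# quarter-degree within the half)
_ROW_OFFSET = {"A": 0, "B": 0, "C": 1, "D": 1}
_COL_OFFSET = {"A": 0, "B": 1, "C": 0, "D": 1}


def parse_qds(code: str) -> tuple:
    """Parse a QDS code into global quarter-degree (row, col) indices.

    Rows count southward (codes are treated as southern-hemisphere, the
    convention of the grid this scheme comes from), columns eastward.
    """
    mobj = _QDS_RE.match(str(code).strip().upper())
    if mobj is None:
        raise FormatError(f"invalid QDS code: {code!r}")
    lat_deg, lon_deg, l1, l2 = int(mobj.group(1)), int(mobj.group(2)), mobj.group(3), mobj.group(4)
    row = 4 * lat_deg + 2 * _ROW_OFFSET[l1] + _ROW_OFFSET[l2]
    col = 4 * lon_deg + 2 * _COL_OFFSET[l1] + _COL_OFFSET[l2]
    return row, col


def qds_code(row: int, col: int) -> str:
    """Inverse of :func:`parse_qds`."""
    lat_deg, r = divmod(row, 4)
    lon_deg, c = divmod(col, 4)
    first = {(0, 0): "A", (0, 1): "B", (1, 0): "C", (1, 1): "D"}[(r // 2, c // 2)]
    second = {(0, 0): "A", (0, 1): "B", (1, 0): "C", (1, 1): "D"}[(r % 2, c % 2)]
    return f"{lat_deg:02d}{lon_deg:02d}{first}{second}"


def qds_centroid(code: str) -> tuple:
    """(lon, lat) centroid of a QDS cell; latitudes are southern (negative)."""
    row, col = parse_qds(code)
    lon = (col + 0.5) * 0.25
    lat = -((row + 0.5) * 0.25)
    return lon, lat


def qds_adjacency(cell_ids: Sequence[str], scheme: str = "queen") -> CellGrid:
    """Neighbourhood of quarter-degree cells.

    ``rook`` joins cells sharing an edge; ``queen`` (the default) also joins
    cells sharing only a corner.
    """
    if scheme not in ("rook", "queen"):
        raise ConfigurationError(f"unknown adjacency scheme {scheme!r}")
    bad = []
    pos = {}
    for cid in cell_ids:
        try:
            pos[str(cid)] = parse_qds(cid)
        except FormatError:
            bad.append(str(cid))
    if bad:
        raise FormatError(f"invalid QDS codes: {bad}")
    by_rc = {rc: cid for cid, rc in pos.items()}
    adj = {cid: set() for cid in pos}
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for cid, (r, c) in pos.items():
        for dr, dc in offsets:
            nbr = by_rc.get((r + dr, c + dc))
            if nbr is not None:
                adj[cid].add(nbr)
    coords = {cid: qds_centroid(cid) for cid in pos}
    return CellGrid(adjacency=adj, coordinates=coords)


# ---------------------------------------------------------------------------
# Refinement filters
# ---------------------------------------------------------------------------

def refine_cells(m: OccurrenceMatrix, min_widespread: int = 20,
                 restricted_max_range: int = 5) -> RefinementReport:
    """Select cells adequate for clustering.

    A cell is kept when it (i) contains at least one range-restricted taxon
    (full range <= ``restricted_max_range`` cells) and (ii) contains at
    least ``min_widespread`` widespread taxa (range > ``restricted_max_range``),
    the latter guarding against under-sampled cells. Reason codes:
    ``no restricted taxa`` and ``under-sampled``.
    """
    if len(m.cells) == 0 or len(m.taxa) == 0:
        raise ValidationError("empty matrix")
    ranges = m.range_vector()
    restricted = ranges <= restricted_max_range
    widespread = ~restricted
    n_restricted = m.incidence[:, restricted].sum(axis=1)
    n_widespread = m.incidence[:, widespread].sum(axis=1)
    report = RefinementReport()
    for i, cell in enumerate(m.cells):
        reasons = []
        if n_restricted[i] < 1:
            reasons.append("no restricted taxa")
        if n_widespread[i] < min_widespread:
            reasons.append("under-sampled")
        if reasons:
            report.dropped_cells[cell] = tuple(reasons)
        else:
            report.kept_cells.add(cell)
    flags = flag_clustering_taxa(m)
    report.clustering_taxa = flags.clustering_taxa
    report.singleton_taxa = flags.singleton_taxa
    return report


def flag_clustering_taxa(m: OccurrenceMatrix) -> RefinementReport:
    """Split taxa into clustering taxa (full range >= 2) and singletons.

    Single-cell taxa cannot contribute to clustering; they are flagged, not
    deleted, because endemism accounting downstream still needs them.
    """
    report = RefinementReport(kept_cells=set(m.cells))
    for t in m.taxa:
        if m.range_sizes[t] <= 1:
            report.singleton_taxa.add(t)
        else:
            report.clustering_taxa.add(t)
    return report
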