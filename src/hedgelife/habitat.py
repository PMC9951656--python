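"""Urban/rural site classification from an integer-coded land-cover raster.

Each site is classified from the land-cover cells whose centers lie within
a fixed radius of the center of the cell containing the site.  At the
conventional 100 m resolution and a 500 m radius this neighborhood is
exactly the 81 lattice cells with offsets dx^2 + dy^2 <= 25 — the
cell-center-to-cell-center convention is the only one that yields that
count, which pins down the geometry.  Land-cover codes are reclassified to
``urban`` / ``rural`` / ``other`` and the site takes the label of
whichever of urban/rural holds the strictly greater cell count (``other``
is excluded from the comparison; ties are surfaced as ``unclassified``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .records import DeathRecord, Habitat

logger = logging.getLogger(__name__)

__all__ = [
    "LandCoverGrid",
    "Neighborhood",
    "SiteClassification",
    "DEFAULT_CORINE_RECLASS",
    "disc_offsets",
    "neighborhood_cells",
    "classify_site",
    "classify_records",
    "read_grid",
    "write_grid",
    "read_reclass",
]

# CORINE level-3 code blocks: 1-11 artificial surfaces; 12-22 agricultural;
# 23-34 forest & semi-natural; 35-39 wetlands; 40-44 water bodies.
# Artificial -> urban, everything else in the landscape -> rural.  This is a
# documented approximation of the published reclassification and is
# user-overridable via a two-column (code, category) file.
DEFAULT_CORINE_RECLASS: dict[int, str] = {
    **{code: "urban" for code in range(1, 12)},
    **{code: "rural" for code in range(12, 45)},
}


@dataclass
class LandCoverGrid:
    """A rectangular integer-coded raster on a metric grid.

    ``codes[0, 0]`` is the north-west cell; ``origin`` is the (x, y) of the
    lower-left (south-west) corner of the raster in the same metric
    coordinate system as the site coordinates; ``cell_size`` is in meters.
    """

    codes: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 100.0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("land-cover codes must form a 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.codes.shape[0]

    @property
    def ncols(self) -> int:
        return self.codes.shape[1]

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the metric point (x, y)."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row_from_south = int(np.floor((y - self.origin[1]) / self.cell_size))
        row = self.nrows - 1 - row_from_south
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid")
        return row, col


@dataclass
class Neighborhood:
    codes: np.ndarray
    truncated: bool


@dataclass
class SiteClassification:
    label: Habitat
    n_urban: int
    n_rural: int
    n_other: int
    truncated: bool

    @property
    def n_cells(self) -> int:
        return self.n_urban + self.n_rural + self.n_other


def disc_offsets(radius: float, cell_size: float) -> list[tuple[int, int]]:
    """Lattice offsets (drow, dcol) whose center-to-center distance is
    within ``radius``; 81 offsets at radius 500 and cell 100."""
    k = int(np.floor(radius / cell_size))
    r2 = (radius / cell_size) ** 2
    return [
        (di, dj)
        for di in range(-k, k + 1)
        for dj in range(-k, k + 1)
        if di * di + dj * dj <= r2
    ]


def neighborhood_cells(
    center: tuple[float, float], grid: LandCoverGrid, radius: float = 500.0
) -> Neighborhood:
    """Codes of all cells whose centers fall within ``radius`` of the
    center of the cell containing ``center`` (metric x, y).

    Neighborhoods clipped by the grid edge are returned with
    ``truncated=True``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    row, col = grid.cell_index(*center)
    codes = []
    truncated = False
    for di, dj in disc_offsets(radius, grid.cell_size):
        i, j = row + di, col + dj
        if 0 <= i < grid.nrows and 0 <= j < grid.ncols:
            codes.append(grid.codes[i, j])
        else:
            truncated = True
    return Neighborhood(codes=np.asarray(codes), truncated=truncated)


def classify_site(
    center: tuple[float, float],
    grid: LandCoverGrid,
    reclass: Mapping[int, str] | None = None,
    radius: float = 500.0,
) -> SiteClassification:
    """Majority urban/rural call over the neighborhood of a site.

    Codes absent from ``reclass`` count as ``other`` with a warning; equal
    urban and rural counts yield ``unclassified``.
    """
    reclass = DEFAULT_CORINE_RECLASS if reclass is None else reclass
    hood = neighborhood_cells(center, grid, radius)
    n_urban = n_rural = n_other = 0
    unmapped: set[int] = set()
    for code in hood.codes:
        category = reclass.get(int(code))
        if category == "urban":
            n_urban += 1
        elif category == "rural":
            n_rural += 1
        else:
            if category is None:
                unmapped.add(int(code))
            n_other += 1
    if unmapped:
        logger.warning(
            "land-cover codes %s not in reclass map; counted as 'other'",
            sorted(unmapped),
        )
    if n_urban > n_rural:
        label = Habitat.URBAN
    elif n_rural > n_urban:
        label = Habitat.RURAL
    else:
        label = Habitat.UNCLASSIFIED
    return SiteClassification(
        label=label,
        n_urban=n_urban,
        n_rural=n_rural,
        n_other=n_other,
        truncated=hood.truncated,
    )


def classify_records(
    records: Sequence[DeathRecord],
    grid: LandCoverGrid,
    reclass: Mapping[int, str] | None = None,
    radius: float = 500.0,
    transform: Callable[[float, float], tuple[float, float]] | None = None,
) -> list[DeathRecord]:
    """Return copies of ``records`` with the habitat column (re)assigned.

    ``transform`` maps (longitude, latitude) to metric grid coordinates;
    by default the record coordinates are taken to already be metric
    (projection is a configuration concern, not hard-coded here).  Records
    without coordinates, or whose site falls outside the grid, keep their
    existing habitat value.
    """
    out: list[DeathRecord] = []
    n_skipped = 0
    for r in records:
        if r.longitude is None or r.latitude is None:
            out.append(r)
            n_skipped += 1
            continue
        xy = (
            transform(r.longitude, r.latitude)
            if transform is not None
            else (r.longitude, r.latitude)
        )
        try:
            site = classify_site(xy, grid, reclass=reclass, radius=radius)
        except ValueError:
            out.append(r)
            n_skipped += 1
            continue
        out.append(replace(r, habitat=site.label))
    if n_skipped:
        logger.info("habitat: %d records left unclassified (no usable site)", n_skipped)
    return out


# ---------------------------------------------------------------------------
# text I/O (ESRI ASCII grid, the standard plain-text raster interchange)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_grid(path: str | Path) -> LandCoverGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize
    header followed by rows north to south)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValueError(f"grid file {path} missing header key {key!r}")
    codes = np.array(
        [[int(v) for v in line.split()] for line in lines[body_start:] if line.strip()]
    )
    if codes.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body shape {codes.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return LandCoverGrid(
        codes=codes,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
    )


def write_grid(grid: LandCoverGrid, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]}\n")
        fh.write(f"yllcorner {grid.origin[1]}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        for row in grid.codes:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_reclass(path: str | Path) -> dict[int, str]:
    """Read a two-column (code, category) reclassification file; comma or
    whitespace delimited, '#' comments allowed."""
    mapping: dict[int, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'code category'")
        code, category = parts
        category = category.lower()
        if category not in ("urban", "rural", "other"):
            raise ValueError(f"{path}:{lineno}: unknown category {category!r}")
        mapping[int(code)] = category
    return mapping
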