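"""Clone-level 3D spatial statistics.

Quantities computed per clone: per-axis extents, Delaunay-triangulation
edge lengths (clonal dispersion), convex-hull volume, decomposition into
disconnected elements (clusters of apposed cells vs isolated cells),
doublet detection, normalized cortical depth, depth binning, and relative
dispersion expressed as percent of the local cortical thickness per cell.

Axis convention: ``x`` mediolateral (ML), ``y`` dorsoventral depth (DV,
increasing from the pial surface toward the ventricle), ``z``
anteroposterior (AP).  All coordinates in µm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from .color_model import CellRecord, Clone

AXIS_INDEX = {"ML": 0, "DV": 1, "AP": 2}

DEFAULT_DOUBLET_UM = 6.0
DEFAULT_DEPTH_TOL = 0.02
DEFAULT_N_BINS = 6


def _coords(obj) -> np.ndarray:
    """Accept a Clone, a sequence of CellRecord, or an (n, 3) array."""
    if isinstance(obj, Clone):
        return obj.coordinates()
    arr = np.asarray(obj, dtype=float) if not (
        len(obj) and isinstance(obj[0], CellRecord)
    ) else np.array([[c.x, c.y, c.z] for c in obj], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return arr


def _cell_ids(obj, n: int) -> list:
    if isinstance(obj, Clone):
        return [c.cell_id for c in obj.cells]
    if len(obj) and isinstance(obj[0], CellRecord):
        return [c.cell_id for c in obj]
    return list(range(n))


# ---------------------------------------------------------------------------
# Extents, Delaunay, hull
# ---------------------------------------------------------------------------

def axis_extents(clone) -> tuple[float, float, float]:
    """Per-axis max-min spread (extent_dv, extent_ml, extent_ap) in µm."""
    pts = _coords(clone)
    span = pts.max(axis=0) - pts.min(axis=0)
    return float(span[1]), float(span[0]), float(span[2])


@dataclass
class DelaunayEdges:
    """Unique Delaunay edge lengths of a clone, with degeneracy fallback."""

    lengths: np.ndarray
    fallback: bool  # True when pairwise distances replaced the triangulation

    @property
    def mean(self) -> float:
        return float(np.mean(self.lengths))

    @property
    def median(self) -> float:
        return float(np.median(self.lengths))

    @property
    def max(self) -> float:
        return float(np.max(self.lengths))


def delaunay_edge_lengths(clone) -> DelaunayEdges:
    """Lengths of all unique 3D Delaunay edges of the clone's cells.

    For fewer than 4 cells, or affinely degenerate (collinear/coplanar)
    configurations where no 3D triangulation exists, all pairwise distances
    are returned instead, with ``fallback=True``.
    """
    pts = _coords(clone)
    n = len(pts)
    if n < 2:
        raise ValueError("dispersion undefined for singleton")
    rank = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9 * max(1.0, np.abs(pts).max()))
    if n < 4 or rank < 3:
        return DelaunayEdges(lengths=np.sort(pdist(pts)), fallback=True)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return DelaunayEdges(lengths=np.sort(pdist(pts)), fallback=True)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = int(simplex[i]), int(simplex[j])
                edges.add((min(a, b), max(a, b)))
    lens = np.sort(
        [float(np.linalg.norm(pts[a] - pts[b])) for a, b in edges]
    )
    return DelaunayEdges(lengths=np.asarray(lens), fallback=False)


def convex_hull_volume(clone) -> tuple[float, bool]:
    """3D convex-hull volume (µm³); degenerate input yields (0, True)."""
    pts = _coords(clone)
    if len(pts) < 4:
        return 0.0, True
    rank = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9 * max(1.0, np.abs(pts).max()))
    if rank < 3:
        return 0.0, True
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False


# ---------------------------------------------------------------------------
# Elements and doublets
# ---------------------------------------------------------------------------

@dataclass
class ElementDecomposition:
    """Clone split into connected elements at the disconnection distance."""

    elements: list[set]  # cell-id sets
    n_elements: int
    clustered_cells: int  # cells in elements of size >= 2


def _components(pts: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    adj = csr_matrix(adjacency)
    _, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == k) for k in range(labels.max() + 1)]


def decompose_elements(clone, disconnect_um: float) -> ElementDecomposition:
    """Split a clone into elements: components at distance <= disconnect_um.

    Cells farther apart than the disconnection distance (astrocyte mean
    diameter + s.d. at the stage under study) are considered disconnected;
    an element of two or more cells is a cluster of apposed cells, a
    singleton element is an isolated cell.
    """
    if disconnect_um <= 0:
        raise ValueError("disconnect_um must be > 0")
    pts = _coords(clone)
    ids = _cell_ids(clone, len(pts))
    if len(pts) == 1:
        return ElementDecomposition([{ids[0]}], 1, 0)
    dm = squareform(pdist(pts))
    comps = _components(pts, dm <= disconnect_um)
    elements = [set(ids[i] for i in comp) for comp in comps]
    clustered = sum(len(e) for e in elements if len(e) >= 2)
    return ElementDecomposition(elements, len(elements), clustered)


@dataclass
class DoubletResult:
    """Pairs of sister cells with apposed somata (< nuclear size apart)."""

    doublets: list[tuple]          # cell-id pairs (components of size 2)
    multiplets: list[tuple]        # components of size > 2 (not doublets)

    @property
    def cells_in_doublets(self) -> int:
        return 2 * len(self.doublets)


def detect_doublets(clone, doublet_um: float = DEFAULT_DOUBLET_UM) -> DoubletResult:
    """Detect doublets: components at distance strictly < doublet_um.

    The threshold defaults to the mean astrocyte nuclear size (6 µm).
    Components of exactly two cells are doublets; larger components are
    reported as multiplets, not doublets.
    """
    if doublet_um <= 0:
        raise ValueError("doublet_um must be > 0")
    pts = _coords(clone)
    ids = _cell_ids(clone, len(pts))
    if len(pts) < 2:
        return DoubletResult([], [])
    dm = squareform(pdist(pts))
    comps = _components(pts, dm < doublet_um)
    doublets, multiplets = [], []
    for comp in comps:
        if len(comp) == 2:
            doublets.append(tuple(sorted((ids[comp[0]], ids[comp[1]]), key=str)))
        elif len(comp) > 2:
            multiplets.append(tuple(sorted((ids[i] for i in comp), key=str)))
    return DoubletResult(doublets, multiplets)


# ---------------------------------------------------------------------------
# Cortical frame: depth normalization
# ---------------------------------------------------------------------------

@dataclass
class CorticalFrame:
    """Pial and ventricular boundary polylines defining normalized depth.

    Polylines are piecewise-linear curves in the (ML, DV) = (x, y) plane of
    one section, in µm, with the pial boundary above (smaller y) and the
    ventricular boundary below.  Depth is measured along the DV axis by
    linear interpolation of each boundary at the cell's ML position.
    """

    pial: np.ndarray          # (n, 2) x,y
    ventricular: np.ndarray   # (m, 2) x,y
    section_id: str | None = None

    def __post_init__(self) -> None:
        self.pial = np.asarray(self.pial, dtype=float).reshape(-1, 2)
        self.ventricular = np.asarray(self.ventricular, dtype=float).reshape(-1, 2)
        for name, poly in (("pial", self.pial), ("ventricular", self.ventricular)):
            if len(poly) < 2:
                raise ValueError(f"{name} polyline needs at least 2 points")
        # np.interp needs increasing x
        self.pial = self.pial[np.argsort(self.pial[:, 0])]
        self.ventricular = self.ventricular[np.argsort(self.ventricular[:, 0])]

    @classmethod
    def flat(cls, thickness_um: float, x_range: tuple[float, float] = (0.0, 1e4)) -> "CorticalFrame":
        """Frame with flat parallel boundaries (pia at y=0)."""
        x0, x1 = x_range
        return cls(
            pial=np.array([[x0, 0.0], [x1, 0.0]]),
            ventricular=np.array([[x0, thickness_um], [x1, thickness_um]]),
        )

    @classmethod
    def from_json(cls, path) -> "CorticalFrame":
        with open(path) as fh:
            rec = json.load(fh)
        if isinstance(rec, list):
            rec = rec[0]
        return cls(
            pial=np.asarray(rec["pial"], dtype=float),
            ventricular=np.asarray(rec["ventricular"], dtype=float),
            section_id=rec.get("section_id"),
        )

    def pial_y(self, x: float) -> float:
        return float(np.interp(x, self.pial[:, 0], self.pial[:, 1]))

    def ventricular_y(self, x: float) -> float:
        return float(np.interp(x, self.ventricular[:, 0], self.ventricular[:, 1]))

    def thickness(self, x: float) -> float:
        th = self.ventricular_y(x) - self.pial_y(x)
        if th <= 0:
            raise ValueError(f"non-positive cortical thickness at x={x}")
        return th


def relative_depth(cell, frame: CorticalFrame, tol: float = DEFAULT_DEPTH_TOL) -> float:
    """Normalized cortical depth in [0, 1]: 0 at pia, 1 at ventricular limit.

    ``depth = d_pial / (d_pial + d_vent)`` with both distances measured
    along the DV axis at the cell's ML position.  Cells outside the
    ``[-tol, 1+tol]`` band raise with the cell id; values within the
    tolerance band are clamped into [0, 1].
    """
    if isinstance(cell, CellRecord):
        x, y, cid = cell.x, cell.y, cell.cell_id
    else:
        x, y = float(cell[0]), float(cell[1])
        cid = "<anonymous>"
    yp = frame.pial_y(x)
    yv = frame.ventricular_y(x)
    th = yv - yp
    if th <= 0:
        raise ValueError(f"non-positive cortical thickness at x={x}")
    depth = (y - yp) / th
    if depth < -tol or depth > 1 + tol:
        raise ValueError(
            f"cell {cid} lies outside the cortical band (depth={depth:.3f})"
        )
    return float(min(max(depth, 0.0), 1.0))


@dataclass
class CloneDepthSummary:
    barycenter_depth: float
    upper_lower: str            # 'U' (barycenter < 0.5) or 'L'
    depths: np.ndarray          # per-cell normalized depth
    bin_indices: np.ndarray     # per-cell depth bin (0 = pial surface)
    n_bins: int


def clone_depth_summary(
    clone, frame: CorticalFrame, n_bins: int = DEFAULT_N_BINS,
    tol: float = DEFAULT_DEPTH_TOL,
) -> CloneDepthSummary:
    """Barycenter depth, upper/lower class, and per-cell depth bins.

    The clone barycenter is the arithmetic mean of member cells' relative
    DV positions; clones with barycenter above mid-thickness are 'U'pper,
    otherwise 'L'ower.  Bins split the thickness into ``n_bins`` equal
    slices, bin 0 at the pial surface; depth 1.0 is clamped into the last
    bin.
    """
    cells = clone.cells if isinstance(clone, Clone) else clone
    depths = np.array([relative_depth(c, frame, tol=tol) for c in cells])
    bins = np.minimum((depths * n_bins).astype(int), n_bins - 1)
    bary = float(depths.mean())
    return CloneDepthSummary(
        barycenter_depth=bary,
        upper_lower="U" if bary < 0.5 else "L",
        depths=depths,
        bin_indices=bins,
        n_bins=n_bins,
    )


def relative_dispersion(
    clone, frame: CorticalFrame, axis: str = "DV"
) -> float:
    """Axis dispersion per cell, in % of the local cortical thickness.

    (axis extent / cortical thickness x 100) / clone size, with the
    thickness evaluated at the clone barycenter's ML position.  Singleton
    clones have zero dispersion.
    """
    pts = _coords(clone)
    if len(pts) < 2:
        return 0.0
    try:
        ax = AXIS_INDEX[axis.upper()]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(AXIS_INDEX)}, got {axis!r}")
    extent = float(pts[:, ax].max() - pts[:, ax].min())
    th = frame.thickness(float(pts[:, 0].mean()))
    return extent / th * 100.0 / len(pts)


# ---------------------------------------------------------------------------
# Within-clone pair distances (EdU analysis)
# ---------------------------------------------------------------------------

@dataclass
class PairDistances:
    distances: list[float]
    flagged_clones: list[str]   # clones with > 2 filter-positive cells


def pair_distances(
    clones: Sequence[Clone],
    predicate: Callable[[CellRecord], bool],
) -> PairDistances:
    """3D distances between filter-positive sister cells within clones.

    Clones with exactly two positive cells contribute one distance; clones
    with more contribute all pairwise distances and are flagged.
    """
    distances: list[float] = []
    flagged: list[str] = []
    for clone in clones:
        pos = [c for c in clone.cells if predicate(c)]
        if len(pos) < 2:
            continue
        pts = np.array([[c.x, c.y, c.z] for c in pos])
        d = pdist(pts)
        distances.extend(float(v) for v in d)
        if len(pos) > 2:
            flagged.append(clone.clone_id)
    return PairDistances(distances, flagged)


# ---------------------------------------------------------------------------
# Combined per-clone summary
# ---------------------------------------------------------------------------

@dataclass
class CloneSpatialSummary:
    """All spatial statistics of one clone, one row of the tidy report."""

    clone_id: str
    size: int
    extent_dv: float
    extent_ml: float
    extent_ap: float
    delaunay_mean: float | None
    delaunay_median: float | None
    delaunay_max: float | None
    delaunay_fallback: bool | None
    hull_volume: float
    hull_degenerate: bool
    n_elements: int
    clustered_cells: int
    n_doublets: int
    cells_in_doublets: int
    n_multiplets: int
    barycenter_depth: float | None = None
    upper_lower: str | None = None
    relative_dispersion_dv: float | None = None
    relative_dispersion_ml: float | None = None


def clone_spatial_summary(
    clone: Clone,
    disconnect_um: float,
    doublet_um: float = DEFAULT_DOUBLET_UM,
    frame: CorticalFrame | None = None,
    n_bins: int = DEFAULT_N_BINS,
    depth_tol: float = DEFAULT_DEPTH_TOL,
) -> CloneSpatialSummary:
    """Compute the full spatial summary of one clone.

    Depth-dependent fields stay ``None`` when no cortical frame is given.
    """
    ext_dv, ext_ml, ext_ap = axis_extents(clone)
    if clone.size >= 2:
        de = delaunay_edge_lengths(clone)
        d_mean, d_median, d_max, d_fb = de.mean, de.median, de.max, de.fallback
    else:
        d_mean = d_median = d_max = d_fb = None
    vol, degen = convex_hull_volume(clone)
    dec = decompose_elements(clone, disconnect_um)
    dbl = detect_doublets(clone, doublet_um)
    summary = CloneSpatialSummary(
        clone_id=clone.clone_id,
        size=clone.size,
        extent_dv=ext_dv,
        extent_ml=ext_ml,
        extent_ap=ext_ap,
        delaunay_mean=d_mean,
        delaunay_median=d_median,
        delaunay_max=d_max,
        delaunay_fallback=d_fb,
        hull_volume=vol,
        hull_degenerate=degen,
        n_elements=dec.n_elements,
        clustered_cells=dec.clustered_cells,
        n_doublets=len(dbl.doublets),
        cells_in_doublets=dbl.cells_in_doublets,
        n_multiplets=len(dbl.multiplets),
    )
    if frame is not None:
        ds = clone_depth_summary(clone, frame, n_bins=n_bins, tol=depth_tol)
        summary.barycenter_depth = ds.barycenter_depth
        summary.upper_lower = ds.upper_lower
        summary.relative_dispersion_dv = relative_dispersion(clone, frame, "DV")
        summary.relative_dispersion_ml = relative_dispersion(clone, frame, "ML")
    return summary
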