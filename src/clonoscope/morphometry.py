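"""Single-astrocyte arbor morphometry from SWC reconstructions.

Reads standard SWC files (7 whitespace-separated columns: index,
structure code, x, y, z, radius, parent; '#' comments), validates the
tree, optionally rescales coordinates to physical µm, and extracts the
arbor metrics used to describe astrocyte maturation: branch number, total
branch length, model volume (sum of truncated-cone segment volumes),
ending count, and branch/ending densities within a territory proxy (the
convex hull of the node cloud).

Branch convention: a branch is a maximal path between consecutive
topological events (root, branch point, tip), the L-measure "N_branch"
convention.  Soma nodes (structure code 1) are contracted into a single
root event so that multi-point somata do not create spurious branches;
they still contribute to the territory hull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

SOMA_CODE = 1


@dataclass
class SwcNode:
    node_id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for root

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class ArborModel:
    """Validated rooted tree of tapered segments for one astrocyte."""

    nodes: dict[int, SwcNode]
    root: int
    children: dict[int, list[int]] = field(default_factory=dict)
    name: str = ""

    def positions(self) -> np.ndarray:
        return np.array([[n.x, n.y, n.z] for n in self.nodes.values()])


@dataclass
class ArborMetrics:
    """L-measure-style summary of one arbor."""

    n_branches: int
    total_length: float            # µm
    model_volume: float            # µm³, sum of frustum volumes
    n_endings: int
    n_bifurcations: int
    n_branch_points: int           # includes multifurcations
    has_multifurcation: bool
    territory_volume_proxy: float  # µm³, convex hull of all nodes
    territory_degenerate: bool
    branch_density: float | None   # per µm³ (None when hull degenerate)
    ending_density: float | None
    single_node: bool = False


def read_swc(
    path,
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ArborModel:
    """Parse and validate an SWC file, applying anisotropic µm scaling.

    Raises descriptive errors on multiple roots, dangling parent ids,
    cycles, or non-positive radii.
    """
    path = Path(path)
    nodes: dict[int, SwcNode] = {}
    sx, sy, sz = scale
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
        nid, struct = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if nid in nodes:
            raise ValueError(f"{path.name}: duplicate node id {nid}")
        if r <= 0:
            raise ValueError(f"{path.name}: node {nid} has non-positive radius {r}")
        nodes[nid] = SwcNode(nid, struct, x * sx, y * sy, z * sz, r, parent)
    if not nodes:
        raise ValueError(f"{path.name}: no nodes")

    roots = [n.node_id for n in nodes.values() if n.parent == -1]
    if len(roots) == 0:
        raise ValueError(f"{path.name}: no root node (parent -1)")
    if len(roots) > 1:
        raise ValueError(f"{path.name}: multiple roots {sorted(roots)}")
    for n in nodes.values():
        if n.parent != -1 and n.parent not in nodes:
            raise ValueError(f"{path.name}: node {n.node_id} references absent parent {n.parent}")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    for n in nodes.values():
        if n.parent != -1:
            children[n.parent].append(n.node_id)
    for kids in children.values():
        kids.sort()

    # connectivity / acyclicity: walk up from every node to the root
    root = roots[0]
    for n in nodes.values():
        seen = set()
        cur = n.node_id
        while cur != root:
            if cur in seen:
                raise ValueError(f"{path.name}: cycle involving node {cur}")
            seen.add(cur)
            cur = nodes[cur].parent
    return ArborModel(nodes=nodes, root=root, children=children, name=path.stem)


def _frustum_volume(h: float, r1: float, r2: float) -> float:
    return math.pi * h / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)


def _contracted_topology(arbor: ArborModel):
    """Children map with all soma nodes merged into one virtual root.

    Returns (virtual_root_key, children-of-key map) over node ids, where
    the key 'soma' stands for the contracted soma when the root subgraph
    has structure code 1, else the root node id is used as-is.
    """
    soma_ids = {
        nid for nid, n in arbor.nodes.items() if n.structure == SOMA_CODE
    }
    # only soma nodes connected to the root through soma nodes are contracted
    connected_soma = set()
    if arbor.root in soma_ids:
        stack = [arbor.root]
        while stack:
            cur = stack.pop()
            connected_soma.add(cur)
            for kid in arbor.children[cur]:
                if kid in soma_ids and kid not in connected_soma:
                    stack.append(kid)
    if not connected_soma:
        return arbor.root, dict(arbor.children)

    virtual = "soma"
    children: dict = {virtual: []}
    for nid, kids in arbor.children.items():
        if nid in connected_soma:
            children[virtual].extend(k for k in kids if k not in connected_soma)
        else:
            children[nid] = [k for k in kids]
    children[virtual].sort()
    return virtual, children


def arbor_metrics(arbor: ArborModel) -> ArborMetrics:
    """Extract branch/length/volume/ending metrics from a validated arbor.

    Lengths and frustum volumes sum over all parent-child segments outside
    the contracted soma; densities divide counts by the convex-hull volume
    of all node positions (a territory proxy, since the true territorial
    volume comes from fluorescence segmentation and can be supplied
    externally instead).
    """
    if len(arbor.nodes) == 1:
        hull_vol, degen = _hull_volume(arbor.positions())
        return ArborMetrics(
            n_branches=0, total_length=0.0, model_volume=0.0,
            n_endings=1, n_bifurcations=0, n_branch_points=0,
            has_multifurcation=False,
            territory_volume_proxy=hull_vol, territory_degenerate=degen,
            branch_density=None, ending_density=None, single_node=True,
        )

    root_key, children = _contracted_topology(arbor)

    # length and volume over segments between non-contracted nodes
    total_length = 0.0
    model_volume = 0.0
    contracted = root_key == "soma"
    for n in arbor.nodes.values():
        if n.parent == -1:
            continue
        parent = arbor.nodes[n.parent]
        both_soma = (
            contracted
            and n.structure == SOMA_CODE
            and parent.structure == SOMA_CODE
        )
        if both_soma:
            continue  # intra-soma wiring carries no arbor length
        h = float(np.linalg.norm(n.position - parent.position))
        total_length += h
        model_volume += _frustum_volume(h, parent.radius, n.radius)

    # branch decomposition over the contracted topology
    def out_degree(key) -> int:
        return len(children.get(key, []))

    tips = [k for k in children if out_degree(k) == 0 and k != root_key]
    branch_points = [
        k for k in children if k != root_key and out_degree(k) >= 2
    ]
    multifurcations = [k for k in branch_points if out_degree(k) > 2]
    # every topological event below the root terminates exactly one branch
    n_branches = len(tips) + len(branch_points)
    if out_degree(root_key) > 1:
        # a branching root emits its branches without terminating one itself
        pass
    bifurcations = [k for k in branch_points if out_degree(k) == 2]

    hull_vol, degen = _hull_volume(arbor.positions())
    branch_density = None if degen else n_branches / hull_vol
    ending_density = None if degen else len(tips) / hull_vol
    return ArborMetrics(
        n_branches=n_branches,
        total_length=total_length,
        model_volume=model_volume,
        n_endings=len(tips),
        n_bifurcations=len(bifurcations),
        n_branch_points=len(branch_points),
        has_multifurcation=bool(multifurcations),
        territory_volume_proxy=hull_vol,
        territory_degenerate=degen,
        branch_density=branch_density,
        ending_density=ending_density,
    )


def _hull_volume(points: np.ndarray) -> tuple[float, bool]:
    if len(points) < 4:
        return 0.0, True
    if np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-9) < 3:
        return 0.0, True
    try:
        return float(ConvexHull(points).volume), False
    except QhullError:
        return 0.0, True


def metrics_row(arbor: ArborModel, territory_volume: float | None = None) -> dict:
    """Tidy one-row dict for an arbor, optionally with an external
    (segmentation-derived) territory volume overriding the hull proxy."""
    m = arbor_metrics(arbor)
    vol = territory_volume if territory_volume is not None else m.territory_volume_proxy
    row = {
        "arbor": arbor.name,
        "n_branches": m.n_branches,
        "total_length_um": m.total_length,
        "model_volume_um3": m.model_volume,
        "n_endings": m.n_endings,
        "n_bifurcations": m.n_bifurcations,
        "has_multifurcation": m.has_multifurcation,
        "territory_volume_um3": vol,
        "territory_is_proxy": territory_volume is None,
        "branch_density_per_um3": (m.n_branches / vol) if vol else None,
        "ending_density_per_um3": (m.n_endings / vol) if vol else None,
    }
    return row
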