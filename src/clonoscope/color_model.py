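"""Combinatorial color displays and clone calling.

Multicolor lineage tracing with paired Brainbow-style transgenes (a
cytoplasmic and a nuclear reporter, each stochastically expressing one of
three fluorescent proteins per genomic copy after Cre recombination) marks
each labeled cell with an observable *color display*: the pair of
fluorescent-protein sets detected in the cytoplasm and in the nucleus.
Because recombination and genomic integration happen in the progenitor,
all cells of a clone inherit the same display.  Displays that are rare in
the overall labeled population, and that show co-integration of both
transgenes, therefore act as clonal identity keys: cells sharing such a
display within a bounded spatial distance are called as one clone.

This module provides the display algebra (enumeration of the theoretical
combination space, frequency inventories, rarity selection) and the
spatial single-linkage clone caller.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

#: Canonical fluorescent-protein symbols (cyan, yellow, red) in display order.
FLUOROPHORES: tuple[str, ...] = ("C", "Y", "R")

_FP_RANK = {fp: i for i, fp in enumerate(FLUOROPHORES)}

DEFAULT_RARITY_THRESHOLD = 0.02
DEFAULT_LINKAGE_UM = 600.0


def _canon(fps: Iterable[str]) -> frozenset[str]:
    s = frozenset(fps)
    bad = s - set(FLUOROPHORES)
    if bad:
        raise ValueError(f"unknown fluorophore symbol(s): {sorted(bad)}")
    return s


@dataclass(frozen=True)
class ColorDisplay:
    """Per-compartment fluorescent-protein sets of one labeled cell.

    Parameters
    ----------
    cyto :
        Set of fluorophores detected in the cytoplasm (subset of ``C,Y,R``).
    nuc :
        Set of fluorophores detected in the nucleus.

    A cell with both compartments empty is unlabeled and is not a valid
    display.  Equality is element-wise set equality; displays are hashable
    and totally ordered through :meth:`encode`.
    """

    cyto: frozenset[str]
    nuc: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cyto", _canon(self.cyto))
        object.__setattr__(self, "nuc", _canon(self.nuc))
        if not self.cyto and not self.nuc:
            raise ValueError("display with both compartments empty is unlabeled")

    # -- construction / encoding -------------------------------------------------
    @classmethod
    def from_strings(cls, cyto: str, nuc: str, sep: str = ";") -> "ColorDisplay":
        """Parse a display from two separator-joined compartment strings.

        Empty or whitespace-only strings denote an unlabeled compartment.
        """
        def parse(s: str) -> frozenset[str]:
            s = (s or "").strip()
            if not s:
                return frozenset()
            return frozenset(tok.strip() for tok in s.split(sep) if tok.strip())

        return cls(parse(cyto), parse(nuc))

    def _enc_set(self, s: frozenset[str]) -> str:
        return "".join(fp for fp in FLUOROPHORES if fp in s)

    def encode(self) -> str:
        """Canonical string encoding, e.g. ``'CY|R'`` (cytoplasm|nucleus)."""
        return f"{self._enc_set(self.cyto)}|{self._enc_set(self.nuc)}"

    def compartment_strings(self, sep: str = ";") -> tuple[str, str]:
        return (
            sep.join(fp for fp in FLUOROPHORES if fp in self.cyto),
            sep.join(fp for fp in FLUOROPHORES if fp in self.nuc),
        )

    @property
    def co_integrated(self) -> bool:
        """True when both compartments carry at least one fluorophore.

        Co-expression of the cytoplasmic and the nuclear transgene is the
        first criterion for a display to serve as a clonal identity key.
        """
        return bool(self.cyto) and bool(self.nuc)

    def __lt__(self, other: "ColorDisplay") -> bool:
        return self._sort_key() < other._sort_key()

    def _sort_key(self):
        return (
            len(self.cyto),
            tuple(sorted(_FP_RANK[f] for f in self.cyto)),
            len(self.nuc),
            tuple(sorted(_FP_RANK[f] for f in self.nuc)),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ColorDisplay({self.encode()!r})"


@dataclass
class CellRecord:
    """One labeled cell: 3D position (µm), display and annotations."""

    cell_id: str
    x: float
    y: float
    z: float
    display: ColorDisplay
    animal_id: str
    stage: str
    subtype: str = "unknown"
    edu_positive: bool | None = None
    ki67_positive: bool | None = None

    def __post_init__(self) -> None:
        if not str(self.animal_id):
            raise ValueError(f"cell {self.cell_id}: empty animal_id")
        if not str(self.stage):
            raise ValueError(f"cell {self.cell_id}: empty stage")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class FrequencyTable:
    """Counts and fractions of each distinct display within one scope."""

    entries: dict[ColorDisplay, tuple[int, float]]
    total_cells: int
    scope: str = "pooled"

    def fraction(self, display: ColorDisplay) -> float:
        return self.entries.get(display, (0, 0.0))[1]

    def count(self, display: ColorDisplay) -> int:
        return self.entries.get(display, (0, 0.0))[0]

    def as_rows(self) -> list[dict]:
        return [
            {"display": d.encode(), "count": c, "fraction": f}
            for d, (c, f) in self.entries.items()
        ]


@dataclass
class Clone:
    """A called clone: cells sharing one rare display under spatial linkage."""

    clone_id: str
    cells: list[CellRecord]
    display: ColorDisplay
    animal_id: str
    stage: str
    max_pairwise_um: float = 0.0
    diameter_flag: bool = False

    def __post_init__(self) -> None:
        for c in self.cells:
            if c.display != self.display or c.animal_id != self.animal_id or c.stage != self.stage:
                raise ValueError(
                    f"clone {self.clone_id}: cell {c.cell_id} does not share "
                    "the clone's display/animal/stage"
                )

    @property
    def size(self) -> int:
        return len(self.cells)

    def coordinates(self) -> np.ndarray:
        return np.array([[c.x, c.y, c.z] for c in self.cells], dtype=float)

    @property
    def composition_class(self) -> str:
        """Subtype composition: ``PrA-only``, ``PiA-only``, ``heterogeneous``.

        Clones whose members carry neither a protoplasmic (PrA) nor a pial
        (PiA) annotation are classed ``unknown``.
        """
        kinds = {c.subtype for c in self.cells} & {"PrA", "PiA"}
        if kinds == {"PrA"}:
            return "PrA-only"
        if kinds == {"PiA"}:
            return "PiA-only"
        if len(kinds) == 2:
            return "heterogeneous"
        return "unknown"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_theoretical_combinations(
    max_copies_per_transgene: int,
) -> tuple[int, list[ColorDisplay]]:
    """Enumerate distinguishable color displays for 1..n copies per transgene.

    Each genomic copy of a transgene independently either stays in its
    default state or expresses exactly one of the three fluorophores in its
    compartment.  With up to ``n`` copies a compartment can therefore show
    any fluorophore subset of size at most ``min(n, 3)``.  A display is the
    (cytoplasm set, nucleus set) pair; the fully default pair is excluded.

    Returns ``(count, states)`` with states sorted canonically.  Zero copies
    yield no labeled state.
    """
    n = int(max_copies_per_transgene)
    if n < 0:
        raise ValueError("max_copies_per_transgene must be >= 0")
    if n == 0:
        return 0, []
    k = min(n, len(FLUOROPHORES))
    subsets = [
        frozenset(c)
        for r in range(k + 1)
        for c in itertools.combinations(FLUOROPHORES, r)
    ]
    states = [
        ColorDisplay(cy, nu)
        for cy in subsets
        for nu in subsets
        if cy or nu
    ]
    states.sort()
    return len(states), states


def tabulate_display_frequencies(
    cells: Sequence[CellRecord],
    scope: str = "pooled",
) -> FrequencyTable | dict[str, FrequencyTable]:
    """Tabulate display counts and fractions.

    With ``scope='pooled'`` a single table over all cells is returned; with
    ``scope='per_animal'`` a dict of per-animal tables.  Entries are ordered
    lexicographically on the canonical display encoding.
    """
    if not cells:
        raise ValueError("no labeled cells")
    if scope == "pooled":
        return _tabulate(cells, "pooled")
    if scope == "per_animal":
        by_animal: dict[str, list[CellRecord]] = defaultdict(list)
        for c in cells:
            by_animal[c.animal_id].append(c)
        return {a: _tabulate(v, "per_animal") for a, v in sorted(by_animal.items())}
    raise ValueError(f"unknown scope {scope!r}")


def _tabulate(cells: Sequence[CellRecord], scope: str) -> FrequencyTable:
    counts: dict[ColorDisplay, int] = defaultdict(int)
    for c in cells:
        counts[c.display] += 1
    total = len(cells)
    entries = {
        d: (n, n / total) for d, n in sorted(counts.items(), key=lambda kv: kv[0])
    }
    return FrequencyTable(entries=entries, total_cells=total, scope=scope)


def select_rare_displays(
    table: FrequencyTable,
    threshold: float = DEFAULT_RARITY_THRESHOLD,
) -> set[ColorDisplay]:
    """Displays usable as clonal identity keys.

    A display qualifies when (i) it shows co-integration of both transgenes
    (non-empty cytoplasmic *and* nuclear sets) and (ii) its frequency among
    labeled cells is strictly below ``threshold`` (default 2%).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    return {
        d
        for d, (_, frac) in table.entries.items()
        if frac < threshold and d.co_integrated
    }


def _single_linkage_components(coords: np.ndarray, linkage_um: float) -> np.ndarray:
    """Component labels of the graph joining pairs at distance < linkage_um."""
    n = len(coords)
    if n == 1:
        return np.zeros(1, dtype=int)
    dm = squareform(pdist(coords))
    adj = csr_matrix(dm < linkage_um)
    _, labels = connected_components(adj, directed=False)
    return labels


def call_clones(
    cells: Sequence[CellRecord],
    rare: set[ColorDisplay] | Mapping[str, set[ColorDisplay]],
    linkage_um: float = DEFAULT_LINKAGE_UM,
) -> tuple[list[Clone], list[CellRecord]]:
    """Partition cells with rare displays into spatially linked clones.

    Within each (animal, stage, rare display) group, cells are joined by
    edges whenever their 3D distance is strictly below ``linkage_um``
    (default 600 µm); each connected component is one clone (single
    linkage).  A component whose maximal pairwise distance reaches
    ``linkage_um`` is still emitted but flagged as a diameter violation.
    Cells whose display is not rare are returned unassigned.

    ``rare`` may be a single set (pooled rarity) or a per-animal mapping.
    Coordinates must be in µm; NaN coordinates raise with the offending
    cell id.
    """
    for c in cells:
        if not all(math.isfinite(v) for v in (c.x, c.y, c.z)):
            raise ValueError(f"non-finite coordinates for cell {c.cell_id}")

    def is_rare(cell: CellRecord) -> bool:
        if isinstance(rare, Mapping):
            return cell.display in rare.get(cell.animal_id, set())
        return cell.display in rare

    groups: dict[tuple[str, str, ColorDisplay], list[CellRecord]] = defaultdict(list)
    unassigned: list[CellRecord] = []
    for c in cells:
        if is_rare(c):
            groups[(c.animal_id, c.stage, c.display)].append(c)
        else:
            unassigned.append(c)

    clones: list[Clone] = []
    for (animal, stage, display) in sorted(
        groups, key=lambda k: (k[0], k[1], k[2])
    ):
        members = sorted(groups[(animal, stage, display)], key=lambda c: str(c.cell_id))
        coords = np.array([[c.x, c.y, c.z] for c in members], dtype=float)
        labels = _single_linkage_components(coords, linkage_um)
        for lab in range(labels.max() + 1):
            idx = np.flatnonzero(labels == lab)
            sub = [members[i] for i in idx]
            if len(sub) > 1:
                diam = float(pdist(coords[idx]).max())
            else:
                diam = 0.0
            clones.append(
                Clone(
                    clone_id=f"{animal}:{stage}:{display.encode()}:{lab}",
                    cells=sub,
                    display=display,
                    animal_id=animal,
                    stage=stage,
                    max_pairwise_um=diam,
                    diameter_flag=diam >= linkage_um,
                )
            )
    return clones, unassigned
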