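"""Synthetic labeled-cortex datasets with full ground truth.

The generator emulates the statistical structure that the clonal analysis
assumes, so every pipeline stage can be verified without microscopy data:

* combinatorial label genotypes — 1-3 genomic copies per transgene, each
  copy independently default or expressing one of three fluorophores,
  giving a display-frequency spectrum with common and rare combinations;
* overdispersed clone sizes (zero-truncated negative binomial, mean 7.1,
  s.d. 4.6 at the default P7-like conditions);
* multi-element spatial layouts (1 + Poisson(1.8) disconnected elements
  per clone, spaced ~150 µm along a DV-elongated random walk, cells
  scattered within elements as clusters of apposed somata);
* doublets (a configurable fraction of cells, default 20%, paired with a
  partner closer than the 6 µm nuclear size);
* subtype composition (76/5/19% protoplasmic-only / pial-only /
  heterogeneous clones, pial cells confined to the top 3% of the depth
  axis) and larger clones in the upper half of the cortex;
* background cells carrying common single-transgene displays, so the
  rarity filter has non-trivial work.

All sister cells of a clone share one display (recombination and
integration happen in the progenitor); displays are unique per animal so
the emitted ground truth is exactly recoverable by the clone caller.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .color_model import FLUOROPHORES, CellRecord, ColorDisplay

_SUBTYPE_CLASSES = ("PrA-only", "PiA-only", "heterogeneous")


@dataclass
class GenerationConfig:
    """Study-condition parameters of the synthetic cortical slab."""

    seed: int | None = 0
    n_clones: int = 200
    n_animals: int = 12
    stage: str = "P7"
    # slab dimensions, µm: (DV thickness, ML width, AP depth) = (y, x, z)
    slab_um: tuple[float, float, float] = (1400.0, 2000.0, 2000.0)
    # distribution of genomic copy number per transgene on {1, 2, 3}
    copy_number_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    # per-copy recombination outcome: (C, Y, R, default)
    recombination_probs: tuple[float, float, float, float] = (0.3, 0.3, 0.3, 0.1)
    clone_size_mean: float = 7.1
    clone_size_sd: float = 4.6
    elements_rate: float = 1.8           # elements per clone = 1 + Poisson(rate)
    element_spread_um: float = 40.0      # radial RMS of intra-element scatter
    element_spacing_um: float = 150.0
    apposition_um: float = 55.0          # max nearest-neighbour gap inside an element
    doublet_fraction: float = 0.20       # fraction of cells in doublets
    doublet_max_um: float = 6.0
    subtype_mix: tuple[float, float, float] = (0.76, 0.05, 0.19)
    pia_depth_fraction: float = 0.03     # pial cells live above this depth
    upper_size_multiplier: float = 1.5   # upper-half clones are larger
    background_common_label_fraction: float = 0.70
    edu_pair_fraction: float = 0.10      # clones given one EdU+ doublet pair

    def validate(self) -> None:
        if self.n_clones < 1 or self.n_animals < 1:
            raise ValueError("n_clones and n_animals must be >= 1")
        if any(d <= 0 for d in self.slab_um):
            raise ValueError("slab dimensions must be > 0")
        if self.element_spacing_um > min(self.slab_um):
            raise ValueError("element spacing exceeds the slab: impossible geometry")
        for name, probs, total in (
            ("copy_number_weights", self.copy_number_weights, 1.0),
            ("recombination_probs", self.recombination_probs, 1.0),
            ("subtype_mix", self.subtype_mix, 1.0),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - total) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to {total}")
        for name, v in (
            ("doublet_fraction", self.doublet_fraction),
            ("background_common_label_fraction", self.background_common_label_fraction),
            ("pia_depth_fraction", self.pia_depth_fraction),
            ("edu_pair_fraction", self.edu_pair_fraction),
        ):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.upper_size_multiplier < 1:
            raise ValueError("upper_size_multiplier must be >= 1")
        if self.clone_size_sd ** 2 <= self.clone_size_mean:
            raise ValueError(
                "clone size must be overdispersed (sd**2 > mean) for the "
                "negative-binomial law"
            )


@dataclass
class Genotype:
    """Copy numbers and per-copy recombination outcomes of one progenitor."""

    cyto_copies: int
    nuc_copies: int
    cyto_outcomes: tuple[str, ...]   # fluorophore symbol or 'default' per copy
    nuc_outcomes: tuple[str, ...]

    @property
    def display(self) -> ColorDisplay | None:
        cy = frozenset(o for o in self.cyto_outcomes if o != "default")
        nu = frozenset(o for o in self.nuc_outcomes if o != "default")
        if not cy and not nu:
            return None
        return ColorDisplay(cy, nu)


@dataclass
class GroundTruth:
    """Per-cell and per-clone truth emitted alongside the cell table."""

    cells: dict[str, dict]   # cell_id -> clone_id, element_id, doublet_partner, subtype
    clones: dict[str, dict]  # clone_id -> display, animal, stage, size, ...

    def clone_labels(self, cell_ids: Sequence[str]) -> list:
        """True clone label per cell id (None for background cells)."""
        return [self.cells.get(cid, {}).get("clone_id") for cid in cell_ids]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"cells": self.cells, "clones": self.clones}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(cells=d["cells"], clones=d["clones"])


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def sample_genotype(config: GenerationConfig, rng: np.random.Generator) -> Genotype:
    outcomes = list(FLUOROPHORES) + ["default"]
    probs = np.asarray(config.recombination_probs, dtype=float)
    n_cy, n_nu = rng.choice([1, 2, 3], size=2, p=config.copy_number_weights)
    return Genotype(
        cyto_copies=int(n_cy),
        nuc_copies=int(n_nu),
        cyto_outcomes=tuple(rng.choice(outcomes, size=int(n_cy), p=probs)),
        nuc_outcomes=tuple(rng.choice(outcomes, size=int(n_nu), p=probs)),
    )


def sample_label_genotype(
    config: GenerationConfig,
    rng: np.random.Generator,
    require_cointegrated: bool = False,
) -> ColorDisplay:
    """Draw one labeled cell's color display from the genotype model.

    Fully default genotypes (unlabeled) are resampled; with
    ``require_cointegrated`` genotypes are resampled until both
    compartments carry a fluorophore.
    """
    while True:
        d = sample_genotype(config, rng).display
        if d is None:
            continue
        if require_cointegrated and not d.co_integrated:
            continue
        return d


def _truncated_nb_size(mean: float, sd: float, rng: np.random.Generator) -> int:
    """Zero-truncated negative-binomial clone size with given mean/sd."""
    var = sd * sd
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    while True:
        k = int(rng.negative_binomial(r, p))
        if k >= 1:
            return k


@dataclass
class CloneGeometry:
    points: np.ndarray               # (size, 3) µm, x=ML y=DV z=AP
    element_ids: np.ndarray          # (size,) int
    doublet_pairs: list[tuple[int, int]]  # index pairs


def generate_clone_geometry(
    config: GenerationConfig,
    size: int,
    rng: np.random.Generator,
    center: np.ndarray | None = None,
    depth_region: tuple[float, float] | None = None,
) -> CloneGeometry:
    """Place one clone's cells: elements, apposed scatter, doublets.

    Element count is 1 + Poisson(rate) truncated at the clone size;
    element centers follow a DV-elongated random walk with steps of
    ~element_spacing_um.  Cells scatter around their element center with
    Gaussian offsets (radial RMS = element_spread_um), each new cell
    resampled until it lies within the apposition reach of an already
    placed cell so that elements are clusters of apposed somata.  A
    doublet_fraction of cells is then paired with a partner strictly
    closer than doublet_max_um.  All cells are kept inside the slab.

    ``depth_region`` optionally restricts the clone center's normalized
    depth interval (e.g. ``(0.0, 0.03)`` for pial clones).
    """
    if size < 1:
        raise ValueError("clone size must be >= 1")
    config.validate()
    dv, ml, ap = config.slab_um
    if center is None:
        lo, hi = depth_region if depth_region is not None else (0.03, 0.97)
        center = np.array(
            [rng.uniform(0.05 * ml, 0.95 * ml),
             rng.uniform(lo * dv, hi * dv),
             rng.uniform(0.05 * ap, 0.95 * ap)]
        )
    center = np.asarray(center, dtype=float)

    n_el = min(1 + int(rng.poisson(config.elements_rate)), size)
    centers = [center]
    for _ in range(1, n_el):
        step = rng.normal(size=3)
        step[1] *= 2.0  # DV-elongated clone anisotropy
        step /= np.linalg.norm(step)
        spacing = max(rng.normal(config.element_spacing_um, 0.2 * config.element_spacing_um),
                      0.4 * config.element_spacing_um)
        nxt = centers[-1] + step * spacing
        nxt = np.clip(nxt, [0, 0, 0], [ml, dv, ap])
        centers.append(nxt)

    sizes = np.ones(n_el, dtype=int)
    sizes += rng.multinomial(size - n_el, np.ones(n_el) / n_el)

    sigma = config.element_spread_um / np.sqrt(3.0)
    points: list[np.ndarray] = []
    element_ids: list[int] = []
    for ei, (c, s) in enumerate(zip(centers, sizes)):
        placed = [c + rng.normal(0, sigma, 3)]
        for _ in range(int(s) - 1):
            q = None
            for _attempt in range(200):
                cand = c + rng.normal(0, sigma, 3)
                dmin = min(float(np.linalg.norm(cand - p)) for p in placed)
                if 1.0 < dmin <= config.apposition_um:
                    q = cand
                    break
            if q is None:  # fall back to apposing the last placed cell
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                q = placed[-1] + direction * rng.uniform(10.0, config.apposition_um)
            placed.append(q)
        points.extend(placed)
        element_ids.extend([ei] * int(s))
    pts = np.array(points)
    elem = np.array(element_ids)

    # doublets: expected fraction of cells paired, strictly < doublet_max_um
    target = config.doublet_fraction * size / 2.0
    n_pairs = int(target) + (1 if rng.random() < target - int(target) else 0)
    n_pairs = min(n_pairs, size // 2)
    pairs: list[tuple[int, int]] = []
    if n_pairs:
        chosen = rng.permutation(size)[: 2 * n_pairs]
        for a, b in zip(chosen[::2], chosen[1::2]):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pts[b] = pts[a] + direction * rng.uniform(
                1.5, config.doublet_max_um - 1.0
            )
            elem[b] = elem[a]
            pairs.append((int(a), int(b)))

    pts = np.clip(pts, [0, 0, 0], [ml, dv, ap])
    # renumber elements consecutively (a doublet move can empty an element)
    _, elem = np.unique(elem, return_inverse=True)
    return CloneGeometry(points=pts, element_ids=elem, doublet_pairs=pairs)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

#: Common background displays: a single fluorophore in a single compartment
#: (cells that integrated only one of the two transgenes).  These never
#: satisfy the co-integration criterion, whatever their frequency.
_COMMON_DISPLAYS = [
    ColorDisplay(frozenset({fp}), frozenset()) for fp in FLUOROPHORES
] + [ColorDisplay(frozenset(), frozenset({fp})) for fp in FLUOROPHORES]


def _composition_counts(mix: tuple[float, float, float], n: int) -> list[int]:
    """Largest-remainder apportionment of clones to composition classes."""
    raw = [m * n for m in mix]
    counts = [int(v) for v in raw]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


@dataclass
class SyntheticDataset:
    cells: list[CellRecord]
    truth: GroundTruth
    config: GenerationConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            cy, nu = c.display.compartment_strings()
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "animal_id": c.animal_id,
                    "stage": c.stage,
                    "x_um": c.x,
                    "y_um": c.y,
                    "z": c.z,
                    "z_unit": "um",
                    "cyto_display": cy,
                    "nuc_display": nu,
                    "subtype": c.subtype,
                    "edu": c.edu_positive,
                    "ki67": c.ki67_positive,
                }
            )
        return pd.DataFrame(rows)


def generate_dataset(
    config: GenerationConfig,
    seed: int | None = None,
) -> SyntheticDataset:
    """Generate the full labeled slab: clones plus background cells.

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dv, ml, ap = config.slab_um

    # composition classes, deterministically apportioned then shuffled
    n_pr, n_pi, n_het = _composition_counts(config.subtype_mix, config.n_clones)
    classes = (
        ["PrA-only"] * n_pr + ["PiA-only"] * n_pi + ["heterogeneous"] * n_het
    )
    rng.shuffle(classes)

    animals = [f"A{i % config.n_animals + 1:02d}" for i in range(config.n_clones)]
    used_displays: dict[str, set[ColorDisplay]] = {a: set() for a in set(animals)}

    # dataset-wide mean stays at clone_size_mean despite the upper boost:
    # rescale the base mean by the expected fraction of upper clones, which
    # exceeds 1/2 because pial and heterogeneous clones sit near the surface
    p_upper_pra = (0.5 - 0.03) / (0.97 - 0.03)
    p_upper = (
        config.subtype_mix[0] * p_upper_pra
        + config.subtype_mix[1]
        + config.subtype_mix[2]
    )
    base_mean = config.clone_size_mean / (
        p_upper * config.upper_size_multiplier + (1.0 - p_upper)
    )

    cells: list[CellRecord] = []
    truth_cells: dict[str, dict] = {}
    truth_clones: dict[str, dict] = {}
    counter = 0

    for i in range(config.n_clones):
        animal = animals[i]
        cls = classes[i]
        if cls == "PiA-only":
            depth_region = (0.0, config.pia_depth_fraction)
        elif cls == "heterogeneous":
            # pial members must stay spatially linked to the parenchymal part
            depth_region = (config.pia_depth_fraction, 0.25)
        else:
            depth_region = (0.03, 0.97)
        center = np.array(
            [rng.uniform(0.05 * ml, 0.95 * ml),
             rng.uniform(depth_region[0] * dv, depth_region[1] * dv),
             rng.uniform(0.05 * ap, 0.95 * ap)]
        )
        upper = center[1] / dv < 0.5
        mean_i = base_mean * (config.upper_size_multiplier if upper else 1.0)
        sd_i = config.clone_size_sd * mean_i / config.clone_size_mean
        sd_i = max(sd_i, np.sqrt(mean_i) * 1.05)  # keep overdispersion valid
        size = _truncated_nb_size(mean_i, sd_i, rng)
        if cls == "heterogeneous":
            size = max(size, 2)

        # unique co-integrated display within the animal
        for _attempt in range(10_000):
            display = sample_label_genotype(config, rng, require_cointegrated=True)
            if display not in used_displays[animal]:
                break
        else:
            raise RuntimeError(
                f"could not find an unused co-integrated display for {animal}"
            )
        used_displays[animal].add(display)

        # assemble parenchymal and pial parts separately so doublet pairs
        # never straddle the subtype boundary
        if cls == "PiA-only":
            n_pia = size
        elif cls == "heterogeneous":
            n_pia = 1 + int(rng.binomial(size - 2, 0.25)) if size > 2 else 1
        else:
            n_pia = 0
        n_pra = size - n_pia

        parts_pts: list[np.ndarray] = []
        parts_elem: list[np.ndarray] = []
        doublet_pairs: list[tuple[int, int]] = []
        subtypes_list: list[str] = []
        if n_pra:
            geom = generate_clone_geometry(config, n_pra, rng, center=center)
            parts_pts.append(geom.points)
            parts_elem.append(geom.element_ids)
            doublet_pairs.extend(geom.doublet_pairs)
            subtypes_list.extend(["PrA"] * n_pra)
        if n_pia:
            # tight surface cluster above the clone, inside the pial band,
            # with doublet headroom below the band ceiling
            y_hi = max(
                config.pia_depth_fraction * dv - config.doublet_max_um,
                0.5 * config.pia_depth_fraction * dv,
            )
            surf = np.column_stack(
                [
                    rng.normal(center[0], 12.0, n_pia),
                    rng.uniform(0.0, y_hi, n_pia),
                    rng.normal(center[2], 12.0, n_pia),
                ]
            )
            surf = np.clip(surf, [0, 0, 0], [ml, dv, ap])
            target = config.doublet_fraction * n_pia / 2.0
            n_pairs = int(target) + (1 if rng.random() < target - int(target) else 0)
            perm = rng.permutation(n_pia)[: 2 * min(n_pairs, n_pia // 2)]
            for a, b in zip(perm[::2], perm[1::2]):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                surf[b] = np.clip(
                    surf[a] + direction * rng.uniform(1.5, config.doublet_max_um - 1.0),
                    [0, 0, 0],
                    [ml, dv, ap],
                )
                doublet_pairs.append((int(a) + n_pra, int(b) + n_pra))
            offset = parts_elem[0].max() + 1 if parts_elem else 0
            parts_pts.append(surf)
            parts_elem.append(np.full(n_pia, offset, dtype=int))
            subtypes_list.extend(["PiA"] * n_pia)
        pts = np.vstack(parts_pts)
        elem = np.concatenate(parts_elem)
        subtypes = np.array(subtypes_list, dtype=object)

        clone_id = f"clone{i:04d}"
        edu_pair = (
            doublet_pairs[0]
            if doublet_pairs and rng.random() < config.edu_pair_fraction
            else None
        )
        member_ids = []
        for j in range(size):
            cid = f"c{counter:06d}"
            counter += 1
            member_ids.append(cid)
            edu = bool(edu_pair is not None and j in edu_pair)
            cells.append(
                CellRecord(
                    cell_id=cid,
                    x=float(pts[j, 0]),
                    y=float(pts[j, 1]),
                    z=float(pts[j, 2]),
                    display=display,
                    animal_id=animal,
                    stage=config.stage,
                    subtype=str(subtypes[j]),
                    edu_positive=edu,
                    ki67_positive=bool(edu and rng.random() < 0.5),
                )
            )
            truth_cells[cid] = {
                "clone_id": clone_id,
                "element_id": int(elem[j]),
                "doublet_partner": None,
                "subtype": str(subtypes[j]),
            }
        for a, b in doublet_pairs:
            truth_cells[member_ids[a]]["doublet_partner"] = member_ids[b]
            truth_cells[member_ids[b]]["doublet_partner"] = member_ids[a]
        truth_clones[clone_id] = {
            "display": display.encode(),
            "animal_id": animal,
            "stage": config.stage,
            "size": int(size),
            "n_elements": int(elem.max() + 1),
            "n_doublet_pairs": len(doublet_pairs),
            "composition_class": cls,
            "upper": bool(upper),
            "barycenter_depth": float(pts[:, 1].mean() / dv),
            "cell_ids": member_ids,
        }

    # background cells with common (single-transgene) displays
    n_clone_cells = counter
    f = config.background_common_label_fraction
    n_bg = int(round(n_clone_cells * f / (1.0 - f))) if f > 0 else 0
    for _ in range(n_bg):
        cid = f"c{counter:06d}"
        counter += 1
        display = _COMMON_DISPLAYS[int(rng.integers(len(_COMMON_DISPLAYS)))]
        cells.append(
            CellRecord(
                cell_id=cid,
                x=float(rng.uniform(0, ml)),
                y=float(rng.uniform(0, dv)),
                z=float(rng.uniform(0, ap)),
                display=display,
                animal_id=f"A{int(rng.integers(config.n_animals)) + 1:02d}",
                stage=config.stage,
                subtype="unknown",
                edu_positive=False,
                ki67_positive=False,
            )
        )

    truth = GroundTruth(cells=truth_cells, clones=truth_clones)
    return SyntheticDataset(cells=cells, truth=truth, config=config)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write cells.csv, truth.json and the resolved config YAML."""
    import yaml
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells_path = out / "cells.csv"
    truth_path = out / "truth.json"
    cfg_path = out / "cfg-resolved.yaml"
    dataset.to_frame().to_csv(cells_path, index=False)
    dataset.truth.to_json(truth_path)
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(dataset.config), fh, sort_keys=True)
    return {
        "cells": str(cells_path),
        "truth": str(truth_path),
        "config": str(cfg_path),
    }
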