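"""End-to-end orchestration and the group-comparison protocol.

``run_pipeline`` chains the full clonal analysis: display inventory →
rarity selection → spatial clone calling → per-clone spatial summaries
(plus orientation when z is µm-resolved, plus depth statistics when a
cortical frame is given) → per-stage aggregates → nonparametric group
comparisons.  Everything is deterministic given the inputs and seed, and
every aggregate is recomputable from the emitted per-clone table.

Group comparisons follow the usual nonparametric protocol for this kind
of data: Mann-Whitney for two groups, Kruskal-Wallis with Dunn's multiple
comparisons for three or more.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .color_model import (
    CellRecord,
    Clone,
    call_clones,
    select_rare_displays,
    tabulate_display_frequencies,
)
from .config import AnalysisConfig
from .io import file_checksum, read_cell_table, read_frame, z_resolution_is_sectional
from .orientation import fit_principal_axis
from .spatial_stats import CorticalFrame, clone_spatial_summary

logger = logging.getLogger("clonoscope")


# ---------------------------------------------------------------------------
# Statistics protocol
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    groups: list[str]
    posthoc: pd.DataFrame | None = None
    warning: str | None = None


def _dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's multiple-comparison z tests on pooled ranks, tie-corrected."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    k = len(groups)
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(p * m, 1.0) if adjust == "bonferroni" else p
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": z,
                "p_raw": p,
                "p_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    *groups: Sequence[float],
    labels: Sequence[str] | None = None,
    alternative: str = "two-sided",
    dunn_adjust: str = "bonferroni",
) -> GroupComparison:
    """Compare 2 groups (Mann-Whitney) or >=3 (Kruskal-Wallis + Dunn).

    Two-sided by default; one-sided alternatives apply to the two-group
    rank-sum test only.  Exact small-sample Mann-Whitney p-values are used
    when there are no ties.  Pooled all-identical values return p = 1 with
    a tie warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("each group needs at least one value")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            statistic=float("nan"),
            p_value=1.0,
            method="degenerate (all values identical)",
            groups=labels,
            warning="all pooled values identical; comparison is uninformative",
        )
    if len(arrays) == 2:
        res = stats.mannwhitneyu(
            arrays[0], arrays[1], alternative=alternative, method="auto"
        )
        return GroupComparison(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            method=f"mann-whitney ({alternative})",
            groups=labels,
        )
    res = stats.kruskal(*arrays)
    posthoc = _dunn_posthoc(arrays, labels, adjust=dunn_adjust)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"kruskal-wallis + dunn ({dunn_adjust})",
        groups=labels,
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    per_clone: pd.DataFrame
    aggregates: pd.DataFrame
    tests: list[GroupComparison]
    clones: list[Clone]
    unassigned_cells: int
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def report_hash(self) -> str:
        """Deterministic digest of the per-clone table."""
        return hashlib.sha256(
            self.per_clone.to_csv(index=False).encode()
        ).hexdigest()

    def write(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "per_clone": str(out / "clones.csv"),
            "aggregates": str(out / "aggregates.csv"),
            "tests": str(out / "tests.json"),
            "provenance": str(out / "provenance.json"),
        }
        self.per_clone.to_csv(paths["per_clone"], index=False)
        self.aggregates.to_csv(paths["aggregates"], index=False)
        with open(paths["tests"], "w") as fh:
            json.dump(
                [
                    {
                        "method": t.method,
                        "groups": t.groups,
                        "statistic": t.statistic,
                        "p_value": t.p_value,
                        "warning": t.warning,
                        "posthoc": (
                            t.posthoc.to_dict("records") if t.posthoc is not None else None
                        ),
                    }
                    for t in self.tests
                ],
                fh,
                indent=1,
            )
        with open(paths["provenance"], "w") as fh:
            json.dump(self.provenance, fh, indent=1)
        return paths


def _per_clone_row(
    clone: Clone,
    config: AnalysisConfig,
    frame: CorticalFrame | None,
    orient: bool,
) -> dict:
    s = clone_spatial_summary(
        clone,
        disconnect_um=config.disconnect_for(clone.stage),
        doublet_um=config.doublet_um,
        frame=frame,
        n_bins=config.n_depth_bins,
        depth_tol=config.depth_tol,
    )
    row = {
        "clone_id": clone.clone_id,
        "animal_id": clone.animal_id,
        "stage": clone.stage,
        "display": clone.display.encode(),
        "size": clone.size,
        "composition_class": clone.composition_class,
        "max_pairwise_um": clone.max_pairwise_um,
        "diameter_flag": clone.diameter_flag,
        **{
            k: v
            for k, v in asdict(s).items()
            if k not in {"clone_id", "size"}
        },
    }
    if orient and clone.size >= 2:
        try:
            ax = fit_principal_axis(clone)
            row["axis_angle_deg"] = ax.angle_to_radial
            row["radial_projection_um"] = ax.radial_projection
            row["axis_degenerate"] = ax.degenerate
        except ValueError:
            row["axis_angle_deg"] = None
            row["radial_projection_um"] = None
            row["axis_degenerate"] = None
    else:
        row["axis_angle_deg"] = None
        row["radial_projection_um"] = None
        row["axis_degenerate"] = None
    return row


def _sem(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0


def _aggregate(per_clone: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for stage, grp in per_clone.groupby("stage", sort=True):
        sizes = grp["size"].to_numpy(dtype=float)
        total_cells = sizes.sum()
        row = {
            "stage": stage,
            "n_clones": len(grp),
            "n_cells": int(total_cells),
            "mean_clone_size": float(sizes.mean()),
            "sem_clone_size": _sem(sizes),
            "sd_clone_size": float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0,
            "mean_n_elements": float(grp["n_elements"].mean()),
            "sem_n_elements": _sem(grp["n_elements"].to_numpy(dtype=float)),
            "clustered_pct": float(grp["clustered_cells"].sum() / total_cells * 100.0),
            "doublet_pct": float(grp["cells_in_doublets"].sum() / total_cells * 100.0),
        }
        for cls in ("PrA-only", "PiA-only", "heterogeneous"):
            row[f"pct_{cls}"] = float(
                (grp["composition_class"] == cls).mean() * 100.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    cells_path,
    frame_path=None,
    config: AnalysisConfig | None = None,
    cells: list[CellRecord] | None = None,
    frame: CorticalFrame | None = None,
) -> RunReport:
    """Run the full clonal analysis.

    Inputs may be paths (CSV cell table, JSON boundary masks) or already
    constructed objects via ``cells=`` / ``frame=``.  Omitting the frame
    disables only depth-dependent outputs.  The 3D orientation fit is
    skipped, with a logged notice, when any z coordinate is section-
    indexed (section-scale z resolution cannot support a 3D axis fit).
    """
    config = config or AnalysisConfig()
    run_warnings: list[str] = []
    provenance: dict = {"config": asdict(config)}

    orient = True
    if cells is None:
        if cells_path is None:
            raise ValueError("either cells_path or cells must be given")
        cells = read_cell_table(cells_path, config.section_thickness_um)
        provenance["cells_path"] = str(cells_path)
        provenance["cells_sha256"] = file_checksum(cells_path)
        if z_resolution_is_sectional(cells_path):
            orient = False
            msg = "section-indexed z: skipping 3D orientation fits"
            logger.info(msg)
            run_warnings.append(msg)
    if frame is None and frame_path is not None:
        frame = read_frame(frame_path)
        provenance["frame_path"] = str(frame_path)
        provenance["frame_sha256"] = file_checksum(frame_path)
    provenance["n_cells"] = len(cells)
    cfg_yaml = json.dumps(asdict(config), sort_keys=True)
    provenance["config_sha256"] = hashlib.sha256(cfg_yaml.encode()).hexdigest()
    provenance["seed"] = config.seed

    # 1. display inventory and rarity
    table = tabulate_display_frequencies(cells, scope="pooled")
    if config.rarity_scope == "per_animal":
        per_animal = tabulate_display_frequencies(cells, scope="per_animal")
        rare = {
            a: select_rare_displays(t, config.rarity_threshold)
            for a, t in per_animal.items()
        }
        n_rare = len(set().union(*rare.values())) if rare else 0
    else:
        rare = select_rare_displays(table, config.rarity_threshold)
        n_rare = len(rare)
    logger.info("inventory: %d cells, %d distinct displays, %d rare",
                len(cells), len(table.entries), n_rare)
    if n_rare == 0:
        run_warnings.append("no rare displays: empty clone set")

    # 2. clone calling
    clones, unassigned = call_clones(cells, rare, config.linkage_um)
    logger.info("called %d clones; %d cells unassigned", len(clones), len(unassigned))

    # 3. per-clone summaries
    rows = [_per_clone_row(c, config, frame, orient) for c in clones]
    per_clone = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["clone_id", "animal_id", "stage", "display", "size"]
    )

    # 4. aggregates and 5. statistics protocol
    aggregates = _aggregate(per_clone) if len(per_clone) else pd.DataFrame()
    tests: list[GroupComparison] = []
    if len(per_clone):
        stages = sorted(per_clone["stage"].unique())
        if len(stages) >= 2:
            groups = [
                per_clone.loc[per_clone["stage"] == s, "size"].to_numpy(float)
                for s in stages
            ]
            if all(len(g) for g in groups):
                cmp = compare_groups(
                    *groups, labels=[f"size@{s}" for s in stages],
                    dunn_adjust=config.dunn_adjust,
                )
                tests.append(cmp)
        if frame is not None and "upper_lower" in per_clone:
            u = per_clone.loc[per_clone["upper_lower"] == "U", "size"].to_numpy(float)
            l = per_clone.loc[per_clone["upper_lower"] == "L", "size"].to_numpy(float)
            if len(u) and len(l):
                tests.append(
                    compare_groups(u, l, labels=["size@upper", "size@lower"])
                )

    return RunReport(
        per_clone=per_clone,
        aggregates=aggregates,
        tests=tests,
        clones=clones,
        unassigned_cells=len(unassigned),
        provenance=provenance,
        warnings=run_warnings,
    )
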