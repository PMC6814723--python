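"""Genotype sampler, clone geometry, and dataset-level guarantees."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from clonoscope import (
    GenerationConfig,
    generate_clone_geometry,
    generate_dataset,
    sample_label_genotype,
    select_rare_displays,
    tabulate_display_frequencies,
)
from clonoscope.synthetic_data import sample_genotype


class TestGenotypeSampler:
    def test_degenerate_recombination_always_cyan(self, rng):
        cfg = GenerationConfig(recombination_probs=(1.0, 0.0, 0.0, 0.0))
        for _ in range(20):
            d = sample_label_genotype(cfg, rng)
            assert d.cyto == frozenset({"C"}) and d.nuc == frozenset({"C"})

    def test_single_copy_no_default_uniform_over_pure_pairs(self, rng):
        cfg = GenerationConfig(
            copy_number_weights=(1.0, 0.0, 0.0),
            recombination_probs=(1 / 3, 1 / 3, 1 / 3, 0.0),
        )
        n = 30_000
        counts = {}
        for _ in range(n):
            d = sample_label_genotype(cfg, rng)
            counts[d] = counts.get(d, 0) + 1
        assert len(counts) == 9  # pure single-FP pairs only
        p = 1 / 9
        tol = 4 * np.sqrt(p * (1 - p) / n)
        for c in counts.values():
            assert c / n == pytest.approx(p, abs=tol)

    def test_three_copies_reach_triple_fp_compartments(self, rng):
        cfg = GenerationConfig(
            copy_number_weights=(0.0, 0.0, 1.0),
            recombination_probs=(1 / 3, 1 / 3, 1 / 3, 0.0),
        )
        seen = False
        for _ in range(500):
            g = sample_genotype(cfg, rng)
            if g.display and len(g.display.cyto) == 3:
                seen = True
                break
        assert seen

    def test_cointegration_filter(self, rng):
        cfg = GenerationConfig()
        for _ in range(50):
            assert sample_label_genotype(cfg, rng, require_cointegrated=True).co_integrated


class TestCloneGeometry:
    def test_singleton_inside_slab(self, rng):
        cfg = GenerationConfig()
        g = generate_clone_geometry(cfg, 1, rng)
        assert g.points.shape == (1, 3)
        ml, dv, ap = cfg.slab_um[1], cfg.slab_um[0], cfg.slab_um[2]
        assert (g.points >= 0).all()
        assert (g.points <= [ml, dv, ap]).all()

    def test_tight_single_element_clone_is_compact(self, rng):
        cfg = GenerationConfig(elements_rate=0.0, element_spread_um=1.0,
                               doublet_fraction=0.0)
        g = generate_clone_geometry(cfg, 10, rng, center=np.array([1000.0, 700.0, 1000.0]))
        d = np.linalg.norm(g.points[:, None] - g.points[None, :], axis=-1)
        assert d.max() < 20.0
        assert np.unique(g.element_ids).size == 1

    def test_full_doublet_fraction_pairs_every_cell(self, rng):
        cfg = GenerationConfig(doublet_fraction=1.0)
        g = generate_clone_geometry(cfg, 8, rng, center=np.array([1000.0, 700.0, 1000.0]))
        assert len(g.doublet_pairs) == 4
        for a, b in g.doublet_pairs:
            assert np.linalg.norm(g.points[a] - g.points[b]) < cfg.doublet_max_um

    def test_impossible_geometry_rejected(self, rng):
        cfg = GenerationConfig(element_spacing_um=5000.0)
        with pytest.raises(ValueError, match="impossible geometry"):
            generate_clone_geometry(cfg, 5, rng)

    def test_apposed_scatter_links_elements_internally(self, rng):
        cfg = GenerationConfig(doublet_fraction=0.0)
        g = generate_clone_geometry(cfg, 12, rng, center=np.array([1000.0, 700.0, 1000.0]))
        for eid in np.unique(g.element_ids):
            pts = g.points[g.element_ids == eid]
            if len(pts) < 2:
                continue
            # every cell apposed to some other cell of its element
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min(axis=1).max() <= cfg.apposition_um + 1e-9


class TestDataset:
    def test_deterministic_given_seed(self):
        cfg = GenerationConfig(n_clones=30)
        a = generate_dataset(cfg, seed=5).to_frame().to_csv(index=False)
        b = generate_dataset(cfg, seed=5).to_frame().to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self):
        cfg = GenerationConfig(n_clones=30)
        a = generate_dataset(cfg, seed=5).to_frame().to_csv(index=False)
        b = generate_dataset(cfg, seed=6).to_frame().to_csv(index=False)
        assert a != b

    def test_all_cells_inside_slab(self, dataset200):
        dv, ml, ap = dataset200.config.slab_um
        for c in dataset200.cells:
            assert 0 <= c.x <= ml and 0 <= c.y <= dv and 0 <= c.z <= ap

    def test_pial_cells_confined_to_surface_band(self, dataset200):
        dv = dataset200.config.slab_um[0]
        band = dataset200.config.pia_depth_fraction
        for c in dataset200.cells:
            if c.subtype == "PiA":
                assert c.y / dv < band

    def test_sister_cells_share_display_animal(self, dataset200):
        by_cell = {c.cell_id: c for c in dataset200.cells}
        for rec in dataset200.truth.clones.values():
            members = [by_cell[cid] for cid in rec["cell_ids"]]
            assert len({m.display for m in members}) == 1
            assert len({m.animal_id for m in members}) == 1

    def test_displays_unique_within_animal(self, dataset200):
        seen = set()
        for rec in dataset200.truth.clones.values():
            key = (rec["animal_id"], rec["display"])
            assert key not in seen
            seen.add(key)

    def test_mean_clone_size_near_configured(self, dataset200):
        sizes = [rec["size"] for rec in dataset200.truth.clones.values()]
        assert np.mean(sizes) == pytest.approx(
            dataset200.config.clone_size_mean, rel=0.10
        )

    def test_composition_counts_match_mix(self, dataset200):
        from collections import Counter

        c = Counter(r["composition_class"] for r in dataset200.truth.clones.values())
        n = dataset200.config.n_clones
        mix = dataset200.config.subtype_mix
        assert c["PrA-only"] == round(mix[0] * n)
        assert c["PiA-only"] == round(mix[1] * n)
        assert c["heterogeneous"] == round(mix[2] * n)

    def test_rarity_monotone_in_copy_number_weight(self):
        """More weight on 2-3 copies makes rare (multi-FP) displays commoner."""
        def rare_cell_fraction(weights, seed=3):
            # 8 clones/animal: the single-copy pool has only 9 co-integrated
            # displays per animal, so uniqueness must stay satisfiable
            cfg = GenerationConfig(
                n_clones=96, copy_number_weights=weights,
                background_common_label_fraction=0.0,
            )
            ds = generate_dataset(cfg, seed=seed)
            table = tabulate_display_frequencies(ds.cells)
            rare = {d for d, (_, f) in table.entries.items() if f < 0.02}
            return sum(table.count(d) for d in rare) / table.total_cells

        low = rare_cell_fraction((1.0, 0.0, 0.0))
        high = rare_cell_fraction((0.0, 0.0, 1.0))
        assert high > low

    def test_upper_null_multiplier_is_calibrated(self):
        """upper_size_multiplier=1 must produce no upper/lower size effect."""
        from scipy.stats import mannwhitneyu

        rejections = 0
        for seed in range(15):
            cfg = GenerationConfig(n_clones=80, upper_size_multiplier=1.0)
            ds = generate_dataset(cfg, seed=100 + seed)
            dv = cfg.slab_um[0]
            upper, lower = [], []
            for rec in ds.truth.clones.values():
                (upper if rec["barycenter_depth"] < 0.5 else lower).append(rec["size"])
            p = mannwhitneyu(upper, lower).pvalue
            rejections += p < 0.05
        assert rejections <= 3  # ~5% expected under the null

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GenerationConfig(subtype_mix=(0.5, 0.5, 0.5)).validate()
        with pytest.raises(ValueError):
            GenerationConfig(clone_size_sd=1.0).validate()
        with pytest.raises(ValueError):
            GenerationConfig(n_clones=0).validate()

    def test_write_round_trip(self, tmp_path):
        from clonoscope.synthetic_data import GroundTruth, write_dataset

        ds = generate_dataset(GenerationConfig(n_clones=10), seed=2)
        paths = write_dataset(ds, tmp_path)
        truth = GroundTruth.from_json(paths["truth"])
        assert set(truth.clones) == set(ds.truth.clones)
        from clonoscope.io import read_cell_table

        cells = read_cell_table(paths["cells"])
        assert len(cells) == len(ds.cells)
        assert {c.cell_id for c in cells} == {c.cell_id for c in ds.cells}
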