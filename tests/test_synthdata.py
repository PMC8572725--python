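"""The synthetic world: determinism, planted structure, count calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from k9me import chic, synthdata
from k9me.expression import normalize_counts


class TestDeterminism:
    def test_same_seed_byte_identical_world(self, tmp_path):
        cfg = synthdata.SimulationConfig(seed=123)
        d1, d2 = tmp_path / "w1", tmp_path / "w2"
        synthdata.generate_world(cfg).write(d1)
        synthdata.generate_world(cfg).write(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes(), f.name

    def test_different_seeds_differ(self):
        w1 = synthdata.generate_world(synthdata.SimulationConfig(seed=1))
        w2 = synthdata.generate_world(synthdata.SimulationConfig(seed=2))
        assert w1.genome.sequences != w2.genome.sequences

    def test_downstream_simulations_deterministic(self, world):
        c1 = synthdata.simulate_expression_counts(world)
        c2 = synthdata.simulate_expression_counts(world)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)


class TestWorldStructure:
    def test_planted_consensus_at_recorded_offsets(self, world):
        pwm_by_name = {p.name: p for p in world.pwms}
        planted = world.truth[world.truth["planted_motifs"] != ""]
        assert len(planted) == world.config.n_genes["silenced_derepressible"]
        for gid, row in planted.iterrows():
            consensus = pwm_by_name[row["planted_motifs"]].consensus
            offset = int(row["motif_offset"])
            seq = world.genome[row["chrom"]]
            assert seq[offset : offset + len(consensus)] == consensus

    def test_no_derepressible_genes_no_planted_motifs(self):
        cfg = synthdata.SimulationConfig(
            seed=5,
            n_genes={
                "muscle_expressed": 10,
                "silenced_derepressible": 0,
                "silenced_stable": 10,
                "background": 10,
            },
        )
        w = synthdata.generate_world(cfg)
        assert (w.truth["planted_motifs"] == "").all()

    def test_domains_cover_silenced_genes(self, world):
        silenced = world.truth[world.truth["h3k9_domain"]]
        for _, row in silenced.iterrows():
            covered = any(
                d.chrom == row["chrom"]
                and d.start <= row["span_start"]
                and row["span_end"] <= d.end
                for d in world.domains
            )
            assert covered

    def test_capacity_error_when_genes_do_not_fit(self):
        cfg = synthdata.SimulationConfig(
            seed=1, chrom_length=30_000,
            n_genes={
                "muscle_expressed": 100,
                "silenced_derepressible": 100,
                "silenced_stable": 0,
                "background": 0,
            },
        )
        with pytest.raises(ValueError, match="fit"):
            synthdata.generate_world(cfg)

    def test_group_invariants(self, world):
        t = world.truth
        ab = t["group_label"].isin(["A", "B"])
        assert (t.loc[ab, "derepression_fc"] > 1).all()
        assert (t.loc[t["derepression_fc"] > 1, "class"] == "silenced_derepressible").all()
        assert (t.loc[t["group_label"] == "C", "class"] == "silenced_stable").all()


class TestExpressionCounts:
    def test_poisson_limit_means(self):
        """With dispersion 0 and no planted effects, per-gene sample
        means stay within 3 standard errors of the baseline."""
        cfg = synthdata.SimulationConfig(
            seed=11, nb_dispersion=0.0, library_size_sigma=0.0,
            derepression_fc=1.0, replicates=3,
        )
        truth = synthdata.make_null_truth(500, baseline=100.0)
        cm = synthdata.simulate_expression_counts(truth, cfg)
        means = cm.counts.mean(axis=1)  # 12 samples per gene
        se = np.sqrt(100.0 / cm.counts.shape[1])
        frac_in = float(((means - 100.0).abs() <= 3 * se).mean())
        assert frac_in > 0.98

    def test_derepression_fold_change_monte_carlo(self):
        """Planted fc=16 at baseline 20: mutant means approach 320."""
        cfg = synthdata.SimulationConfig(
            seed=13, replicates=3, library_size_sigma=0.0
        )
        w_truth = synthdata.make_null_truth(300, baseline=20.0)
        w_truth["class"] = "silenced_derepressible"
        w_truth["derepression_fc"] = 16.0
        cm = synthdata.simulate_expression_counts(w_truth, cfg)
        mut_cols = [
            c for c in cm.counts.columns
            if c.startswith(("met-2_", "met-2 set-25"))
        ]
        grand_mean = float(cm.counts[mut_cols].values.mean())
        # 1,800 draws of NB(320, 0.1): SE ~ sqrt(320 + 0.1*320^2)/42 ~ 2.4
        assert grand_mean == pytest.approx(320.0, abs=15.0)

    def test_set25_matches_wt(self, world, expression_counts):
        cm = expression_counts
        scaled = normalize_counts(cm.counts)
        wt = scaled[[c for c in scaled if c.startswith("WT")]].mean(axis=1)
        s25 = scaled[[c for c in scaled if c.startswith("set-25")]].mean(axis=1)
        log2fc = np.log2((s25 + 8) / (wt + 8))
        assert abs(float(log2fc.mean())) < 0.1


class TestChicFragments:
    def test_uniform_when_ratio_one(self, world):
        cfg = dataclasses.replace(world.config, chic_ratio=1.0)
        w = dataclasses.replace(world, config=cfg)
        frags = synthdata.simulate_chic_fragments(w, "H3K9me3", genotypes=["WT"])
        template = chic.tile_genome(w.genome, 500)
        track = chic.count_fragments(frags["WT"][0], template)
        in_dom = out_dom = in_n = out_n = 0.0
        for d in w.domains:
            vals = track.values[d.chrom][d.start // 500 : d.end // 500]
            in_dom += vals.sum()
            in_n += len(vals)
        total = track.flat()
        out_dom = total.sum() - in_dom
        out_n = len(total) - in_n
        assert in_dom / in_n == pytest.approx(out_dom / out_n, rel=0.1)

    def test_double_mutant_loses_h3k9me3(self, world):
        frags = synthdata.simulate_chic_fragments(
            world, "H3K9me3", genotypes=["met-2 set-25"]
        )
        template = chic.tile_genome(world.genome, 500)
        track = chic.count_fragments(frags["met-2 set-25"][0], template)
        in_dom = in_n = 0.0
        for d in world.domains:
            vals = track.values[d.chrom][d.start // 500 : d.end // 500]
            in_dom += vals.sum()
            in_n += len(vals)
        total = track.flat()
        out_rate = (total.sum() - in_dom) / (len(total) - in_n)
        assert in_dom / in_n == pytest.approx(out_rate, rel=0.1)

    def test_deep_sampling_recovers_planted_rate_ratio(self):
        """At high depth the in/out fragment density ratio matches the
        configured rate ratio."""
        cfg = synthdata.SimulationConfig(seed=17, chic_fragments=400_000)
        w = synthdata.generate_world(cfg)
        frags = synthdata.simulate_chic_fragments(w, "H3K9me3", genotypes=["WT"])
        dom_len = sum(len(d) for d in w.domains)
        genome_len = sum(w.chrom_lengths.values())
        n_in = 0
        for f in frags["WT"][0]:
            mid = (f.start + f.end) // 2
            if any(d.chrom == f.chrom and d.start <= mid < d.end for d in w.domains):
                n_in += 1
        n_out = len(frags["WT"][0]) - n_in
        density_ratio = (n_in / dom_len) / (n_out / (genome_len - dom_len))
        assert density_ratio == pytest.approx(cfg.chic_ratio, rel=0.1)


class TestAccessibilityAndDamid:
    def test_group_a_peaks_unchanged(self, world, atac_damid):
        peaks, peak_counts, _ = atac_damid
        scaled = normalize_counts(peak_counts.counts)
        mut = scaled[[c for c in scaled if c.startswith("met-2 set-25")]].mean(axis=1)
        wt = scaled[[c for c in scaled if c.startswith("WT")]].mean(axis=1)
        ratio = (mut + 8) / (wt + 8)
        a_genes = world.genes_of_group("A")
        c_genes = world.genes_of_group("C")
        assert float(ratio[a_genes].mean()) < 1.5
        assert float(ratio[c_genes].mean()) > 3.0

    def test_zero_depth_gives_zero_counts(self, world):
        cfg = dataclasses.replace(
            world.config, peak_base_mean=0.0, damid_depth=0.0
        )
        w = dataclasses.replace(world, config=cfg)
        _, peak_counts, damid_counts = synthdata.simulate_accessibility_and_damid(w)
        assert (peak_counts.counts.values == 0).all()
        assert (damid_counts.counts.values == 0).all()


class TestRenderNuclei:
    def test_truth_distance_for_centred_focus_is_radius(self):
        cfg = synthdata.SimulationConfig(seed=3)
        shape, voxel = cfg.image_shape, cfg.voxel_size
        centre = tuple(s * v / 2 for s, v in zip(shape, voxel))
        mask = synthdata._ideal_mask(shape, voxel, centre, cfg.nucleus_radius)
        d = synthdata._exact_boundary_distance(centre, mask, voxel)
        assert d == pytest.approx(cfg.nucleus_radius, abs=1.5 * max(voxel))

    def test_noiseless_focus_is_local_maximum(self, config):
        cfg = dataclasses.replace(
            config, snr=50.0, outside_focus_fraction=0.0, foci_per_nucleus=1
        )
        scenes = synthdata.render_nuclei(cfg, n_nuclei=1)
        sc = scenes[0]
        t = sc.truth.iloc[0]
        zi = int(round(t["z"] / cfg.voxel_size[0]))
        yi = int(round(t["y"] / cfg.voxel_size[1]))
        xi = int(round(t["x"] / cfg.voxel_size[2]))
        ch1 = sc.stack[1]
        local = ch1[
            max(0, zi - 2) : zi + 3, max(0, yi - 2) : yi + 3, max(0, xi - 2) : xi + 3
        ]
        assert ch1[zi, yi, xi] >= local.max() * 0.8

    def test_anisotropic_truth_matches_brute_force(self):
        """Truth distances are physical-unit distances to boundary voxel
        centres, verified against an exhaustive search."""
        cfg = synthdata.SimulationConfig(seed=7, voxel_size=(0.2, 0.1, 0.1))
        scenes = synthdata.render_nuclei(cfg, n_nuclei=1)
        sc = scenes[0]
        mask = synthdata._ideal_mask(
            cfg.image_shape, cfg.voxel_size, sc.nucleus_centre, sc.nucleus_radius
        )
        bg = np.argwhere(~mask) * np.array(cfg.voxel_size)
        for _, t in sc.truth.iterrows():
            if not t["inside"]:
                continue
            p = np.array([t["z"], t["y"], t["x"]])
            want = float(np.sqrt(((bg - p) ** 2).sum(axis=1)).min())
            assert t["true_distance"] == pytest.approx(want, abs=1e-9)

    def test_tiff_round_trip(self, tmp_path, config):
        import tifffile

        scenes = synthdata.render_nuclei(config, n_nuclei=1)
        scenes[0].write_tiff(tmp_path / "scene.tif")
        back = tifffile.imread(tmp_path / "scene.tif")
        np.testing.assert_allclose(back, scenes[0].stack.astype(np.float32))
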