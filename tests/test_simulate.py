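"""Synthetic-data generator: determinism, Brownian laws, planted structure."""

import numpy as np
import pandas as pd
import pytest

import expevo as ev


class TestSimulateTree:
    def test_same_seed_same_newick(self):
        a = ev.simulate_tree(5, 1.0, seed=42)
        b = ev.simulate_tree(5, 1.0, seed=42)
        assert a.to_newick() == b.to_newick()
        assert a.to_newick() != ev.simulate_tree(5, 1.0, seed=43).to_newick()

    def test_node_counts(self):
        t = ev.simulate_tree(5, 1.0, seed=1)
        assert len(t.leaf_names) == 5
        assert len(t.internal_nodes) == 4  # 2n - 1 nodes total

    def test_ultrametric(self):
        t = ev.simulate_tree(8, 2.5, seed=2)
        depths = [t.depth(i) for i in t.leaves]
        np.testing.assert_allclose(depths, 2.5, atol=1e-9)

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            ev.simulate_tree(1, 1.0, seed=0)


class TestEvolveCharacters:
    def test_zero_rate_copies_root(self, five_taxon_tree):
        rng = np.random.default_rng(0)
        vals = ev.evolve_characters(five_taxon_tree, np.full(10, 3.3), 0.0, rng)
        for v in vals.values():
            np.testing.assert_allclose(v, 3.3)

    def test_variance_law(self, five_taxon_tree):
        # Var(tip - root) = sigma^2 * depth, within 10% over 2,000 characters
        rng = np.random.default_rng(27)
        sigma2 = 1.7
        vals = ev.evolve_characters(five_taxon_tree, np.zeros(2000), sigma2, rng)
        for leaf in five_taxon_tree.leaf_names:
            depth = five_taxon_tree.depth(five_taxon_tree.node_id(leaf))
            assert vals[leaf].var() == pytest.approx(sigma2 * depth, rel=0.10)

    def test_covariance_law(self, five_taxon_tree):
        # Cov(tip_i, tip_j) = sigma^2 * shared path length, within 15%
        rng = np.random.default_rng(28)
        t = five_taxon_tree
        vals = ev.evolve_characters(t, np.zeros(2000), 1.0, rng)
        a, b = t.leaf_names[0], t.leaf_names[1]
        shared = t.depth(t.mrca(a, b))
        cov = np.cov(vals[a], vals[b])[0, 1]
        if shared > 0.05:  # relative tolerance meaningless near zero
            assert cov == pytest.approx(shared, rel=0.15)


class TestPlantShift:
    def _tips(self, tree, n_genes=10, T=5):
        rng = np.random.default_rng(29)
        return {sp: rng.normal(size=(n_genes, T)) for sp in tree.leaf_names}

    def test_zero_shift_is_identity(self, five_taxon_tree):
        tips = self._tips(five_taxon_tree)
        out, mask = ev.plant_shift(tips, five_taxon_tree, "sp1", 0, 0.0, [1, 2])
        for sp in tips:
            np.testing.assert_array_equal(out[sp], tips[sp])

    def test_shift_applied_only_where_planted(self, five_taxon_tree):
        tips = self._tips(five_taxon_tree)
        out, mask = ev.plant_shift(tips, five_taxon_tree, "sp2", 3, 4.0, [0, 5])
        diff = out["sp2"] - tips["sp2"]
        assert diff[0, 3] == pytest.approx(4.0) and diff[5, 3] == pytest.approx(4.0)
        assert np.count_nonzero(diff) == 2
        for sp in tips:
            if sp != "sp2":
                np.testing.assert_array_equal(out[sp], tips[sp])

    def test_non_terminal_branch_rejected(self, five_taxon_tree):
        tips = self._tips(five_taxon_tree)
        with pytest.raises(ValueError, match="terminal"):
            ev.plant_shift(tips, five_taxon_tree, five_taxon_tree.root_name, 0, 1.0, [0])


class TestEmitDataset:
    def test_deterministic_outputs(self, tmp_path):
        cfg = ev.SimConfig(n_genes=50, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        ev.emit_dataset(cfg).write(d1)
        ev.emit_dataset(cfg).write(d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_silent_fraction_close_to_binomial(self):
        ds = ev.emit_dataset(ev.SimConfig(n_genes=1000, fraction_silent=0.02, seed=6))
        n_silent = int(ds.truth.genes["silent"].sum())
        assert n_silent == 20  # rounded fraction, planted exactly
        # silent genes should fail the activity call in every species
        from expevo.activity import call_activity, z_transform
        silent_clusters = set(ds.truth.genes.index[ds.truth.genes["silent"]])
        sp = ds.tree.leaf_names[0]
        calls = call_activity(z_transform(ds.matrices[sp]))
        members = ds.scog_map.table[sp]
        silent_genes = [members[c] for c in silent_clusters]
        assert not calls.loc[silent_genes, "active"].any()

    def test_emitted_files_round_trip_through_readers(self, tmp_path):
        ds = ev.emit_dataset(ev.SimConfig(n_genes=30, seed=7))
        ds.write(tmp_path)
        tree = ev.parse_newick((tmp_path / "tree.nwk").read_text())
        assert tree.to_newick() == ds.tree.to_newick()
        for sp in ds.matrices:
            m = ev.read_expression_table(tmp_path / f"expression_{sp}.tsv", sp)
            assert m.n_genes == 30
        scog = ev.read_scog_map(tmp_path / "scogs.tsv", list(ds.matrices))
        assert len(scog) == 30
        flags = ev.read_annotation_flags(tmp_path / "flags.tsv")
        assert flags == ds.flags

    def test_truth_recovered_from_noiseless_low_rate_tips(self):
        # ancestral reconstruction applied to noiseless tips approaches the
        # planted internal-node truth as the Brownian rate shrinks
        def rmse(rate, seed=8):
            cfg = ev.SimConfig(
                n_genes=200, bm_rate=rate, count_noise=False,
                fraction_silent=0.0, n_planted=0, seed=seed,
            )
            ds = ev.emit_dataset(cfg)
            fcs = {
                sp: pd.DataFrame(
                    ds.truth.node_deltas[sp],
                    index=ds.scog_map.cluster_ids,
                )
                for sp in ds.tree.leaf_names
            }
            errs = []
            for t in range(5):
                tips = pd.DataFrame(
                    {sp: fcs[sp][t] for sp in ds.tree.leaf_names}
                )
                est = ev.bm_reconstruct(ds.tree, tips)
                for node, vals in est.node_values.items():
                    truth = ds.truth.node_deltas[node][:, t]
                    errs.append(np.mean((vals - truth) ** 2))
            return np.sqrt(np.mean(errs))

        assert rmse(0.01) < rmse(1.0)
        assert rmse(0.0001) < 0.02

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValueError):
            ev.SimConfig(fraction_silent=1.5)
        with pytest.raises(ValueError):
            ev.SimConfig(n_genes=10, n_planted=11)
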