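import numpy as np
import pandas as pd
import pytest

from conftest import small_sim_config
from phosphodrug import modules_gba, syndata
from phosphodrug.datatypes import DataError, IntensityMatrix, SetCollection


def block_instance(seed=0, n_cells=40, block_size=15, n_noise=30, lam=3.0):
    """Two planted correlated blocks (r ~ lam^2/(lam^2+1)) plus noise."""
    rng = np.random.default_rng(seed)
    rows, labels = {}, {}
    for b in range(2):
        z = rng.normal(size=n_cells)
        for i in range(block_size):
            name = f"B{b}_{i}"
            rows[name] = lam * z + rng.normal(size=n_cells)
            labels[name] = b + 1
    for i in range(n_noise):
        name = f"N{i}"
        rows[name] = rng.normal(size=n_cells)
        labels[name] = 0
    df = pd.DataFrame(rows).T
    df.columns = [f"C{j}" for j in range(n_cells)]
    return df, pd.Series(labels)


class TestTopologicalOverlap:
    def test_identical_features_beta_one(self):
        # two identical features: a = 1, TOM = 1
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5]},
        ).T
        df = pd.concat([df, df.rename(index={"x": "y"})])
        part_adj = np.abs(df.T.corr().to_numpy()) ** 1
        tom = modules_gba.topological_overlap(part_adj)
        assert tom[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(12)
        a = np.abs(rng.uniform(size=(4, 4)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = modules_gba.topological_overlap(a)
        n = 4
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                oracle = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_bounds_symmetry_diagonal(self):
        rng = np.random.default_rng(13)
        a = np.abs(rng.uniform(size=(20, 20))) ** 6
        a = (a + a.T) / 2
        tom = modules_gba.topological_overlap(a)
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert (tom >= -1e-12).all() and (tom <= 1 + 1e-12).all()
        assert np.allclose(np.diag(tom), 1.0)


class TestDetectModules:
    def test_two_planted_blocks_recovered_noise_unassigned(self):
        df, labels = block_instance(seed=0)
        part = modules_gba.detect_modules(df)
        block_labels = {
            b: set(part.labels[labels[labels == b].index]) for b in (1, 2)
        }
        assert all(len(v) == 1 and 0 not in v for v in block_labels.values())
        assert block_labels[1] != block_labels[2]
        noise = part.labels[labels[labels == 0].index]
        assert (noise == 0).all()

    def test_low_beta_rejected(self):
        df, _ = block_instance()
        with pytest.raises(DataError):
            modules_gba.detect_modules(df, beta=0.5)

    def test_all_missing_feature_named_in_error(self):
        df, _ = block_instance(n_noise=5)
        df.loc["N0"] = np.nan
        with pytest.raises(DataError, match="N0"):
            modules_gba.detect_modules(df)

    def test_too_few_cell_lines(self):
        df, _ = block_instance(n_cells=5)
        with pytest.raises(DataError):
            modules_gba.detect_modules(df)

    def test_recovery_ari_on_planted_blocks(self):
        # stochastic invariant: ARI >= 0.9 at r = 0.9, n = 60, 10 seeds
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            df, labels = block_instance(seed=seed, n_cells=60, lam=3.0)
            part = modules_gba.detect_modules(df)
            planted = labels[labels > 0]
            aris.append(adjusted_rand_score(planted, part.labels[planted.index]))
        assert np.mean(aris) >= 0.9

    def test_eigenfeature_tracks_module_mean(self):
        df, labels = block_instance(seed=3, n_cells=60)
        part = modules_gba.detect_modules(df)
        for mod in part.module_ids:
            members = part.members(mod)
            z = df.loc[members].sub(df.loc[members].mean(axis=1), axis=0)
            z = z.div(df.loc[members].std(axis=1, ddof=0), axis=0)
            r = np.corrcoef(part.eigenfeatures[mod], z.mean(axis=0))[0, 1]
            assert r >= 0.9


def _assoc_setup(seed=1):
    cfg = small_sim_config(seed=seed)
    protein, psite, pathways, kin, drugs, phenotype, ann, truth = (
        syndata.generate_dataset(cfg)
    )
    combined = pd.concat([protein.values, psite.values])
    partition = modules_gba.detect_modules(combined)
    return partition, pathways, phenotype, combined, truth


class TestAssociateAxes:
    def test_empty_set_collection_no_axis1_edges(self):
        partition, _, phenotype, combined, _ = _assoc_setup()
        empty = SetCollection({}, universe=combined.index)
        assoc = modules_gba.associate_axes(partition, empty, phenotype, combined)
        assert not assoc.edges_of_kind("set-module")
        assert not assoc.edges_of_kind("set-phenotype")

    def test_planted_circuit_present(self):
        partition, pathways, phenotype, combined, truth = _assoc_setup()
        assoc = modules_gba.associate_axes(partition, pathways, phenotype, combined)
        diff_name = sorted(pathways.names)[-1]  # the planted differential set
        kinds = {
            (e.kind, e.a) for e in assoc.edges
        }
        assert any(k == "set-module" and a == diff_name for k, a in kinds)
        assert any(k == "set-phenotype" and a == diff_name for k, a in kinds)
        assert assoc.edges_of_kind("module-phenotype")

    def test_single_class_phenotype_raises(self):
        partition, pathways, phenotype, combined, _ = _assoc_setup()
        all_pos = pd.Series(1, index=phenotype.index)
        with pytest.raises(DataError):
            modules_gba.associate_axes(partition, pathways, all_pos, combined)

    def test_permutation_null_controls_edges(self):
        # permuted phenotypes must not produce significant edge circuits
        partition, pathways, phenotype, combined, _ = _assoc_setup()
        rng = np.random.default_rng(0)
        n_edges = n_tests = 0
        for _ in range(20):
            perm = pd.Series(
                rng.permutation(phenotype.to_numpy()), index=phenotype.index
            )
            assoc = modules_gba.associate_axes(partition, pathways, perm, combined)
            pheno_edges = (
                assoc.edges_of_kind("module-phenotype")
                + assoc.edges_of_kind("set-phenotype")
            )
            n_edges += len(pheno_edges)
            n_tests += len(partition.module_ids) + len(pathways)
        assert n_edges <= max(1, 0.05 * n_tests)

    def test_eigenfeature_level_option_runs(self):
        partition, pathways, phenotype, combined, _ = _assoc_setup()
        assoc = modules_gba.associate_axes(
            partition, pathways, phenotype, combined, level="eigenfeature"
        )
        assert assoc.edges_of_kind("module-phenotype")


class TestGuiltByAssociation:
    def test_set_members_excluded_and_planted_candidates_found(self):
        partition, pathways, phenotype, combined, truth = _assoc_setup()
        assoc = modules_gba.associate_axes(partition, pathways, phenotype, combined)
        cand = modules_gba.guilt_by_association(assoc, pathways, partition)
        assert len(cand)
        for _, row in cand.iterrows():
            assert row["feature"] not in pathways.members(row["set"])
        # planted differential p-sites are unannotated and must surface
        diff_psites = {f for f, _ in truth.differential_features if "_p" in f}
        found = diff_psites & set(cand["feature"])
        assert len(found) >= 0.8 * len(diff_psites)

    def test_no_significant_edges_empty_output(self):
        partition, pathways, phenotype, combined, _ = _assoc_setup()
        assoc = modules_gba.HiveAssociation(
            axis_sets=pathways.names,
            axis_modules=partition.module_ids,
            axis_phenotype=["positive", "negative"],
            edges=[],
            member_tests=pd.DataFrame(columns=["statistic", "p", "q", "effect", "n"]),
            q_threshold=0.05,
        )
        cand = modules_gba.guilt_by_association(assoc, pathways, partition)
        assert cand.empty


class TestRecapitulationOverlap:
    def _matrices(self, shared_fraction=1.0, seed=0, n_pairs=30, n_cells=40):
        """Plant correlated pairs; `shared_fraction` of the phospho-level
        pairs are also correlated at the protein level."""
        rng = np.random.default_rng(seed)
        prot, phos = {}, {}
        pairs = []
        n_shared = int(round(shared_fraction * n_pairs))
        for k in range(n_pairs):
            a, b = f"A{k}", f"B{k}"
            pairs.append((a, b))
            z = rng.normal(size=n_cells)
            phos[a] = 5 * z + rng.normal(size=n_cells)
            phos[b] = 5 * z + rng.normal(size=n_cells)
            if k < n_shared:
                w = rng.normal(size=n_cells)
                prot[a] = 5 * w + rng.normal(size=n_cells)
                prot[b] = 5 * w + rng.normal(size=n_cells)
            else:
                prot[a] = rng.normal(size=n_cells)
                prot[b] = rng.normal(size=n_cells)
        cells = [f"C{j}" for j in range(n_cells)]
        protein = IntensityMatrix(
            pd.DataFrame(prot).T.set_axis(cells, axis=1), "protein"
        )
        phospho = IntensityMatrix(
            pd.DataFrame(phos).T.set_axis(cells, axis=1), "phosphoprotein"
        )
        return protein, phospho, pairs

    def test_identical_matrices_full_overlap(self):
        protein, phospho, pairs = self._matrices(shared_fraction=1.0)
        protein = IntensityMatrix(phospho.values.copy(), "protein")
        res = modules_gba.recapitulation_overlap(protein, phospho, pairs)
        assert res.overlap_fraction == pytest.approx(1.0)

    def test_disjoint_levels_zero_overlap(self):
        protein, phospho, pairs = self._matrices(shared_fraction=0.0)
        res = modules_gba.recapitulation_overlap(protein, phospho, pairs)
        assert res.overlap_fraction == pytest.approx(0.0, abs=0.1)

    def test_half_shared_recovers_half(self):
        fractions = [
            modules_gba.recapitulation_overlap(
                *self._matrices(shared_fraction=0.5, seed=seed)
            ).overlap_fraction
            for seed in range(20)
        ]
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.1)

    def test_pathway_enrichment_reported(self):
        protein, phospho, pairs = self._matrices(shared_fraction=1.0)
        paths = SetCollection(
            {"PW": [p for ab in pairs[:10] for p in ab]}
        )
        res = modules_gba.recapitulation_overlap(
            protein, phospho, pairs, pathways=paths
        )
        assert set(res.enrichment) == {"protein", "phosphoprotein"}
        assert {"pathway", "p", "q"} <= set(res.enrichment["protein"].columns)

    def test_no_testable_pairs_raises(self):
        protein, phospho, _ = self._matrices()
        with pytest.raises(DataError):
            modules_gba.recapitulation_overlap(protein, phospho, [("X", "Y")])
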