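import numpy as np
import pytest

import isdgkit as ik
from isdgkit.records import InvalidArgumentError


def leaf_edge_lengths(tree):
    return [e.length for e in tree.preorder_edge_iter() if e.tail_node is not None]


class TestSampleTree:
    def test_smallest_valid_tree(self):
        t = ik.sample_tree(2, seed=0)
        leaves = [l.taxon.label for l in t.leaf_node_iter()]
        assert len(leaves) == 2 and len(set(leaves)) == 2
        assert all(l > 0 for l in leaf_edge_lengths(t))

    def test_too_few_taxa(self):
        with pytest.raises(InvalidArgumentError):
            ik.sample_tree(1, seed=0)

    def test_determinism(self):
        a = ik.sample_tree(16, seed=42).as_string(schema="newick")
        b = ik.sample_tree(16, seed=42).as_string(schema="newick")
        assert a == b

    def test_branch_scale_doubles_mean_length(self):
        """Doubling branch_scale doubles mean branch length (Monte Carlo)."""
        base, doubled = [], []
        for s in range(100):
            base.extend(leaf_edge_lengths(ik.sample_tree(8, 0.2, seed=s)))
            doubled.extend(leaf_edge_lengths(ik.sample_tree(8, 0.4, seed=s)))
        base, doubled = np.array(base), np.array(doubled)
        ratio = doubled.mean() / base.mean()
        se = ratio * np.sqrt(
            (base.std() / base.mean()) ** 2 / len(base)
            + (doubled.std() / doubled.mean()) ** 2 / len(doubled))
        assert abs(ratio - 2.0) < 3 * se + 1e-6


class TestEvolveFamily:
    def test_planted_triad_invariant_without_degradation(self):
        cfg = ik.SimConfig(n_taxa=12, degraded_fraction=0.0, n_decoys=0,
                           n_duplicates=0, n_fusions=0, seed=3)
        tree = ik.sample_tree(12, seed=3)
        records, truth = ik.evolve_family(tree, cfg)
        for r in records:
            local = {full: i for i, full in enumerate(truth.site_maps[r.id])}
            for p, res in zip(cfg.triad_positions, "NWH"):
                assert r.sequence[local[p]] == res
            assert truth.triad_status[r.id] == 3

    def test_zero_branch_lengths_copy_root(self):
        tree = ik.parse_newick("((T01:0,T02:0):0,T03:0);")
        tree.is_rooted = True
        cfg = ik.SimConfig(n_taxa=3, insert_clade=(), n_decoys=0,
                           n_duplicates=0, n_fusions=0, degraded_fraction=0,
                           triad_positions=(41, 70, 90),
                           aux_positions=(30, 50, 65), seed=1)
        records, truth = ik.evolve_family(tree, cfg)
        for r in records:
            assert r.sequence == truth.root_sequence

    def test_substitution_proportion_matches_matrix_exponential(self, lg_model):
        """One branch of length 1: changed-site fraction vs 1 - sum pi_i P_ii."""
        tree = ik.parse_newick("(T01:0.0,T02:1.0);")
        tree.is_rooted = True
        cfg = ik.SimConfig(n_taxa=2, domain_length=10000, insert_clade=(),
                           n_decoys=0, n_duplicates=0, n_fusions=0,
                           triad_positions=(), aux_positions=(),
                           degraded_fraction=0, alpha=None, seed=5)
        records, _ = ik.evolve_family(tree, cfg)
        a, b = records[0].sequence, records[1].sequence
        observed = np.mean([x != y for x, y in zip(a, b)])
        P = lg_model.transition_matrix(1.0)
        expected = 1.0 - float(lg_model.stationary @ np.diag(P))
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert abs(observed - expected) < 3 * se

    def test_insert_clade_composition_and_length(self, default_family):
        cfg, records, truth = default_family
        fam = {r.id: r for r in records if r.id in truth.triad_status}
        ins = set(range(cfg.insert_start + 1,
                        cfg.insert_start + cfg.insert_length + 1))
        for rid in truth.insert_clade_ids:
            r = fam[rid]
            assert len(r.sequence) == cfg.domain_length + cfg.insert_length
            local = [i for i, full in enumerate(truth.site_maps[rid])
                     if full in ins]
            block = [r.sequence[i] for i in local]
            frac = np.mean([c in "SGH" for c in block])
            assert frac >= 0.6
        for rid in set(truth.triad_status) - set(truth.insert_clade_ids):
            assert len(fam[rid].sequence) == cfg.domain_length

    def test_position_colliding_with_insert_is_refused(self):
        with pytest.raises(InvalidArgumentError):
            ik.SimConfig(triad_positions=(41, 80, 130))  # 80 inside 61..105

    def test_leaf_count_mismatch(self):
        cfg = ik.SimConfig(n_taxa=8, seed=0)
        with pytest.raises(InvalidArgumentError):
            ik.evolve_family(ik.sample_tree(5, seed=0), cfg)


class TestConfounders:
    def test_identity_when_all_zero(self, default_family):
        cfg, _, _ = default_family
        base_cfg = ik.SimConfig(n_taxa=8, n_decoys=0, n_duplicates=0,
                                n_fusions=0, seed=9)
        tree = ik.sample_tree(8, seed=9)
        records, truth = ik.evolve_family(tree, base_cfg)
        out, truth2 = ik.add_confounders(records, truth, base_cfg)
        assert [r.id for r in out] == [r.id for r in records]

    def test_record_count_is_exact(self, default_family):
        cfg, records, truth = default_family
        expected = cfg.n_taxa + cfg.n_decoys + cfg.n_duplicates + cfg.n_fusions
        assert len(records) == expected

    def test_fusion_construction(self, default_family):
        cfg, records, truth = default_family
        by_id = {r.id: r for r in records}
        for fid, (a, b), junction in truth.fusion_registry:
            fusion = by_id[fid]
            assert len(fusion.sequence) == (len(by_id[a].sequence) + 6
                                            + len(by_id[b].sequence))
            assert junction == len(by_id[a].sequence)
            assert fusion.sequence.startswith(by_id[a].sequence)
            assert fusion.sequence.endswith(by_id[b].sequence)

    def test_duplicates_at_least_98_percent_identical(self):
        cfg = ik.SimConfig(n_taxa=10, n_duplicates=5, n_decoys=0,
                           n_fusions=0, seed=13)
        records, truth = ik.simulate_dataset(cfg)
        by_id = {r.id: r for r in records}
        n_new = sum(len(v) for v in truth.duplicate_clusters.values())
        assert n_new == 5
        for src, dups in truth.duplicate_clusters.items():
            for d in dups:
                a, b = by_id[src].sequence, by_id[d].sequence
                assert len(a) == len(b)
                ident = np.mean([x == y for x, y in zip(a, b)])
                assert ident >= 0.98

    def test_fusions_need_two_family_records(self):
        cfg = ik.SimConfig(n_taxa=2, n_fusions=1, seed=0)
        tree = ik.sample_tree(2, seed=0)
        records, truth = ik.evolve_family(tree, cfg)
        with pytest.raises(InvalidArgumentError):
            ik.add_confounders(records[:1], truth, cfg)

    def test_every_non_decoy_in_exactly_one_category(self, default_family):
        cfg, records, truth = default_family
        dups = {d for v in truth.duplicate_clusters.values() for d in v}
        fusions = {f for f, _, _ in truth.fusion_registry}
        family = set(truth.triad_status)
        for r in records:
            cats = [r.id in family, r.id in dups, r.id in fusions,
                    r.id in set(truth.decoy_ids)]
            assert sum(cats) == 1


class TestFixtureIO:
    def test_round_trip(self, tmp_path, default_family):
        _, records, truth = default_family
        ik.write_fixture(records, truth, tmp_path / "fx")
        back, truth2 = ik.read_fixture(tmp_path / "fx")
        assert [(r.id, r.sequence, r.taxonomy) for r in back] == \
            [(r.id, r.sequence, r.taxonomy) for r in records]
        assert truth2.triad_status == truth.triad_status
        assert truth2.fusion_registry == truth.fusion_registry
        assert truth2.duplicate_clusters == truth.duplicate_clusters
        assert sorted(truth2.decoy_ids) == sorted(truth.decoy_ids)
        for rid, coords in truth.site_maps.items():
            assert (truth2.site_maps[rid] == coords).all()

    def test_empty_records_refused(self, tmp_path, default_family):
        _, _, truth = default_family
        with pytest.raises(InvalidArgumentError):
            ik.write_fixture([], truth, tmp_path / "fx")

    def test_checksums_deterministic(self, tmp_path):
        manifests = []
        for d in ("a", "b"):
            records, truth = ik.simulate_dataset(ik.SimConfig(seed=21))
            manifests.append(ik.write_fixture(records, truth, tmp_path / d))
        assert manifests[0] == manifests[1]


def test_config_validation_errors():
    with pytest.raises(InvalidArgumentError):
        ik.SimConfig(n_taxa=1)
    with pytest.raises(InvalidArgumentError):
        ik.SimConfig(degraded_fraction=1.5)
    with pytest.raises(InvalidArgumentError):
        ik.SimConfig(alpha=0.0)
    with pytest.raises(InvalidArgumentError):
        ik.SimConfig(triad_positions=(41, 41, 130))
    with pytest.raises(InvalidArgumentError):
        ik.SimConfig(n_decoys=-1)
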