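import numpy as np
import pytest

import binacle as b
from binacle.cluster import BinRegistry, ClusterError, mcl_refine, mean_silhouette
from binacle.distances import DistanceMatrix


def dm_of(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=list(ids), d=d, compared_sites=np.zeros_like(d, dtype=int))


def random_dm(n, rng, scale=0.1):
    d = rng.uniform(0, scale, (n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return dm_of([f"s{i:02d}" for i in range(n)], d)


class TestSingleLinkage:
    def test_all_distant_gives_singletons(self):
        dm = random_dm(6, np.random.default_rng(0), scale=0.5)
        p = b.single_linkage(dm, 1e-6)
        assert p.n_clusters() == 6

    def test_chaining(self):
        d = [[0, 0.01, 0.03], [0.01, 0, 0.01], [0.03, 0.01, 0]]
        p = b.single_linkage(dm_of("ABC", d), 0.015)
        assert p.n_clusters() == 1

    def test_matches_connected_components_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(4, 15))
            dm = random_dm(n, rng)
            t = float(rng.uniform(0, 0.1))
            p = b.single_linkage(dm, t)
            g = nx.Graph()
            g.add_nodes_from(dm.ids)
            for i in range(n):
                for j in range(i + 1, n):
                    if dm.d[i, j] <= t:
                        g.add_edge(dm.ids[i], dm.ids[j])
            oracle = {frozenset(c) for c in nx.connected_components(g)}
            got = {frozenset(m) for m in p.clusters().values()}
            assert got == oracle

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        dm = random_dm(12, rng)
        prev = b.single_linkage(dm, 0.0)
        for t in np.linspace(0.005, 0.1, 12):
            cur = b.single_linkage(dm, float(t))
            # every previous cluster is contained in one current cluster
            for members in prev.clusters().values():
                assert len({cur.assignment[m] for m in members}) == 1
            prev = cur

    def test_bad_threshold_rejected(self):
        dm = random_dm(3, np.random.default_rng(1))
        with pytest.raises(ClusterError):
            b.single_linkage(dm, 1.5)


class TestMCL:
    def test_disconnected_blocks_separate(self):
        d = np.full((6, 6), 0.04)
        d[:3, :3] = 0.001
        d[3:, 3:] = 0.001
        np.fill_diagonal(d, 0)
        p = mcl_refine(dm_of([f"s{i}" for i in range(6)], d), inflation=2.0)
        got = {frozenset(m) for m in p.clusters().values()}
        assert got == {frozenset({"s0", "s1", "s2"}), frozenset({"s3", "s4", "s5"})}

    def test_all_cross_zero_similarity_gives_singletons(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0)
        p = mcl_refine(dm_of("ABCD", d), inflation=2.0)
        assert p.n_clusters() == 4

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ClusterError):
            mcl_refine(random_dm(4, np.random.default_rng(2)), inflation=1.0)

    def test_planted_two_blocks_recovered(self):
        rng = np.random.default_rng(42)
        ok = 0
        for _ in range(50):
            n1, n2 = 4, 5
            n = n1 + n2
            blocks = [0] * n1 + [1] * n2
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    v = rng.uniform(0.002, 0.008) if blocks[i] == blocks[j] else rng.uniform(0.03, 0.05)
                    d[i, j] = d[j, i] = v
            ids = [f"s{i}" for i in range(n)]
            p = mcl_refine(dm_of(ids, d), inflation=2.0)
            got = {frozenset(m) for m in p.clusters().values()}
            ok += got == {frozenset(ids[:n1]), frozenset(ids[n1:])}
        assert ok >= 48


class TestSilhouette:
    def test_two_tight_distant_pairs_hand_value(self):
        d = np.array(
            [
                [0.00, 0.01, 0.20, 0.22],
                [0.01, 0.00, 0.21, 0.19],
                [0.20, 0.21, 0.00, 0.02],
                [0.22, 0.19, 0.02, 0.00],
            ]
        )
        dm = dm_of("ABCD", d)
        p = b.Partition(assignment={"A": "u", "B": "u", "C": "v", "D": "v"})
        # hand: s(A) = (0.21-0.01)/0.21, s(B) = (0.20-0.01)/0.20, ...
        expect = np.mean(
            [
                (0.21 - 0.01) / 0.21,
                (0.20 - 0.01) / 0.20,
                (0.205 - 0.02) / 0.205,
                (0.205 - 0.02) / 0.205,
            ]
        )
        assert mean_silhouette(dm, p) == pytest.approx(expect)

    def test_single_cluster_zero_by_convention(self):
        dm = random_dm(5, np.random.default_rng(3))
        p = b.Partition(assignment={i: "c" for i in dm.ids})
        assert mean_silhouette(dm, p) == 0.0

    def test_all_singletons_zero(self):
        dm = random_dm(5, np.random.default_rng(3))
        p = b.Partition(assignment={i: i for i in dm.ids})
        assert mean_silhouette(dm, p) == 0.0


class TestBinRegistry:
    def test_label_format_and_sequence(self):
        reg = BinRegistry()
        assert reg.assign(["a"]) == "AAA0001"
        assert reg.assign(["b", "c"]) == "AAA0002"
        assert reg.assign(["a"]) == "AAA0001"  # same content, same label

    def test_persistence_round_trip(self, tmp_path):
        reg = BinRegistry()
        l1 = reg.assign(["x", "y"])
        reg.save(tmp_path / "reg.json")
        reg2 = BinRegistry.load(tmp_path / "reg.json")
        assert reg2.assign(["x", "y"]) == l1
        assert reg2.assign(["z"]) != l1


class TestReslPartition:
    def test_true_partition_recovered(self, small_sim):
        part = b.resl_partition(small_sim["dm"])
        ari, split_err, merge_err = b.score_partition(small_sim["truth"], part)
        assert split_err == [] and merge_err == []
        assert ari >= 0.95

    def test_refinement_never_merges_seed_clusters(self, small_sim):
        dm = small_sim["dm"]
        seeds = b.single_linkage(dm, 0.022)
        part = b.resl_partition(dm)
        for members in part.clusters().values():
            assert len({seeds.assignment[m] for m in members}) == 1

    def test_duplicate_specimen_is_stable(self, small_sim):
        dm = small_sim["dm"]
        part = b.resl_partition(dm)
        # duplicate row: append a copy of the first specimen
        n = len(dm.ids)
        d2 = np.zeros((n + 1, n + 1))
        d2[:n, :n] = dm.d
        d2[n, :n] = d2[:n, n] = dm.d[0, :]
        dup = dm_of(dm.ids + ["dup0"], d2)
        part2 = b.resl_partition(dup)
        assert part2.assignment["dup0"] == part2.assignment[dm.ids[0]]
        for members in part.clusters().values():
            rep = {part2.assignment[m] for m in members}
            assert len(rep) == 1  # others unchanged as a partition

    def test_label_stability_and_new_divergent_label(self, small_sim):
        dm = small_sim["dm"]
        reg = BinRegistry()
        p1 = b.resl_partition(dm, registry=reg)
        p2 = b.resl_partition(dm, registry=reg)
        assert p1.assignment == p2.assignment
        # add one very divergent specimen
        n = len(dm.ids)
        d2 = np.full((n + 1, n + 1), 0.15)
        d2[:n, :n] = dm.d
        d2[n, n] = 0
        grown = dm_of(dm.ids + ["new"], d2)
        p3 = b.resl_partition(grown, registry=reg)
        old_labels = set(p1.assignment.values())
        assert {p3.assignment[i] for i in dm.ids} == old_labels
        assert p3.assignment["new"] not in old_labels

    def test_haplogroup_split_within_seed_cluster(self):
        # two haplogroups 1.6% apart sit inside one 2.2% seed cluster and
        # must be separated by the refinement stage
        cfg = b.SimConfig(
            n_species=4, specimens_per_species=(6, 6),
            split_species=((0, 0.016),), intraspecific_theta=0.002, seed=3,
        )
        records, specimens, truth = b.simulate(cfg)
        matrix, _ = b.align_records(records, b.default_profile())
        part = b.resl_partition(b.distance_matrix(matrix))
        s0 = [i for i, s in truth.species_of.items() if s == "Species_00"]
        labels = {truth.haplogroup_of[i]: part.assignment[i] for i in s0}
        by_hap = {}
        for i in s0:
            by_hap.setdefault(truth.haplogroup_of[i], set()).add(part.assignment[i])
        assert by_hap["A"] != by_hap["B"]
        assert len(by_hap["A"]) == len(by_hap["B"]) == 1
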