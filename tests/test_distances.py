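import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import binacle as b
from binacle.distances import (
    DistanceError,
    DistanceMatrix,
    barcode_gap_table,
    cluster_summary,
    collapse_haplotypes,
    p_distance,
)
from binacle.qc import AlignedMatrix


def matrix_of(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return AlignedMatrix(ids=ids, rows=rows, offsets=[0] * len(rows))


class TestPDistance:
    def test_single_mismatch(self):
        assert p_distance("ACGT", "ACGA") == (0.25, 4)

    def test_ambiguity_excluded(self):
        assert p_distance("ACNT", "ACGT") == (0.0, 3)

    def test_gap_excluded(self):
        assert p_distance("AC-T", "ACGT") == (0.0, 3)

    def test_zero_overlap_is_error(self):
        with pytest.raises(DistanceError):
            p_distance("NNNN", "ACGT")

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(8)
        alphabet = list("ACGTN-")
        for _ in range(50):
            a = "".join(rng.choice(alphabet, size=600, p=[0.23] * 4 + [0.05, 0.03]))
            c = "".join(rng.choice(alphabet, size=600, p=[0.23] * 4 + [0.05, 0.03]))
            mism = sites = 0
            for x, y in zip(a, c):
                if x in "ACGT" and y in "ACGT":
                    sites += 1
                    mism += x != y
            assert p_distance(a, c) == (mism / sites, sites)


class TestPDistanceProperties:
    @given(data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_bounded_and_deletion_consistent(self, data):
        n = data.draw(st.integers(min_value=10, max_value=120))
        a = "A" + data.draw(st.text(alphabet="ACGTN-", min_size=n, max_size=n))
        c = "A" + data.draw(st.text(alphabet="ACGTN-", min_size=n, max_size=n))
        d_ac, sites = p_distance(a, c)
        assert p_distance(c, a) == (d_ac, sites)
        assert 0.0 <= d_ac <= 1.0
        assert sites <= sum(x in "ACGT" for x in a)


class TestDistanceMatrix:
    def test_identical_rows_all_zero(self):
        dm = b.distance_matrix(matrix_of(["ACGT" * 30] * 3), min_overlap=10)
        assert np.all(dm.d == 0)

    def test_matches_elementwise_p_distance(self, small_sim):
        dm, matrix = small_sim["dm"], small_sim["matrix"]
        rng = np.random.default_rng(0)
        for _ in range(30):
            i, j = rng.integers(len(dm.ids), size=2)
            d, n = p_distance(matrix.rows[i], matrix.rows[j])
            assert dm.d[i, j] == pytest.approx(d, abs=1e-15)
            if i != j:
                assert dm.compared_sites[i, j] == n

    def test_symmetry_and_zero_diagonal(self, small_sim):
        dm = small_sim["dm"]
        assert np.array_equal(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)

    def test_low_overlap_pairs_flagged(self):
        rows = ["ACGT" * 10 + "-" * 80, "-" * 80 + "ACGT" * 10]
        dm = b.distance_matrix(matrix_of(rows))
        assert dm.flagged_pairs and dm.flagged_pairs[0][2] in ("low_overlap", "zero_overlap")

    def test_removing_specimen_leaves_rest_unchanged(self, small_sim):
        dm, matrix = small_sim["dm"], small_sim["matrix"]
        sub_align = matrix.subset(matrix.ids[1:])
        dm2 = b.distance_matrix(sub_align)
        np.testing.assert_array_equal(dm.submatrix(matrix.ids[1:]).d, dm2.d)


class TestCollapseHaplotypes:
    def test_identical_sequences_one_haplotype(self):
        dm = b.distance_matrix(matrix_of(["ACGT" * 30] * 3))
        counts = collapse_haplotypes(dm, {i: "sp" for i in dm.ids})
        assert counts == {"sp": 1}

    def test_one_substitution_two_haplotypes(self):
        s = "ACGT" * 30
        dm = b.distance_matrix(matrix_of([s, s[:-1] + "A"]))
        counts = collapse_haplotypes(dm, {i: "sp" for i in dm.ids})
        assert counts == {"sp": 2}

    def test_planted_haplotypes_recovered(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), size=600))
        haplos = [base]
        for k in range(1, 4):  # 4 distinct haplotypes differing at k sites
            s = list(base)
            for pos in range(k):
                s[pos * 7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos * 7]]
            haplos.append("".join(s))
        rows = [haplos[i % 4] for i in range(12)]
        dm = b.distance_matrix(matrix_of(rows))
        counts = collapse_haplotypes(dm, {i: "sp" for i in dm.ids})
        assert counts == {"sp": 4}


class TestSpeciesSummary:
    def test_singleton_species_has_no_intra(self, small_sim):
        summaries = b.species_summary(small_sim["dm"], small_sim["specimens"])
        by = {s.species_label: s for s in summaries}
        for s in by.values():
            if s.n_specimens == 1:
                assert s.mean_intra is None and s.max_intra is None

    def test_pair_mean_equals_max(self):
        rows = ["A" * 200, "A" * 199 + "C", "G" * 200]
        dm = b.distance_matrix(matrix_of(rows, ids=["x1", "x2", "y1"]))
        specs = [
            b.SpecimenRecord(specimen_id="x1", species_label="X x"),
            b.SpecimenRecord(specimen_id="x2", species_label="X x"),
            b.SpecimenRecord(specimen_id="y1", species_label="Y y"),
        ]
        (sx, sy) = b.species_summary(dm, specs)
        assert sx.mean_intra == sx.max_intra == pytest.approx(1 / 200)
        assert sx.nn_species == "Y y"

    def test_nn_is_minimum_heterospecific_distance(self, small_sim):
        dm = small_sim["dm"]
        specimens = {m.specimen_id: m for m in small_sim["specimens"]}
        summaries = b.species_summary(dm, specimens)
        labels = {i: specimens[i].species_label for i in dm.ids}
        for s in summaries:
            own = [i for i in dm.ids if labels[i] == s.species_label]
            other = [i for i in dm.ids if labels[i] != s.species_label]
            brute = min(
                dm.d[dm.index(a), dm.index(o)] for a in own for o in other
            )
            assert s.nn_distance == pytest.approx(brute, abs=1e-15)

    def test_excluded_ranks_do_not_appear(self, small_sim):
        dm = small_sim["dm"]
        specs = [
            b.SpecimenRecord(
                specimen_id=m.specimen_id,
                species_label="Channa sp." if i == 0 else m.species_label,
                label_rank="genus_only" if i == 0 else m.label_rank,
            )
            for i, m in enumerate(small_sim["specimens"])
        ]
        summaries = b.species_summary(dm, specs)
        assert "Channa sp." not in {s.species_label for s in summaries}


class TestClusterSummary:
    def test_pair_at_zero(self):
        dm = b.distance_matrix(matrix_of(["A" * 200] * 2))
        internal, between = cluster_summary(dm, {i: "c1" for i in dm.ids})
        assert internal == {"c1": 0.0}
        assert between == {}

    def test_hand_computed_four_points(self):
        d = np.array(
            [
                [0.00, 0.01, 0.10, 0.12],
                [0.01, 0.00, 0.11, 0.09],
                [0.10, 0.11, 0.00, 0.02],
                [0.12, 0.09, 0.02, 0.00],
            ]
        )
        dm = DistanceMatrix(ids=list("abcd"), d=d, compared_sites=np.zeros((4, 4), int))
        internal, between = cluster_summary(dm, {"a": "u", "b": "u", "c": "v", "d": "v"})
        assert internal == {"u": pytest.approx(0.01), "v": pytest.approx(0.02)}
        assert between[("u", "v")] == pytest.approx((0.10 + 0.12 + 0.11 + 0.09) / 4)

    def test_missing_id_is_error(self):
        dm = b.distance_matrix(matrix_of(["A" * 200] * 2))
        with pytest.raises(DistanceError):
            cluster_summary(dm, {dm.ids[0]: "c"})


class TestBarcodeGap:
    def test_flags(self):
        mk = lambda label, mx, nn: b.distances.SpeciesSummary(
            species_label=label, n_specimens=3, n_haplotypes=2,
            mean_intra=mx / 2, max_intra=mx, nn_distance=nn, nn_species="other",
        )
        df = barcode_gap_table([mk("gapped", 0.003, 0.02), mk("overlapping", 0.074, 0.02)])
        flags = dict(zip(df.species_label, df.barcode_gap))
        assert flags == {"gapped": True, "overlapping": False}

    def test_undefined_intra_flag_none(self):
        s = b.distances.SpeciesSummary(
            species_label="single", n_specimens=1, n_haplotypes=1,
            mean_intra=None, max_intra=None, nn_distance=0.05, nn_species="o",
        )
        df = barcode_gap_table([s])
        assert df.barcode_gap[0] is None

    def test_enforced_gap_all_true(self):
        cfg = b.SimConfig(
            n_species=6, specimens_per_species=(3, 5),
            intraspecific_theta=0.0015, interspecific_range=(0.06, 0.12), seed=2,
        )
        records, specimens, _ = b.simulate(cfg)
        matrix, _ = b.align_records(records, b.default_profile())
        dm = b.distance_matrix(matrix)
        df = barcode_gap_table(b.species_summary(dm, specimens))
        assert df.barcode_gap.all()
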