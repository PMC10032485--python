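"""KO library construction, signature-space annotation, RPKM and ordination."""

import numpy as np
import pandas as pd
import pytest

from sigmeta.classify import fragment_reads
from sigmeta.errors import DataError
from sigmeta.functional import (
    KOProfile,
    annotate_fragments,
    bray_curtis,
    build_ko_library,
    principal_coordinates,
    profiles_to_matrix,
    rpkm,
    top_n_union,
)
from sigmeta.simulate import generate_ko_genes


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLibrary:
    def test_shared_ko_pools_union_of_genes(self):
        rng = np.random.default_rng(0)
        g1, g2 = _random_seq(rng, 100), _random_seq(rng, 120)
        lib = build_ko_library([("K00001", g1, 7), ("K00001", g2, 8)])
        assert set(lib) == {"K00001"}
        assert lib["K00001"].aggregate_length == 220

    def test_disjoint_kos_stay_separate(self):
        rng = np.random.default_rng(1)
        records = [(f"K{i}", _random_seq(rng, 60)) for i in range(1, 7)]
        lib = build_ko_library(records)
        assert len(lib) == 6

    def test_duplicate_gene_counted_once(self):
        rng = np.random.default_rng(2)
        g = _random_seq(rng, 100)
        lib = build_ko_library([("K1", g), ("K1", g)])
        assert lib["K1"].aggregate_length == 100

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            build_ko_library([])


class TestAnnotate:
    @pytest.fixture()
    def two_ko_library(self):
        rng = np.random.default_rng(3)
        shared = _random_seq(rng, 50)
        g1 = _random_seq(rng, 150) + shared
        g2 = shared + _random_seq(rng, 150)
        lib = build_ko_library([("K1", g1), ("K2", g2)])
        return lib, g1, g2, shared

    def test_unique_fragment_counts_with_multiplicity(self, two_ko_library):
        lib, g1, _, _ = two_ko_library
        profile = annotate_fragments({g1[0:50]: 3}, lib)
        counts = dict(zip(profile.table["ko_id"], profile.table["count"]))
        assert counts == {"K1": 3, "K2": 0}

    def test_multi_ko_fragment_discarded(self, two_ko_library):
        lib, _, _, shared = two_ko_library
        profile = annotate_fragments({shared: 2}, lib)
        assert profile.table["count"].sum() == 0
        assert profile.discarded_multi == 2

    def test_conservation(self, two_ko_library):
        lib, g1, g2, shared = two_ko_library
        rng = np.random.default_rng(4)
        fragments = {
            g1[10:60]: 2,
            g2[60:110]: 1,
            shared: 5,
            _random_seq(rng, 50): 4,  # matches nothing
        }
        profile = annotate_fragments(fragments, lib)
        assigned = profile.table["count"].sum()
        assert (
            assigned + profile.discarded_multi + profile.discarded_nohit
            == profile.total_fragments
            == 12
        )

    def test_planted_overlap_discards_shared_space(self):
        """Reads from the shared block between two KOs never count."""
        koset = generate_ko_genes(n_kos=2, cross_ko_overlap=1.0, gene_length=300, seed=5)
        lib = build_ko_library([(ko, seq) for ko, seq, _ in koset.records])
        reads = [seq for seq in koset.genes.values()]
        fragments, _ = fragment_reads(reads)
        profile = annotate_fragments(fragments, lib)
        assert profile.table["count"].sum() == 0
        assert profile.discarded_multi == profile.total_fragments


class TestRPKM:
    def test_worked_value(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_count(self):
        assert rpkm(0, 1000, 100) == 0.0

    def test_doubling_depth_halves_value(self):
        assert rpkm(10, 1000, 2 * 10**6) == pytest.approx(rpkm(10, 1000, 10**6) / 2)

    def test_zero_denominators_rejected(self):
        with pytest.raises(DataError):
            rpkm(10, 0, 100)
        with pytest.raises(DataError):
            rpkm(10, 100, 0)


def _profile_from(sample_id, values):
    table = pd.DataFrame(
        {"ko_id": list(values), "count": 1, "rpkm": list(values.values())}
    )
    return KOProfile(sample_id, table, total_fragments=1, discarded_multi=0, discarded_nohit=0)


class TestTopNUnion:
    def test_fewer_than_n_returns_all(self):
        p = _profile_from("s1", {"K1": 5.0, "K2": 3.0, "K3": 1.0})
        assert top_n_union([p], n=500) == {"K1", "K2", "K3"}

    def test_identical_top_sets_union_is_same(self):
        p1 = _profile_from("s1", {"K1": 5.0, "K2": 3.0})
        p2 = _profile_from("s2", {"K1": 4.0, "K2": 9.0})
        assert top_n_union([p1, p2], n=2) == {"K1", "K2"}

    def test_disjoint_top_sets_union(self):
        p1 = _profile_from("s1", {"K1": 5.0, "K2": 3.0, "K5": 0.1})
        p2 = _profile_from("s2", {"K3": 4.0, "K4": 9.0, "K6": 0.1})
        assert top_n_union([p1, p2], n=2) == {"K1", "K2", "K3", "K4"}

    def test_tie_break_by_ko_id(self):
        p = _profile_from("s1", {"K2": 5.0, "K1": 5.0, "K3": 5.0})
        assert top_n_union([p], n=2) == {"K1", "K2"}


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert bray_curtis(m).at["a", "b"] == 0.0

    def test_disjoint_support_is_one(self):
        m = pd.DataFrame([[2.0, 0.0], [0.0, 2.0]], index=["a", "b"])
        assert bray_curtis(m).at["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_third(self):
        m = pd.DataFrame([[1.0, 1.0], [1.0, 0.0]], index=["a", "b"])
        assert bray_curtis(m).at["a", "b"] == pytest.approx(1 / 3)

    def test_bounds_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.random((5, 8)))
        dm = bray_curtis(m).to_numpy()
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)
        assert ((dm >= 0) & (dm <= 1)).all()

    def test_two_zero_rows_rejected(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DataError):
            bray_curtis(m)


class TestPCoA:
    def test_identical_samples_coincide(self):
        m = pd.DataFrame(
            [[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        coords, _ = principal_coordinates(m)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_equilateral_distances_preserved(self):
        m = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        coords, _ = principal_coordinates(m, n_axes=2)
        pts = coords.to_numpy()
        d01 = np.linalg.norm(pts[0] - pts[1])
        d02 = np.linalg.norm(pts[0] - pts[2])
        d12 = np.linalg.norm(pts[1] - pts[2])
        assert d01 == pytest.approx(d02) == pytest.approx(d12) == pytest.approx(1.0)

    def test_euclidean_input_recovered(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(7)
        points = rng.random((4, 2))
        dm = pd.DataFrame(squareform(pdist(points)))
        coords, explained = principal_coordinates(dm, n_axes=2)
        recon = squareform(pdist(coords.to_numpy()))
        assert np.allclose(recon, dm.to_numpy(), atol=1e-8)
        assert explained.sum() == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        """Coordinates agree (up to sign) with scikit-bio's PCoA."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.random((6, 10)))
        dm = bray_curtis(m)
        ours, _ = principal_coordinates(dm, n_axes=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.to_numpy()), number_of_dimensions=2
        ).samples.to_numpy()
        for axis in range(2):
            ref_axis = ref[:, axis]
            got = ours.to_numpy()[:, axis]
            assert np.allclose(got, ref_axis, atol=1e-8) or np.allclose(
                got, -ref_axis, atol=1e-8
            )

    def test_asymmetric_rejected(self):
        m = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(DataError):
            principal_coordinates(m)

    def test_planted_clusters_separate_on_first_axis(self):
        """Two KO-usage groups should split along PCo1 (silhouette > 0.5)."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(9)
        base_a = rng.random(30) * np.array([1] * 15 + [0] * 15)
        base_b = rng.random(30) * np.array([0] * 15 + [1] * 15)
        rows, labels = [], []
        for i in range(6):
            noise = 0.05 * rng.random(30)
            rows.append((base_a if i < 3 else base_b) + noise)
            labels.append(int(i < 3))
        m = pd.DataFrame(rows)
        coords, _ = principal_coordinates(bray_curtis(m), n_axes=2)
        score = silhouette_score(coords.to_numpy()[:, :1], labels)
        assert score > 0.5


class TestProfilesToMatrix:
    def test_restriction_and_fill(self):
        p1 = _profile_from("s1", {"K1": 5.0, "K2": 3.0})
        p2 = _profile_from("s2", {"K2": 1.0, "K3": 2.0})
        m = profiles_to_matrix([p1, p2], ko_ids={"K1", "K2"})
        assert list(m.columns) == ["K1", "K2"]
        assert m.at["s2", "K1"] == 0.0
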