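"""Interaction detectors, SIFt fingerprints and pose clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from poseval import fixtures, interactions
from poseval.interactions import (
    InteractionFingerprint,
    PoseRecord,
    build_sift,
    cluster_poses,
    detect_hbonds,
    detect_hydrophobic,
    detect_ionic,
    detect_pipi,
    select_top_k,
    tanimoto,
)

from conftest import make_structure


def _hb_complex(angle_dha=180.0, d_ha=2.0):
    """Ligand O-H donor aimed at a receptor O acceptor with set geometry."""
    theta = np.deg2rad(180.0 - angle_dha)
    h = np.array([0.0, 0.96, 0.0])
    acceptor = h + d_ha * np.array([np.sin(theta), np.cos(theta), 0.0])
    return make_structure(
        [("O", [0, 0, 0], {"name": "O1"}),
         ("H", h, {"name": "H1"}),
         ("O", acceptor, {"name": "OG", "res_name": "SER"})],
        roles=["ligand", "ligand", "receptor"],
    )


class TestHBonds:
    def test_linear_inside_cutoffs(self):
        assert len(detect_hbonds(_hb_complex(180.0, 2.0))) == 1

    def test_bent_angle_rejected(self):
        assert detect_hbonds(_hb_complex(100.0, 2.0)) == []

    def test_distance_rejected(self):
        assert detect_hbonds(_hb_complex(180.0, 3.2)) == []

    def test_direction_follows_ligand_role(self):
        rec = detect_hbonds(_hb_complex())[0]
        assert rec.direction == "donor"
        assert rec.residue == ("A", 1, "SER")

    def test_planted_fixture_matches_exhaustive_enumeration(self):
        complex, _ = fixtures.make_toy_complex(n_hb=3)
        found = detect_hbonds(complex)
        assert len(found) == 3
        # oracle: exhaustive pairwise scan over every D-H x A combination
        coords = complex.coords
        roles = complex.role_mask
        expected = 0
        for d, ad in enumerate(complex.atoms):
            if ad.element not in ("N", "O"):
                continue
            hs = [j for j, a in enumerate(complex.atoms)
                  if a.element == "H" and roles[j] == roles[d]
                  and 0 < np.linalg.norm(coords[j] - coords[d]) <= 1.25]
            for acc, aa in enumerate(complex.atoms):
                if aa.element not in ("N", "O") or roles[acc] == roles[d]:
                    continue
                for h in hs:
                    r = np.linalg.norm(coords[h] - coords[acc])
                    v1 = coords[d] - coords[h]
                    v2 = coords[acc] - coords[h]
                    cosang = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
                    if r <= 2.8 and np.degrees(np.arccos(cosang)) >= 120.0:
                        expected += 1
        assert len(found) == expected


class TestRingsChargesContacts:
    def _ring_pair(self, dist, angle_deg):
        ang = np.arange(6) * np.pi / 3
        lig = np.column_stack([1.39 * np.cos(ang), np.zeros(6), 1.39 * np.sin(ang)])
        rot = Rotation.from_euler("x", angle_deg, degrees=True).as_matrix()
        rec = lig @ rot.T + np.array([0.0, dist, 0.0])
        structure = make_structure(
            [("C", c) for c in lig] + [("C", c, {"res_name": "PHE"}) for c in rec],
            roles=["ligand"] * 6 + ["receptor"] * 6,
        )
        rings = {"ligand": [list(range(6))], "receptor": [list(range(6, 12))]}
        return structure, rings

    def test_face_to_face(self):
        s, rings = self._ring_pair(3.8, 0.0)
        recs = detect_pipi(s, rings)
        assert len(recs) == 1 and recs[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_edge_to_face(self):
        s, rings = self._ring_pair(5.0, 90.0)
        assert len(detect_pipi(s, rings)) == 1

    def test_distance_cutoff(self):
        s, rings = self._ring_pair(6.0, 0.0)
        assert detect_pipi(s, rings) == []

    def test_small_ring_rejected(self):
        s, rings = self._ring_pair(3.8, 0.0)
        rings["ligand"][0] = rings["ligand"][0][:2]
        with pytest.raises(ValueError):
            detect_pipi(s, rings)

    def _ion_pair(self, dist, lig_charge=1.0):
        return make_structure(
            [("N", [0, 0, 0], {"charge": lig_charge}),
             ("O", [0, dist, 0], {"name": "OD1", "res_name": "ASP"})],
            roles=["ligand", "receptor"],
        )

    def test_ionic_pair_found(self):
        assert len(detect_ionic(self._ion_pair(3.0))) == 1

    def test_ionic_distance_cutoff(self):
        assert detect_ionic(self._ion_pair(5.0)) == []

    def test_like_charges_rejected(self):
        s = make_structure(
            [("N", [0, 0, 0], {"charge": 1.0}),
             ("N", [0, 3, 0], {"name": "NZ", "res_name": "LYS"})],
            roles=["ligand", "receptor"],
        )
        assert detect_ionic(s) == []

    def test_no_charges_errors(self):
        s = make_structure([("C", [0, 0, 0]), ("C", [0, 3, 0])],
                           roles=["ligand", "receptor"])
        for a in s.atoms:
            a.charge = None
        with pytest.raises(ValueError):
            detect_ionic(s)

    def test_hydrophobic_pair_and_polarity_rule(self):
        plain = make_structure([("C", [0, 0, 0]), ("C", [0, 4, 0])],
                               roles=["ligand", "receptor"])
        assert len(detect_hydrophobic(plain)) == 1
        # carbonyl-like receptor C (bonded to O) is excluded
        carbonyl = make_structure(
            [("C", [0, 0, 0]), ("C", [0, 4, 0]), ("O", [0, 5.2, 0])],
            roles=["ligand", "receptor", "receptor"],
        )
        assert detect_hydrophobic(carbonyl) == []

    def test_two_hydrophobic_residues(self):
        complex, _ = fixtures.make_toy_complex(n_hydrophobic=2)
        assert len(detect_hydrophobic(complex)) == 2


def test_detectors_rigid_invariant(rng):
    complex, rings = fixtures.make_toy_complex(n_hb=2, n_pipi=1, n_ionic=1,
                                               n_hydrophobic=1)
    rot = Rotation.random(random_state=11).as_matrix()
    shift = np.array([7.0, -3.0, 2.0])
    moved = complex.with_coords(complex.coords @ rot.T + shift)

    def signature(c):
        return sorted((r.kind, r.residue, round(r.distance, 6))
                      for r in interactions.detect_all(c, ring_defs=rings))

    assert signature(moved) == signature(complex)


def test_cutoff_monotonicity():
    complex, _ = fixtures.make_toy_complex(n_hb=2, n_hydrophobic=2)
    base_hb = len(detect_hbonds(complex, d_ha_max=2.8))
    base_ph = len(detect_hydrophobic(complex, d_max=4.5))
    assert len(detect_hbonds(complex, d_ha_max=3.5)) >= base_hb
    assert len(detect_hydrophobic(complex, d_max=6.0)) >= base_ph


# ---------------------------------------------------------------- SIFt


def _site(complex):
    seen = {}
    for i, a in enumerate(complex.atoms):
        if complex.role_mask[i] == "receptor":
            seen[(a.chain, a.res_id, a.res_name)] = None
    return list(seen)


def test_sift_single_hb_donor_contact():
    complex, _ = fixtures.make_toy_complex(n_hb=1, n_filler=0)
    pose = PoseRecord("p1", complex, score=-10.0)
    fp = build_sift(pose, _site(complex))
    ser_row = fp.residue_index.index(("A", 1, "SER"))
    bits = dict(zip(interactions.SIFT_BITS, fp.bits[ser_row]))
    assert bits["any_contact"] == 1 and bits["polar"] == 1
    # ligand donates, so the residue side accepts
    assert bits["hb_acceptor"] == 1 and bits["hb_donor"] == 0


def test_sift_no_contacts_all_zero():
    complex, _ = fixtures.make_toy_complex(n_hb=1, n_filler=0)
    # move the ligand far away
    coords = complex.coords
    for i in complex.indices(role="ligand"):
        coords[i] += [0.0, 50.0, 0.0]
    pose = PoseRecord("p_far", complex.with_coords(coords), score=-5.0)
    fp = build_sift(pose, _site(complex))
    assert fp.bits.sum() == 0


def test_sift_matches_hand_built_matrix():
    complex, rings = fixtures.make_toy_complex(n_hb=1, n_pipi=1, n_filler=0)
    pose = PoseRecord("p", complex, score=-8.0)
    fp = build_sift(pose, _site(complex), ring_defs=rings)
    expected = {}
    for key in fp.residue_index:
        expected[key] = np.zeros(9, dtype=np.uint8)
    # SER 1: sidechain contact + polar + residue-acceptor HB
    expected[("A", 1, "SER")][[0, 2, 3, 6]] = 1
    # PHE 2: sidechain contact + aromatic + hydrophobic (stacked rings touch)
    expected[("A", 2, "PHE")][[0, 2, 4, 7]] = 1
    # GLY 3: the binding-site backbone anchor sits at the contact radius
    expected[("A", 3, "GLY")][[0, 1]] = 1
    for k, key in enumerate(fp.residue_index):
        np.testing.assert_array_equal(fp.bits[k], expected[key], err_msg=str(key))


def test_sift_empty_site_errors():
    complex, _ = fixtures.make_toy_complex()
    with pytest.raises(ValueError):
        build_sift(PoseRecord("p", complex, 0.0), [])


def _fp(bits_rows):
    idx = [("A", i + 1, "RES") for i in range(len(bits_rows))]
    return InteractionFingerprint(idx, np.array(bits_rows, dtype=np.uint8))


def test_tanimoto_closed_forms():
    a = _fp([[1, 1, 0, 0, 0, 0, 0, 0, 0]])
    assert tanimoto(a, a) == 1.0
    b = _fp([[0, 0, 1, 1, 0, 0, 0, 0, 0]])
    assert tanimoto(a, b) == 0.0
    c = _fp([[1, 1, 1, 1, 0, 0, 0, 0, 0]])  # 3 shared of 5 set total
    d = _fp([[1, 1, 1, 0, 1, 0, 0, 0, 0]])
    assert tanimoto(c, d) == pytest.approx(0.6)
    zero = _fp([[0] * 9])
    assert tanimoto(zero, zero) == 1.0


def test_tanimoto_residue_mismatch():
    a = _fp([[1] + [0] * 8])
    b = InteractionFingerprint([("B", 9, "XXX")], np.zeros((1, 9), dtype=np.uint8))
    with pytest.raises(ValueError):
        tanimoto(a, b)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=18, max_size=18),
       st.lists(st.integers(0, 1), min_size=18, max_size=18))
def test_tanimoto_properties(xs, ys):
    a = _fp([xs[:9], xs[9:]])
    b = _fp([ys[:9], ys[9:]])
    t = tanimoto(a, b)
    assert 0.0 <= t <= 1.0
    assert t == tanimoto(b, a)
    assert tanimoto(a, a) == 1.0


# ---------------------------------------------------------------- clustering


def _pose(pid, bits, score):
    complex, _ = fixtures.make_toy_complex(n_filler=0)
    return PoseRecord(pid, complex, score, fingerprint=_fp(bits))


ARCHETYPES = [
    [[1, 1, 0, 0, 0, 0, 0, 0, 0], [0] * 9],
    [[0, 0, 1, 1, 0, 0, 0, 0, 0], [0] * 9],
    [[0] * 9, [1, 0, 0, 0, 1, 0, 0, 0, 0]],
    [[0] * 9, [0, 1, 0, 0, 0, 1, 0, 0, 1]],
]


def test_identical_fingerprints_collapse_to_best_score():
    poses = [_pose(f"p{i}", ARCHETYPES[0], score=-7.0 - i) for i in range(4)]
    result = cluster_poses(poses)
    assert result.n_clusters == 1
    assert result.representatives[0].pose_id == "p3"  # lowest score


def test_disjoint_fingerprints_stay_separate():
    poses = [_pose("a", ARCHETYPES[0], -9.0), _pose("b", ARCHETYPES[1], -8.0)]
    assert cluster_poses(poses).n_clusters == 2


def test_archetype_clusters_match_brute_force():
    poses = [
        _pose(f"p{i}", ARCHETYPES[i % 4], score=-10.0 + 0.1 * i) for i in range(8)
    ]
    result = cluster_poses(poses, sim_threshold=0.7)
    assert result.n_poses == 8 and result.n_clusters == 4
    # brute-force check: a valid complete-linkage partition at threshold has
    # all within-cluster similarities >= t; here archetypes are disjoint, so
    # the partition must equal the archetype grouping exactly
    groups = {}
    for c in result.clusters:
        for p in c:
            groups[p.pose_id] = id(c)
    for i, j in itertools.combinations(range(8), 2):
        same = groups[f"p{i}"] == groups[f"p{j}"]
        assert same == (i % 4 == j % 4)


def test_partition_is_permutation_invariant(rng):
    poses = [_pose(f"p{i}", ARCHETYPES[i % 4], score=-10.0 + 0.1 * i)
             for i in range(8)]
    base = cluster_poses(poses)
    shuffled = list(poses)
    rng.shuffle(shuffled)
    perm = cluster_poses(shuffled)
    def as_sets(res):
        return {frozenset(p.pose_id for p in c) for c in res.clusters}
    assert as_sets(base) == as_sets(perm)
    assert [p.pose_id for p in base.representatives] == \
           [p.pose_id for p in perm.representatives]


def test_every_pose_in_exactly_one_cluster():
    poses = [_pose(f"p{i}", ARCHETYPES[i % 3], -5.0 - i) for i in range(9)]
    result = cluster_poses(poses)
    ids = [p.pose_id for c in result.clusters for p in c]
    assert sorted(ids) == sorted(p.pose_id for p in poses)


def test_empty_pose_list_errors():
    with pytest.raises(ValueError):
        cluster_poses([])


def test_select_top_k():
    reps = [_pose(f"p{i}", ARCHETYPES[0], score=-float(i)) for i in range(15)]
    top = select_top_k(reps, k=3)
    assert [p.score for p in top] == [-14.0, -13.0, -12.0]
    assert len(select_top_k(reps[:2], k=3)) == 2
    assert select_top_k(reps, k=1)[0].score == -14.0
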