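"""Scaffold screening: enumeration combinatorics, mirroring, matching, ranking."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from octmatch.errors import InsufficientSitesError
from octmatch.fixtures import make_toy_scaffold_library
from octmatch.geometry import RigidTransform, bond_angle, polygon_error
from octmatch.scaffold import (
    HotspotStub,
    ScaffoldGeometry,
    enumerate_targets,
    match_scaffold,
    mirror_residue,
    mirror_scaffold,
    rank_matches,
)


@pytest.fixture(scope="module")
def library():
    return make_toy_scaffold_library(16, seed=0)


class TestEnumerateTargets:
    def test_four_sites_give_four_triangles(self, library):
        scaffolds, _ = library
        instances = enumerate_targets(scaffolds[0], 3)
        combos = {inst[1].sites for inst in instances}
        assert len(combos) == 4

    def test_four_sites_give_32_search_instances(self, library):
        scaffolds, _ = library
        assert len(enumerate_targets(scaffolds[0], 3)) == 32

    def test_three_sites_give_eight_instances(self, library):
        scaffolds, _ = library
        s = scaffolds[0]
        small = ScaffoldGeometry(
            scaffold_id="s3",
            residues=s.residues[:3],
            takeoff_sites=s.takeoff_sites[:3],
        )
        assert len(enumerate_targets(small, 3)) == 8

    @pytest.mark.parametrize("m,n", [(4, 3), (5, 3), (6, 4), (8, 2)])
    def test_closed_form_count(self, m, n, rng):
        residues = []
        for i in range(m):
            cb = rng.normal(size=3) * 4
            from octmatch.fixtures import _make_residue

            residues.append(_make_residue(f"R{i}", cb, rng.normal(size=3), rng))
        s = ScaffoldGeometry(
            scaffold_id="x",
            residues=tuple(residues),
            takeoff_sites=tuple((i, "CB") for i in range(m)),
        )
        assert len(enumerate_targets(s, n)) == math.comb(m, n) * 2**n

    def test_too_few_sites_raise(self, library):
        scaffolds, _ = library
        with pytest.raises(InsufficientSitesError):
            enumerate_targets(scaffolds[0], 5)


class TestMirror:
    def test_empty_subset_is_identity(self, library):
        scaffolds, _ = library
        s = scaffolds[0]
        same = mirror_scaffold(s, [])
        for a, b in zip(s.residues, same.residues):
            for name in a.atoms:
                assert np.allclose(a.atoms[name], b.atoms[name])

    def test_involution(self, library):
        scaffolds, _ = library
        s = scaffolds[1]
        twice = mirror_scaffold(mirror_scaffold(s, [0, 2]), [0, 2])
        for a, b in zip(s.residues, twice.residues):
            for name in a.atoms:
                assert np.allclose(a.atoms[name], b.atoms[name], atol=1e-9)
        assert twice.enantiomer_labels == s.enantiomer_labels

    def test_mirror_flips_labels(self, library):
        scaffolds, _ = library
        flipped = mirror_scaffold(scaffolds[0], [1])
        assert flipped.enantiomer_labels[1] == "D"
        assert flipped.enantiomer_labels[0] == "L"

    def test_mirror_preserves_within_residue_distances(self, library):
        scaffolds, _ = library
        res = scaffolds[0].residues[0]
        mirrored = mirror_residue(res)
        names = sorted(res.atoms)
        before = [
            np.linalg.norm(res.atoms[a] - res.atoms[b])
            for a, b in itertools.combinations(names, 2)
        ]
        after = [
            np.linalg.norm(mirrored.atoms[a] - mirrored.atoms[b])
            for a, b in itertools.combinations(names, 2)
        ]
        assert np.allclose(before, after, atol=1e-9)


def exhaustive_match_oracle(scaffolds, stubs, delta, delta_angle):
    """Independent direct screen: no library code paths shared with the
    implementation beyond data containers; superposition via scipy."""
    target = np.array([st.connect_coord for st in stubs])
    n = len(stubs)
    survivors = set()
    for s in scaffolds:
        for combo in itertools.combinations(range(s.n_sites), n):
            for mask in itertools.product((False, True), repeat=n):
                coords = np.array(
                    [s.site_coord(site, mir) for site, mir in zip(combo, mask)]
                )
                for perm in itertools.permutations(range(n)):
                    ordered = coords[list(perm)]
                    dmat = lambda p: np.linalg.norm(
                        p[:, None, :] - p[None, :, :], axis=-1
                    )
                    err = np.abs(dmat(ordered) - dmat(target)).max()
                    if err > delta:
                        continue
                    rot, _ = Rotation.align_vectors(
                        target - target.mean(axis=0), ordered - ordered.mean(axis=0)
                    )
                    placed = lambda x: rot.apply(x - ordered.mean(axis=0)) + target.mean(axis=0)
                    ok = True
                    for stub_idx, kk in enumerate(perm):
                        site = combo[kk]
                        ri, _ = s.takeoff_sites[site]
                        res = s.residues[ri]
                        if mask[kk]:
                            res = mirror_residue(res)
                        for ja in stubs[stub_idx].optimal_angles:
                            ang = bond_angle(
                                placed(res.atoms[ja.arm_atom]),
                                placed(res.atoms[ja.vertex_atom]),
                                stubs[stub_idx].connect_coord,
                            )
                            if abs(ang - ja.optimal) > delta_angle:
                                ok = False
                    if ok:
                        survivors.add((s.scaffold_id, combo, mask))
                        break
    return survivors


class TestMatchScaffold:
    def test_known_answer_is_perfect(self, library):
        scaffolds, stubs = library
        matches = match_scaffold(scaffolds[:1], stubs, delta=0.3, delta_angle=0.2)
        best = rank_matches(matches)[0]
        assert best.scaffold_id == "scaffold00"
        assert best.shape_rmsd == pytest.approx(0.0, abs=1e-9)
        assert best.angle_rmsd == pytest.approx(0.0, abs=1e-9)
        assert best.polygon_err == pytest.approx(0.0, abs=1e-9)

    def test_scaled_stubs_never_match(self, library):
        scaffolds, stubs = library
        delta = 0.3
        scaled = [
            HotspotStub(
                name=st.name,
                atoms={k: v * (1 + 2 * delta) for k, v in st.atoms.items()},
                connect_atom=st.connect_atom,
                optimal_angles=st.optimal_angles,
            )
            for st in stubs
        ]
        # scaling by (1 + 2*delta) inflates every >=5 Å edge far beyond delta
        assert match_scaffold(scaffolds, scaled, delta=delta, delta_angle=0.2) == []

    def test_survivors_equal_exhaustive_oracle(self):
        scaffolds, stubs = make_toy_scaffold_library(10, seed=3)
        delta, delta_angle = 0.8, 0.25
        matches = match_scaffold(scaffolds, stubs, delta=delta, delta_angle=delta_angle)
        got = {(m.scaffold_id, m.sites, m.mirror_mask) for m in matches}
        want = exhaustive_match_oracle(scaffolds, stubs, delta, delta_angle)
        assert got == want

    def test_checkangle_invariant_under_global_rigid_motion(self, rng):
        """Moving the whole problem rigidly must not change the survivor set."""
        scaffolds, stubs = make_toy_scaffold_library(6, seed=5)
        base = match_scaffold(scaffolds, stubs, delta=0.6, delta_angle=0.25)
        rot = Rotation.random(random_state=np.random.RandomState(8)).as_matrix()
        trans = np.array([3.0, -7.0, 11.0])
        move = RigidTransform(rot, trans)
        moved_scaffolds = [
            ScaffoldGeometry(
                scaffold_id=s.scaffold_id,
                residues=tuple(
                    type(r)(name=r.name,
                            atoms={k: move.apply(v)[0] for k, v in r.atoms.items()},
                            backbone=r.backbone)
                    for r in s.residues
                ),
                takeoff_sites=s.takeoff_sites,
            )
            for s in scaffolds
        ]
        moved_stubs = [
            HotspotStub(
                name=st.name,
                atoms={k: move.apply(v)[0] for k, v in st.atoms.items()},
                connect_atom=st.connect_atom,
                optimal_angles=st.optimal_angles,
            )
            for st in stubs
        ]
        moved = match_scaffold(moved_scaffolds, moved_stubs, delta=0.6, delta_angle=0.25)
        key = lambda ms: sorted((m.scaffold_id, m.sites, m.mirror_mask) for m in ms)
        assert key(base) == key(moved)
        for b, m in zip(rank_matches(base), rank_matches(moved)):
            assert b.shape_rmsd == pytest.approx(m.shape_rmsd, abs=1e-8)
            assert b.angle_rmsd == pytest.approx(m.angle_rmsd, abs=1e-8)


class TestFlexibleStubs:
    def test_manifold_stubs_route_through_octree_search(self, rng):
        """A stub with a cloud of attachment positions still finds the
        known-answer scaffold, now via the adaptive search."""
        from octmatch.manifold import Manifold

        scaffolds, stubs = make_toy_scaffold_library(2, seed=0)
        flex = []
        for st in stubs:
            cloud = np.vstack(
                [st.connect_coord,
                 st.connect_coord + rng.uniform(-1.5, 1.5, size=(10, 3))]
            )
            flex.append(
                HotspotStub(
                    name=st.name, atoms=st.atoms, connect_atom=st.connect_atom,
                    optimal_angles=st.optimal_angles,
                    manifold=Manifold(points=cloud),
                )
            )
        matches = match_scaffold(scaffolds, flex, delta=0.3, delta_angle=0.2)
        assert any(m.scaffold_id == "scaffold00" for m in matches)
        for m in matches:
            assert m.polygon_err <= 0.3 + 1e-9


class TestRankMatches:
    def test_perfect_match_ranks_first(self, library):
        scaffolds, stubs = library
        matches = match_scaffold(scaffolds, stubs, delta=0.5, delta_angle=0.2)
        ranked = rank_matches(matches)
        assert ranked[0].scaffold_id == "scaffold00"
        assert ranked[0].shape_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_order_matches_independent_sort(self, library):
        scaffolds, stubs = library
        matches = match_scaffold(scaffolds, stubs, delta=0.5, delta_angle=0.25)
        w = 2.5
        ranked = rank_matches(matches, weight=w)
        scores = [m.shape_rmsd**2 + w * m.angle_rmsd**2 for m in ranked]
        assert scores == sorted(scores)

    def test_single_match_is_itself(self, library):
        scaffolds, stubs = library
        matches = match_scaffold(scaffolds[:1], stubs, delta=0.1, delta_angle=0.2)
        ranked = rank_matches(matches)
        assert len(ranked) >= 1
        assert ranked[0].scaffold_id == "scaffold00"
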