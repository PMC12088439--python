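import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from catm.occupancy import mask_voxel_indices
from catm.orientation import (RotationGrid, angle_between_axes,
                              euler_to_rotation, normal_axis,
                              rotation_from_axis)
from catm.placement import (Candidate, CandidateList, CatmConfig, clash_check,
                            greedy_place, local_match, merge_assignments,
                            run_catm)
from catm.particles import ParticleSet
from catm.volume import Volume

IDENT = Rotation.identity()


@pytest.fixture(scope="module")
def frame():
    return Volume(np.zeros((64, 64, 64), dtype=np.float32))


class TestLocalMatch:
    def test_isolated_particle_recovered_from_anchor(self, single_particle_scene,
                                                     nuc_template, imaging):
        vol, pos, rot = single_particle_scene
        out = local_match(vol, nuc_template, pos, 5.0, RotationGrid(15.0),
                          imaging)
        best = out.candidates[0]
        assert np.linalg.norm(best.position - pos) <= np.sqrt(3)
        err = angle_between_axes(normal_axis(best.rotation), normal_axis(rot))
        assert err <= 15.0 + 5.0

    def test_retention_threshold_respected(self, single_particle_scene,
                                           nuc_template, imaging):
        vol, pos, _ = single_particle_scene
        out = local_match(vol, nuc_template, pos, 5.0, RotationGrid(20.0),
                          imaging, retain_threshold=0.3)
        assert all(c.ccc >= 0.3 for c in out.candidates)

    def test_anchor_in_pure_noise_unassigned(self, rng, nuc_template, imaging):
        noise = Volume(rng.normal(size=(64, 64, 64)).astype(np.float32))
        out = local_match(noise, nuc_template, np.array([32.0, 32, 32]), 3.0,
                          RotationGrid(30.0), imaging, retain_threshold=0.9)
        assert out.candidates == []


class TestClashCheck:
    def test_distant_discs_no_clash(self, nuc_mask, frame):
        assert not clash_check(nuc_mask, frame, [20, 20, 20], IDENT,
                               [40, 40, 40], IDENT)

    def test_coaxial_face_to_face_overlap(self, nuc_mask, frame):
        assert clash_check(nuc_mask, frame, [32, 32, 30], IDENT,
                           [32, 32, 33], IDENT)

    def test_edge_to_edge_touching_no_overlap(self, nuc_mask, frame):
        # centers one diameter apart in-plane: surfaces touch exactly; with
        # the strict half-sample mask convention this is not a clash at
        # tolerance 0 (oracle: count shared voxels directly)
        pa, pb = np.array([26.0, 32, 32]), np.array([37.0, 32, 32])
        ia = mask_voxel_indices(nuc_mask, IDENT, pa, frame)
        ib = mask_voxel_indices(nuc_mask, IDENT, pb, frame)
        assert len(np.intersect1d(ia, ib, assume_unique=True)) == 0
        assert not clash_check(nuc_mask, frame, pa, IDENT, pb, IDENT,
                               tolerance_voxels=0)


def _lists_from(specs):
    """Build candidate lists from [(anchor, [(pos, rot, ccc), ...]), ...]."""
    out = []
    for i, (anchor, cands) in enumerate(specs):
        cl = [Candidate(np.asarray(p, float), r, c) for p, r, c in cands]
        cl.sort(key=lambda c: -c.ccc)
        out.append(CandidateList(i, np.asarray(anchor, float), cl))
    return out


class TestGreedyPlace:
    def test_no_clash_everyone_gets_top_candidate(self, nuc_mask, frame):
        lists = _lists_from([
            ([16, 16, 16], [([16, 16, 16], IDENT, 0.9),
                            ([17, 16, 16], IDENT, 0.5)]),
            ([44, 44, 44], [([44, 44, 44], IDENT, 0.7)]),
        ])
        st = greedy_place(lists, frame, nuc_mask)
        assert st.placed[0].ccc == 0.9 and st.placed[1].ccc == 0.7
        assert st.rejected == []

    def test_second_candidate_resolves_clash(self, nuc_mask, frame):
        # particle 1's top pose sits face-to-face on particle 0; its second
        # pose (offset along z) does not
        side = rotation_from_axis([1.0, 0.0, 0.0])
        lists = _lists_from([
            ([32, 32, 30], [([32, 32, 30], IDENT, 0.9)]),
            ([32, 32, 34], [([32, 32, 33], IDENT, 0.8),
                            ([32, 32, 38], IDENT, 0.6)]),
        ])
        st = greedy_place(lists, frame, nuc_mask)
        assert st.placed[1].position[2] == 38.0

    def test_deterministic_tie_break_by_particle_id(self, nuc_mask, frame):
        lists = _lists_from([
            ([20, 20, 20], [([20, 20, 20], IDENT, 0.8)]),
            ([20, 20, 24], [([20, 20, 23], IDENT, 0.8)]),
        ])
        st1 = greedy_place(lists, frame, nuc_mask)
        st2 = greedy_place(_lists_from([
            ([20, 20, 20], [([20, 20, 20], IDENT, 0.8)]),
            ([20, 20, 24], [([20, 20, 23], IDENT, 0.8)]),
        ]), frame, nuc_mask)
        assert sorted(st1.placed) == sorted(st2.placed)
        for k in st1.placed:
            assert np.array_equal(st1.placed[k].position, st2.placed[k].position)

    def test_pairwise_resolution_of_stacked_discs(self, nuc_mask, frame):
        # particle 1's top pose clashes with particle 0's top pose; the
        # jointly optimal solution moves particle 0 to its second pose so
        # that particle 1 can keep its best one (summed CCC 1.73 beats the
        # single-particle downgrade 1.70)
        lists = _lists_from([
            ([32, 32, 30], [([32, 32, 31], IDENT, 0.9),
                            ([32, 32, 29], IDENT, 0.85)]),
            ([32, 32, 35], [([32, 32, 34], IDENT, 0.88),
                            ([32, 32, 36], IDENT, 0.80)]),
        ])
        st = greedy_place(lists, frame, nuc_mask)
        assert len(st.placed) == 2
        assert st.placed[0].position[2] == 29.0
        assert st.placed[1].position[2] == 34.0
        total = sum(c.ccc for c in st.placed.values())
        assert total == pytest.approx(1.73)

    def test_unresolvable_keeps_higher_ccc(self, nuc_mask, frame):
        lists = _lists_from([
            ([32, 32, 32], [([32, 32, 32], IDENT, 0.9)]),
            ([32, 32, 34], [([32, 32, 33], IDENT, 0.6),
                            ([32, 32, 34], IDENT, 0.5)]),
        ])
        st = greedy_place(lists, frame, nuc_mask)
        assert 0 in st.placed and 1 not in st.placed
        assert st.rejected == [(1, "clash_unresolved")]

    def test_replacement_must_not_clash_third_party(self, nuc_mask, frame):
        # particle 2 forces a pairwise re-placement of particle 1; the pair
        # option that would push particle 1 onto particle 0 is excluded
        lists = _lists_from([
            ([20, 32, 32], [([20, 32, 32], IDENT, 0.95)]),          # fixed
            ([32, 32, 32], [([32, 32, 32], IDENT, 0.9),
                            ([26, 32, 32], IDENT, 0.89),             # clashes 0
                            ([32, 32, 38], IDENT, 0.2)]),
            ([32, 32, 35], [([32, 32, 34], IDENT, 0.85),
                            ([32, 32, 33], IDENT, 0.8)]),
        ])
        st = greedy_place(lists, frame, nuc_mask)
        if 1 in st.placed:  # any solution must be clash-free vs particle 0
            assert not clash_check(nuc_mask, frame,
                                   st.placed[0].position, IDENT,
                                   st.placed[1].position, IDENT)

    def test_unassigned_particles_logged(self, nuc_mask, frame):
        lists = [CandidateList(0, np.array([10.0, 10, 10]), [])]
        st = greedy_place(lists, frame, nuc_mask)
        assert st.rejected == [(0, "unassigned")]


class TestRunCatm:
    def test_zero_centroids_empty_result(self, single_particle_scene,
                                         nuc_template, imaging):
        vol, _, _ = single_particle_scene
        parts, log = run_catm(vol, nuc_template, np.zeros((0, 3)), imaging)
        assert len(parts) == 0 and log["n_anchors"] == 0

    def test_output_clash_free_and_from_candidates(self, nuc_template,
                                                   nuc_mask, imaging):
        import pandas as pd
        from catm.simulate import GroundTruth, degrade, render_volume
        rows = [{"x": 24.0, "y": 24, "z": 24, "tilt": 0.0,
                 "kind": "nucleosome_disc"},
                {"x": 24.0, "y": 24, "z": 31, "tilt": 0.0,
                 "kind": "nucleosome_disc"},
                {"x": 45.0, "y": 45, "z": 40, "tilt": 90.0,
                 "kind": "nucleosome_disc"}]
        gt = GroundTruth(ParticleSet(pd.DataFrame(rows)),
                         np.array([64.0, 64, 64]))
        vol = degrade(render_volume(gt), imaging)
        parts, log = run_catm(vol, nuc_template, gt.particles.positions,
                              imaging, CatmConfig(angular_step=15.0))
        assert len(parts) == 3
        frame = Volume(np.zeros_like(vol.data))
        rots = parts.rotations
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                assert not clash_check(nuc_mask, frame, parts.positions[i],
                                       rots[i], parts.positions[j], rots[j],
                                       tolerance_voxels=int(0.05 * nuc_mask.data.sum()))


class TestMergeAssignments:
    def test_collapsed_refined_particles_deduplicated(self, nuc_mask, frame):
        import pandas as pd
        refined = ParticleSet(pd.DataFrame([
            {"x": 20.0, "y": 20, "z": 20, "score": 0.9},
            {"x": 20.5, "y": 20, "z": 20, "score": 0.8},  # overlaid duplicate
        ]))
        out = merge_assignments(ParticleSet(), refined, nuc_mask, frame)
        assert len(out) == 1 and out.positions[0, 0] == 20.0

    def test_missing_primary_particle_restored(self, nuc_mask, frame):
        import pandas as pd
        primary = ParticleSet(pd.DataFrame([
            {"x": 20.0, "y": 20, "z": 20, "score": 0.9},
            {"x": 40.0, "y": 40, "z": 40, "score": 0.7},
        ]))
        refined = ParticleSet(pd.DataFrame([
            {"x": 20.2, "y": 20, "z": 20, "score": 0.95},
        ]))
        out = merge_assignments(primary, refined, nuc_mask, frame)
        assert len(out) == 2
        assert 40.0 in out.positions[:, 0]

    def test_idempotent_on_identical_sets(self, nuc_mask, frame):
        import pandas as pd
        ps = ParticleSet(pd.DataFrame([
            {"x": 20.0, "y": 20, "z": 20, "score": 0.9},
            {"x": 40.0, "y": 40, "z": 40, "score": 0.7},
        ]))
        out = merge_assignments(ps, ps, nuc_mask, frame)
        assert len(out) == 2
        np.testing.assert_allclose(np.sort(out.positions, axis=0),
                                   np.sort(ps.positions, axis=0))
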