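import numpy as np
import pytest

from osteomorph import (LandmarkConfiguration, Mesh, TemplateDefinition,
                        closest_point_on_mesh, project_patch, relax_to_consensus,
                        relax_to_template, slide_iteration)
from osteomorph.geometry_core import bending_energy_matrix


# ---------------------------------------------------------------------------
# nearest point on mesh
# ---------------------------------------------------------------------------

def _cube_mesh():
    verts = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
    faces = np.array([
        [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
        [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
        [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
    ])
    return Mesh(verts, faces)


class TestClosestPoint:
    def test_point_on_triangle_returns_itself(self):
        mesh = _cube_mesh()
        q = np.array([[0.3, 0.4, 0.0]])  # on the z=0 face
        out, dist, _ = closest_point_on_mesh(mesh, q)
        np.testing.assert_allclose(out, q, atol=1e-12)
        assert dist[0] == pytest.approx(0.0, abs=1e-12)

    def test_exterior_point_projects_to_face(self):
        out, dist, _ = closest_point_on_mesh(_cube_mesh(), np.array([[0.5, 0.5, 2.0]]))
        np.testing.assert_allclose(out[0], [0.5, 0.5, 1.0], atol=1e-12)
        assert dist[0] == pytest.approx(1.0)

    def test_vertex_and_edge_regions(self):
        out, dist, _ = closest_point_on_mesh(
            _cube_mesh(), np.array([[-1.0, -1.0, -1.0], [0.5, -1.0, -1.0]])
        )
        np.testing.assert_allclose(out[0], [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(out[1], [0.5, 0, 0], atol=1e-12)

    def test_matches_bruteforce_on_random_queries(self, small_template, rng):
        mesh = small_template.mesh
        q = rng.normal(size=(20, 3)) * 150 + [0, 0, 200]
        out, dist, _ = closest_point_on_mesh(mesh, q)
        tri = mesh.vertices[mesh.faces]
        for k in range(len(q)):
            # brute force: dense barycentric sampling of every triangle
            u = np.linspace(0, 1, 25)
            uu, vv = np.meshgrid(u, u)
            keep = uu + vv <= 1
            bary = np.stack([1 - uu[keep] - vv[keep], uu[keep], vv[keep]], axis=1)
            pts = np.einsum("bk,mkd->mbd", bary, tri).reshape(-1, 3)
            d_brute = np.linalg.norm(pts - q[k], axis=1).min()
            assert dist[k] <= d_brute + 1e-9


# ---------------------------------------------------------------------------
# patch projection
# ---------------------------------------------------------------------------

def _fixed_subset(template, points=None):
    idx = template.fixed_indices
    pts = template.config.points if points is None else points
    return LandmarkConfiguration(
        "spec", template.config.element, "left", pts[idx],
        template.config.classes[idx], template.config.group[idx],
    )


class TestProjectPatch:
    def test_identity_specimen(self, small_template):
        proj = project_patch(small_template, small_template.mesh, _fixed_subset(small_template))
        si = small_template.surface_indices
        np.testing.assert_allclose(
            proj.points[si], small_template.config.points[si], atol=1e-6
        )

    def test_affine_equivariance(self, small_template, rng):
        # an affinely deformed specimen: TPS warp is exactly affine, and
        # the projected points land on the affinely mapped surface
        A = np.eye(3) + rng.normal(scale=0.03, size=(3, 3))
        shift = np.array([5.0, -3.0, 10.0])
        spec_mesh = Mesh(small_template.mesh.vertices @ A + shift,
                         small_template.mesh.faces.copy())
        spec_pts = small_template.config.points @ A + shift
        proj = project_patch(small_template, spec_mesh, _fixed_subset(small_template, spec_pts))
        si = small_template.surface_indices
        np.testing.assert_allclose(proj.points[si], spec_pts[si], atol=1e-4)

    def test_empty_mesh_rejected(self, small_template):
        empty = Mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError, match="mesh"):
            project_patch(small_template, empty, _fixed_subset(small_template))

    def test_fixed_count_mismatch(self, small_template):
        bad = _fixed_subset(small_template)
        bad = LandmarkConfiguration(bad.specimen_id, bad.element, bad.side,
                                    bad.points[:-1], bad.classes[:-1], bad.group[:-1])
        with pytest.raises(ValueError, match="fixed landmarks"):
            project_patch(small_template, small_template.mesh, bad)


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------

def _toy_template():
    """Two straight-line curves plus off-plane anatomical anchors; the 3
    curve semilandmarks may slide along x only."""
    pts = np.array([
        [0.0, 0.0, 0.0],   # 0 anat: curve-0 start
        [3.0, 0.0, 0.0],   # 1 anat: curve-0 end
        [0.0, 5.0, 1.0],   # 2 anat: curve-1 start
        [3.0, 5.0, 1.0],   # 3 anat: curve-1 end
        [1.5, 2.0, 4.0],   # 4 anat: off-plane anchor
        [1.0, 0.0, 0.0],   # 5 curve semi (curve 0)
        [2.0, 0.0, 0.0],   # 6 curve semi (curve 0)
        [1.5, 5.0, 1.0],   # 7 curve semi (curve 1)
    ])
    classes = np.array(["anatomical"] * 5 + ["curve_semi"] * 3)
    group = np.array([-1, -1, -1, -1, -1, 0, 0, 1])
    config = LandmarkConfiguration("toy", "complete_femur", "left", pts, classes, group)
    return TemplateDefinition(config=config, curves=[[0, 5, 6, 1], [2, 7, 3]])


def _oracle_bending_energy(source, target):
    """Independent TPS bending-energy evaluation (own kernel and solve)."""
    p = len(source)
    d = np.sqrt(((source[:, None] - source[None, :]) ** 2).sum(-1))
    K = -d
    P = np.c_[np.ones(p), source]
    L = np.zeros((p + 4, p + 4))
    L[:p, :p], L[:p, p:], L[p:, :p] = K, P, P.T
    sol = np.linalg.solve(L, np.r_[target, np.zeros((4, 3))])
    W = sol[:p]
    return float(sum(W[:, k] @ K @ W[:, k] for k in range(3)))


class TestSlideIteration:
    def test_stationary_when_reference_equals_config(self):
        tpl = _toy_template()
        ref = tpl.config.points
        out = slide_iteration(tpl.config, ref, tpl)
        assert np.abs(out.points - ref).max() < 1e-8

    def test_matches_grid_search_minimum(self):
        tpl = _toy_template()
        # reference: semilandmarks displaced along their curves
        ref = tpl.config.points.copy()
        ref[5, 0] += 0.30
        ref[6, 0] -= 0.25
        ref[7, 0] += 0.20
        out = slide_iteration(tpl.config, ref, tpl)
        be_impl = _oracle_bending_energy(ref, out.points)

        # dense grid search (±0.5, step 0.01) over the three tangential
        # offsets, evaluated with an independently coded TPS solve
        p = len(ref)
        d = np.sqrt(((ref[:, None] - ref[None, :]) ** 2).sum(-1))
        K = -d
        P = np.c_[np.ones(p), ref]
        L = np.zeros((p + 4, p + 4))
        L[:p, :p], L[:p, p:], L[p:, :p] = K, P, P.T
        Linv_top = np.linalg.inv(L)[:p]
        step = np.arange(-0.5, 0.5 + 1e-9, 0.01)
        grid = np.stack(np.meshgrid(step, step, step, indexing="ij"), axis=-1).reshape(-1, 3)
        base = tpl.config.points
        best = np.inf
        for lo in range(0, len(grid), 50000):
            T = grid[lo : lo + 50000]
            Y = np.broadcast_to(base, (len(T), p, 3)).copy()
            Y[:, [5, 6, 7], 0] += T
            rhs = np.concatenate([Y, np.zeros((len(T), 4, 3))], axis=1)
            W = np.einsum("ij,bjd->bid", Linv_top, rhs)
            be = np.einsum("bid,ij,bjd->b", W, K, W)
            best = min(best, float(be.min()))
        assert be_impl <= best + 1e-9
        assert best - be_impl < 1e-3 * max(best, 1e-12) + 1e-9

    def test_anatomical_points_bitwise_unchanged(self, small_template, default_population):
        spec = default_population[0].config
        ref = small_template.config.points
        out = slide_iteration(spec, ref, small_template, small_template.mesh)
        a = small_template.anatomical_indices
        assert (out.points[a] == spec.points[a]).all()

    def test_zero_tangents_leave_config_unchanged(self, monkeypatch):
        tpl = _toy_template()
        import osteomorph.semilandmarks as sl
        monkeypatch.setattr(sl, "_curve_tangents",
                            lambda template, pts: {5: np.zeros(3), 6: np.zeros(3), 7: np.zeros(3)})
        ref = tpl.config.points + 0.1
        out = slide_iteration(tpl.config, ref, tpl)
        np.testing.assert_array_equal(out.points, tpl.config.points)

    def test_never_increases_bending_energy(self, small_template, default_population):
        ref = small_template.config.points
        B = bending_energy_matrix(ref)
        for s in default_population[:5]:
            be0 = np.einsum("id,ij,jd->", s.config.points, B, s.config.points)
            out = slide_iteration(s.config, ref, small_template, bending_matrix=B)
            be1 = np.einsum("id,ij,jd->", out.points, B, out.points)
            assert be1 <= be0 + 1e-9 * max(abs(be0), 1.0)


class TestRelaxation:
    def test_zero_iterations_identity(self, small_template, default_population):
        configs = [s.config for s in default_population[:4]]
        res = relax_to_template(configs, small_template, n_iter=0)
        for a, b in zip(res.configs, configs):
            np.testing.assert_array_equal(a.points, b.points)

    def test_template_trace_non_increasing(self, small_template, default_population):
        configs = [s.config for s in default_population[:8]]
        res = relax_to_template(configs, small_template, n_iter=5)
        trace = np.asarray(res.bending_energy_trace)
        assert len(trace) == 6
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_specimen_equal_to_template_never_moves(self, small_template):
        configs = [small_template.config.with_points(small_template.config.points.copy(),
                                                     specimen_id=f"c{i}") for i in range(3)]
        res = relax_to_template(configs, small_template, n_iter=3)
        for c in res.configs:
            assert np.abs(c.points - small_template.config.points).max() < 1e-8

    def test_consensus_trace_non_increasing(self, small_template, default_population):
        configs = [s.config for s in default_population[:8]]
        res = relax_to_consensus(configs, small_template, n_iter=2)
        trace = np.asarray(res.bending_energy_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_consensus_relaxation_permutation_invariant(self, small_template, default_population):
        configs = [s.config for s in default_population[:6]]
        res_a = relax_to_consensus(configs, small_template, n_iter=2)
        perm = [3, 0, 5, 1, 4, 2]
        res_b = relax_to_consensus([configs[i] for i in perm], small_template, n_iter=2)
        for i, j in enumerate(perm):
            assert np.abs(res_a.configs[j].points - res_b.configs[i].points).max() < 1e-9

    def test_full_protocol_deterministic(self, small_template, default_population):
        configs = [s.config for s in default_population[:5]]
        a = relax_to_consensus(relax_to_template(configs, small_template, 2).configs,
                               small_template, 1)
        b = relax_to_consensus(relax_to_template(configs, small_template, 2).configs,
                               small_template, 1)
        for x, y in zip(a.configs, b.configs):
            np.testing.assert_array_equal(x.points, y.points)

    def test_negative_iterations_rejected(self, small_template, default_population):
        with pytest.raises(ValueError):
            relax_to_template([s.config for s in default_population[:3]],
                              small_template, n_iter=-1)


def test_curve_path_must_end_at_anatomical():
    pts = np.random.default_rng(0).normal(size=(5, 3))
    classes = np.array(["anatomical", "curve_semi", "curve_semi", "curve_semi", "anatomical"])
    config = LandmarkConfiguration("t", "complete_femur", "left", pts, classes,
                                   np.array([-1, 0, 0, 0, -1]))
    TemplateDefinition(config=config, curves=[[0, 1, 2, 3, 4]])  # valid
    with pytest.raises(ValueError, match="anatomical"):
        TemplateDefinition(config=config, curves=[[1, 2, 3]])
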