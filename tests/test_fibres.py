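import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scapstab.fibres import (
    N_NODES,
    SphereSurface,
    build_fibre_set,
    check_tension,
    effective_endpoints,
    line_of_action,
    solve_fibre_set,
    solve_path,
    tension_report,
)


def _circle(n=36, r=10.0, center=(0.0, 0.0, 0.0), normal_axis=1):
    t = 2 * np.pi * np.arange(n) / n
    pts = np.zeros((n, 3))
    axes = [i for i in range(3) if i != normal_axis]
    pts[:, axes[0]] = r * np.cos(t)
    pts[:, axes[1]] = r * np.sin(t)
    return pts + np.asarray(center)


def _wrap_oracle(origin, insertion, center, radius):
    d1 = np.linalg.norm(origin - center)
    d2 = np.linalg.norm(insertion - center)
    alpha = np.arccos(np.dot(origin - center, insertion - center) / (d1 * d2))
    theta = alpha - np.arccos(radius / d1) - np.arccos(radius / d2)
    return np.sqrt(d1**2 - radius**2) + np.sqrt(d2**2 - radius**2) + radius * theta


class TestBuild:
    def test_fibre_counts(self, default_bones):
        fs = build_fibre_set(default_bones.fossa_origin_perimeter,
                             default_bones.insertion_perimeter)
        assert len(fs) == 50
        assert len(fs.by_sheet("deep")) == 30
        assert len(fs.by_sheet("superficial")) == 20

    def test_deep_origins_equally_spaced_on_circle(self):
        origin_loop = _circle(n=360, r=12.0, center=(0, 10, 0))
        ins_loop = _circle(n=360, r=3.0, center=(30, 0, 0))
        fs = build_fibre_set(origin_loop, ins_loop)
        deep = np.array([f.origin for f in fs.by_sheet("deep")])
        centered = deep - [0, 10, 0]
        ang = np.unwrap(np.arctan2(centered[:, 2], centered[:, 0]))
        gaps = np.diff(ang)
        assert np.ptp(np.abs(gaps)) < 1e-9

    def test_median_ap_split_is_25_25(self, default_bones):
        fs = build_fibre_set(default_bones.fossa_origin_perimeter,
                             default_bones.insertion_perimeter)
        n_ant = sum(f.subregion == "anterior" for f in fs.fibres)
        assert n_ant == 25
        assert sum(f.subregion == "posterior" for f in fs.fibres) == 25

    def test_superficial_fibres_sample_superior_segment(self, default_bones):
        fs = build_fibre_set(default_bones.fossa_origin_perimeter,
                             default_bones.insertion_perimeter)
        sup_y = np.mean([f.origin[1] for f in fs.by_sheet("superficial")])
        deep_y = np.mean([f.origin[1] for f in fs.by_sheet("deep")])
        assert sup_y > deep_y

    def test_degenerate_perimeter_rejected(self):
        with pytest.raises(ValueError):
            build_fibre_set(np.zeros((2, 3)), _circle())


class TestSolvePath:
    def test_unobstructed_path_is_straight(self):
        a, b = np.array([0.0, 0, 0]), np.array([10.0, 0, 0])
        p = solve_path(a, b, sphere=(np.array([5.0, 8.0, 0.0]), 2.0))
        assert not p.wrapped
        assert abs(p.length - 10.0) < 1e-9
        assert p.nodes.shape == (N_NODES, 3)

    def test_wrap_length_matches_closed_form(self, rng):
        for _ in range(100):
            C = rng.uniform(-5, 5, 3)
            r = rng.uniform(1.0, 5.0)
            pts = []
            while len(pts) < 2:
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                pts.append(C + rng.uniform(1.5 * r, 6 * r) * u)
            p = solve_path(pts[0], pts[1], sphere=(C, r))
            if not p.wrapped:
                continue
            assert abs(p.length - _wrap_oracle(pts[0], pts[1], C, r)) < 1e-6

    def test_symmetric_coplanar_wrap(self):
        C, r = np.array([0.0, 0.0, 0.0]), 3.0
        a = np.array([-10.0, 1.0, 0.0])
        b = np.array([10.0, 1.0, 0.0])
        p = solve_path(a, b, sphere=(C, r))
        assert p.wrapped
        assert abs(p.length - _wrap_oracle(a, b, C, r)) < 1e-6
        # no node penetrates the obstacle
        assert np.min(np.linalg.norm(p.nodes - C, axis=1)) >= r - 1e-6

    def test_length_decreases_monotonically_with_radius(self):
        a = np.array([-10.0, 1.0, 0.0])
        b = np.array([10.0, 1.0, 0.0])
        lengths = []
        for r in [4.0, 3.0, 2.0, 1.5, 1.0, 0.5]:
            lengths.append(solve_path(a, b, sphere=(np.zeros(3), r)).length)
        assert all(l2 <= l1 + 1e-12 for l1, l2 in zip(lengths, lengths[1:]))
        assert abs(lengths[-1] - np.linalg.norm(b - a)) < 0.02

    def test_origin_inside_obstacle_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            solve_path(np.zeros(3), np.array([10.0, 0, 0]),
                       sphere=(np.zeros(3), 2.0))

    def test_length_invariant_to_rigid_motion(self, rng):
        C, r = np.array([0.0, 0.5, 0.0]), 3.0
        a, b = np.array([-9.0, 1.0, 2.0]), np.array([8.0, 2.0, -1.0])
        p0 = solve_path(a, b, sphere=(C, r))
        R = Rotation.random(rng=rng).as_matrix()
        t = np.array([4.0, -7.0, 11.0])
        p1 = solve_path(R @ a + t, R @ b + t, sphere=(R @ C + t, r))
        assert abs(p0.length - p1.length) < 1e-8


class TestCoherence:
    def test_zero_weight_equals_independent_shortest_paths(self, default_bones):
        fs = build_fibre_set(default_bones.fossa_origin_perimeter,
                             default_bones.insertion_perimeter)
        sphere = (np.array([25.0, 0.0, 0.0]), default_bones.head_radius)
        T = np.eye(4)
        T[:3, 3] = sphere[0]
        free = solve_fibre_set(fs, sphere, T, coherence_weight=0.0)
        for f, p in zip(fs.fibres, free):
            ind = solve_path(f.origin, T[:3, :3] @ f.insertion + T[:3, 3], sphere)
            np.testing.assert_allclose(p.nodes, ind.nodes, atol=1e-12)

    def test_divergence_decreases_with_weight(self, default_bones):
        fs = build_fibre_set(default_bones.fossa_origin_perimeter,
                             default_bones.insertion_perimeter)
        sphere = (np.array([25.0, 0.0, 0.0]), default_bones.head_radius)
        T = np.eye(4)
        T[:3, 3] = sphere[0]

        def max_adjacent_divergence(weight):
            paths = solve_fibre_set(fs, sphere, T, coherence_weight=weight)
            deep = [p for f, p in zip(fs.fibres, paths) if f.sheet == "deep"]
            worst = 0.0
            for a, b in zip(deep, deep[1:]):
                worst = max(worst, np.max(np.linalg.norm(a.nodes - b.nodes, axis=1)))
            return worst

        d = [max_adjacent_divergence(w) for w in (0.0, 0.2, 0.4)]
        assert d[0] >= d[1] >= d[2]


class TestEndpointsAndLoa:
    def test_straight_fibre_falls_back_to_raw_endpoints(self):
        p = solve_path(np.zeros(3), np.array([10.0, 0, 0]), sphere=None)
        sph = SphereSurface(np.array([100.0, 100, 100]), 1.0)
        eo, ei = effective_endpoints(p, sph, sph, contact_tol=0.1)
        assert (eo, ei) == (0, 99)

    def test_wrapped_fibre_insertion_at_tangent_point(self):
        C, r = np.zeros(3), 3.0
        a = np.array([-10.0, 1.0, 0.0])
        b = C + r * np.array([1.0, 0.0, 0.0])  # insertion on the sphere
        p = solve_path(a, b, sphere=(C, r))
        surf = SphereSurface(C, r)
        _, ei = effective_endpoints(p, None, surf, contact_tol=0.01)
        # analytic scapula-side tangency point
        d1 = np.linalg.norm(a - C)
        beta1 = np.arccos(r / d1)
        e1 = (a - C) / d1
        perp = (b - C) - np.dot(b - C, e1) * e1
        em = perp / np.linalg.norm(perp)
        t1 = C + r * (np.cos(beta1) * e1 + np.sin(beta1) * em)
        node_gap = p.length / (N_NODES - 1)
        assert np.linalg.norm(p.nodes[ei] - t1) <= node_gap + 1e-9

    def test_unbounded_contact_tol_rejected(self):
        p = solve_path(np.zeros(3), np.array([10.0, 0, 0]))
        surf = SphereSurface(np.zeros(3), 1.0)
        with pytest.raises(ValueError, match="contact_tol"):
            effective_endpoints(p, surf, surf, contact_tol=np.inf)

    def test_line_of_action_definition(self):
        p = solve_path(np.array([0.0, 3.0, 4.0]), np.zeros(3))
        loa = line_of_action(p)
        np.testing.assert_allclose(loa, [0.0, 0.6, 0.8], atol=1e-12)

    def test_line_of_action_equivariance(self, rng):
        a, b = np.array([-9.0, 1.0, 2.0]), np.array([8.0, 2.0, -1.0])
        C, r = np.array([0.0, 0.5, 0.0]), 3.0
        p0 = solve_path(a, b, sphere=(C, r))
        surf0 = SphereSurface(C, r)
        effective_endpoints(p0, None, surf0, 0.05)
        loa0 = line_of_action(p0)
        R = Rotation.random(rng=rng).as_matrix()
        p1 = solve_path(R @ a, R @ b, sphere=(R @ C, r))
        effective_endpoints(p1, None, SphereSurface(R @ C, r), 0.05)
        loa1 = line_of_action(p1)
        np.testing.assert_allclose(loa1, R @ loa0, atol=1e-8)


class TestTension:
    def test_flags_follow_slack_length(self):
        p = solve_path(np.zeros(3), np.array([10.0, 0, 0]))
        assert check_tension(p, slack_length=9.0)
        assert not check_tension(p, slack_length=11.0)

    def test_report_one_row_per_pose(self, default_bones):
        from scapstab.kinematics import base_path
        from scapstab.pipeline import simulate_stability

        _, lengths = simulate_stability(default_bones, base_path())
        rep = tension_report(lengths)
        assert rep.shape == (19, 50)
        assert rep[0].all()  # first pose defines the slack lengths
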