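"""Sholl profiles, neurite length, soma shape metrics, SWC I/O."""

import numpy as np
import pytest

from photoflux import morphology as mo
from photoflux import synthetic as syn


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def random_tree(rng, n_nodes=12, scale=20.0):
    xyz = [np.zeros(3)]
    parents = [-1]
    for i in range(1, n_nodes):
        p = int(rng.integers(0, i))
        xyz.append(xyz[p] + rng.normal(0, scale / 3, 3))
        parents.append(p)
    xyz = np.asarray(xyz)
    return mo.NeuronTree(
        ids=np.arange(1, n_nodes + 1),
        type_code=np.r_[1, np.full(n_nodes - 1, 3)],
        xyz=xyz,
        radius=np.full(n_nodes, 0.5),
        parent_id=np.asarray([p + 1 if p >= 0 else -1 for p in parents]),
    )


def sholl_oracle(tree, step):
    """Closed-form crossing count per segment: multiples of step in (lo, hi]."""
    p, c = tree.segments()
    soma = tree.soma_xyz
    dp = np.linalg.norm(p - soma, axis=1)
    dc = np.linalg.norm(c - soma, axis=1)
    max_d = max(dp.max(), dc.max())
    n_shells = max(1, int(np.ceil(max_d / step - 1e-12)))
    counts = np.zeros(n_shells, dtype=int)
    for lo, hi in zip(np.minimum(dp, dc), np.maximum(dp, dc)):
        for k in range(1, n_shells + 1):
            r = k * step
            if lo < r <= hi:
                counts[k - 1] += 1
    return counts


class TestSholl:
    def test_straight_radial_neurite(self):
        tree = syn.generate_morphology("radial", length_um=23.0)
        profile = mo.sholl(tree, step_um=5.0)
        np.testing.assert_array_equal(profile.radii, [5, 10, 15, 20, 25])
        np.testing.assert_array_equal(profile.intersections, [1, 1, 1, 1, 0])

    def test_y_branch_hand_counts(self):
        tree = syn.generate_morphology("y_branch", length_um=30.0, branch_at_um=12.0)
        profile = mo.sholl(tree, step_um=5.0)
        np.testing.assert_array_equal(profile.radii, [5, 10, 15, 20, 25, 30])
        np.testing.assert_array_equal(profile.intersections, [1, 1, 2, 2, 2, 2])

    def test_soma_only_all_zero(self):
        profile = mo.sholl(syn.generate_morphology("soma_only"), step_um=5.0)
        assert profile.intersections.sum() == 0
        assert profile.total_length_um == 0.0

    def test_rotation_invariance(self, rng):
        tree = random_tree(rng)
        base = mo.sholl(tree, step_um=5.0).intersections
        for _ in range(3):
            q = random_rotation(rng)
            rotated = mo.NeuronTree(
                ids=tree.ids,
                type_code=tree.type_code,
                xyz=tree.xyz @ q.T,
                radius=tree.radius,
                parent_id=tree.parent_id,
            )
            np.testing.assert_array_equal(
                mo.sholl(rotated, step_um=5.0).intersections, base
            )

    def test_small_radius_counts_primary_neurites(self):
        tree = syn.generate_morphology("y_branch", length_um=30.0, branch_at_um=12.0)
        profile = mo.sholl(tree, step_um=0.25)
        assert profile.intersections[0] == 1  # one soma-incident trunk

    def test_agreement_with_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            tree = random_tree(rng, n_nodes=int(rng.integers(3, 15)))
            profile = mo.sholl(tree, step_um=5.0)
            np.testing.assert_array_equal(
                profile.intersections, sholl_oracle(tree, 5.0)
            )


class TestTreeValidation:
    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            mo.NeuronTree(
                ids=[1, 2],
                type_code=[1, 1],
                xyz=np.zeros((2, 3)),
                radius=[1, 1],
                parent_id=[-1, -1],
            )

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="missing parent"):
            mo.NeuronTree(
                ids=[1, 2],
                type_code=[1, 3],
                xyz=np.zeros((2, 3)),
                radius=[1, 1],
                parent_id=[-1, 9],
            )

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle|root"):
            mo.NeuronTree(
                ids=[1, 2, 3],
                type_code=[1, 3, 3],
                xyz=np.zeros((3, 3)),
                radius=[1, 1, 1],
                parent_id=[-1, 3, 2],
            )


class TestTotalNeuriteLength:
    def test_two_node_tree(self):
        tree = mo.NeuronTree(
            ids=[1, 2],
            type_code=[1, 3],
            xyz=np.array([[0, 0, 0], [0, 3, 0]], dtype=float),
            radius=[1, 1],
            parent_id=[-1, 1],
        )
        assert mo.total_neurite_length(tree) == pytest.approx(3.0)

    def test_y_branch_hand_geometry(self):
        tree = syn.generate_morphology("y_branch", length_um=30.0, branch_at_um=12.0)
        theta = np.deg2rad(30.0)
        b = 12.0 * np.cos(theta)
        ray = -b + np.sqrt(b**2 + 30.0**2 - 12.0**2)
        assert mo.total_neurite_length(tree) == pytest.approx(12.0 + 2 * ray, rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        tree = random_tree(rng)
        q = random_rotation(rng)
        moved = mo.NeuronTree(
            ids=tree.ids,
            type_code=tree.type_code,
            xyz=tree.xyz @ q.T + np.array([5.0, -3.0, 1.0]),
            radius=tree.radius,
            parent_id=tree.parent_id,
        )
        assert mo.total_neurite_length(moved) == pytest.approx(
            mo.total_neurite_length(tree), rel=1e-9
        )


class TestSomaMetrics:
    @staticmethod
    def ellipse(a, b, n=256):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return mo.SomaContour(np.c_[a * np.cos(th), b * np.sin(th)])

    def test_circle(self):
        m = mo.soma_metrics(self.ellipse(10, 10))
        assert m["area_um2"] == pytest.approx(np.pi * 100, rel=0.005)
        assert m["major_axis_um"] == pytest.approx(20.0, rel=0.005)
        assert m["minor_axis_um"] == pytest.approx(20.0, rel=0.005)
        assert m["aspect_ratio"] == pytest.approx(1.0, abs=0.005)

    def test_ellipse_analytic(self):
        m = mo.soma_metrics(self.ellipse(10, 5, n=512))
        assert m["area_um2"] == pytest.approx(np.pi * 50, rel=0.005)
        assert m["major_axis_um"] == pytest.approx(20.0, rel=0.005)
        assert m["minor_axis_um"] == pytest.approx(10.0, rel=0.005)
        assert m["aspect_ratio"] == pytest.approx(2.0, rel=0.01)

    def test_triangle_shoelace_exact(self):
        m = mo.soma_metrics(mo.SomaContour([[0, 0], [4, 0], [0, 3]]))
        assert m["area_um2"] == pytest.approx(6.0, abs=1e-12)

    def test_orientation_independent(self):
        v = [[0, 0], [4, 0], [0, 3]]
        a = mo.soma_metrics(mo.SomaContour(v))
        b = mo.soma_metrics(mo.SomaContour(v[::-1]))
        assert a == pytest.approx(b)

    def test_self_intersecting_rejected(self):
        bowtie = [[0, 0], [2, 2], [2, 0], [0, 2]]
        with pytest.raises(ValueError, match="self-intersecting"):
            mo.soma_metrics(mo.SomaContour(bowtie))


class TestSwcIO:
    def test_roundtrip(self, tmp_path, rng):
        tree = random_tree(rng)
        path = tmp_path / "tree.swc"
        mo.write_swc(tree, path)
        back = mo.read_swc(path)
        assert len(back) == len(tree)
        np.testing.assert_allclose(back.xyz, tree.xyz, rtol=1e-5)
        np.testing.assert_array_equal(back.parent_id, tree.parent_id)

    def test_comments_and_bad_columns(self, tmp_path):
        path = tmp_path / "t.swc"
        path.write_text("# comment\n1 1 0 0 0 1 -1\n")
        assert len(mo.read_swc(path)) == 1
        path.write_text("1 1 0 0 0 1\n")
        with pytest.raises(ValueError, match="7"):
            mo.read_swc(path)
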