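"""Superimposition: centroid size, rigid fits, GPA with object symmetry, ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caniform as cf
from caniform.procrustes import _reflect_relabel, error_variance_component
from conftest import random_rotation


class TestCentroidSize:
    def test_unit_cross(self):
        coords = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
        assert cf.centroid_size(coords) == pytest.approx(2.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25)
    def test_homogeneous_of_degree_one(self, c):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(36, 3))
        assert cf.centroid_size(c * coords) == pytest.approx(
            c * cf.centroid_size(coords), rel=1e-10
        )

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(36, 3))
        centroid = coords.mean(axis=0)
        total = 0.0
        for row in coords:
            for a in range(3):
                total += (row[a] - centroid[a]) ** 2
        assert cf.centroid_size(coords) == pytest.approx(np.sqrt(total), abs=1e-12)


class TestOpaFit:
    def test_self_fit_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3))
        rot, t, res = cf.opa_fit(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        assert res == pytest.approx(0.0, abs=1e-18)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        r_true = random_rotation(rng)
        rot, _, res = cf.opa_fit(x, x @ r_true)
        np.testing.assert_allclose(rot, r_true, atol=1e-8)
        assert res < 1e-16

    def test_mirrored_target_not_reachable_by_rotation(self):
        """Reflections are forbidden: the rigid residual must exceed the
        residual of an unconstrained orthogonal fit."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 3))
        mirrored = x.copy()
        mirrored[:, 0] *= -1
        _, _, res = cf.opa_fit(x, mirrored)
        a0 = x - x.mean(0)
        b0 = mirrored - mirrored.mean(0)
        s = np.linalg.svd(a0.T @ b0, compute_uv=False)
        res_orthogonal = float(np.sum(a0**2) + np.sum(b0**2) - 2 * s.sum())
        assert res > res_orthogonal + 1e-6
        assert res_orthogonal == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_configuration_raises(self):
        x = np.zeros((5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            cf.opa_fit(x, x)


def _perturbed_copies(template, rng, n, scale_noise=0.0):
    out = []
    for _ in range(n):
        c = template + rng.normal(scale=scale_noise, size=template.shape)
        rot = random_rotation(rng)
        s = rng.uniform(0.5, 2.0)
        out.append(s * (c @ rot) + rng.normal(size=3) * 10)
    return np.stack(out)


class TestGPA:
    def test_identical_symmetric_shapes_align_exactly(self, template, symmetry):
        labels, tpl = template
        rng = np.random.default_rng(5)
        configs = _perturbed_copies(tpl, rng, 5)
        gpa = cf.GeneralizedProcrustes(symmetry=symmetry, labels=labels).fit(configs)
        for a in gpa.aligned_:
            np.testing.assert_allclose(a, gpa.aligned_[0], atol=1e-8)
        np.testing.assert_allclose(gpa.consensus_, gpa.aligned_[0], atol=1e-8)

    def test_invariance_to_rigid_motion_and_scale(self, template, symmetry):
        """Aligned coordinates are unchanged when inputs are arbitrarily
        rotated, translated and scaled."""
        labels, tpl = template
        rng = np.random.default_rng(6)
        shapes = np.stack(
            [tpl + rng.normal(scale=0.01, size=tpl.shape) for _ in range(6)]
        )
        gpa1 = cf.GeneralizedProcrustes(
            symmetry=symmetry, labels=labels, max_iter=300
        ).fit(shapes)
        moved = np.stack([
            rng.uniform(0.5, 3.0) * (c @ random_rotation(rng)) + rng.normal(size=3)
            for c in shapes
        ])
        gpa2 = cf.GeneralizedProcrustes(
            symmetry=symmetry, labels=labels, max_iter=300
        ).fit(moved)
        np.testing.assert_allclose(gpa1.aligned_, gpa2.aligned_, atol=1e-8)
        np.testing.assert_allclose(gpa1.symmetric_, gpa2.symmetric_, atol=1e-8)

    def test_aligned_configurations_have_unit_centroid_size(self, template, symmetry):
        labels, tpl = template
        rng = np.random.default_rng(7)
        shapes = _perturbed_copies(tpl, rng, 6, scale_noise=0.02)
        gpa = cf.GeneralizedProcrustes(symmetry=symmetry, labels=labels).fit(shapes)
        for a in gpa.aligned_:
            assert cf.centroid_size(a) == pytest.approx(1.0, abs=1e-10)

    def test_consensus_is_mean_of_aligned(self, template, symmetry):
        labels, tpl = template
        rng = np.random.default_rng(8)
        shapes = _perturbed_copies(tpl, rng, 6, scale_noise=0.02)
        gpa = cf.GeneralizedProcrustes(symmetry=symmetry, labels=labels).fit(shapes)
        pool_mean_change = np.abs(
            gpa.transform(shapes).mean(axis=0) - gpa.consensus_
        ).max()
        assert pool_mean_change < 1e-6

    def test_symmetric_component_fixed_under_reflect_relabel(self, template, symmetry):
        labels, tpl = template
        rng = np.random.default_rng(9)
        shapes = _perturbed_copies(tpl, rng, 5, scale_noise=0.03)
        gpa = cf.GeneralizedProcrustes(symmetry=symmetry, labels=labels).fit(shapes)
        perm = symmetry.swap_permutation(labels)
        for s in gpa.symmetric_:
            np.testing.assert_allclose(_reflect_relabel(s, perm), s, atol=1e-12)

    def test_two_config_distance_matches_closed_form(self):
        """Pairwise GPA distance equals the closed-form orthogonal
        Procrustes solution for two unit-size configurations."""
        rng = np.random.default_rng(10)
        for _ in range(20):
            a, b = rng.normal(size=(2, 12, 3))
            gpa = cf.GeneralizedProcrustes().fit(np.stack([a, b]))
            d_gpa = np.linalg.norm(gpa.aligned_[0] - gpa.aligned_[1])
            a0 = a - a.mean(0)
            a0 /= np.linalg.norm(a0)
            b0 = b - b.mean(0)
            b0 /= np.linalg.norm(b0)
            u, s, vt = np.linalg.svd(a0.T @ b0)
            d = np.sign(np.linalg.det(u @ vt))
            d_oracle = np.sqrt(max(2.0 - 2.0 * (s[0] + s[1] + d * s[2]), 0.0))
            assert d_gpa == pytest.approx(d_oracle, abs=1e-10)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(11)
        shapes = rng.normal(size=(8, 15, 3))
        gpa = cf.GeneralizedProcrustes(max_iter=500).fit(shapes)
        trace = gpa.objective_trace_
        assert np.all(np.diff(trace) <= 1e-12)


class TestProcrustesAnova:
    def test_identical_replicates_give_zero_error(self, template, symmetry):
        labels, tpl = template
        rng = np.random.default_rng(12)
        shapes = []
        ids = []
        for i in range(4):
            c = tpl + rng.normal(scale=0.02, size=tpl.shape)
            shapes.extend([c, c])
            ids.extend([f"s{i}", f"s{i}"])
        gpa = cf.GeneralizedProcrustes(symmetry=symmetry, labels=labels).fit(
            np.stack(shapes)
        )
        # replicate pairs are identical inputs -> identical aligned copies
        table = cf.procrustes_anova(gpa.aligned_, ids)
        assert table.effects[1][1] == pytest.approx(0.0, abs=1e-16)
        assert np.isinf(table.goodall_f)
        assert table.p == 0.0

    def test_error_variance_recovery(self, template, symmetry):
        """The error mean square recovers the injected replicate variance."""
        labels, tpl = template
        rng = np.random.default_rng(13)
        sigma_e = 0.004
        shapes, ids = [], []
        for i in range(100):
            c = tpl + rng.normal(scale=0.02, size=tpl.shape)
            for _ in range(2):
                rep = c + rng.normal(scale=sigma_e, size=tpl.shape)
                rot = random_rotation(rng)
                shapes.append(rep @ rot + rng.normal(size=3))
                ids.append(f"s{i}")
        gpa = cf.GeneralizedProcrustes(symmetry=symmetry, labels=labels).fit(
            np.stack(shapes)
        )
        table = cf.procrustes_anova(gpa.aligned_, ids)
        est = error_variance_component(table)
        assert est == pytest.approx(sigma_e**2, rel=0.10)

    def test_null_goodall_f_near_one(self, template, symmetry):
        """With no individual effect the F ratio hovers around 1."""
        labels, tpl = template
        rng = np.random.default_rng(14)
        fs = []
        for _ in range(5):
            shapes, ids = [], []
            for i in range(40):
                for _ in range(2):
                    shapes.append(tpl + rng.normal(scale=0.01, size=tpl.shape))
                    ids.append(f"s{i}")
            gpa = cf.GeneralizedProcrustes(symmetry=symmetry, labels=labels).fit(
                np.stack(shapes)
            )
            fs.append(cf.procrustes_anova(gpa.aligned_, ids).goodall_f)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.1)

    def test_single_replicate_everywhere_raises(self, template):
        labels, tpl = template
        with pytest.raises(ValueError, match="inestimable"):
            cf.procrustes_anova(np.stack([tpl, tpl, tpl]), ["a", "b", "c"])


class TestAverageReplicates:
    def test_identical_replicates_average_to_themselves(self):
        rng = np.random.default_rng(15)
        c = rng.normal(size=(5, 3))
        ids, shapes, cs = cf.average_replicates(
            np.stack([c, c]), np.array([3.0, 5.0]), ["a", "a"]
        )
        assert ids == ["a"]
        np.testing.assert_allclose(shapes[0], c, atol=1e-15)
        assert cs[0] == pytest.approx(4.0)

    def test_symmetric_pair_averages_to_known_mean(self):
        rng = np.random.default_rng(16)
        mean = rng.normal(size=(5, 3))
        d = rng.normal(size=(5, 3))
        _, shapes, _ = cf.average_replicates(
            np.stack([mean + d, mean - d]), np.array([1.0, 1.0]), ["a", "a"]
        )
        np.testing.assert_allclose(shapes[0], mean, atol=1e-12)
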