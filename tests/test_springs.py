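import numpy as np
import pytest

from carpalfem.mesh import VolumeMesh
from carpalfem.springs import (SpringElement, SpringSet, build_spring_set,
                               spring_energy, spring_force, spring_tangent)
from carpalfem.tables import LIGAMENT_ROWS


def _spring(k=1.0, L0=1.0, tension_only=False):
    return SpringElement("s", "a", 0, "b", 1, k=k, rest_length=L0,
                         tension_only=tension_only)


class TestSpringForce:
    def test_zero_at_rest_length(self):
        s = _spring(k=230.0, L0=2.0)
        fa, fb = spring_force(s, [0, 0, 0], [2, 0, 0])
        assert np.allclose(fa, 0) and np.allclose(fb, 0)

    def test_dorsal_scapholunate_magnitude(self):
        # k = 230 N/mm stretched by 0.1 mm -> 23 N axial
        s = _spring(k=230.0, L0=2.0)
        fa, fb = spring_force(s, [0, 0, 0], [2.1, 0, 0])
        assert np.linalg.norm(fa) == pytest.approx(23.0)
        assert np.allclose(fa, -fb)
        assert fa[0] > 0        # stretched spring pulls a toward b

    def test_tension_only_slack(self):
        s = _spring(k=100.0, L0=2.0, tension_only=True)
        fa, fb = spring_force(s, [0, 0, 0], [1.9, 0, 0])
        assert np.allclose(fa, 0) and np.allclose(fb, 0)

    def test_newtons_third_law_random(self, rng):
        s = _spring(k=75.0, L0=1.3)
        for _ in range(20):
            xa, xb = rng.standard_normal((2, 3)) * 3
            fa, fb = spring_force(s, xa, xb)
            assert np.allclose(fa + fb, 0.0)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            spring_force(_spring(), [1, 1, 1], [1, 1, 1])


class TestSpringTangent:
    def test_matches_finite_differences(self, rng):
        s = _spring(k=50.75, L0=1.7)
        h = 1e-6
        for _ in range(10):
            x = rng.standard_normal(6) * 2
            if np.linalg.norm(x[3:] - x[:3]) < 0.1:
                continue
            K = spring_tangent(s, x[:3], x[3:])
            assert np.allclose(K, K.T)
            for j in range(6):
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                # gradient of energy = internal force = -applied force
                gp = np.concatenate(spring_force(s, xp[:3], xp[3:]))
                gm = np.concatenate(spring_force(s, xm[:3], xm[3:]))
                fd = -(gp - gm) / (2 * h)
                assert np.allclose(K[:, j], fd, rtol=1e-5, atol=1e-6)

    def test_axial_stiffness_at_reference(self):
        s = _spring(k=1.0, L0=2.0)
        K = spring_tangent(s, [0, 0, 0], [2, 0, 0])
        assert K[0, 0] == pytest.approx(1.0)      # N/mm along the axis
        assert K[1, 1] == pytest.approx(0.0)      # no geometric stiffness
        # a single unstressed spring constrains exactly one mode
        w = np.linalg.eigvalsh(K)
        assert (w > 1e-12).sum() == 1

    def test_energy_gradient_consistency(self, rng):
        s = _spring(k=10.0, L0=0.8)
        h = 1e-6
        x = rng.standard_normal(6)
        fa, fb = spring_force(s, x[:3], x[3:])
        for j in range(3):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (spring_energy(s, xp[:3], xp[3:])
                  - spring_energy(s, xm[:3], xm[3:])) / (2 * h)
            assert fd == pytest.approx(-fa[j], rel=1e-5, abs=1e-8)


@pytest.fixture(scope="module")
def wrist_mesh(default_model):
    from carpalfem.pipeline import mesh_model
    return mesh_model(default_model,
                      {"radius": 3.5, "scaphoid": 2.5, "lunate": 2.5,
                       "capitate": 2.6, "slil": 1.3})


class TestBuildSpringSet:

    def test_table_stiffness_multiset(self, default_model, wrist_mesh):
        springs = build_spring_set(default_model.landmarks, wrist_mesh)
        expected = sorted([150.0, 150.0, 230.0, 75.0, 40.0, 10.0, 50.0,
                           75.0, 50.75, 50.75])
        assert sorted(springs.stiffnesses()) == expected

    def test_unstressed_at_reference(self, default_model, wrist_mesh):
        springs = build_spring_set(default_model.landmarks, wrist_mesh)
        x = wrist_mesh.nodes
        for s in springs.elements:
            fa, fb = spring_force(s, x[s.node_a], x[s.node_b])
            assert np.allclose(fa, 0.0, atol=1e-9)

    def test_endpoints_on_named_parts(self, default_model, wrist_mesh):
        springs = build_spring_set(default_model.landmarks, wrist_mesh)
        for s in springs.elements:
            assert s.node_a in wrist_mesh.part_nodes(s.part_a)
            assert s.node_b in wrist_mesh.part_nodes(s.part_b)

    def test_unique_names(self, default_model, wrist_mesh):
        springs = build_spring_set(default_model.landmarks, wrist_mesh)
        names = [s.name for s in springs.elements]
        assert len(names) == len(set(names))
        assert len(springs.provenance) == len(names)

    def test_distant_landmark_rejected(self, default_model, wrist_mesh):
        lm = default_model.landmarks
        shifted = type(lm)([type(e)(e.ligament, e.part_a,
                                    e.point_a + 100.0, e.part_b, e.point_b)
                            for e in lm.entries])
        with pytest.raises(ValueError, match="tolerance"):
            build_spring_set(shifted, wrist_mesh, tolerance=3.0)

    def test_serialization(self, default_model, wrist_mesh):
        springs = build_spring_set(default_model.landmarks, wrist_mesh)
        text = springs.to_text()
        assert text.count("\n") == len(springs) + 1
        assert "230" in text


def test_element_invariants():
    with pytest.raises(ValueError):
        SpringElement("s", "a", 0, "b", 1, k=-1.0, rest_length=1.0)
    with pytest.raises(ValueError):
        SpringElement("s", "a", 3, "b", 3, k=1.0, rest_length=1.0)
    with pytest.raises(ValueError):
        SpringElement("s", "a", 0, "b", 1, k=1.0, rest_length=-0.5)


def test_table_has_published_rows():
    assert len(LIGAMENT_ROWS) == 9
    ks = sorted(r[3] for r in LIGAMENT_ROWS)
    assert ks == sorted([150, 150, 230, 75, 40, 10, 50, 75, 50.75])
    # the combined row keeps its printed wording
    assert any(r[2] == "Scaphoid+Lunate" for r in LIGAMENT_ROWS)
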