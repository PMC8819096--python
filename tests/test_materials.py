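import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from carpalfem.materials import (LinearElasticParams, MooneyRivlinParams,
                                 bulk_modulus, default_library,
                                 library_from_config, library_to_config,
                                 ligament_bulk_as_printed, linear_stress,
                                 mr_energy, mr_first_piola, mr_stress,
                                 poisson_from_bulk)

CARTILAGE = MooneyRivlinParams(C1=4.1, C2=0.41, K=19.3)


class TestBulkPoissonRelations:
    def test_cartilage_bulk_modulus(self):
        # E = 11.6 MPa, nu = 0.4 gives the model's cartilage K
        assert bulk_modulus(11.6, 0.4) == pytest.approx(19.3, abs=0.05)

    def test_zero_poisson_limit(self):
        assert bulk_modulus(3.0, 0.0) == pytest.approx(1.0)

    def test_slil_poisson_ratio(self):
        # E = 4.89 MPa with the ligament bulk modulus gives nu ~= 0.41
        nu = poisson_from_bulk(4.89, ligament_bulk_as_printed())
        assert nu == pytest.approx(0.41, abs=0.005)
        assert nu == pytest.approx(0.4114, abs=1e-4)

    @given(E=st.floats(0.1, 1e4), nu=st.floats(0.01, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_mutual_inverses(self, E, nu):
        # the inversion is defined on the positive-Poisson branch (E < 3K)
        assert poisson_from_bulk(E, bulk_modulus(E, nu)) == \
            pytest.approx(nu, abs=1e-9)

    def test_slil_bulk_from_experimental_pair(self):
        # inverse consistency: the (E, nu) pair recovered for the SLIL
        # maps back onto its bulk modulus
        assert bulk_modulus(4.89, 0.41139) == pytest.approx(9.198,
                                                            abs=2e-3)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            bulk_modulus(10.0, 0.5)
        with pytest.raises(ValueError):
            poisson_from_bulk(30.0, 10.0)   # E >= 3K

    def test_ligament_bulk_as_printed(self):
        assert ligament_bulk_as_printed() == 9.19802
        # the documented reproduction chain for the printed constant
        assert 1000 * 832.4e-6 * 11.05e-6 * 1e6 == \
            pytest.approx(9.19802, abs=1e-5)
        assert default_library()["slil"].K == ligament_bulk_as_printed()


class TestMooneyRivlinEnergy:
    def test_reference_is_stress_free(self):
        assert mr_energy(np.eye(3), CARTILAGE) == 0.0
        assert np.allclose(mr_stress(np.eye(3), CARTILAGE), 0.0)

    def test_pure_dilatation(self):
        # isochoric invariants stay at 3: only the volumetric term remains
        F = 1.1 ** (1 / 3) * np.eye(3)
        assert mr_energy(F, CARTILAGE) == \
            pytest.approx(0.5 * 19.3 * 0.1 ** 2, rel=1e-6)

    def test_isochoric_uniaxial_closed_form(self):
        lam = 1.2
        p = MooneyRivlinParams(C1=4.1, C2=0.0, K=19.3)
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        assert mr_energy(F, p) == \
            pytest.approx(4.1 * (lam ** 2 + 2 / lam - 3), rel=1e-9)

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            mr_energy(-np.eye(3), CARTILAGE)

    def test_nonnegative_near_identity(self, rng):
        for _ in range(100):
            F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
            if np.linalg.det(F) > 0:
                assert mr_energy(F, CARTILAGE) >= -1e-12

    def test_objectivity_rotations(self, rng):
        for i in range(5):
            R = Rotation.random(random_state=i).as_matrix()
            assert mr_energy(R, CARTILAGE) == pytest.approx(0.0, abs=1e-12)
            assert np.abs(mr_stress(R, CARTILAGE)).max() < 1e-10


class TestMooneyRivlinStress:
    def test_matches_energy_gradient(self, rng):
        """First Piola stress equals central finite differences of W."""
        h = 1e-6
        for _ in range(20):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            P = mr_first_piola(F, CARTILAGE)
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    fd = (mr_energy(Fp, CARTILAGE)
                          - mr_energy(Fm, CARTILAGE)) / (2 * h)
                    assert P[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_cauchy_stress_symmetric(self, rng):
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0
        sig = mr_stress(F, CARTILAGE)
        assert np.allclose(sig, sig.T)

    def test_neo_hookean_reduction(self, rng):
        """With C2 = 0 the energy is compressible neo-Hookean."""
        p = MooneyRivlinParams(C1=0.9, C2=0.0, K=5.0)
        for _ in range(10):
            F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
            J = np.linalg.det(F)
            if J <= 0:
                continue
            I1 = np.trace(F.T @ F)
            W_nh = 0.9 * (J ** (-2 / 3) * I1 - 3) + 0.5 * 5.0 * (J - 1) ** 2
            assert mr_energy(F, p) == pytest.approx(W_nh, rel=1e-12)


class TestLinearElastic:
    def test_zero_strain(self):
        p = LinearElasticParams(E=18.0, nu=0.2)
        assert np.allclose(linear_stress(np.zeros((3, 3)), p), 0.0)

    def test_hydrostatic_consistency_with_bulk(self):
        # hydrostatic strain eps*I must give stress 3 K eps I
        p = LinearElasticParams(E=18.0, nu=0.2)
        eps = 0.01 * np.eye(3)
        K = bulk_modulus(18.0, 0.2)
        assert np.allclose(linear_stress(eps, p), 3 * K * 0.01 * np.eye(3))

    def test_matches_voigt_assembly(self, rng):
        """Independent 6x6 Voigt-matrix route gives the same stress."""
        p = LinearElasticParams(E=100.0, nu=0.25)
        lam, mu = p.lame
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[3:, 3:] = mu * np.eye(3)
        e = rng.standard_normal((3, 3))
        eps = 0.5 * (e + e.T)
        v = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                      2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]])
        sv = D @ v
        sig = linear_stress(eps, p)
        assert np.allclose(
            [sig[0, 0], sig[1, 1], sig[2, 2], sig[0, 1], sig[1, 2],
             sig[0, 2]], [sv[0], sv[1], sv[2], sv[3], sv[4], sv[5]])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            LinearElasticParams(E=-1.0, nu=0.2)
        with pytest.raises(ValueError):
            LinearElasticParams(E=1.0, nu=0.6)
        with pytest.raises(ValueError):
            MooneyRivlinParams(C1=-1.0, C2=0.5, K=1.0)


def test_default_library_values():
    lib = default_library()
    assert (lib["cortical"].E, lib["cortical"].nu) == (18.0, 0.2)
    assert (lib["cancellous"].E, lib["cancellous"].nu) == (100.0, 0.25)
    assert (lib["cartilage"].C1, lib["cartilage"].C2) == (4.1, 0.41)
    assert lib["slil"].C1 == pytest.approx(832.4e-6)
    assert lib["slil"].C2 == pytest.approx(11.05e-6)


def test_library_config_round_trip():
    lib = default_library()
    assert library_from_config(library_to_config(lib)) == lib
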