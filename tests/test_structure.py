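"""Kabsch superposition, domain RMSDs, ensemble precision, distances."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from spinrelax.structure import (
    Selection,
    StructureEnsemble,
    ensemble_rmsd_to_mean,
    interhelix_distance,
    kabsch_superpose,
    load_structure,
    mean_structure,
    subset_rmsd,
)

ALL_CA = Selection(((1, 10**6),), "CA")


def ca_structure(n=60, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return StructureEnsemble(
        [{(i + 1, "CA"): rng.normal(size=3) * scale for i in range(n)}]
    )


def transformed(st, rot, trans):
    return StructureEnsemble(
        [{k: rot @ v + trans for k, v in m.items()} for m in st.models],
        name=st.name,
    )


def brute_force_min_rmsd(a, b, n_starts=20, seed=0):
    """Independent optimal-rotation oracle: numerical minimization over
    rotation vectors after centroid removal, multi-start."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((a @ r.T - b) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        res = minimize(cost, rng.normal(scale=1.5, size=3), method="Nelder-Mead",
                       options=dict(xatol=1e-12, fatol=1e-14, maxiter=2000))
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_self_superposition_is_identity(self):
        st = ca_structure()
        rot, trans, rmsd, _ = kabsch_superpose(st, st, ALL_CA)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-12)
        assert np.allclose(trans, 0.0, atol=1e-12)

    def test_rigid_copy_recovers_inverse_transform(self):
        st = ca_structure(seed=1)
        rot_true = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
        moved = transformed(st, rot_true, np.array([3.0, -7.0, 1.5]))
        rot, _, rmsd, back = kabsch_superpose(moved, st, ALL_CA)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot @ rot_true, np.eye(3), atol=1e-9)
        assert np.allclose(back.models[0][(1, "CA")], st.models[0][(1, "CA")])

    def test_rotation_is_always_proper(self):
        # a reflection-like correspondence must still give det(R) = +1
        st = ca_structure(seed=2, n=10)
        mirrored = StructureEnsemble(
            [{k: v * np.array([-1.0, 1.0, 1.0]) for k, v in st.models[0].items()}]
        )
        rot, _, _, _ = kabsch_superpose(mirrored, st, ALL_CA)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_rotation_search_on_random_point_sets(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 3)) * 5
        b = rng.normal(size=(5, 3)) * 5
        st_a = StructureEnsemble([{(i + 1, "CA"): a[i] for i in range(5)}])
        st_b = StructureEnsemble([{(i + 1, "CA"): b[i] for i in range(5)}])
        _, _, rmsd, _ = kabsch_superpose(st_a, st_b, ALL_CA)
        assert rmsd == pytest.approx(brute_force_min_rmsd(a, b, seed=seed), abs=1e-6)

    def test_unpairable_selection_reports_mismatches(self):
        st = ca_structure(n=10)
        other = StructureEnsemble([{(i + 100, "CA"): v for (i, _), v in st.models[0].items()}])
        with pytest.raises(ValueError, match="unpaired"):
            kabsch_superpose(st, other, ALL_CA)


class TestSubsetRmsd:
    def test_zero_for_identical_structures(self):
        st = ca_structure(n=200, seed=3)
        assert subset_rmsd(st, st, Selection.from_domain("CORE")) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_invariant_under_prerotation_of_either_input(self):
        a = ca_structure(n=200, seed=4)
        b = ca_structure(n=200, seed=5)
        sel = Selection.from_domain("CORE")
        base = subset_rmsd(a, b, sel)
        rot = Rotation.from_euler("xyz", [10, 60, -30], degrees=True).as_matrix()
        assert subset_rmsd(transformed(a, rot, np.array([1.0, 2, 3])), b, sel) == (
            pytest.approx(base, rel=1e-9)
        )
        assert subset_rmsd(a, transformed(b, rot, np.array([-4.0, 0, 9])), sel) == (
            pytest.approx(base, rel=1e-9)
        )

    def test_symmetric_in_its_arguments(self):
        a = ca_structure(n=200, seed=6)
        b = ca_structure(n=200, seed=7)
        sel = Selection.from_domain("NMP_LID")
        assert subset_rmsd(a, b, sel) == pytest.approx(subset_rmsd(b, a, sel), rel=1e-9)

    def test_fit_and_measure_selections_can_differ(self):
        # displace the lid region only: core-fit RMSD over the lid sees it,
        # lid-local fit does not
        a = ca_structure(n=200, seed=8)
        shifted = {
            k: (v + np.array([4.0, 0, 0]) if 122 <= k[0] <= 167 else v)
            for k, v in a.models[0].items()
        }
        b = StructureEnsemble([shifted])
        core = Selection.from_domain("CORE")
        lid = Selection.from_domain("LID")
        assert subset_rmsd(a, b, core, lid) == pytest.approx(4.0, rel=1e-6)
        assert subset_rmsd(a, b, lid) == pytest.approx(0.0, abs=1e-9)


class TestEnsemblePrecision:
    def test_identical_models_have_zero_spread(self):
        m = ca_structure(n=50, seed=9).models[0]
        ens = StructureEnsemble([dict(m) for _ in range(5)])
        mean, sd = ensemble_rmsd_to_mean(ens, ALL_CA)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_noise_gives_sigma_sqrt3_spread(self):
        """Mean + N(0, sigma^2) per coordinate: expected RMSD to the mean is
        sigma*sqrt(3) (up to the sqrt(1-1/m) mean-estimation shrinkage)."""
        rng = np.random.default_rng(10)
        base = {(i + 1, "CA"): rng.normal(size=3) * 20 for i in range(1000)}
        sigma, m = 0.4, 20
        models = [
            {k: v + rng.normal(0, sigma, 3) for k, v in base.items()}
            for _ in range(m)
        ]
        mean, _ = ensemble_rmsd_to_mean(StructureEnsemble(models), ALL_CA)
        expected = sigma * np.sqrt(3) * np.sqrt(1 - 1 / m)
        assert mean == pytest.approx(expected, rel=0.05)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            ensemble_rmsd_to_mean(ca_structure(), ALL_CA)


class TestDistances:
    def test_three_four_five_triangle(self):
        st = StructureEnsemble(
            [{(1, "CA"): np.zeros(3), (2, "CA"): np.array([3.0, 4.0, 0.0])}]
        )
        first, mean, sd = interhelix_distance(st, 1, 2)
        assert first == 5.0 and mean == 5.0 and sd == 0.0

    def test_missing_residue_is_an_error(self):
        st = ca_structure(n=10)
        with pytest.raises(ValueError, match="missing C-alpha"):
            interhelix_distance(st, 1, 99)

    def test_invariant_under_rigid_motion(self):
        st = ca_structure(n=10, seed=11)
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True).as_matrix()
        moved = transformed(st, rot, np.array([8.0, -2, 4]))
        assert interhelix_distance(moved, 2, 9)[0] == pytest.approx(
            interhelix_distance(st, 2, 9)[0], rel=1e-12
        )


class TestPdbRoundTrip:
    def test_load_structure_reads_written_pdb(self, tmp_path):
        """A tiny synthetic two-model PDB file survives a read round trip."""
        pdb = tmp_path / "toy.pdb"
        lines = []
        coords = {1: (0.0, 0.0, 0.0), 2: (3.0, 4.0, 0.0)}
        for model in (1, 2):
            lines.append(f"MODEL     {model:4d}")
            serial = 1
            for res, (x, y, z) in coords.items():
                zz = z + (model - 1) * 0.5
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA A{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{zz:8.3f}  1.00  0.00           C"
                )
                serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        pdb.write_text("\n".join(lines) + "\n")

        st = load_structure(pdb)
        assert st.n_models == 2
        assert interhelix_distance(st, 1, 2)[0] == pytest.approx(5.0)
        assert st.models[1][(2, "CA")][2] == pytest.approx(0.5)

    def test_mean_structure_of_two_translated_models(self):
        base = ca_structure(n=30, seed=12).models[0]
        # second model: same conformation, rigidly displaced - the mean after
        # superposition equals the conformation itself
        moved = {k: v + np.array([5.0, 5.0, 5.0]) for k, v in base.items()}
        ens = StructureEnsemble([base, moved])
        mean_st = mean_structure(ens)
        _, _, rmsd, _ = kabsch_superpose(mean_st, StructureEnsemble([base]), ALL_CA)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
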