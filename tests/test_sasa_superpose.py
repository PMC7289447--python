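import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cochap.simulate import generate_toy_complex
from cochap.structure import (
    Structure,
    buried_hydrophobic_area,
    cluster_frames_single_linkage,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    sasa_quadrature_tolerance,
    shrake_rupley_sasa,
)


def carbons(coords):
    n = len(coords)
    return Structure(
        chain_ids=np.array(["A"] * n),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["GLY"] * n),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        coords=np.asarray(coords, dtype=float),
    )


class TestSASA:
    def test_isolated_sphere_is_exact(self):
        area = shrake_rupley_sasa(carbons([[0, 0, 0]]))[0]
        assert area == pytest.approx(4 * np.pi * 0.31**2, rel=1e-12)

    def test_distant_atoms_do_not_occlude(self):
        s = carbons([[0, 0, 0], [10, 0, 0]])
        areas = shrake_rupley_sasa(s)
        assert areas.sum() == pytest.approx(2 * 4 * np.pi * 0.31**2, rel=1e-12)

    def test_fully_enclosed_atom_has_zero_area(self):
        # icosahedral-ish shell of carbons tightly surrounding one atom
        shell = []
        for phi in np.linspace(0, np.pi, 6):
            for theta in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                shell.append(
                    0.25 * np.array([
                        np.sin(phi) * np.cos(theta),
                        np.sin(phi) * np.sin(theta),
                        np.cos(phi),
                    ])
                )
        # dedupe poles
        uniq = []
        for p in shell:
            if not any(np.allclose(p, q, atol=1e-8) for q in uniq):
                uniq.append(p)
        s = carbons([[0, 0, 0]] + uniq)
        assert shrake_rupley_sasa(s)[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance_within_quadrature_tolerance(self):
        s, _ = generate_toy_complex(5, 9)
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = s.transformed(R, np.array([1.0, -2.0, 0.5]))
        tol = sasa_quadrature_tolerance(s)
        assert shrake_rupley_sasa(moved).sum() == pytest.approx(
            shrake_rupley_sasa(s).sum(), abs=tol
        )

    def test_cross_check_against_reference_implementation(self):
        import biotite.structure as bst

        from cochap.structure.core import _to_atom_array

        s, _ = generate_toy_complex(6, 1)
        ours = shrake_rupley_sasa(s).sum()
        theirs = bst.sasa(
            _to_atom_array(s), probe_radius=1.4, point_number=960, vdw_radii="Single"
        ).sum() / 100.0  # A^2 -> nm^2
        assert ours == pytest.approx(theirs, abs=2 * sasa_quadrature_tolerance(s))

    def test_unknown_element_warns_with_default_radius(self):
        s = carbons([[0, 0, 0]])
        s.elements = np.array(["XX"])
        with pytest.warns(UserWarning, match="default radius"):
            shrake_rupley_sasa(s)


class TestBuriedHydrophobic:
    def test_separated_chains_bury_nothing(self):
        s, _ = generate_toy_complex(5, 2, separation=10.0)
        assert buried_hydrophobic_area(s, "A", "B") == pytest.approx(
            0.0, abs=sasa_quadrature_tolerance(s)
        )

    def test_burial_non_negative(self):
        for seed in range(5):
            s, _ = generate_toy_complex(6, seed)
            assert buried_hydrophobic_area(s, "A", "B") >= -sasa_quadrature_tolerance(s)

    def test_leucine_stack_matches_direct_sasa_difference(self):
        s, _ = generate_toy_complex(6, 3)
        from cochap.constants import HYDROPHOBIC_RESIDUES

        total = 0.0
        bound_areas = shrake_rupley_sasa(s)
        for chain in ("A", "B"):
            alone = s.subset(s.chain_ids == chain)
            alone_areas = shrake_rupley_sasa(alone)
            hmask_alone = np.isin(alone.res_names, sorted(HYDROPHOBIC_RESIDUES))
            hmask_bound = (s.chain_ids == chain) & np.isin(
                s.res_names, sorted(HYDROPHOBIC_RESIDUES)
            )
            total += alone_areas[hmask_alone].sum() - bound_areas[hmask_bound].sum()
        assert buried_hydrophobic_area(s, "A", "B") == pytest.approx(total, abs=1e-12)
        assert total > 0  # the planted Leu-Leu stack buries surface

    def test_missing_chain_rejected(self):
        s, _ = generate_toy_complex(4, 0)
        with pytest.raises(ValueError):
            buried_hydrophobic_area(s, "A", "C")


class TestKabsch:
    def test_self_superposition_zero_rmsd(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = kabsch_superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        R0 = Rotation.random(random_state=5).as_matrix()
        Y = X @ R0.T + np.array([0.3, -1.0, 2.0])
        R, t, rmsd = kabsch_superpose(X, Y)
        assert rmsd < 1e-10
        np.testing.assert_allclose(R, R0, atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_beats_rotation_grid_oracle(self):
        # 4-point asymmetric set vs a perturbed copy: the closed-form
        # optimum must match a dense random SO(3) search within its
        # resolution, and never be worse
        rng = np.random.default_rng(2)
        X = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0.5, 0.5, 1.5]])
        Y = X @ Rotation.random(random_state=3).as_matrix().T + rng.normal(0, 0.1, (4, 3))
        _, _, rmsd = kabsch_superpose(X, Y)
        grid = Rotation.random(4000, random_state=4)
        best = np.inf
        yc = Y - Y.mean(axis=0)
        xc = X - X.mean(axis=0)
        for R in grid.as_matrix():
            cand = np.sqrt(np.mean(np.sum((xc @ R.T - yc) ** 2, axis=1)))
            best = min(best, cand)
        assert rmsd <= best + 1e-12
        assert best - rmsd < 0.1  # grid resolution

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestSingleLinkageClustering:
    def frames_from(self, offsets, seed=0):
        # non-rigid displacement field scaled per frame (rigid shifts would
        # be removed by the superposition step)
        base, _ = generate_toy_complex(4, seed)
        rng = np.random.default_rng(seed + 100)
        field = rng.normal(size=base.coords.shape)
        field /= np.sqrt(np.mean(np.sum(field**2, axis=1)))
        frames = []
        for k, off in enumerate(offsets):
            f = base.subset(np.ones(base.n_atoms, dtype=bool))
            jitter = np.random.default_rng(k).normal(0, 0.001, base.coords.shape)
            f.coords = base.coords + off * field + jitter
            frames.append(f)
        return frames

    def test_identical_frames_one_cluster(self):
        base, _ = generate_toy_complex(4, 1)
        clusters = cluster_frames_single_linkage([base] * 4, cutoff=0.18)
        assert len(clusters) == 1
        assert clusters[0].members == [0, 1, 2, 3]

    def test_two_distinct_bundles(self):
        # rigid shifts are removed by superposition; distort one bundle
        base, _ = generate_toy_complex(4, 1)
        other = base.subset(np.ones(base.n_atoms, dtype=bool))
        rng = np.random.default_rng(3)
        other.coords = base.coords + rng.normal(0, 0.5, base.coords.shape)
        clusters = cluster_frames_single_linkage([base, base, other, other], cutoff=0.18)
        assert len(clusters) == 2

    def test_chain_linkage_is_transitive(self):
        base, _ = generate_toy_complex(4, 1)
        rng = np.random.default_rng(4)
        direction = rng.normal(size=base.coords.shape)
        direction /= np.sqrt(np.mean(np.sum(direction**2, axis=1)))
        frames = []
        for k in range(3):
            f = base.subset(np.ones(base.n_atoms, dtype=bool))
            f.coords = base.coords + 0.15 * k * direction
            frames.append(f)
        rmsd = pairwise_rmsd_matrix(frames)
        cutoff = 0.9 * rmsd[0, 2]
        assert rmsd[0, 1] < cutoff and rmsd[1, 2] < cutoff < rmsd[0, 2]
        clusters = cluster_frames_single_linkage(frames, cutoff=cutoff)
        assert len(clusters) == 1  # A-B-C chained through B

    def test_order_invariance(self):
        frames = self.frames_from([0.0, 0.0, 1.0, 1.0, 5.0])
        a = cluster_frames_single_linkage(frames, cutoff=0.18)
        perm = [4, 2, 0, 3, 1]
        b = cluster_frames_single_linkage([frames[i] for i in perm], cutoff=0.18)
        sets_a = {frozenset(c.members) for c in a}
        sets_b = {frozenset(perm[i] for i in c.members) for c in b}
        assert sets_a == sets_b
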