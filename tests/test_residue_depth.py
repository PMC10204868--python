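import numpy as np
import pytest
from scipy.stats import spearmanr

from ebdiff.eb_io import parse_breakdown
from ebdiff.fixtures import make_toy_structure
from ebdiff.interaction_diff import RenumberingMismatchError
from ebdiff.residue_depth import (
    VDW_RADII,
    build_surface,
    depth_energy_join,
    residue_depth,
)
from ebdiff.structure_io import Atom, EmptyStructureError, Residue, Structure

from tests.conftest import residue_centers


def _single_atom_structure(element="C", n_copies=1):
    atoms = [Atom("CA", element, 0.0, 0.0, 0.0) for _ in range(n_copies)]
    res = Residue("A", 1, 1, "ALA", atoms)
    return Structure([res])


def _rigid_transform(s, seed=42):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(size=3) * 30
    residues = []
    for r in s.residues:
        atoms = [
            Atom(a.name, a.element, *(q @ np.array([a.x, a.y, a.z]) + t))
            for a in r.atoms
        ]
        residues.append(Residue(r.chain_id, r.author_seq_id, r.renumbered_id,
                                r.restype3, atoms))
    return Structure(residues)


class TestBuildSurface:
    def test_single_atom_keeps_all_samples_at_expanded_radius(self):
        cloud = build_surface(_single_atom_structure(), probe_radius=1.5,
                              samples_per_atom=100)
        assert len(cloud.points) == 100
        radii = np.linalg.norm(cloud.points, axis=1)
        assert radii == pytest.approx(VDW_RADII["C"] + 1.5, abs=1e-9)

    def test_fully_overlapping_atoms_keep_their_duplicate_points(self):
        cloud = build_surface(_single_atom_structure(n_copies=2),
                              samples_per_atom=50)
        assert len(cloud.points) == 100  # nothing occluded at equal radius

    def test_empty_structure_raises(self):
        with pytest.raises(EmptyStructureError):
            build_surface(Structure([Residue("A", 1, 1, "ALA", [])]))

    def test_occlusion_matches_brute_force_all_pairs(self):
        # ~100-atom cluster; compare retained points with an O(n²·samples)
        # check done without the spatial index
        s, _ = make_toy_structure(20, "ball", seed=9)
        probe, k = 1.5, 120
        cloud = build_surface(s, probe_radius=probe, samples_per_atom=k)
        centers, radii = [], []
        for res in s.residues:
            for a in res.heavy_atoms:
                centers.append([a.x, a.y, a.z])
                radii.append(VDW_RADII.get(a.element, 1.70))
        centers = np.array(centers)
        expanded = np.array(radii) + probe
        from ebdiff.residue_depth import _sample_directions
        cutoff = 2.0 * (expanded.max())
        dirs = _sample_directions(centers, k, cutoff)
        kept = []
        for i in range(len(centers)):
            pts = centers[i] + expanded[i] * dirs[i]
            dist = np.linalg.norm(
                pts[:, None, :] - centers[None, :, :], axis=2)
            dist[:, i] = np.inf
            survive = np.all(dist >= expanded[None, :] - 1e-9, axis=1)
            kept.append(pts[survive])
        brute = np.concatenate(kept)
        assert cloud.points.shape == brute.shape
        assert np.allclose(cloud.points, brute, atol=0)


class TestResidueDepth:
    def test_free_glycine_is_fully_exposed(self):
        atoms = [Atom("N", "N", -1.2, 0.6, -0.4), Atom("CA", "C", 0, 0, 0),
                 Atom("C", "C", 1.2, 0.6, 0.4), Atom("O", "O", 1.3, 1.8, 0.4)]
        s = Structure([Residue("A", 1, 1, "GLY", atoms)])
        rec = residue_depth(s, build_surface(s))[0]
        assert 0 < rec.depth < max(VDW_RADII.values()) + 1.5 + 0.1

    def test_depth_equals_brute_force_nearest_point_oracle(self, ball):
        s, cloud, _ = ball
        records = residue_depth(s, cloud)
        for res, rec in zip(s.residues, records):
            coords = np.array([[a.x, a.y, a.z] for a in res.heavy_atoms])
            # brute force: full distance matrix, no spatial index
            d = np.linalg.norm(
                coords[:, None, :] - cloud.points[None, :, :], axis=2)
            assert rec.depth == pytest.approx(float(d.min(axis=1).mean()),
                                              abs=1e-9)

    def test_depth_rank_correlates_with_burial(self, ball):
        s, cloud, _ = ball
        dep = np.array([r.depth for r in residue_depth(s, cloud)])
        centers = residue_centers(s)
        dist = np.linalg.norm(centers - centers.mean(axis=0), axis=1)
        rho, _ = spearmanr(dep, -dist)
        assert rho >= 0.95

    def test_central_residue_deeper_than_peripheral(self, ball):
        s, cloud, _ = ball
        dep = np.array([r.depth for r in residue_depth(s, cloud)])
        centers = residue_centers(s)
        dist = np.linalg.norm(centers - centers.mean(axis=0), axis=1)
        assert dep[np.argmin(dist)] > dep[np.argmax(dist)]

    def test_rigid_motion_invariance(self, ball):
        s, cloud, _ = ball
        d0 = residue_depth(s, cloud)
        s2 = _rigid_transform(s)
        d2 = residue_depth(s2, build_surface(s2))
        for a, b in zip(d0, d2):
            assert b.depth == pytest.approx(a.depth, abs=1e-6)

    def test_remote_cluster_does_not_perturb_depths(self):
        s, _ = make_toy_structure(12, "ball", seed=4)
        d0 = residue_depth(s, build_surface(s, samples_per_atom=240))
        far = 2 * (max(VDW_RADII.values()) + 1.5) + 60.0
        extra = Residue("B", 99, 13, "ALA",
                        [Atom("CA", "C", far, far, far)])
        s2 = Structure(s.residues + [extra])
        d2 = residue_depth(s2, build_surface(s2, samples_per_atom=240))
        for a, b in zip(d0, d2[:12]):
            assert b.depth == pytest.approx(a.depth, abs=1e-6)

    def test_sampling_density_stability(self, ball):
        s, cloud, _ = ball
        d960 = residue_depth(s, cloud)
        d240 = residue_depth(s, build_surface(s, samples_per_atom=240))
        for a, b in zip(d960, d240):
            assert abs(a.depth - b.depth) < 0.2


class TestDepthEnergyJoin:
    HEADER = (
        "SCORE: pose_id resi1 pdbid1 restype1 resi2 pdbid2 restype2"
        " fa_atr total description"
    )

    def _table(self, rows):
        return parse_breakdown("\n".join([self.HEADER] + rows))

    def test_identical_inputs_give_zero_deltas(self):
        s, _ = make_toy_structure(3, "extended", sequence="AGS", seed=0)
        cloud = build_surface(s, samples_per_atom=120)
        depths = residue_depth(s, cloud)
        rows = [
            "SCORE: 1 1 1A ALA -- -- onebody -1.0 -1.0 r",
            "SCORE: 1 2 2A GLY -- -- onebody -0.5 -0.5 r",
            "SCORE: 1 3 3A SER -- -- onebody -0.2 -0.2 r",
            "SCORE: 1 1 1A ALA 2 2A GLY -0.3 -0.3 r",
        ]
        t = self._table(rows)
        joined = depth_energy_join(depths, depths, t, t)
        assert all(r.delta_net == pytest.approx(0.0) for r in joined)
        assert all(r.missing_in is None for r in joined)

    def test_onebody_shift_propagates_to_delta_net(self):
        s, _ = make_toy_structure(2, "extended", sequence="AG", seed=0)
        depths = residue_depth(s, build_surface(s, samples_per_atom=120))
        t_ref = self._table([
            "SCORE: 1 1 1A ALA -- -- onebody -1.0 -1.0 r",
            "SCORE: 1 2 2A GLY -- -- onebody -0.5 -0.5 r",
        ])
        t_mut = self._table([
            "SCORE: 1 1 1A ALA -- -- onebody -1.0 -1.0 r",
            "SCORE: 1 2 2A GLY -- -- onebody 1.5 1.5 r",
        ])
        joined = depth_energy_join(depths, depths, t_ref, t_mut)
        assert joined[0].delta_net == pytest.approx(0.0)
        assert joined[1].delta_net == pytest.approx(2.0)

    def test_restype_contradiction_raises(self):
        s, _ = make_toy_structure(2, "extended", sequence="AG", seed=0)
        depths = residue_depth(s, build_surface(s, samples_per_atom=120))
        t = self._table([
            "SCORE: 1 1 1A TRP -- -- onebody -1.0 -1.0 r",
            "SCORE: 1 2 2A GLY -- -- onebody -0.5 -0.5 r",
        ])
        with pytest.raises(RenumberingMismatchError):
            depth_energy_join(depths, depths, t, t)

    def test_missing_residue_is_flagged_not_dropped(self):
        s, _ = make_toy_structure(2, "extended", sequence="AG", seed=0)
        depths = residue_depth(s, build_surface(s, samples_per_atom=120))
        t_full = self._table([
            "SCORE: 1 1 1A ALA -- -- onebody -1.0 -1.0 r",
            "SCORE: 1 2 2A GLY -- -- onebody -0.5 -0.5 r",
        ])
        t_short = self._table([
            "SCORE: 1 1 1A ALA -- -- onebody -1.0 -1.0 r",
        ])
        joined = depth_energy_join(depths, depths, t_full, t_short)
        flagged = [r for r in joined if r.residue == 2]
        assert flagged and flagged[0].missing_in == "mut"
        assert flagged[0].delta_net is None
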