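"""Linker sampling, pool generation and rigid-body fitting."""

import numpy as np
import pytest

from confensa import (AssemblySpec, CoordinateModel, ScatteringCurve,
                      build_pool, sample_linker, rigid_body_fit,
                      radius_of_gyration, debye_intensity)
from confensa.conformers import (BOND_LENGTH, GeometryError, SamplingError,
                                 build_p2_pool, hinge_subtemplates)
from confensa.synth import _globule


class TestSampleLinker:
    def test_single_bead_tether(self):
        w = sample_linker(np.zeros(3), 1, rng=0)
        assert w.shape == (1, 3)
        assert np.linalg.norm(w[0]) == pytest.approx(BOND_LENGTH)

    def test_bond_lengths_fixed(self):
        w = sample_linker(np.zeros(3), 12, rng=1)
        steps = np.linalg.norm(np.diff(np.vstack([np.zeros(3), w]), axis=0),
                               axis=1)
        np.testing.assert_allclose(steps, BOND_LENGTH, rtol=1e-9)

    def test_bridging_closure_100_seeds(self):
        end = np.array([10.0, 0, 0])
        for seed in range(100):
            w = sample_linker(np.zeros(3), 15, anchor_end=end, rng=seed)
            closure = abs(np.linalg.norm(end - w[-1]) - BOND_LENGTH)
            assert closure < 0.5

    def test_end_to_end_statistics(self):
        """Excluded volume inflates <R^2> above the ideal chain's n*b^2,
        but not beyond the full self-avoiding-walk swelling (~1.6x)."""
        rng = np.random.default_rng(0)
        e2 = [np.sum(sample_linker(np.zeros(3), 15, rng=rng)[-1] ** 2)
              for _ in range(1000)]
        ratio = np.mean(e2) / (15 * BOND_LENGTH ** 2)
        assert 1.0 < ratio < 1.6

    def test_unreachable_anchor_raises(self):
        with pytest.raises(GeometryError):
            sample_linker(np.zeros(3), 3, anchor_end=np.array([60.0, 0, 0]))

    def test_context_avoidance(self):
        # a dense wall of beads right next to the anchor
        wall = np.mgrid[-20:21:2.0, -20:21:2.0, 1:2][:3]
        wall = np.column_stack([w.ravel() for w in wall])
        w = sample_linker(np.zeros(3), 10, context=wall, rng=3)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(wall).query(w)
        assert d.min() >= 3.0


class TestBuildPool:
    def test_rigid_spec_reproduces_template(self, toy_templates):
        closed, _, _ = toy_templates
        spec = AssemblySpec(
            rigid_bodies={"all": [(1, int(closed.residue_numbers.max()))]},
            flexible_segments=[])
        pool = build_pool(closed, spec, n_members=5, seed=0)
        assert pool.rg_values.std() == 0.0
        np.testing.assert_allclose(np.asarray(pool.members[0], dtype=float),
                                   closed.positions, atol=1e-6)

    def test_tether_pool_spread(self, small_pools):
        pool_c, _ = small_pools
        spread = pool_c.rg_values.std()
        assert 0.0 < spread < 6.0
        assert len(pool_c) == 200

    def test_hinge_pool_extends_rg(self, toy_templates):
        closed, _, dmap = toy_templates
        h_lo, h_hi = dmap.flexible[1]
        spec = AssemblySpec(
            rigid_bodies={"reg": [(1, h_lo - 1)],
                          "cat": [(h_hi + 1, int(closed.residue_numbers.max()))]},
            flexible_segments=[(h_lo, h_hi)])
        pool = build_pool(closed, spec, n_members=60, seed=5)
        assert pool.rg_values.max() >= radius_of_gyration(closed) + 5.0

    def test_same_seed_reproducible(self, toy_templates, tether_spec):
        closed, _, _ = toy_templates
        a = build_pool(closed, tether_spec, n_members=20, seed=42)
        b = build_pool(closed, tether_spec, n_members=20, seed=42)
        np.testing.assert_array_equal(a.rg_values, b.rg_values)

    def test_members_clash_free(self, small_pools):
        """Re-sampled content (the moved head block and the linker) keeps
        the steric cutoff from everything else in every member."""
        from scipy.spatial import cKDTree
        pool_c, _ = small_pools
        rng = np.random.default_rng(0)
        resnum = pool_c.template.residue_numbers
        mobile = resnum <= 94          # head block + tethered linker
        for idx in rng.choice(len(pool_c), 10, replace=False):
            pos = np.asarray(pool_c.members[idx], dtype=float)
            tree = cKDTree(pos[~mobile])
            d, _ = tree.query(pos[mobile])
            bad = np.flatnonzero(d < 3.0 * 0.99)
            # only the covalent join (94 -> 95) may come closer
            assert all(int(resnum[mobile][b]) == 94 for b in bad)

    def test_rg_values_match_members(self, small_pools):
        pool_c, _ = small_pools
        i = 7
        m = pool_c.member_model(i)
        assert radius_of_gyration(m) == pytest.approx(
            float(pool_c.rg_values[i]), rel=1e-5)


@pytest.fixture(scope="module")
def two_domain_toy():
    """Two 60-residue globules joined by a 10-residue linker."""
    rng = np.random.default_rng(4)
    a = _globule(60, rng)
    b = _globule(60, rng) + np.array([33.0, 0.0, 0.0])
    ctx = np.vstack([a, b])
    ctx = ctx[(np.linalg.norm(ctx - a[-1], axis=1) > 5.0)
              & (np.linalg.norm(ctx - b[0], axis=1) > 5.0)]
    linker = sample_linker(a[-1], 10, anchor_end=b[0], rng=7, context=ctx)
    pos = np.vstack([a, linker, b])
    model = CoordinateModel(pos)
    spec = AssemblySpec(rigid_bodies={"A": [(1, 60)], "B": [(71, 130)]},
                        flexible_segments=[(61, 70)])
    return model, spec


class TestRigidBodyFit:
    def test_fixed_point_at_truth(self, two_domain_toy):
        model, spec = two_domain_toy
        q = np.linspace(0.01, 0.3, 80)
        inten = debye_intensity(model.positions, q)
        exp = ScatteringCurve(q, inten, 0.01 * inten)
        best, fr, breakdown = rigid_body_fit(
            spec, model, exp, n_restarts=1, n_steps=30, seed=0)
        assert fr.chi2 <= 0.2
        assert breakdown["continuity_penalty"] == 0.0

    def test_recovers_planted_translation(self, two_domain_toy):
        model, spec = two_domain_toy
        rng = np.random.default_rng(9)
        q = np.linspace(0.01, 0.3, 80)
        truth_i = debye_intensity(model.positions, q)
        sig = 0.02 * truth_i
        exp = ScatteringCurve(q, truth_i + rng.normal(0, sig), sig)
        # perturbed start: swing domain A away
        start = model.copy()
        mask = start.residue_numbers <= 60
        start.positions[mask] += np.array([0.0, 18.0, 0.0])
        best, fr, breakdown = rigid_body_fit(
            spec, start, exp, n_restarts=4, n_steps=600, seed=1)
        assert fr.chi2 <= 1.2
        # inter-domain centroid distance restored within 2 A
        d_true = np.linalg.norm(
            model.positions[:60].mean(axis=0) - model.positions[70:].mean(axis=0))
        d_fit = np.linalg.norm(
            best.positions[:60].mean(axis=0) - best.positions[70:].mean(axis=0))
        assert abs(d_fit - d_true) <= 2.0
        assert breakdown["continuity_penalty"] == 0.0

    def test_p2_dimer_axis_offset_recovery(self):
        rng = np.random.default_rng(5)
        mono = CoordinateModel(_globule(80, rng) + np.array([18.0, 0, 0]))
        from confensa import apply_p2
        dimer, _ = apply_p2(mono)
        q = np.linspace(0.01, 0.25, 70)
        inten = debye_intensity(dimer.positions, q)
        sig = 0.01 * inten
        exp = ScatteringCurve(q, inten + rng.normal(0, sig), sig)
        spec = AssemblySpec(rigid_bodies={"all": [(1, 80)]},
                            flexible_segments=[], symmetry="P2")
        best, fr, breakdown = rigid_body_fit(
            spec, mono, exp, n_restarts=3, n_steps=400, seed=2)
        # output dimer must be exactly two-fold symmetric; separation of
        # the two monomer centroids recovered within 2 A
        best_dimer, _ = apply_p2(best)
        n = len(mono)
        sep_fit = np.linalg.norm(best_dimer.positions[:n].mean(axis=0)
                                 - best_dimer.positions[n:].mean(axis=0))
        sep_true = 2 * 18.0
        assert abs(sep_fit - sep_true) <= 2.0


class TestP2Pool:
    def test_members_exactly_symmetric(self, toy_templates, tether_spec):
        closed, _, _ = toy_templates
        posed = closed.transformed(
            translation=np.array([radius_of_gyration(closed), 0, 0])
            - closed.centroid())
        pool = build_p2_pool(posed, tether_spec, n_members=5, seed=3)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec([0, 0, np.pi]).as_matrix()
        for mem in pool.members:
            pos = np.asarray(mem, dtype=float)
            n = len(pos) // 2
            np.testing.assert_allclose(pos[:n] @ R.T, pos[n:], atol=1e-4)


class TestHingeSubtemplates:
    def test_representative_templates(self, toy_templates):
        closed, _, dmap = toy_templates
        h_lo, h_hi = dmap.flexible[1]
        spec = AssemblySpec(
            rigid_bodies={"reg": [(1, h_lo - 1)],
                          "cat": [(h_hi + 1, int(closed.residue_numbers.max()))]},
            flexible_segments=[(h_lo, h_hi)])
        subs = hinge_subtemplates(closed, spec, k=4, n_coarse=60, seed=1)
        assert 2 <= len(subs) <= 4
        rgs = [radius_of_gyration(s) for s in subs]
        assert max(rgs) - min(rgs) > 1.0   # distinct hinge angles
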