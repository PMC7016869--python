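"""Shared fixtures: analytic oracles and small synthetic worlds.

The analytic solid sphere is the main closed-form oracle: its form factor,
radius of gyration (sqrt(3/5) R) and pair-distance distribution are all
known exactly, so Guinier fits, the indirect Fourier transform and the
shape reconstruction can be checked without reference to any external
tool.  Expensive objects (toy templates, conformer pools) are session
scoped.
"""

import numpy as np
import pytest

from confensa import (CoordinateModel, ScatteringCurve, AssemblySpec,
                      build_pool, make_toy_multidomain)


def sphere_intensity(q, radius, i0=1.0):
    """Form-factor intensity of a uniform solid sphere (exact)."""
    x = np.asarray(q) * radius
    f = 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3
    return i0 * f ** 2


def sphere_pr(r, radius):
    """Exact (unnormalized) pair-distance distribution of a solid sphere."""
    r = np.asarray(r, dtype=float)
    x = r / (2.0 * radius)
    p = r ** 2 * (1.0 - 1.5 * x + 0.5 * x ** 3)
    p[r > 2 * radius] = 0.0
    return p


@pytest.fixture(scope="session")
def sphere_curve():
    """Noise-free sphere curve, R = 30 A, I(0) = 100, tiny formal errors."""
    radius = 30.0
    q = np.linspace(0.005, 0.35, 300)
    inten = sphere_intensity(q, radius, i0=100.0)
    sig = np.maximum(1e-4 * 100.0 * np.sqrt(inten / 100.0), 1e-9 * 100.0)
    return ScatteringCurve(q, inten, sig, {"radius": radius})


@pytest.fixture(scope="session")
def globule_500():
    """A 500-bead random filled ball (Rg ~ 17 A) for Debye cross-checks."""
    rng = np.random.default_rng(1)
    pts = []
    while len(pts) < 500:
        p = rng.uniform(-22, 22, 3)
        if np.linalg.norm(p) < 22:
            pts.append(p)
    return CoordinateModel(np.array(pts))


@pytest.fixture(scope="session")
def toy_templates():
    """Closed and extended toy multi-domain templates plus the domain map."""
    closed, dmap = make_toy_multidomain(packing="closed", seed=3)
    extended, _ = make_toy_multidomain(packing="extended", seed=3)
    return closed, extended, dmap


@pytest.fixture(scope="session")
def tether_spec(toy_templates):
    closed, _, dmap = toy_templates
    lo, hi = dmap.flexible[0]
    return AssemblySpec(
        rigid_bodies={"head": [(1, lo - 1)],
                      "core": [(hi + 1, int(closed.residue_numbers.max()))]},
        flexible_segments=[(lo, hi)])


@pytest.fixture(scope="session")
def small_pools(toy_templates, tether_spec):
    """Two 200-member pools (compact/extended) with precomputed curves."""
    closed, extended, _ = toy_templates
    q = np.linspace(0.012, 0.30, 150)
    pool_c = build_pool(closed, tether_spec, n_members=200, seed=11,
                        template_id="compact")
    pool_e = build_pool(extended, tether_spec, n_members=200, seed=12,
                        template_id="extended")
    pool_c.compute_curves(q)
    pool_e.compute_curves(q)
    return pool_c, pool_e
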