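"""Synthetic multi-domain structures and simulated scattering experiments.

Everything downstream of raw data collection can be exercised without any
downloads: toy multi-domain proteins (compact domain globules joined by
flexible linkers, with a closed/extended hinge), conformational mixtures
with known fractions, monomer/dimer equilibria, and sample/buffer curve
pairs with q-dependent counting noise, a smooth buffer profile and a
transmission mismatch — all with the ground truth recorded beside the data.

The toy globules are jittered-lattice spheres at an effective volume of
176 A^3 per residue.  That is deliberately the *apparent* (hydrated)
scattering volume implied by the Porod-volume-to-mass ratio for proteins
(Vp ~ 1.6 A^3/Da at ~110 Da/residue), not the dry packing volume, so the
molecular-weight estimators see realistic curves.  Sizes default to the
six-domain architecture of a ~100 kDa exchange factor (an N-terminal
domain tethered by a 15-residue linker, regulatory DEP/CNBD block, hinge,
and catalytic REM/RA/GEF block).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .curves import ScatteringCurve
from .debye import debye_intensity
from .structures import CoordinateModel, DomainMap, apply_p2, radius_of_gyration
from .conformers import (AssemblySpec, BOND_LENGTH, MIN_SEPARATION,
                         SamplingError, sample_linker)

__all__ = ["GroundTruth", "make_toy_multidomain", "simulate_experiment",
           "make_scenario", "default_q_grid"]

RESIDUE_VOLUME = 176.0     # A^3 apparent volume per residue (see module doc)
RESIDUE_MASS = 110.0       # Da per residue (average amino acid)

# EPAC1-like six-domain architecture: NTD, DEP, CNBD, REM, RA, GEF
DEFAULT_DOMAIN_SIZES = (79, 110, 130, 130, 130, 300)
DEFAULT_DOMAIN_NAMES = ("NTD", "DEP", "CNBD", "REM", "RA", "GEF")
NTD_LINKER = 15            # residues 80-94 in the reference numbering


@dataclass
class GroundTruth:
    """Everything needed to score a recovery: components, fractions, states.

    Each entry of ``components`` is one thermodynamic state, represented
    either by a single conformer (a rigid species) or by a list of
    conformers (a planted sub-ensemble whose members contribute equal
    weight within the state).  ``fractions`` are per-state number
    fractions summing to 1.
    """

    components: list                     # per state: CoordinateModel | list
    fractions: np.ndarray                # per-state number fractions, sum 1
    oligomer_states: list                # ints, per state
    transmission: float
    noise: dict
    seed: int
    labels: list = field(default_factory=list)
    domain_map: DomainMap | None = None
    templates: list = field(default_factory=list)   # base models per state
    scenario: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        self.components = [c if isinstance(c, list) else [c]
                           for c in self.components]
        if len(self.components) != len(self.fractions):
            raise ValueError("one fraction per state required")

    @property
    def masses(self) -> np.ndarray:
        """Relative molecular mass per state (oligomer multiplicity is
        already included in the conformer bead counts)."""
        return np.array([np.mean([len(c) for c in state]) * RESIDUE_MASS
                         for state in self.components])

    def state_rg_means(self) -> np.ndarray:
        """Mean radius of gyration of each planted state ensemble."""
        return np.array([np.mean([radius_of_gyration(c) for c in state])
                         for state in self.components])

    def to_json(self, path) -> None:
        doc = {
            "scenario": self.scenario,
            "fractions": self.fractions.tolist(),
            "oligomer_states": list(self.oligomer_states),
            "transmission": self.transmission,
            "noise": self.noise,
            "seed": self.seed,
            "labels": list(self.labels),
            "state_sizes": [[len(c) for c in state]
                            for state in self.components],
            "state_rg_means": self.state_rg_means().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _globule(n: int, rng: np.random.Generator,
             spacing: float | None = None, jitter: float = 0.9) -> np.ndarray:
    """Compact quasi-random globule of n beads on a jittered cubic lattice.

    Beads fill a sphere whose volume is n * RESIDUE_VOLUME; a serpentine
    ordering makes successive beads spatial neighbours so the result can
    stand in for a folded chain.  Minimum inter-bead distance stays above
    the steric cutoff because jitter < (spacing - MIN_SEPARATION)/2.
    """
    if spacing is None:
        spacing = RESIDUE_VOLUME ** (1.0 / 3.0)   # ~5.6 A
    radius = (3.0 * n * RESIDUE_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = int(np.ceil(radius / spacing)) + 1
    ax = np.arange(-half, half + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.linalg.norm(pts, axis=1)
    order = np.argsort(r, kind="stable")
    pts = pts[order[:n]]
    pts = pts + rng.uniform(-jitter / 2, jitter / 2, pts.shape)
    # serpentine chain ordering: sort into x-slabs, alternate y direction
    keys = np.round(pts[:, 0] / spacing).astype(int)
    ykeys = np.round(pts[:, 1] / spacing).astype(int)
    orderc = np.lexsort((pts[:, 2], np.where(keys % 2 == 0, ykeys, -ykeys), keys))
    return pts[orderc] - pts.mean(axis=0)


def make_toy_multidomain(
    domain_sizes=DEFAULT_DOMAIN_SIZES,
    linker_lengths=None,
    packing: str = "closed",
    seed: int = 0,
    domain_names=None,
    hinge_after_domain: int = 2,
) -> tuple[CoordinateModel, DomainMap]:
    """Build a toy multi-domain C-alpha model with flexible linkers.

    Domains are compact globules strung N- to C-terminal; ``packing``
    'closed' packs all domains into mutual contact around a common centre,
    'extended' swings the block of domains N-terminal of the hinge (after
    domain index ``hinge_after_domain``, 0-based) away from the rest.  The
    returned DomainMap labels the domain spans and flexible segments
    (the first linker, emulating a tethered N-terminal domain, plus a
    5-residue hinge at the swing point).
    """
    if len(domain_sizes) < 2:
        raise ValueError("need at least 2 domains")
    if packing not in ("closed", "extended"):
        raise ValueError("packing must be 'closed' or 'extended'")
    rng = np.random.default_rng(seed)
    if linker_lengths is None:
        linker_lengths = (NTD_LINKER,) + (2,) * (len(domain_sizes) - 2)
    if len(linker_lengths) != len(domain_sizes) - 1:
        raise ValueError("need len(domain_sizes)-1 linker lengths")
    if domain_names is None:
        domain_names = DEFAULT_DOMAIN_NAMES[:len(domain_sizes)] if \
            len(domain_sizes) <= 6 else [f"D{i}" for i in range(len(domain_sizes))]

    radii = [(3.0 * n * RESIDUE_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
             for n in domain_sizes]

    # place domain centres in mutual contact: greedy, pulling toward the
    # cluster centroid for compactness
    centers = [np.zeros(3)]
    for i in range(1, len(domain_sizes)):
        target_d = radii[i] + radii[i - 1] + 1.0
        best = None
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            c = centers[i - 1] + target_d * u
            ok = all(np.linalg.norm(c - centers[j]) >= radii[i] + radii[j] - 2.0
                     for j in range(i - 1))
            if not ok:
                continue
            compactness = np.linalg.norm(c - np.mean(centers, axis=0))
            if best is None or compactness < best[0]:
                best = (compactness, c)
        if best is None:
            raise SamplingError("could not pack domains")
        centers.append(best[1])
    centers = [c - np.mean(centers, axis=0) for c in centers]

    if packing == "extended":
        # swing the N-terminal block (domains 0..hinge_after_domain) away
        block = list(range(hinge_after_domain + 1))
        rest = list(range(hinge_after_domain + 1, len(domain_sizes)))
        pivot = centers[hinge_after_domain]
        away = pivot - np.mean([centers[j] for j in rest], axis=0)
        away /= np.linalg.norm(away)
        shift = (radii[hinge_after_domain] + radii[hinge_after_domain + 1]) * 1.0
        for j in block:
            centers[j] = centers[j] + shift * away

    positions = []
    resnums = []
    labels = []
    domains = {}
    flexible = []
    res = 1
    prev_end_pos = None
    for i, (n, name) in enumerate(zip(domain_sizes, domain_names)):
        g = _globule(n, rng) + centers[i]
        if i > 0:
            nlk = linker_lengths[i - 1]
            lk_start = res
            # bridge from the previous domain's last bead to this domain's
            # first bead
            ctx = np.vstack([np.asarray(positions), g]) if positions else g
            # free the exit/entry corridors: beads right at the anchors
            # would otherwise block the walk's first and last steps
            near = (np.linalg.norm(ctx - prev_end_pos, axis=1) < 5.0) | \
                   (np.linalg.norm(ctx - g[0], axis=1) < 5.0)
            ctx = ctx[~near]
            try:
                walk = sample_linker(prev_end_pos, nlk, anchor_end=g[0],
                                     rng=rng, min_separation=MIN_SEPARATION,
                                     context=ctx)
            except Exception:
                # anchors too far for the linker: route through a straight
                # guide (toy construction, not a physical chain)
                frac = np.linspace(0, 1, nlk + 2)[1:-1, None]
                walk = prev_end_pos + frac * (g[0] - prev_end_pos)
            for p in walk:
                positions.append(p)
                resnums.append(res)
                labels.append(f"linker{i}")
                res += 1
            flexible_span = (lk_start, res - 1)
            if i == 1:
                flexible.append(flexible_span)   # tethered NTD linker
        start = res
        for p in g:
            positions.append(p)
            resnums.append(res)
            labels.append(name)
            res += 1
        domains[name] = (start, res - 1)
        prev_end_pos = g[-1]

    # a short hinge span at the start of the first post-block domain
    hinge_domain = domain_names[hinge_after_domain + 1]
    h_lo = domains[hinge_domain][0]
    model = CoordinateModel(np.array(positions),
                            residue_numbers=np.array(resnums),
                            domain_labels=np.array(labels))
    dmap = DomainMap(domains=domains,
                     flexible=flexible + [(h_lo, h_lo + 4)])
    return model, dmap


def default_q_grid(n: int = 600, qmin: float = 0.012, qmax: float = 0.67) -> np.ndarray:
    """The simulated camera q range (a lab Kratky-type camera)."""
    return np.linspace(qmin, qmax, n)


def simulate_experiment(
    truth: GroundTruth,
    q_grid: np.ndarray | None = None,
    i0_per_mass: float = 1.0,
    noise_floor: float = 1.0,
    exposure_factor: float = 0.1,
    buffer_profile: dict | None = None,
    seed: int | None = None,
) -> tuple[ScatteringCurve, ScatteringCurve]:
    """Simulate a sample/buffer curve pair from a ground truth.

    The ideal signal is the mass-scaled mixture of the component Debye
    curves, scaled so I(0) equals the number-average molecular weight in
    daltons times ``i0_per_mass`` (the calibrated-intensity convention).
    The buffer is b0*exp(-q/qb) + b1; the recorded sample is
    signal + t*buffer with the truth's transmission factor t.  Counting
    noise sigma(q) = noise_floor * sqrt(I_total(q)*E)/E (E =
    ``exposure_factor``) is applied independently to both curves.
    """
    if noise_floor < 0 or exposure_factor <= 0:
        raise ValueError("noise parameters must be positive")
    if q_grid is None:
        q_grid = default_q_grid()
    q = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    masses = truth.masses
    signal = np.zeros_like(q)
    for state, frac, mass in zip(truth.components, truth.fractions, masses):
        state_curve = np.zeros_like(q)
        for comp in state:
            inten = debye_intensity(comp.positions, q, comp.weights,
                                    method="histogram")
            state_curve += inten / inten[0] / len(state)
        signal += frac * state_curve * mass * i0_per_mass

    bp = {"b0": None, "qb": 0.2, "b1": None}
    if buffer_profile:
        bp.update(buffer_profile)
    # default: buffer ~10x the signal at q = 0.2, half decaying and half
    # flat (water/capillary scattering is nearly flat over this range)
    sig_02 = np.interp(0.2, q, signal)
    if bp["b0"] is None and bp["b1"] is None:
        b0 = 10.0 * sig_02 / (np.exp(-0.2 / bp["qb"]) + 1.0)
        b1 = b0
    else:
        b0 = bp["b0"] if bp["b0"] is not None else 10.0 * sig_02
        b1 = bp["b1"] if bp["b1"] is not None else 0.05 * b0
    buffer_ideal = b0 * np.exp(-q / bp["qb"]) + b1

    t = truth.transmission
    sample_ideal = signal + t * buffer_ideal

    E = exposure_factor
    sig_sample = noise_floor * np.sqrt(sample_ideal * E) / E
    sig_buffer = noise_floor * np.sqrt(buffer_ideal * E) / E
    sample_i = sample_ideal + rng.normal(0, sig_sample)
    buffer_i = buffer_ideal + rng.normal(0, sig_buffer)

    meta = {"label": "synthetic sample", "i0_per_mass": i0_per_mass,
            "scenario": truth.scenario}
    sample = ScatteringCurve(q, sample_i, sig_sample, meta)
    buffer = ScatteringCurve(q, buffer_i, sig_buffer,
                             {"label": "synthetic buffer"})
    return sample, buffer


def make_scenario(name: str, params: dict | None = None,
                  seed: int = 0) -> GroundTruth:
    """Fully parameterized ground truths for the canonical test scenarios.

    * ``apo_two_state`` — closed conformer + hinge-extended conformer at
      number fraction ``f`` (default 0.85) closed.
    * ``dimer_equilibrium`` — P2 dimer in equilibrium with monomer at
      monomer fraction ``m`` (default 0.10, mass fraction).
    * ``ternary`` — single rigid complex with a bound partner globule
      (default 167 residues, a small GTPase).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    t = params.pop("transmission", 0.97)
    noise = {"noise_floor": params.pop("noise_floor", 1.0),
             "exposure_factor": params.pop("exposure_factor", 0.1)}
    n_draws = int(params.pop("n_draws", 20))

    def _tether_draws(template, dmap, n, draw_seed):
        """A planted sub-ensemble: n conformers with the first linker
        re-sampled (the mobile-first-domain picture the pools emulate)."""
        from .conformers import AssemblySpec, build_pool
        lo, hi = dmap.flexible[0]
        spec = AssemblySpec(
            rigid_bodies={"head": [(int(template.residue_numbers.min()), lo - 1)],
                          "core": [(hi + 1, int(template.residue_numbers.max()))]},
            flexible_segments=[(lo, hi)])
        pool = build_pool(template, spec, n_members=n, seed=draw_seed,
                          template_id="planted")
        return [pool.member_model(i) for i in range(n)]

    if name == "apo_two_state":
        f = params.pop("f", 0.85)
        closed, dmap = make_toy_multidomain(packing="closed", seed=seed)
        extended, _ = make_toy_multidomain(packing="extended", seed=seed)
        state_c = _tether_draws(closed, dmap, n_draws, seed + 101)
        state_e = _tether_draws(extended, dmap, n_draws, seed + 202)
        return GroundTruth([state_c, state_e], [f, 1.0 - f], [1, 1], t, noise,
                           seed, labels=["closed", "extended"],
                           domain_map=dmap, templates=[closed, extended],
                           scenario=name)
    if name == "dimer_equilibrium":
        m = params.pop("m", 0.10)
        mono, dmap = make_toy_multidomain(packing="extended", seed=seed)
        shifted = mono.transformed(
            translation=np.array([radius_of_gyration(mono) * 1.05, 0.0, 0.0]))
        dimer, _ = apply_p2(shifted)
        state_m = _tether_draws(mono, dmap, n_draws, seed + 101)
        # the dimer state is itself an ensemble: both tethered first
        # domains re-sampled under the two-fold constraint
        from .conformers import AssemblySpec, build_p2_pool
        lo, hi = dmap.flexible[0]
        spec = AssemblySpec(
            rigid_bodies={"head": [(int(shifted.residue_numbers.min()), lo - 1)],
                          "core": [(hi + 1, int(shifted.residue_numbers.max()))]},
            flexible_segments=[(lo, hi)])
        dpool = build_p2_pool(shifted, spec, n_members=n_draws, seed=seed + 202)
        state_d = [dpool.member_model(i) for i in range(n_draws)]
        # m is the monomer *mass* fraction; convert to number fractions
        n_mono = (m / 1.0) / (m / 1.0 + (1 - m) / 2.0)
        return GroundTruth([state_m, state_d], [n_mono, 1 - n_mono], [1, 2], t,
                           noise, seed, labels=["monomer", "dimer"],
                           domain_map=dmap, templates=[mono, shifted],
                           scenario=name)
    if name == "ternary":
        enzyme, dmap = make_toy_multidomain(packing="extended", seed=seed)
        partner_n = params.pop("partner_residues", 167)
        partner = _globule(partner_n, rng)
        # dock the partner at the surface of the catalytic (last) domain
        cat = enzyme.positions[enzyme.domain_labels == "GEF"] \
            if enzyme.domain_labels is not None else enzyme.positions
        c = cat.mean(axis=0)
        u = c - enzyme.positions.mean(axis=0)
        u = u / max(np.linalg.norm(u), 1e-9)
        r_cat = (3 * len(cat) * RESIDUE_VOLUME / (4 * np.pi)) ** (1 / 3)
        r_par = (3 * partner_n * RESIDUE_VOLUME / (4 * np.pi)) ** (1 / 3)
        partner = partner + c + (r_cat + r_par + 1.0) * u
        n_e = len(enzyme)
        complex_model = CoordinateModel(
            np.vstack([enzyme.positions, partner]),
            chain_ids=np.array(["A"] * n_e + ["B"] * partner_n),
            residue_numbers=np.concatenate([enzyme.residue_numbers,
                                            np.arange(1, partner_n + 1)]))
        return GroundTruth([complex_model], [1.0], [1], t, noise, seed,
                           labels=["ternary"], domain_map=dmap,
                           templates=[complex_model], scenario=name)
    raise ValueError(f"unknown scenario {name!r}")
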