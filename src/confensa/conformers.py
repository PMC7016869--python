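"""Conformer-pool generation and SAXS-restrained rigid-body fitting.

Multi-domain proteins with flexible inter-domain linkers populate an
ensemble of conformations in solution.  This module realizes that picture
at residue (C-alpha) resolution: rigid domain blocks taken from a template
model, connected by self-avoiding random-walk linkers with a fixed
3.8 A virtual bond, are re-sampled thousands of times to build pools of
sterically allowed conformers whose theoretical curves feed the ensemble
selection.  A simulated-annealing rigid-body optimizer fits body poses
directly against an experimental curve, with clash and chain-continuity
penalties, optionally under a two-fold (P2) symmetry constraint.

A "melted hinge" is modelled by declaring an interior span flexible: the
block upstream of the hinge swings as a rigid unit about the re-sampled
hinge conformation, which is how a helix-to-coil transition of a hinge
region changes the global shape without remodelling the domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .curves import ScatteringCurve
from .debye import debye_intensity, fit_scale, debye_curve
from .structures import CoordinateModel, apply_p2

__all__ = ["AssemblySpec", "ConformerPool", "GeometryError", "SamplingError",
           "sample_linker", "build_pool", "rigid_body_fit",
           "hinge_subtemplates"]

BOND_LENGTH = 3.8      # A, successive C-alpha virtual bond
MIN_SEPARATION = 3.0   # A, steric exclusion between non-bonded beads
MAX_GAP = 4.2          # A, allowed successive-residue gap across body joins


class GeometryError(ValueError):
    """Unreachable anchors or otherwise infeasible geometry."""


class SamplingError(RuntimeError):
    """Retry budget exhausted while sampling a conformation."""


@dataclass
class AssemblySpec:
    """Partition of a chain into rigid bodies and flexible segments.

    ``rigid_bodies`` maps body names to lists of inclusive residue spans;
    ``flexible_segments`` lists spans re-sampled per conformer.  Every
    residue must belong to exactly one body or segment.  ``symmetry`` is
    'P1' (none) or 'P2' (homodimer two-fold).
    """

    rigid_bodies: dict
    flexible_segments: list
    symmetry: str = "P1"

    def __post_init__(self) -> None:
        if self.symmetry not in ("P1", "P2"):
            raise ValueError("symmetry must be 'P1' or 'P2'")
        seen: dict[int, str] = {}
        for name, spans in self.rigid_bodies.items():
            for lo, hi in spans:
                for r in range(lo, hi + 1):
                    if r in seen:
                        raise ValueError(f"residue {r} in both {seen[r]} and {name}")
                    seen[r] = name
        for lo, hi in self.flexible_segments:
            for r in range(lo, hi + 1):
                if r in seen:
                    raise ValueError(f"residue {r} in both {seen[r]} and a "
                                     "flexible segment")
                seen[r] = "flexible"

    def validate_against(self, template: CoordinateModel) -> None:
        covered = set()
        for spans in self.rigid_bodies.values():
            for lo, hi in spans:
                covered.update(range(lo, hi + 1))
        for lo, hi in self.flexible_segments:
            covered.update(range(lo, hi + 1))
        missing = set(int(r) for r in template.residue_numbers) - covered
        if missing:
            raise ValueError(f"{len(missing)} template residues not covered "
                             f"by the assembly spec (e.g. {sorted(missing)[:5]})")


@dataclass
class ConformerPool:
    """A set of conformations sharing a template.

    Member coordinates are stored as float32 (memory: pools run to
    thousands of members); Rg values are precomputed and theory curves are
    filled in lazily by :meth:`compute_curves`.
    """

    template_id: str
    template: CoordinateModel
    members: list                      # list of (N, 3) float32 arrays
    rg_values: np.ndarray
    seed: int
    q_grid: np.ndarray | None = None
    curves: np.ndarray | None = None   # (n_members, n_q)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def compute_curves(self, q_grid: np.ndarray,
                       bin_width: float = 0.5) -> np.ndarray:
        """Precompute per-member Debye curves on a shared q grid."""
        q = np.asarray(q_grid, dtype=float)
        out = np.empty((len(self.members), len(q)))
        w = self.template.weights
        for i, pos in enumerate(self.members):
            out[i] = debye_intensity(np.asarray(pos, dtype=float), q, w,
                                     method="histogram", bin_width=bin_width)
        self.q_grid = q
        self.curves = out
        return out

    def member_model(self, i: int) -> CoordinateModel:
        out = self.template.copy()
        out.positions = np.asarray(self.members[i], dtype=float)
        return out


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_linker(
    anchor_start: np.ndarray,
    n_residues: int,
    anchor_end: np.ndarray | None = None,
    bond_length: float = BOND_LENGTH,
    min_separation: float = MIN_SEPARATION,
    context: np.ndarray | CoordinateModel | None = None,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 200,
) -> np.ndarray:
    """Sample a self-avoiding C-alpha random-walk segment.

    Tether mode (``anchor_end`` is None): a free walk of ``n_residues``
    beads grown from ``anchor_start`` with fixed bond length.  Bridging
    mode: the walk additionally closes onto ``anchor_end`` — the last bead
    ends one bond length from it, to within 0.5 A, via iterative end-point
    correction of a target-biased walk.

    Beads keep ``min_separation`` from ``context`` beads and from
    non-bonded beads of the walk itself.
    """
    rng = np.random.default_rng(rng)
    start = np.asarray(anchor_start, dtype=float)
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    ctx = None
    if context is not None:
        pts = context.positions if isinstance(context, CoordinateModel) else \
            np.asarray(context, dtype=float)
        if len(pts):
            ctx = cKDTree(pts)

    bridging = anchor_end is not None
    if bridging:
        end = np.asarray(anchor_end, dtype=float)
        span = np.linalg.norm(end - start)
        if span >= (n_residues + 1) * bond_length - 2 * bond_length:
            raise GeometryError(
                f"anchors {span:.1f} A apart unreachable with {n_residues} "
                f"residues at bond {bond_length} A")

    def clash(p, prior):
        if ctx is not None and len(ctx.query_ball_point(p, min_separation)) > 0:
            return True
        # self-avoidance exempts the two preceding beads (quasi-bonded:
        # the i-1 distance is fixed and i-2 encodes the bond angle)
        if len(prior) > 2:
            d = np.linalg.norm(np.asarray(prior[:-2]) - p, axis=1)
            if (d < min_separation).any():
                return True
        return False

    for _ in range(max_retries):
        beads: list[np.ndarray] = []
        prev = start
        ok = True
        for i in range(n_residues):
            placed = False
            for _try in range(60):
                u = _random_unit(rng)[0]
                if bridging:
                    remaining = n_residues - i          # bonds left incl. closure
                    to_end = end - prev
                    dist = np.linalg.norm(to_end)
                    slack = remaining * bond_length / max(dist, 1e-9)
                    bias = 0.0 if slack > 1.8 else min(4.0, 2.0 / max(slack - 1.0, 0.15))
                    u = u + bias * to_end / max(dist, 1e-9)
                    u = u / np.linalg.norm(u)
                p = prev + bond_length * u
                if not clash(p, beads):
                    placed = True
                    break
            if not placed:
                ok = False
                break
            beads.append(p)
            prev = p
        if not ok:
            continue
        walk = np.array(beads)
        if not bridging:
            return walk
        # iterative end-point correction: drag the chain so the last bead
        # sits one bond from the end anchor, re-normalizing bond lengths
        for _it in range(300):
            v = end - walk[-1]
            dist = np.linalg.norm(v)
            err = dist - bond_length
            if abs(err) < 0.25:
                break
            shift = err * v / max(dist, 1e-9)
            fr = (np.arange(1, n_residues + 1) / n_residues)[:, None]
            walk = walk + fr * shift
            prev = start
            for i in range(n_residues):
                b = walk[i] - prev
                walk[i] = prev + bond_length * b / max(np.linalg.norm(b), 1e-9)
                prev = walk[i]
        closure = abs(np.linalg.norm(end - walk[-1]) - bond_length)
        if closure >= 0.5:
            continue
        bad = False
        if ctx is not None:
            for p in walk:
                if len(ctx.query_ball_point(p, min_separation)) > 0:
                    bad = True
                    break
        if not bad:
            return walk
    raise SamplingError(
        f"failed to sample a {n_residues}-residue "
        f"{'bridging' if bridging else 'tethered'} segment after "
        f"{max_retries} attempts (anchors too constrained or context too "
        "crowded)")


def _chain_order(template: CoordinateModel) -> np.ndarray:
    return np.argsort(template.residue_numbers, kind="stable")


def _resolve_segments(spec: AssemblySpec) -> list:
    """Flexible segments sorted C- to N-terminal (processed outside-in)."""
    return sorted(spec.flexible_segments, key=lambda s: -s[0])


def _sample_member(
    template: CoordinateModel,
    spec: AssemblySpec,
    rng: np.random.Generator,
    min_separation: float,
    max_retries: int = 60,
) -> np.ndarray:
    """One conformer: re-sample all flexible segments, swinging the block
    N-terminal of each as a rigid unit."""
    resnum = template.residue_numbers
    pos = template.positions.copy()
    idx_of = {int(r): i for i, r in enumerate(resnum)}

    for lo, hi in _resolve_segments(spec):
        nseg = hi - lo + 1
        mobile = resnum < lo
        seg_idx = [idx_of[r] for r in range(lo, hi + 1) if r in idx_of]
        fixed = ~mobile
        for i in seg_idx:
            fixed[i] = False
        anchor_c = pos[idx_of[hi + 1]] if (hi + 1) in idx_of else None
        if anchor_c is None:
            raise ValueError(f"flexible segment {lo}-{hi} has no C-side anchor")
        ctx = pos[fixed]

        placed = False
        for _ in range(max_retries):
            walk = sample_linker(anchor_c, nseg, context=ctx, rng=rng,
                                 min_separation=min_separation)
            # walk grows from the C-side anchor toward the N terminus
            seg_pos = walk  # walk[j] is residue hi - j
            if not mobile.any():
                for j, i in enumerate(reversed(seg_idx)):
                    pos[i] = seg_pos[j]
                placed = True
                break
            attach = idx_of.get(lo - 1)
            tip = seg_pos[-1]
            R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
            target = tip + BOND_LENGTH * _random_unit(rng)[0]
            block = pos[mobile]
            block_new = (block - pos[attach]) @ R.T + target
            # the attach bead bonds to the walk tip at BOND_LENGTH, which
            # already exceeds the steric cutoff, so no exemption is needed
            tree = cKDTree(np.vstack([ctx, seg_pos]))
            d, _ = tree.query(block_new)
            clashing = (d < min_separation).sum()
            if clashing == 0:
                pos[mobile] = block_new
                for j, i in enumerate(reversed(seg_idx)):
                    pos[i] = seg_pos[j]
                placed = True
                break
        if not placed:
            raise SamplingError(f"could not place block for segment {lo}-{hi}")
    return pos


def build_pool(
    template: CoordinateModel,
    spec: AssemblySpec,
    n_members: int = 10000,
    seed: int = 0,
    min_separation: float = MIN_SEPARATION,
    template_id: str = "pool",
    member_retry_factor: int = 20,
) -> ConformerPool:
    """Generate a conformer pool by re-sampling all flexible segments.

    Each member independently re-samples every flexible segment of
    ``spec`` (and the rigid-block poses they carry); members are
    clash-free at ``min_separation``.  With no flexible segments all
    members equal the template.  Raises :class:`SamplingError` listing the
    yield if the retry budget is exhausted before ``n_members``.
    """
    spec.validate_against(template)
    rng = np.random.default_rng(seed)
    members: list[np.ndarray] = []
    rgs: list[float] = []

    w = template.weights
    wsum = w.sum()
    budget = n_members * member_retry_factor
    attempts = 0
    while len(members) < n_members and attempts < budget:
        attempts += 1
        if not spec.flexible_segments:
            pos = template.positions.copy()
        else:
            try:
                pos = _sample_member(template, spec, rng, min_separation)
            except SamplingError:
                continue
        members.append(pos.astype(np.float32))
        c = (w @ pos) / wsum
        rgs.append(float(np.sqrt((w * ((pos - c) ** 2).sum(axis=1)).sum() / wsum)))
    if len(members) < n_members:
        raise SamplingError(
            f"pool yield {len(members)}/{n_members} within retry budget")
    return ConformerPool(template_id, template, members, np.array(rgs), seed,
                         meta={"spec_symmetry": spec.symmetry,
                               "n_flexible": len(spec.flexible_segments)})


def build_p2_pool(
    monomer_template: CoordinateModel,
    spec: AssemblySpec,
    n_members: int = 10000,
    seed: int = 0,
    axis_direction=(0.0, 0.0, 1.0),
    axis_point=(0.0, 0.0, 0.0),
    min_separation: float = MIN_SEPARATION,
    template_id: str = "p2-pool",
) -> ConformerPool:
    """Pool of two-fold symmetric dimers from a posed monomer template.

    Each member re-samples the monomer's flexible segments, then the
    symmetry mate is generated by a 180-degree rotation about the given
    axis, so every member is exactly P2 symmetric.  The pool template is
    the dimer built from the unperturbed monomer.
    """
    rng = np.random.default_rng(seed)
    dimer_template, _ = apply_p2(monomer_template, axis_direction, axis_point)
    members, rgs = [], []
    w = dimer_template.weights
    wsum = w.sum()
    axis = np.asarray(axis_direction, dtype=float)
    axis /= np.linalg.norm(axis)
    point = np.asarray(axis_point, dtype=float)
    R180 = Rotation.from_rotvec(np.pi * axis).as_matrix()
    budget = n_members * 20
    attempts = 0
    while len(members) < n_members and attempts < budget:
        attempts += 1
        if spec.flexible_segments:
            try:
                mono = _sample_member(monomer_template, spec, rng,
                                      min_separation)
            except SamplingError:
                continue
        else:
            mono = monomer_template.positions.copy()
        mate = (mono - point) @ R180.T + point
        pos = np.vstack([mono, mate])
        members.append(pos.astype(np.float32))
        c = (w @ pos) / wsum
        rgs.append(float(np.sqrt((w * ((pos - c) ** 2).sum(axis=1)).sum() / wsum)))
    if len(members) < n_members:
        raise SamplingError(
            f"P2 pool yield {len(members)}/{n_members} within retry budget")
    return ConformerPool(template_id, dimer_template, members, np.array(rgs),
                         seed, meta={"spec_symmetry": "P2"})


def hinge_subtemplates(
    template: CoordinateModel,
    spec: AssemblySpec,
    k: int = 4,
    n_coarse: int = 200,
    seed: int = 0,
) -> list[CoordinateModel]:
    """Representative hinge-angle conformers from a coarse melted-hinge pool.

    Generates ``n_coarse`` conformers with the hinge flexible, clusters the
    unit vectors from the hinge exit to the swung block's centroid into
    ``k`` groups (k-means) and returns the member closest to each cluster
    centre.  These frozen sub-templates can then be reused with only the
    terminal linker flexible, giving compact well-sampled pools.
    """
    from scipy.cluster.vq import kmeans2

    pool = build_pool(template, spec, n_members=n_coarse, seed=seed,
                      template_id="hinge-coarse")
    hinge_lo = min(lo for lo, hi in spec.flexible_segments)
    anchor_res = max(hi for lo, hi in spec.flexible_segments) + 1
    idx_anchor = int(np.flatnonzero(template.residue_numbers == anchor_res)[0])
    mobile = template.residue_numbers < hinge_lo
    feats = []
    for pos in pool.members:
        pos = np.asarray(pos, dtype=float)
        v = pos[mobile].mean(axis=0) - pos[idx_anchor]
        feats.append(v / np.linalg.norm(v))
    feats = np.array(feats)
    centroids, labels = kmeans2(feats, k, seed=seed, minit="++")
    out = []
    for c in range(k):
        ingrp = np.flatnonzero(labels == c)
        if len(ingrp) == 0:
            continue
        best = ingrp[np.argmin(np.linalg.norm(feats[ingrp] - centroids[c], axis=1))]
        out.append(pool.member_model(int(best)))
    return out


def _count_clashes(pos, bonded_pairs, min_separation):
    tree = cKDTree(pos)
    pairs = tree.query_pairs(min_separation)
    return sum(1 for p in pairs if p not in bonded_pairs)


def rigid_body_fit(
    spec: AssemblySpec,
    template: CoordinateModel,
    experiment: ScatteringCurve,
    n_restarts: int = 10,
    seed: int = 0,
    n_steps: int = 400,
    t_start: float = 2.0,
    t_end: float = 0.02,
    max_rot_deg: float = 15.0,
    max_trans: float = 5.0,
    min_separation: float = MIN_SEPARATION,
    clash_weight: float = 0.5,
    continuity_weight: float = 10.0,
):
    """Simulated-annealing rigid-body refinement against a curve.

    The state is one conformer (all flexible segments realized); moves
    rotate a mobile block (<= ``max_rot_deg``), translate it
    (<= ``max_trans`` A) or re-sample a flexible segment, re-bridging the
    segment so chain continuity is preserved.  The score is the reduced
    chi2 of the Debye curve against ``experiment`` plus clash and
    chain-continuity penalties.  With P2 symmetry the monomer pose relative
    to the z two-fold axis is searched and the generated dimer is scored.

    Returns (best CoordinateModel, FitResult-like score breakdown dict).
    """
    spec.validate_against(template)
    rng = np.random.default_rng(seed)
    q = experiment.q
    resnum = template.residue_numbers
    idx_of = {int(r): i for i, r in enumerate(resnum)}
    p2 = spec.symmetry == "P2"

    # consecutive-residue pairs crossing a body/segment boundary (the
    # continuity penalty only guards the joins; intra-body geometry is
    # whatever the template provides)
    unit_of: dict[int, str] = {}
    for name, spans in spec.rigid_bodies.items():
        for lo, hi in spans:
            for r in range(lo, hi + 1):
                unit_of[r] = name
    for si, (lo, hi) in enumerate(spec.flexible_segments):
        for r in range(lo, hi + 1):
            unit_of[r] = f"seg{si}"
    order = _chain_order(template)
    consec = [(order[i], order[i + 1]) for i in range(len(order) - 1)
              if resnum[order[i + 1]] == resnum[order[i]] + 1
              and unit_of.get(int(resnum[order[i]]))
              != unit_of.get(int(resnum[order[i + 1]]))]
    bonded = set()
    for i in range(len(order) - 1):
        if resnum[order[i + 1]] == resnum[order[i]] + 1:
            a, b = order[i], order[i + 1]
            bonded.add((min(a, b), max(a, b)))

    def score(pos):
        if p2:
            model = CoordinateModel(pos, template.weights.copy(),
                                    template.chain_ids.copy(),
                                    template.residue_numbers.copy())
            dimer, cl = apply_p2(model, clash_distance=min_separation)
            full = dimer.positions
            wts = dimer.weights
            clash_n = cl
        else:
            full = pos
            wts = template.weights
            clash_n = _count_clashes(pos, bonded, min_separation)
        inten = debye_intensity(full, q, wts, method="histogram")
        theory = ScatteringCurve(q, np.maximum(inten, 1e-300),
                                 np.full(len(q), 1e-12))
        fr = fit_scale(theory, experiment)
        gaps = np.array([np.linalg.norm(pos[a] - pos[b]) for a, b in consec])
        cont = float(np.clip(gaps - MAX_GAP, 0, None).sum())
        total = fr.chi2 + clash_weight * clash_n + continuity_weight * cont
        return total, fr, clash_n, cont

    mobile_masks = []
    for lo, hi in _resolve_segments(spec):
        m = resnum < lo
        if m.any():
            mobile_masks.append((m, (lo, hi)))

    best_pos, best_val, best_parts = None, np.inf, None
    for restart in range(n_restarts):
        if spec.flexible_segments and restart > 0:
            try:
                pos = _sample_member(template, spec, rng, min_separation)
            except SamplingError:
                pos = template.positions.copy()
        else:
            pos = template.positions.copy()
        if p2 and restart > 0:
            # random initial monomer pose
            R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
            pos = pos @ R.T + rng.normal(0, 10.0, 3)
        val, fr, cl, cont = score(pos)
        cur_pos, cur_val = pos, val
        if val < best_val:
            best_pos, best_val, best_parts = pos.copy(), val, (fr, cl, cont)
        cool = (t_end / t_start) ** (1.0 / max(n_steps - 1, 1))
        T = t_start
        for _step in range(n_steps):
            move = rng.integers(3)
            new = cur_pos.copy()
            # move amplitudes shrink with temperature for fine convergence
            amp = max((T / t_start) ** 0.5, 0.05)
            if p2:
                # move the whole monomer relative to the fixed two-fold axis
                if move == 0:
                    ang = np.deg2rad(max_rot_deg) * amp * rng.uniform(-1, 1)
                    axis = _random_unit(rng)[0]
                    R = Rotation.from_rotvec(ang * axis).as_matrix()
                    c = new.mean(axis=0)
                    new = (new - c) @ R.T + c
                else:
                    new = new + rng.uniform(-1, 1, 3) * max_trans * amp
            elif move in (0, 1) and mobile_masks:
                m, (lo, hi) = mobile_masks[rng.integers(len(mobile_masks))]
                if move == 0:
                    ang = np.deg2rad(max_rot_deg) * amp * rng.uniform(-1, 1)
                    axis = _random_unit(rng)[0]
                    R = Rotation.from_rotvec(ang * axis).as_matrix()
                    c = new[m].mean(axis=0)
                    new[m] = (new[m] - c) @ R.T + c
                else:
                    new[m] = new[m] + rng.uniform(-1, 1, 3) * max_trans * amp
                # re-bridge the segment between block and fixed side
                nseg = hi - lo + 1
                a_idx = idx_of.get(lo - 1)
                e_idx = idx_of.get(hi + 1)
                seg_idx = [idx_of[r] for r in range(lo, hi + 1)]
                if a_idx is not None and e_idx is not None:
                    try:
                        walk = sample_linker(new[a_idx], nseg,
                                             anchor_end=new[e_idx], rng=rng,
                                             min_separation=min_separation,
                                             max_retries=20)
                    except (GeometryError, SamplingError):
                        continue
                    for j, i in enumerate(seg_idx):
                        new[i] = walk[j]
            elif spec.flexible_segments:
                try:
                    new = _sample_member(template, spec, rng, min_separation)
                except SamplingError:
                    continue
            else:
                continue
            nval, nfr, ncl, ncont = score(new)
            if nval < cur_val or rng.random() < np.exp((cur_val - nval) / T):
                cur_pos, cur_val = new, nval
                if nval < best_val:
                    best_pos, best_val = new.copy(), nval
                    best_parts = (nfr, ncl, ncont)
            T *= cool
    if best_pos is None:
        raise RuntimeError("no clash-free configuration found")
    fr, cl, cont = best_parts
    out = template.copy()
    out.positions = best_pos
    breakdown = {"chi2": fr.chi2, "scale": fr.scale, "constant": fr.constant,
                 "clashes": int(cl), "continuity_penalty": cont,
                 "total_score": best_val}
    return out, fr, breakdown
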