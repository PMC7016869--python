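"""Coarse-grained coordinate models and geometric operations.

Models are residue-level bead representations (one bead per C-alpha, unit
scattering weight) — adequate for solution scattering, which cannot resolve
the internal structure of domains.  Provides PDB I/O, domain bookkeeping,
radius of gyration, two-fold (P2) symmetry generation, and superposition by
normalized spatial discrepancy (NSD) with optional inversion correction,
mirroring how bead/rigid-body models are compared in the SAXS literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "CoordinateModel",
    "DomainMap",
    "SuperpositionResult",
    "read_model",
    "write_model",
    "radius_of_gyration",
    "apply_p2",
    "superpose_nsd",
    "nsd",
]


@dataclass
class CoordinateModel:
    """A point model: N bead positions with scattering weights and labels."""

    positions: np.ndarray                       # (N, 3) angstrom
    weights: np.ndarray | None = None           # per-bead scattering weight
    chain_ids: np.ndarray | None = None
    residue_numbers: np.ndarray | None = None   # 1-based
    domain_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if n < 1:
            raise ValueError("model must contain at least one bead")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.chain_ids is None:
            self.chain_ids = np.array(["A"] * n)
        else:
            self.chain_ids = np.asarray(self.chain_ids)
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(1, n + 1)
        else:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        for arr in (self.weights, self.chain_ids, self.residue_numbers):
            if len(arr) != n:
                raise ValueError("per-bead arrays must match positions length")
        for ch in np.unique(self.chain_ids):
            resn = self.residue_numbers[self.chain_ids == ch]
            if len(np.unique(resn)) != len(resn):
                raise ValueError(f"duplicate residue numbers in chain {ch}")
        if self.domain_labels is not None:
            self.domain_labels = np.asarray(self.domain_labels)
            if len(self.domain_labels) != n:
                raise ValueError("domain_labels length mismatch")

    def __len__(self) -> int:
        return len(self.positions)

    def copy(self) -> "CoordinateModel":
        return CoordinateModel(
            self.positions.copy(), self.weights.copy(), self.chain_ids.copy(),
            self.residue_numbers.copy(),
            None if self.domain_labels is None else self.domain_labels.copy())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CoordinateModel":
        """Return a copy with positions -> positions @ R.T + t."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation).T
        if translation is not None:
            pos = pos + np.asarray(translation)
        out = self.copy()
        out.positions = pos
        return out

    def centroid(self) -> np.ndarray:
        w = self.weights / self.weights.sum()
        return w @ self.positions

    def select(self, mask: np.ndarray) -> "CoordinateModel":
        return CoordinateModel(
            self.positions[mask], self.weights[mask], self.chain_ids[mask],
            self.residue_numbers[mask],
            None if self.domain_labels is None else self.domain_labels[mask])


@dataclass
class DomainMap:
    """Named residue spans plus flexible segments (inclusive, 1-based).

    ``domains`` maps a name (NTD, DEP, CNBD, REM, RA, GEF, ...) to a
    (start, end) span; ``flexible`` lists spans free to be re-sampled
    (inter-domain linkers, melted hinge).
    """

    domains: dict = field(default_factory=dict)
    flexible: list = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = sorted(self.domains.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 >= b0:
                raise ValueError("domain spans overlap")
        for lo, hi in list(self.domains.values()) + list(self.flexible):
            if lo > hi:
                raise ValueError("span start exceeds span end")

    def residues_in(self, name: str) -> np.ndarray:
        lo, hi = self.domains[name]
        return np.arange(lo, hi + 1)


@dataclass
class SuperpositionResult:
    nsd: float
    rotation: np.ndarray
    translation: np.ndarray
    inverted: bool


def read_model(path, coarse_grain: str = "CA") -> CoordinateModel:
    """Read a PDB file as a bead model (C-alpha only by default).

    Alternate locations are resolved to the highest-occupancy conformer;
    weights are 1 per bead.
    """
    from Bio.PDB import PDBParser

    if coarse_grain not in ("CA", "all"):
        raise ValueError("coarse_grain must be 'CA' or 'all'")
    parser = PDBParser(QUIET=True)
    struct = parser.get_structure("m", path)
    pos, chains, resnums = [], [], []
    model = next(struct.get_models())
    for chain in model:
        for residue in chain:
            atoms = [a for a in residue.get_unpacked_list()
                     if coarse_grain == "all" or a.get_name() == "CA"]
            if not atoms:
                continue
            # highest occupancy among altlocs of the same atom name
            byname: dict[str, object] = {}
            for a in atoms:
                prev = byname.get(a.get_name())
                if prev is None or (a.get_occupancy() or 1.0) > (prev.get_occupancy() or 1.0):
                    byname[a.get_name()] = a
            for a in byname.values():
                pos.append(a.get_coord())
                chains.append(chain.id if chain.id.strip() else "A")
                resnums.append(residue.id[1])
    if not pos:
        raise ValueError(f"{path}: no C-alpha atoms found")
    if coarse_grain == "all":
        # residue numbers repeat across atoms; renumber beads serially per chain
        resnums = list(range(1, len(pos) + 1))
    return CoordinateModel(np.array(pos, dtype=float),
                           chain_ids=np.array(chains),
                           residue_numbers=np.array(resnums))


def write_model(model: CoordinateModel, path) -> None:
    """Write a bead model as C-alpha ATOM records (one residue per bead)."""
    with open(path, "w") as fh:
        serial = 1
        for i in range(len(model)):
            x, y, z = model.positions[i]
            ch = str(model.chain_ids[i])[:1]
            resi = int(model.residue_numbers[i])
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA {ch}{resi:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
            serial += 1
        fh.write("END\n")


def radius_of_gyration(model: CoordinateModel) -> float:
    """Weight-weighted RMS distance of beads from the weighted centroid, in A."""
    if len(model) < 2:
        raise ValueError("need at least 2 beads")
    wsum = model.weights.sum()
    if wsum <= 0:
        raise ValueError("zero total weight")
    c = model.centroid()
    d2 = ((model.positions - c) ** 2).sum(axis=1)
    return float(np.sqrt((model.weights * d2).sum() / wsum))


def apply_p2(
    monomer: CoordinateModel,
    axis_direction: np.ndarray = (0.0, 0.0, 1.0),
    axis_point: np.ndarray = (0.0, 0.0, 0.0),
    clash_distance: float = 3.0,
) -> tuple[CoordinateModel, int]:
    """Generate a homodimer by a 180-degree rotation about a two-fold axis.

    The mate's chain ids get a prime suffix mapped into new letters.  Returns
    (dimer, clash count) where clashes are mate-bead pairs closer than
    ``clash_distance`` — reported, never fatal.
    """
    axis = np.asarray(axis_direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    point = np.asarray(axis_point, dtype=float)
    rot = Rotation.from_rotvec(np.pi * axis).as_matrix()
    mate_pos = (monomer.positions - point) @ rot.T + point

    used = set(np.unique(monomer.chain_ids).tolist())
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    mapping = {}
    for ch in np.unique(monomer.chain_ids):
        new = next(c for c in alphabet if c not in used and c not in mapping.values())
        mapping[str(ch)] = new
    mate_chains = np.array([mapping[str(c)] for c in monomer.chain_ids])

    dimer = CoordinateModel(
        np.vstack([monomer.positions, mate_pos]),
        np.concatenate([monomer.weights, monomer.weights]),
        np.concatenate([monomer.chain_ids, mate_chains]),
        np.concatenate([monomer.residue_numbers, monomer.residue_numbers]),
    )
    tree = cKDTree(monomer.positions)
    clashes = sum(len(hits) for hits in
                  tree.query_ball_point(mate_pos, clash_distance))
    return dimer, int(clashes)


def _mean_nn_spacing(pos: np.ndarray) -> float:
    tree = cKDTree(pos)
    d, _ = tree.query(pos, k=2)
    return float(d[:, 1].mean())


def nsd(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized spatial discrepancy between two point sets (no superposition).

    NSD^2 = 1/2 [ (1/(Na*db^2)) sum_i min_j |a_i-b_j|^2
                + (1/(Nb*da^2)) sum_j min_i |b_j-a_i|^2 ],
    where da, db are each set's mean nearest-neighbour spacing.  0 means the
    sets coincide; values around 1 indicate similar shapes.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    da = _mean_nn_spacing(a) if len(a) > 1 else 1.0
    db = _mean_nn_spacing(b) if len(b) > 1 else 1.0
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, _ = tb.query(a)
    d_ba, _ = ta.query(b)
    val = 0.5 * ((d_ab ** 2).mean() / db ** 2 + (d_ba ** 2).mean() / da ** 2)
    return float(np.sqrt(val))


def _principal_frame(pos: np.ndarray) -> np.ndarray:
    c = pos.mean(axis=0)
    cov = np.cov((pos - c).T)
    if np.linalg.matrix_rank(cov, tol=1e-10) < 3:
        warnings.warn("degenerate (near-collinear) point set; PCA fallback "
                      "may give a poor starting alignment")
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]          # descending variance
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1
    return vecs


def superpose_nsd(
    model: CoordinateModel,
    reference: CoordinateModel,
    try_inversion: bool = True,
    refine: bool = True,
) -> SuperpositionResult:
    """Superpose ``model`` onto ``reference`` minimizing NSD.

    Candidate alignments come from matching principal axes (all four proper
    sign combinations), optionally also for the mirror image of the model
    (scattering cannot distinguish a structure from its inversion); the best
    candidate is polished by a local Nelder-Mead search over the six rigid
    degrees of freedom.
    """
    ref_pos = reference.positions
    ref_frame = _principal_frame(ref_pos)
    ref_c = ref_pos.mean(axis=0)

    best = None
    for inverted in ([False, True] if try_inversion else [False]):
        pos0 = -model.positions if inverted else model.positions
        c0 = pos0.mean(axis=0)
        frame = _principal_frame(pos0)
        for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            signs = np.diag([sx, sy, sx * sy])   # proper rotation
            R = ref_frame @ signs @ frame.T
            t = ref_c - R @ c0
            val = nsd(pos0 @ R.T + t, ref_pos)
            if best is None or val < best[0]:
                best = (val, R, t, inverted)

    val, R, t, inverted = best
    if refine:
        pos0 = -model.positions if inverted else model.positions
        rv0 = Rotation.from_matrix(R).as_rotvec()

        def objective(p):
            Rm = Rotation.from_rotvec(p[:3]).as_matrix()
            return nsd(pos0 @ Rm.T + p[3:], ref_pos)

        res = minimize(objective, np.concatenate([rv0, t]),
                       method="Nelder-Mead",
                       options={"maxiter": 300, "xatol": 1e-3, "fatol": 1e-5})
        if res.fun < val:
            val = float(res.fun)
            R = Rotation.from_rotvec(res.x[:3]).as_matrix()
            t = res.x[3:]
    return SuperpositionResult(float(val), R, np.asarray(t), inverted)
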