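"""Coordinate-level utilities.

* a polyproline-II backbone builder giving the nominal C-alpha-C-alpha
  lengths of Cys-(Pro)n-Trp length-standard peptides;
* exact three-sphere trilateration (two mirror-image solutions) used to map
  DEPET distance changes onto a static structure, with a bootstrap variant;
* Kabsch rigid superposition and per-residue C-alpha displacement maps for
  comparing two conformational states of the same protein.

Coordinates are in Angstrom; dihedrals in degrees at the public surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StructureCoords",
    "TrilaterationResult",
    "build_ppii",
    "trilaterate_displaced",
    "trilaterate_bootstrap",
    "kabsch_superpose",
    "residue_displacement_map",
    "read_structure",
]

log = logging.getLogger(__name__)

# Engh-Huber-style standard backbone geometry
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5


@dataclass
class StructureCoords:
    """Ordered residues, each a dict of atom name -> coordinate array."""

    residues: list[dict]  # {"residue_id": int, "residue_name": str, "atoms": {name: xyz}}
    chain_tag: str = "A"

    def __post_init__(self) -> None:
        ids = [r["residue_id"] for r in self.residues]
        if len(ids) != len(set(ids)):
            raise ValueError("residue ids must be unique")
        self._by_id = {r["residue_id"]: r for r in self.residues}

    def residue_ids(self) -> list[int]:
        return [r["residue_id"] for r in self.residues]

    def atom(self, residue_id: int, atom_name: str) -> np.ndarray:
        try:
            res = self._by_id[residue_id]
        except KeyError as exc:
            raise KeyError(f"no residue {residue_id}") from exc
        try:
            return res["atoms"][atom_name]
        except KeyError as exc:
            raise KeyError(f"residue {residue_id} has no atom {atom_name!r}") from exc

    def ca(self, residue_id: int) -> np.ndarray:
        return self.atom(residue_id, "CA")


@dataclass
class TrilaterationResult:
    """The two mirror solutions of a three-sphere trilateration."""

    branch_upper: np.ndarray
    branch_lower: np.ndarray
    anchor_ids: tuple = ()
    cloud_upper: np.ndarray | None = None  # (n_draws, 3) bootstrap cloud
    cloud_lower: np.ndarray | None = None
    n_infeasible: int = 0

    def displacement_summary(self, base_point, axis=None, ci_level: float = 0.95) -> dict:
        """Signed displacement of each branch cloud from ``base_point`` along ``axis``.

        ``axis`` defaults to the upper-branch direction (the anchor-plane
        normal); pass e.g. (0, 0, 1) to report along the structure's z-axis.
        """
        base = np.asarray(base_point, dtype=float)
        if axis is None:
            axis = self.branch_upper - self.branch_lower
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        out = {}
        alpha = 100.0 * (1.0 - ci_level) / 2.0
        for name, point, cloud in (
            ("upper", self.branch_upper, self.cloud_upper),
            ("lower", self.branch_lower, self.cloud_lower),
        ):
            entry = {"point": point, "displacement": float(np.dot(point - base, axis))}
            if cloud is not None and len(cloud):
                disp = (cloud - base) @ axis
                entry["mean_displacement"] = float(disp.mean())
                entry["ci"] = tuple(np.percentile(disp, [alpha, 100.0 - alpha]))
            out[name] = entry
        return out


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D from internal coordinates relative to A-B-C."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + m @ d_local


def build_ppii(
    n_pro: int,
    phi: float = -75.0,
    psi: float = 150.0,
    omega: float = 180.0,
) -> StructureCoords:
    """Backbone of a Cys-(Pro)n-Trp peptide in the polyproline-II conformation.

    All residues get the same (phi, psi, omega); the peptide's nominal length
    is the distance from the first (Cys) to the last (Trp) C-alpha, roughly
    3.1 Angstrom of rise per residue for the canonical PPII dihedrals.
    """
    if n_pro < 0:
        raise ValueError("n_pro must be non-negative")
    n_res = n_pro + 2
    names = ["CYS"] + ["PRO"] * n_pro + ["TRP"]

    residues: list[dict] = []
    # first residue laid out in the xy-plane
    n_at = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    theta = math.radians(ANGLE_N_CA_C)
    c_at = ca + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    atoms = {"N": n_at, "CA": ca, "C": c_at}
    residues.append({"residue_id": 1, "residue_name": names[0], "atoms": atoms})

    for i in range(1, n_res):
        prev = residues[-1]["atoms"]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_next = _place_atom(prev["C"], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
        # carbonyl oxygen of the previous residue, anti to the next N
        prev["O"] = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        residues.append(
            {
                "residue_id": i + 1,
                "residue_name": names[i],
                "atoms": {"N": n_next, "CA": ca_next, "C": c_next},
            }
        )
    last = residues[-1]["atoms"]
    last["O"] = _place_atom(last["N"], last["CA"], last["C"], BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
    return StructureCoords(residues=residues, chain_tag="ppii")


def ppii_nominal_length(n_pro: int) -> float:
    """First-to-last C-alpha distance of the Cys-(Pro)n-Trp PPII backbone."""
    s = build_ppii(n_pro)
    ids = s.residue_ids()
    return float(np.linalg.norm(s.ca(ids[-1]) - s.ca(ids[0])))


def trilaterate_displaced(anchors, base_point, deltas) -> TrilaterationResult:
    """Exact three-sphere trilateration of a displaced point.

    Target radii are r_i = |anchor_i - base_point| + delta_i. Returns both
    solutions; ``branch_upper`` lies on the positive side of the anchor-plane
    normal (cross product of the two in-plane edges in anchor order).
    """
    A = np.asarray(anchors, dtype=float)
    if A.shape != (3, 3):
        raise ValueError("anchors must be three 3D points")
    base = np.asarray(base_point, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    radii = np.linalg.norm(A - base, axis=1) + deltas
    if np.any(radii <= 0):
        raise ValueError("target radii must all be positive")
    return _trilaterate(A, radii)


def _trilaterate(A: np.ndarray, radii: np.ndarray) -> TrilaterationResult:
    p1, p2, p3 = A
    ex = p2 - p1
    d = np.linalg.norm(ex)
    if d < 1e-12:
        raise ValueError("anchors 1 and 2 coincide")
    ex = ex / d
    v3 = p3 - p1
    i = float(np.dot(ex, v3))
    ey = v3 - i * ex
    j = np.linalg.norm(ey)
    if j < 1e-9:
        raise ValueError("anchors are collinear")
    ey = ey / j
    ez = np.cross(ex, ey)

    r1, r2, r3 = radii
    x = (r1**2 - r2**2 + d**2) / (2.0 * d)
    y = (r1**2 - r3**2 + i**2 + j**2 - 2.0 * i * x) / (2.0 * j)
    z_sq = r1**2 - x**2 - y**2
    if z_sq < -1e-9 * max(r1**2, 1.0):
        raise ValueError(
            f"spheres do not intersect (z^2 = {z_sq:.3e}); radii {radii.tolist()}"
        )
    z = math.sqrt(max(z_sq, 0.0))
    upper = p1 + x * ex + y * ey + z * ez
    lower = p1 + x * ex + y * ey - z * ez
    return TrilaterationResult(branch_upper=upper, branch_lower=lower)


def trilaterate_bootstrap(
    anchors,
    base_point,
    delta_distributions,
    n_draws: int = 10_000,
    seed: int = 0,
) -> TrilaterationResult:
    """Trilateration with bootstrap clouds from sampled distance changes.

    ``delta_distributions`` is a (3, n_samples) array (or list of three 1-D
    arrays): for each draw one delta per anchor is sampled with replacement.
    Infeasible draws (non-intersecting spheres) are excluded and counted;
    more than 50% infeasible raises.
    """
    A = np.asarray(anchors, dtype=float)
    base = np.asarray(base_point, dtype=float)
    dists = [np.atleast_1d(np.asarray(d, dtype=float)) for d in delta_distributions]
    if len(dists) != 3:
        raise ValueError("need one delta distribution per anchor")
    rng = np.random.default_rng(seed)

    central = trilaterate_displaced(A, base, [float(np.mean(d)) for d in dists])
    uppers, lowers = [], []
    n_infeasible = 0
    for _ in range(n_draws):
        deltas = [d[rng.integers(0, len(d))] for d in dists]
        try:
            res = trilaterate_displaced(A, base, deltas)
        except ValueError:
            n_infeasible += 1
            continue
        uppers.append(res.branch_upper)
        lowers.append(res.branch_lower)
    if n_infeasible > 0.5 * n_draws:
        raise RuntimeError(
            f"{n_infeasible}/{n_draws} bootstrap draws were geometrically infeasible"
        )
    return TrilaterationResult(
        branch_upper=central.branch_upper,
        branch_lower=central.branch_lower,
        cloud_upper=np.array(uppers),
        cloud_lower=np.array(lowers),
        n_infeasible=n_infeasible,
    )


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition (Kabsch, proper rotation).

    Returns (rotation, translation, rmsd) with ``moving @ rotation.T +
    translation`` best superposed on ``fixed``.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need >= 3 paired 3D points of equal shape")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def residue_displacement_map(
    struct_a: StructureCoords,
    struct_b: StructureCoords,
    residue_range=None,
) -> pd.DataFrame:
    """Per-residue C-alpha displacement between two states, after superposition.

    Residues absent from either structure (or missing a C-alpha) are dropped
    and logged. ``residue_range`` is an optional (first, last) inclusive pair.
    """
    ids_a = set(struct_a.residue_ids())
    ids_b = set(struct_b.residue_ids())
    shared = sorted(ids_a & ids_b)
    if residue_range is not None:
        lo, hi = residue_range
        shared = [r for r in shared if lo <= r <= hi]
    usable = []
    for rid in shared:
        try:
            struct_a.ca(rid)
            struct_b.ca(rid)
        except KeyError:
            log.info("residue %d missing a C-alpha in one structure; dropped", rid)
            continue
        usable.append(rid)
    dropped = (ids_a | ids_b) - set(usable)
    if dropped:
        log.info("displacement map: %d residue(s) not shared/usable", len(dropped))
    if not usable:
        raise ValueError("no shared residues with C-alpha atoms in range")

    P = np.array([struct_a.ca(r) for r in usable])
    Q = np.array([struct_b.ca(r) for r in usable])
    R, t, rmsd = kabsch_superpose(P, Q)
    moved = P @ R.T + t
    dist = np.linalg.norm(moved - Q, axis=1)
    return pd.DataFrame({"residue_id": usable, "ca_displacement": dist}).assign(rmsd=rmsd)


def read_structure(path, chain: str | None = None) -> StructureCoords:
    """Read ATOM records from a PDB file (first model) into StructureCoords.

    Altloc 'A' or blank preferred; residues keep their PDB numbering.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(iter(structure))
    residues = []
    chain_tag = chain or ""
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        chain_tag = chain_tag or ch.id
        for res in ch:
            hetflag, resseq, _ = res.get_id()
            if hetflag.strip():
                continue
            atoms = {}
            for atom in res:
                if atom.get_altloc() not in (" ", "A"):
                    continue
                atoms[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
            residues.append(
                {"residue_id": int(resseq), "residue_name": res.get_resname(), "atoms": atoms}
            )
        if chain is None:
            break  # first chain only unless told otherwise
    if not residues:
        raise ValueError(f"no ATOM records read from {path}")
    return StructureCoords(residues=residues, chain_tag=chain_tag)
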