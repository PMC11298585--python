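"""Coordinate-level geometry: superposition, SASA, interfaces, helix angles.

Implements the structural measurements used to characterize a carrier
protein-thioesterase (PCP-TE) complex: Kabsch least-squares superposition
with optional outlier-rejecting refinement, Calpha RMSD between structures
(alignment-mediated for non-identical proteins), Shrake-Rupley solvent
accessible surface area and buried interface area, principal-axis helix
angles, catalytic-triad hydrogen-bond distances and radius of gyration.

Author residue numbering (with insertion codes) is used throughout.
"""

from __future__ import annotations

import re
import urllib.request
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

# Bondi-style van der Waals radii (Angstrom); hydrogens are ignored in SASA
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "FE": 55.845,
    "ZN": 65.38, "MG": 24.305, "NA": 22.990, "BR": 79.904, "I": 126.904,
}

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


@dataclass(frozen=True)
class Structure:
    """Atom table: parallel arrays over atoms, author numbering."""

    chain: np.ndarray
    resseq: np.ndarray
    icode: np.ndarray
    resname: np.ndarray
    atname: np.ndarray
    element: np.ndarray
    xyz: np.ndarray
    occupancy: np.ndarray
    altloc: np.ndarray
    het: np.ndarray          # True for non-polymer (HETATM) records

    def __post_init__(self):
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.resseq)

    def mask(self, chain: str | None = None,
             res_ranges: list[tuple[int, int]] | None = None,
             atom_names: list[str] | None = None,
             protein_only: bool = False) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if res_ranges:
            sub = np.zeros(len(self), dtype=bool)
            for lo, hi in res_ranges:
                sub |= (self.resseq >= lo) & (self.resseq <= hi)
            m &= sub
        if atom_names is not None:
            m &= np.isin(self.atname, atom_names)
        if protein_only:
            m &= ~self.het
        return m

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(*(getattr(self, f)[mask] for f in
                           ("chain", "resseq", "icode", "resname", "atname",
                            "element", "xyz", "occupancy", "altloc", "het")))

    def select(self, **kwargs) -> "Structure":
        return self.subset(self.mask(**kwargs))

    def ca_by_residue(self, chain: str | None = None) -> dict[int, np.ndarray]:
        m = self.mask(chain=chain, atom_names=["CA"], protein_only=True)
        return {int(r): x for r, x in zip(self.resseq[m], self.xyz[m])}

    def chains(self) -> list[str]:
        seen = []
        for c in self.chain:
            if c not in seen:
                seen.append(c)
        return seen


def read_structure(path: str | Path, model: int = 0,
                   altloc_policy: str = "occupancy",
                   drop_waters: bool = True) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Keeps one model and one altloc per atom ("occupancy": highest occupancy,
    "first": first encountered / altloc A).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if model >= len(st):
        raise ValueError(f"{path}: model index {model} out of range")
    st.setup_entities()
    mdl = st[model]

    rows = {k: [] for k in ("chain", "resseq", "icode", "resname", "atname",
                            "element", "xyz", "occupancy", "altloc", "het")}
    for chain in mdl:
        for residue in chain:
            if drop_waters and residue.is_water():
                continue
            het = residue.het_flag == "H"
            chosen: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = chosen.get(atom.name)
                if prev is None:
                    chosen[atom.name] = atom
                elif altloc_policy == "occupancy" and atom.occ > prev.occ:
                    chosen[atom.name] = atom
            for atom in chosen.values():
                rows["chain"].append(chain.name)
                rows["resseq"].append(residue.seqid.num)
                rows["icode"].append(residue.seqid.icode.strip())
                rows["resname"].append(residue.name)
                rows["atname"].append(atom.name)
                rows["element"].append(atom.element.name.upper())
                rows["xyz"].append([atom.pos.x, atom.pos.y, atom.pos.z])
                rows["occupancy"].append(atom.occ)
                rows["altloc"].append(atom.altloc or "")
                rows["het"].append(het)
    if not rows["xyz"]:
        raise ValueError(f"{path}: no atoms parsed")
    return Structure(
        chain=np.array(rows["chain"], dtype=object),
        resseq=np.array(rows["resseq"], dtype=int),
        icode=np.array(rows["icode"], dtype=object),
        resname=np.array(rows["resname"], dtype=object),
        atname=np.array(rows["atname"], dtype=object),
        element=np.array(rows["element"], dtype=object),
        xyz=np.array(rows["xyz"], dtype=float),
        occupancy=np.array(rows["occupancy"], dtype=float),
        altloc=np.array(rows["altloc"], dtype=object),
        het=np.array(rows["het"], dtype=bool),
    )


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write fixed-format PDB (enough for round-tripping toy structures)."""
    with open(path, "w") as fh:
        for i in range(len(s)):
            record = "HETATM" if s.het[i] else "ATOM  "
            name = s.atname[i]
            name_field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = s.xyz[i]
            fh.write(
                f"{record}{(i % 99999) + 1:5d} {name_field}{'':1s}{s.resname[i]:>3s} "
                f"{str(s.chain[i])[:1]:1s}{int(s.resseq[i]):4d}{s.icode[i] or '':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{s.occupancy[i]:6.2f}{0.0:6.2f}"
                f"          {s.element[i]:>2s}\n"
            )
        fh.write("END\n")


def fetch_rcsb(pdb_id: str, dest_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download a deposited entry from the RCSB (requires network access)."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{pdb_id.upper()}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, proper (det +1)
    translation: np.ndarray    # x' = R @ x + t
    n_pairs: int
    rmsd: float
    n_rejected: int = 0

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    p, q = moving - cm, fixed - cf
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cf - rot @ cm
    moved = moving @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return rot, t, rmsd


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray,
                     refine: bool = False, max_cycles: int = 5,
                     reject_factor: float = 2.0) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinate sets.

    With ``refine=True``, up to ``max_cycles`` cycles reject pairs deviating
    by more than ``reject_factor`` times the current RMSD and refit on the
    survivors (a coarse analogue of structure-superposition outlier
    rejection); the reported RMSD covers the final pair set.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    n = len(moving)
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    if np.linalg.matrix_rank(moving - moving.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinate set")

    keep = np.ones(n, dtype=bool)
    rot, t, rmsd = _kabsch(moving, fixed)
    if refine:
        for _ in range(max_cycles):
            moved = moving @ rot.T + t
            dev = np.sqrt(np.sum((moved - fixed) ** 2, axis=1))
            new_keep = keep & (dev <= max(reject_factor * rmsd, 1e-6))
            if new_keep.sum() < 3 or new_keep.sum() == keep.sum():
                break
            keep = new_keep
            rot, t, rmsd = _kabsch(moving[keep], fixed[keep])
    return SuperpositionResult(rotation=rot, translation=t,
                               n_pairs=int(keep.sum()), rmsd=rmsd,
                               n_rejected=int(n - keep.sum()))


def _in_ranges(value: int, ranges: list[tuple[int, int]] | None) -> bool:
    return any(lo <= value <= hi for lo, hi in (ranges or []))


def rmsd_ca(a: Structure, b: Structure,
            chain_a: str | None = None, chain_b: str | None = None,
            pairing=None,
            exclude: list[tuple[int, int]] | None = None,
            refine: bool = False) -> SuperpositionResult:
    """Superpose Calpha atoms of ``a`` onto ``b`` and report the RMSD.

    ``pairing`` maps residue numbers of ``a`` to residue numbers of ``b``:
    ``None`` pairs identical numbers, a dict or
    :class:`~lactamscan.pairwise_align.PositionMap` mediates non-identical
    proteins. ``exclude`` removes residue ranges (``a`` numbering, e.g. a
    flexible lid) before superposition.
    """
    ca_a = a.ca_by_residue(chain_a)
    ca_b = b.ca_by_residue(chain_b)
    if pairing is None:
        pairs = [(r, r) for r in sorted(set(ca_a) & set(ca_b))]
    elif hasattr(pairing, "resolve"):
        pairs = []
        for r in sorted(ca_a):
            q = pairing.resolve(r)
            if isinstance(q, int) and q in ca_b:
                pairs.append((r, q))
    else:
        pairs = [(ra, rb) for ra, rb in pairing if ra in ca_a and rb in ca_b]
    pairs = [(ra, rb) for ra, rb in pairs if not _in_ranges(ra, exclude)]
    if not pairs:
        raise ValueError("empty Calpha pairing")
    moving = np.array([ca_a[ra] for ra, _ in pairs])
    fixed = np.array([ca_b[rb] for _, rb in pairs])
    return kabsch_superpose(moving, fixed, refine=refine)


# ---------------------------------------------------------------------------
# SASA and interfaces
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack((np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)))


def sasa_points(xyz: np.ndarray, radii: np.ndarray,
                probe: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_POINTS) -> np.ndarray:
    """Shrake-Rupley per-atom solvent accessible surface areas."""
    xyz = np.asarray(xyz, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(xyz) != len(radii):
        raise ValueError("one radius per atom required")
    sphere = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(xyz)
    out = np.zeros(len(xyz))
    max_r = expanded.max() if len(expanded) else 0.0
    for i in range(len(xyz)):
        ri = expanded[i]
        pts = xyz[i] + ri * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], ri + max_r)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            rj = expanded[j]
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > rj * rj
            if not exposed.any():
                break
        out[i] = exposed.mean() * 4.0 * np.pi * ri * ri
    return out


def _structure_radii(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(mask of atoms entering SASA, per-atom radii). Hydrogens are skipped."""
    keep = np.array([e != "H" and e != "D" for e in s.element])
    radii = np.zeros(len(s))
    for i in np.flatnonzero(keep):
        e = s.element[i]
        if e not in VDW_RADII:
            raise ValueError(
                f"no vdW radius for element {e!r} "
                f"(atom {s.atname[i]} {s.resname[i]} {s.chain[i]}{s.resseq[i]})"
            )
        radii[i] = VDW_RADII[e]
    return keep, radii


def sasa(s: Structure, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_POINTS) -> np.ndarray:
    """Per-atom SASA of a structure; hydrogens contribute zero."""
    keep, radii = _structure_radii(s)
    out = np.zeros(len(s))
    out[keep] = sasa_points(s.xyz[keep], radii[keep], probe, n_points)
    return out


@dataclass(frozen=True)
class InterfaceReport:
    buried_area: float
    per_residue: dict[tuple[str, int], float]
    contacts: list[tuple[str, int]]
    n_atoms_a: int
    n_atoms_b: int


def interface_area(s: Structure, group_a: np.ndarray, group_b: np.ndarray,
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_POINTS,
                   protein_only: bool = True,
                   contact_cutoff: float = 4.5) -> InterfaceReport:
    """Buried interface area ``(SASA_A + SASA_B - SASA_AB) / 2``.

    ``group_a`` / ``group_b`` are disjoint boolean atom masks over ``s``.
    Heteroatoms (e.g. the pantetheine cofactor) are excluded by default.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if np.any(group_a & group_b):
        raise ValueError("overlapping selections")
    if protein_only:
        group_a = group_a & ~s.het
        group_b = group_b & ~s.het
    if not group_a.any() or not group_b.any():
        raise ValueError("empty selection")

    sa = s.subset(group_a)
    sb = s.subset(group_b)
    both = s.subset(group_a | group_b)
    sasa_a = sasa(sa, probe, n_points)
    sasa_b = sasa(sb, probe, n_points)
    sasa_ab = sasa(both, probe, n_points)
    buried = (sasa_a.sum() + sasa_b.sum() - sasa_ab.sum()) / 2.0
    buried = max(buried, 0.0)

    # per-residue buried contribution = SASA lost by that residue's atoms
    na = len(sa)
    lost = np.concatenate([sasa_a, sasa_b]) - sasa_ab
    per_res: dict[tuple[str, int], float] = {}
    for i in range(len(both)):
        key = (str(both.chain[i]), int(both.resseq[i]))
        per_res[key] = per_res.get(key, 0.0) + float(lost[i])
    per_res = {k: v for k, v in per_res.items() if v > 1e-6}

    tree_b = cKDTree(sb.xyz)
    contacts = set()
    hits = tree_b.query_ball_point(sa.xyz, contact_cutoff)
    for i, js in enumerate(hits):
        if js:
            contacts.add((str(sa.chain[i]), int(sa.resseq[i])))
        for j in js:
            contacts.add((str(sb.chain[j]), int(sb.resseq[j])))
    return InterfaceReport(buried_area=float(buried), per_residue=per_res,
                           contacts=sorted(contacts),
                           n_atoms_a=int(na), n_atoms_b=int(len(sb)))


# ---------------------------------------------------------------------------
# helix geometry, triad distances, radius of gyration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixAxis:
    direction: np.ndarray      # unit vector, N-to-C oriented
    centroid: np.ndarray
    n_residues: int


def helix_axis(ca_xyz: np.ndarray) -> HelixAxis:
    """Principal axis of consecutive Calpha coordinates, N->C oriented.

    The trace is first averaged over a one-turn window (4 residues) to cancel
    the helical wobble, then the axis is taken as the principal eigenvector
    of the centered coordinate covariance.
    """
    ca_xyz = np.asarray(ca_xyz, dtype=float)
    if len(ca_xyz) < 5:
        raise ValueError("need at least 5 Calpha atoms")
    centroid = ca_xyz.mean(axis=0)
    smoothed = ca_xyz
    if len(ca_xyz) >= 8:
        kernel = np.ones(4) / 4.0
        smoothed = np.column_stack([
            np.convolve(ca_xyz[:, k], kernel, mode="valid") for k in range(3)])
    centered = smoothed - smoothed.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca_xyz[-1] - ca_xyz[0]) < 0:
        axis = -axis
    return HelixAxis(direction=axis / np.linalg.norm(axis),
                     centroid=centroid, n_residues=len(ca_xyz))


def interhelix_angle(h1: HelixAxis, h2: HelixAxis) -> float:
    """Angle between two oriented helix axes, degrees in [0, 180]."""
    c = float(np.clip(np.dot(h1.direction, h2.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


_NUC_ATOMS = {"CYS": ["SG"], "SER": ["OG"], "THR": ["OG1"], "ALA": ["CB"]}
_ACID_ATOMS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
_HIS_ATOMS = ["ND1", "NE2"]


def triad_geometry(s: Structure, nucleophile: int, asp: int, his: int,
                   chain: str | None = None) -> dict[str, float]:
    """Catalytic-triad hydrogen-bond distances.

    Reports the minimum distance from the His imidazole nitrogens to the
    nucleophile S/O atom (``his_nucleophile``) and to the Asp/Glu carboxylate
    oxygens (``his_asp``), in Angstrom.
    """

    def atoms(resnum: int, allowed: dict[str, list[str]] | None,
              names: list[str] | None = None) -> np.ndarray:
        m = s.mask(chain=chain, res_ranges=[(resnum, resnum)])
        sub = s.subset(m)
        if len(sub) == 0:
            raise ValueError(f"residue {resnum} not found")
        resname = sub.resname[0]
        wanted = names if names is not None else (allowed or {}).get(resname)
        if not wanted:
            raise ValueError(f"residue {resnum} ({resname}): no atom rule")
        sel = sub.subset(np.isin(sub.atname, wanted))
        if len(sel) == 0:
            raise ValueError(
                f"residue {resnum} ({resname}): missing side-chain atoms {wanted}")
        return sel.xyz

    his_xyz = atoms(his, None, _HIS_ATOMS)
    nuc_xyz = atoms(nucleophile, _NUC_ATOMS)
    asp_xyz = atoms(asp, _ACID_ATOMS)

    def min_dist(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)))

    return {
        "his_nucleophile": min_dist(his_xyz, nuc_xyz),
        "his_asp": min_dist(his_xyz, asp_xyz),
    }


def radius_of_gyration(s: Structure | np.ndarray,
                       mass_weighted: bool = True) -> float:
    """Rg = sqrt(sum m_i |x_i - xbar|^2 / sum m_i)."""
    if isinstance(s, Structure):
        xyz = s.xyz
        if mass_weighted:
            masses = np.array([ATOMIC_MASS.get(e, 0.0) for e in s.element])
            if np.any(masses <= 0):
                bad = sorted({e for e, m_ in zip(s.element, masses) if m_ <= 0})
                raise ValueError(f"no atomic mass for elements {bad}")
        else:
            masses = np.ones(len(xyz))
    else:
        xyz = np.asarray(s, dtype=float)
        masses = np.ones(len(xyz))
    center = np.average(xyz, axis=0, weights=masses)
    sq = np.sum((xyz - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


# ---------------------------------------------------------------------------
# selection strings (CLI): "A:2660-2722,2730-2740" or "A" (whole chain)
# ---------------------------------------------------------------------------

_RANGE = re.compile(r"^(-?\d+)-(-?\d+)$")


def selection_mask(s: Structure, spec: str) -> np.ndarray:
    """Parse a "chain:start-end[,start-end...]" selection into an atom mask."""
    spec = spec.strip()
    if ":" in spec:
        chain, _, rest = spec.partition(":")
    else:
        chain, rest = spec, ""
    chain = chain.strip()
    if not chain:
        raise ValueError(f"bad selection {spec!r}: empty chain")
    ranges = []
    if rest.strip():
        for token in rest.split(","):
            m = _RANGE.match(token.strip())
            if not m:
                raise ValueError(f"bad selection token {token.strip()!r}")
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise ValueError(f"bad selection token {token.strip()!r}: start > end")
            ranges.append((lo, hi))
    return s.mask(chain=chain, res_ranges=ranges or None)
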