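"""Structural primitives shared by all pipeline stages.

PDB reading/writing, Kabsch superposition, Shrake-Rupley accessible
surface area and per-residue RMSD over structural ensembles.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "RigidTransform",
    "SASAProfile",
    "EnsembleRMSDProfile",
    "read_pdb",
    "write_pdb",
    "kabsch",
    "sasa",
    "ensemble_per_residue_rmsd",
    "parse_selection",
    "VDW_RADII",
    "MAX_RESIDUE_SASA",
]

# Van der Waals radii (Angstrom), by element.  Fixed bundled table so SASA
# values are reproducible across machines.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

# Theoretical maximum per-residue SASA (Gly-X-Gly, Angstrom^2), used to
# normalise absolute residue SASA into relative exposure.  Values from the
# commonly used theoretical Gly-X-Gly table (Tien et al. 2013).
MAX_RESIDUE_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class StructureModel:
    """Atom-level structure: parallel arrays plus an (n, 3) coordinate block.

    Atom identity is (chain, resnum, icode, atom name), unique per model.
    """

    chains: np.ndarray
    resnums: np.ndarray
    icodes: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    xyz: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.chains)
        for name in ("resnums", "icodes", "resnames", "atom_names", "elements"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[tuple], model_id: int = 1) -> "StructureModel":
        """Build from (chain, resnum, icode, resname, atom_name, element, (x,y,z))."""
        rows = list(atoms)
        if not rows:
            raise ValueError("no atoms")
        return cls(
            chains=np.array([a[0] for a in rows], dtype="U4"),
            resnums=np.array([a[1] for a in rows], dtype=int),
            icodes=np.array([a[2] for a in rows], dtype="U1"),
            resnames=np.array([a[3] for a in rows], dtype="U3"),
            atom_names=np.array([a[4] for a in rows], dtype="U4"),
            elements=np.array([a[5] for a in rows], dtype="U2"),
            xyz=np.array([a[6] for a in rows], dtype=float),
            model_id=model_id,
        )

    # -- basic accessors --------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.chains)

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chains == chain

    def select(self, chain: str | None = None, atom_names: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chains == chain
        if atom_names is not None:
            mask &= np.isin(self.atom_names, list(atom_names))
        return mask

    def residues(self, chain: str | None = None) -> Iterator[tuple]:
        """Yield (chain, resnum, icode, resname, atom_index_array) in file order."""
        order: list[tuple] = []
        seen: dict[tuple, list[int]] = {}
        for i in range(self.n_atoms):
            if chain is not None and self.chains[i] != chain:
                continue
            key = (str(self.chains[i]), int(self.resnums[i]), str(self.icodes[i]))
            if key not in seen:
                seen[key] = []
                order.append((key, str(self.resnames[i])))
            seen[key].append(i)
        for key, resname in order:
            yield key[0], key[1], key[2], resname, np.array(seen[key], dtype=int)

    def residue_keys(self, chain: str | None = None) -> list[tuple]:
        return [(c, rn, ic) for c, rn, ic, _, _ in self.residues(chain)]

    def atom_coords(self, chain: str, atom_name: str) -> np.ndarray:
        """Coordinates of one named atom per residue of the chain, residue order."""
        out = []
        for _, resnum, _, _, idx in self.residues(chain):
            hit = [i for i in idx if self.atom_names[i] == atom_name]
            if not hit:
                raise ValueError(f"residue {chain}:{resnum} missing atom {atom_name}")
            out.append(self.xyz[hit[0]])
        return np.array(out)

    # -- geometry ---------------------------------------------------------

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.chains.copy(), self.resnums.copy(), self.icodes.copy(),
            self.resnames.copy(), self.atom_names.copy(), self.elements.copy(),
            self.xyz.copy(), self.model_id,
        )

    def transformed(self, transform: "RigidTransform", mask: np.ndarray | None = None) -> "StructureModel":
        out = self.copy()
        if mask is None:
            out.xyz = transform.apply(out.xyz)
        else:
            out.xyz[mask] = transform.apply(out.xyz[mask])
        return out


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be orthonormal with det +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class SASAProfile:
    """Per-residue absolute and relative solvent accessible surface area."""

    residue_keys: list  # (chain, resnum, icode)
    resnames: list
    abs_sasa: np.ndarray
    rel_sasa: np.ndarray
    atom_sasa: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.abs_sasa.sum())

    def residue_rel(self, chain: str, resnum: int, icode: str = "") -> float:
        key = (chain, resnum, icode)
        return float(self.rel_sasa[self.residue_keys.index(key)])

    def residue_abs(self, chain: str, resnum: int, icode: str = "") -> float:
        key = (chain, resnum, icode)
        return float(self.abs_sasa[self.residue_keys.index(key)])


@dataclass
class EnsembleRMSDProfile:
    """Per-residue RMSD about the ensemble mean over named backbone atoms."""

    residue_keys: list
    resnames: list
    rmsd: np.ndarray
    align_on: str
    atoms: tuple
    n_frames: int


# ---------------------------------------------------------------------------
# PDB I/O

_PDB_ATOM = re.compile(r"^(ATOM|HETATM)")


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    name = name.lstrip("0123456789")
    if not name:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return name[:2].capitalize()
    return name[0].upper()


def read_pdb(path: str) -> list[StructureModel]:
    """Parse a PDB file into one StructureModel per MODEL block.

    Highest-occupancy altloc is kept; element is inferred from the atom name
    when columns 77-78 are blank.  Duplicate atom keys within a model raise.
    """
    models: list[StructureModel] = []
    # per running model: key -> (occupancy, atom tuple)
    current: dict[tuple, tuple] = {}
    model_id = 1
    saw_model_record = False

    def flush() -> None:
        nonlocal current
        if current:
            atoms = [v[1] for v in current.values()]
            models.append(StructureModel.from_atoms(atoms, model_id=model_id))
        current = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "MODEL":
                flush()
                saw_model_record = True
                try:
                    model_id = int(raw[6:].split()[0])
                except (IndexError, ValueError):
                    model_id = len(models) + 1
            elif rec == "ENDMDL":
                flush()
            elif rec in ("ATOM", "HETATM"):
                try:
                    atom_name = raw[12:16].strip()
                    altloc = raw[16].strip()
                    resname = raw[17:20].strip()
                    chain = raw[21].strip() or " "
                    resnum = int(raw[22:26])
                    icode = raw[26].strip()
                    x = float(raw[30:38])
                    y = float(raw[38:46])
                    z = float(raw[46:54])
                    occ_field = raw[54:60].strip()
                    occupancy = float(occ_field) if occ_field else 1.0
                    element = raw[76:78].strip() if len(raw) >= 78 else ""
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}: unparseable ATOM record at line {lineno}: {exc}") from exc
                if not element:
                    element = _infer_element(atom_name)
                key = (chain, resnum, icode, atom_name)
                atom = (chain, resnum, icode, resname, atom_name, element, (x, y, z))
                if key in current:
                    prev_occ, _, prev_altloc = current[key]
                    if not altloc and not prev_altloc:
                        raise ValueError(
                            f"{path}: duplicate atom {key} at line {lineno}")
                    if occupancy > prev_occ:
                        current[key] = (occupancy, atom, bool(altloc))
                else:
                    current[key] = (occupancy, atom, bool(altloc))
    flush()
    return models


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str) -> None:
    """Write one or more models as standard ATOM records (3-decimal coords)."""
    if isinstance(models, StructureModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for m in models:
            if multi:
                fh.write(f"MODEL     {m.model_id:4d}\n")
            serial = 1
            prev_chain = None
            for i in range(m.n_atoms):
                chain = str(m.chains[i])
                if prev_chain is not None and chain != prev_chain:
                    fh.write("TER\n")
                prev_chain = chain
                name = str(m.atom_names[i])
                # standard alignment: 1-3 char names start in column 14
                field_name = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = m.xyz[i]
                fh.write(
                    f"ATOM  {serial:5d} {field_name:<4s}{'':1s}{str(m.resnames[i]):>3s} "
                    f"{chain:1s}{int(m.resnums[i]):4d}{str(m.icodes[i]) or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                    f"{str(m.elements[i]):>2s}\n"
                )
                serial += 1
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rigid superposition of moving onto fixed.

    Returns the transform (reflection-corrected, det +1) and the minimised
    RMSD.  Requires n >= 3 matched, non-collinear points.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    for pts, label in ((mc, "moving"), (fc, "fixed")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-9 * max(1.0, s[0]):
            raise ValueError(f"degenerate (collinear) {label} point set")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = fixed.mean(axis=0) - rot @ moving.mean(axis=0)
    diff = mc @ rot.T - fc
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return RigidTransform(rot, trans), rmsd


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (no RNG)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(model: StructureModel, probe: float = 1.4, n_points: int = 960) -> SASAProfile:
    """Shrake-Rupley accessible surface area per atom and per residue.

    A lattice point on atom i's inflated sphere is exposed iff it lies
    outside every other atom's inflated sphere.
    """
    unknown = sorted({str(e) for e in model.elements if str(e).capitalize() not in
                      {k.capitalize() for k in VDW_RADII}})
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {', '.join(unknown)}")
    radii = np.array([VDW_RADII[str(e).upper() if str(e).upper() in VDW_RADII
                                else str(e).capitalize()] for e in model.elements])
    inflated = radii + probe
    pts = fibonacci_sphere(n_points)
    xyz = model.xyz
    tree = cKDTree(xyz)
    max_r = inflated.max()
    atom_sasa = np.zeros(model.n_atoms)
    for i in range(model.n_atoms):
        nbrs = [j for j in tree.query_ball_point(xyz[i], inflated[i] + max_r) if j != i]
        sphere = xyz[i] + inflated[i] * pts
        if nbrs:
            nb_xyz = xyz[nbrs]
            nb_r = inflated[nbrs]
            d2 = ((sphere[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (nb_r ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        atom_sasa[i] = 4.0 * math.pi * inflated[i] ** 2 * frac

    keys, names, res_abs, res_rel = [], [], [], []
    for chain, resnum, icode, resname, idx in model.residues():
        keys.append((chain, resnum, icode))
        names.append(resname)
        total = float(atom_sasa[idx].sum())
        res_abs.append(total)
        mx = MAX_RESIDUE_SASA.get(resname)
        res_rel.append(total / mx if mx else float("nan"))
    return SASAProfile(keys, names, np.array(res_abs), np.array(res_rel),
                       atom_sasa, probe, n_points)


# ---------------------------------------------------------------------------
# Residue selections


def parse_selection(selection: str) -> list[tuple[str, int | None, int | None]]:
    """Parse e.g. ``"B:1-121"`` / ``"A:5"`` / ``"B"`` (comma-separated list).

    Ranges are author-numbered, 1-based inclusive.  Returns
    (chain, start, end) triples; start/end None means the whole chain.
    """
    out = []
    for token in selection.split(","):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            out.append((token, None, None))
            continue
        chain, rng = token.split(":", 1)
        if "-" in rng:
            a, b = rng.split("-", 1)
            out.append((chain, int(a), int(b)))
        else:
            out.append((chain, int(rng), int(rng)))
    if not out:
        raise ValueError(f"empty selection: {selection!r}")
    return out


def _selection_residue_keys(model: StructureModel, selection: str) -> list[tuple]:
    spans = parse_selection(selection)
    keys = []
    for chain, resnum, icode, _, _ in model.residues():
        for sel_chain, start, end in spans:
            if chain != sel_chain:
                continue
            if start is None or (start <= resnum <= end):
                keys.append((chain, resnum, icode))
                break
    if not keys:
        raise ValueError(f"selection {selection!r} matches no residues")
    return keys


# ---------------------------------------------------------------------------
# Ensemble per-residue RMSD


def ensemble_per_residue_rmsd(
    frames: Sequence[StructureModel],
    align_on: str,
    atoms: Iterable[str] = ("N", "CA", "C"),
    stride: int = 1,
    residues: str | None = None,
) -> EnsembleRMSDProfile:
    """Per-residue RMSD about the per-atom ensemble mean, after CA alignment.

    Every strided frame is Kabsch-aligned to the first frame on the CA atoms
    of ``align_on``; per residue the RMSD is
    sqrt(mean over frames and named atoms of |x - xbar|^2).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = list(frames)[::stride]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames after striding")
    atom_names = tuple(atoms)

    align_keys = _selection_residue_keys(frames[0], align_on)

    def ca_of(model: StructureModel, keys: list[tuple]) -> np.ndarray:
        lookup = {}
        for i in range(model.n_atoms):
            if model.atom_names[i] == "CA":
                lookup[(str(model.chains[i]), int(model.resnums[i]), str(model.icodes[i]))] = model.xyz[i]
        coords = []
        for key in keys:
            if key not in lookup:
                raise ValueError(f"alignment residue {key} missing CA")
            coords.append(lookup[key])
        return np.array(coords)

    ref_ca = ca_of(frames[0], align_keys)
    aligned: list[StructureModel] = [frames[0]]
    for f in frames[1:]:
        transform, _ = kabsch(ca_of(f, align_keys), ref_ca)
        aligned.append(f.transformed(transform))

    if residues is not None:
        eval_keys = _selection_residue_keys(frames[0], residues)
        eval_set = set(eval_keys)
    else:
        eval_set = None

    keys, resnames_out = [], []
    per_res_coords: list[list[np.ndarray]] = []
    for chain, resnum, icode, resname, _ in frames[0].residues():
        key = (chain, resnum, icode)
        if eval_set is not None and key not in eval_set:
            continue
        keys.append(key)
        resnames_out.append(resname)
        per_res_coords.append([])

    for fi, model in enumerate(aligned):
        lookup: dict[tuple, np.ndarray] = {}
        for i in range(model.n_atoms):
            name = str(model.atom_names[i])
            if name in atom_names:
                lookup[(str(model.chains[i]), int(model.resnums[i]),
                        str(model.icodes[i]), name)] = model.xyz[i]
        for ki, key in enumerate(keys):
            coords = []
            for name in atom_names:
                akey = key + (name,)
                if akey not in lookup:
                    raise ValueError(
                        f"frame {fi}: residue {key[0]}:{key[1]} missing atom {name}")
                coords.append(lookup[akey])
            per_res_coords[ki].append(np.array(coords))

    rmsd_vals = np.zeros(len(keys))
    for ki in range(len(keys)):
        stack = np.stack(per_res_coords[ki])  # (F, A, 3)
        mean = stack.mean(axis=0, keepdims=True)
        rmsd_vals[ki] = math.sqrt(float(((stack - mean) ** 2).sum(axis=2).mean()))

    return EnsembleRMSDProfile(keys, resnames_out, rmsd_vals, align_on,
                               atom_names, len(frames))
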