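"""Ground-truthed synthetic inputs for every pipeline stage.

Generates (i) VHH repertoires with zero-truncated negative-binomial read
counts, Gaussian translated lengths and a controlled defective fraction;
(ii) a toy two-domain antigen/antibody complex; (iii) docked-pose ensembles
with planted clusters and planted outliers.

All generators are pure functions of their spec (single seeded RNG, no
global state); the same seed reproduces output bit-identically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .annotation import AntibodyAnnotation
from .docking import ComplexPose, DomainDefinition
from .repertoire import RepertoireRecord
from .structure import (ONE_TO_THREE, THREE_TO_ONE, RigidTransform,
                        StructureModel, write_pdb)

__all__ = [
    "RepertoireSpec",
    "PoseEnsembleSpec",
    "GroundTruth",
    "ToyComplex",
    "generate_repertoire",
    "build_vhh_sequence",
    "generate_toy_complex",
    "generate_pose_ensemble",
    "write_repertoire_fasta",
    "write_repertoire_fastq",
    "write_pose_ensemble",
]

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
)


@dataclass
class GroundTruth:
    """Planted truth for generated artifacts.

    pose_labels: pose id -> true cluster label (-1 for planted outliers).
    defect_flags: sequence id -> True when a premature stop / frameshift
    was planted.
    """

    pose_labels: dict | None = None
    defect_flags: dict | None = None


# ---------------------------------------------------------------------------
# Repertoire generation


@dataclass(frozen=True)
class RepertoireSpec:
    n_unique: int
    nb_r: float = 2.0
    nb_p: float = 0.5
    length_mean: float = 120.7725
    length_sd: float = 4.8723
    defect_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unique < 1:
            raise ValueError("n_unique must be positive")
        if self.nb_r <= 0:
            raise ValueError("nb_r must be positive")
        if not (0.0 < self.nb_p < 1.0):
            raise ValueError("nb_p must lie strictly inside (0, 1)")
        if self.length_sd < 0:
            raise ValueError("length_sd must be nonnegative")
        if not (0.0 <= self.defect_fraction <= 1.0):
            raise ValueError("defect_fraction must lie in [0, 1]")


def sample_ztnb(rng: np.random.Generator, r: float, p: float, size: int,
                max_rounds: int = 1000) -> np.ndarray:
    """Zero-truncated negative binomial draws: NB(r, p) conditioned on >= 1.

    pmf(k) = C(k+r-1, k) p^r (1-p)^k / (1 - p^r), k >= 1.
    """
    out = rng.negative_binomial(r, p, size=size)
    for _ in range(max_rounds):
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
    raise RuntimeError("zero-truncated NB rejection sampling did not terminate")


def generate_repertoire(spec: RepertoireSpec) -> tuple[list[RepertoireRecord], GroundTruth]:
    """Generate ``n_unique`` distinct nucleotide sequences with planted truth.

    Read counts follow a zero-truncated NB(nb_r, nb_p); translated lengths of
    non-defective sequences follow round(Normal(length_mean, length_sd));
    exactly round(defect_fraction * n_unique) sequences carry one internal
    stop codon or a 1-2 nt deletion.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_unique

    counts = sample_ztnb(rng, spec.nb_r, spec.nb_p, n)

    lengths = np.rint(rng.normal(spec.length_mean, spec.length_sd, size=n)).astype(int)
    for _ in range(100):
        bad = lengths < 1
        if not bad.any():
            break
        lengths[bad] = np.rint(
            rng.normal(spec.length_mean, spec.length_sd, size=int(bad.sum()))).astype(int)
    else:
        raise ValueError(
            "length distribution mis-specified: draws below 1 aa keep occurring")

    codons = np.asarray(SENSE_CODONS)
    seqs: list[str] = []
    seen: set[str] = set()
    for length in lengths:
        for _ in range(100):
            nt = "".join(codons[rng.integers(0, len(codons), size=int(length))])
            if nt not in seen:
                break
        else:
            raise RuntimeError("could not draw a unique nucleotide sequence")
        seen.add(nt)
        seqs.append(nt)

    n_defect = int(round(spec.defect_fraction * n))
    defect_idx = rng.choice(n, size=n_defect, replace=False) if n_defect else np.array([], dtype=int)
    flags = {f"seq{i:06d}": False for i in range(n)}
    for i in sorted(int(j) for j in defect_idx):
        sid = f"seq{i:06d}"
        nt = seqs[i]
        n_codons = len(nt) // 3
        for _ in range(100):
            if rng.random() < 0.5 and n_codons >= 3:
                # one internal stop codon (never the last codon)
                pos = int(rng.integers(0, n_codons - 1))
                stop = STOP_CODONS[int(rng.integers(0, 3))]
                mutated = nt[: 3 * pos] + stop + nt[3 * pos + 3:]
            else:
                # frameshift: delete 1-2 nt at a seeded position
                k = int(rng.integers(1, 3))
                pos = int(rng.integers(0, len(nt) - k))
                mutated = nt[:pos] + nt[pos + k:]
            if mutated not in seen:
                break
        else:
            raise RuntimeError("could not plant a unique defective sequence")
        seen.discard(nt)
        seen.add(mutated)
        seqs[i] = mutated
        flags[sid] = True

    records = [
        RepertoireRecord(id=f"seq{i:06d}", nt_seq=seqs[i], count=int(counts[i]))
        for i in range(n)
    ]
    return records, GroundTruth(defect_flags=flags)


def write_repertoire_fasta(records, path, expand_counts: bool = True) -> None:
    """Write a repertoire as FASTA; with ``expand_counts`` each read is one record."""
    with open(path, "w") as fh:
        for rec in records:
            reps = rec.count if expand_counts else 1
            for _ in range(reps):
                fh.write(f">{rec.id}\n{rec.nt_seq or rec.aa_seq}\n")


def write_repertoire_fastq(records, path, expand_counts: bool = True) -> None:
    """FASTQ variant with constant quality (no base-quality realism)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.nt_seq or rec.aa_seq
            reps = rec.count if expand_counts else 1
            for _ in range(reps):
                fh.write(f"@{rec.id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Synthetic VHH sequence with planted CDR lengths

_FR1A = "QVQLVESGGGLVQPGGSLRLS"          # 21 aa, no C/W
_FR2B = "VRQAPGKGLEGVSA"                 # 14 aa after the FR2 Trp
_FR3A = "RDNAKNTVY" + "LQMNSLGPEDTALYQMNSLGPEDTALY"  # 36 aa, motif at offset 0
_FR4 = "WGQGTQVTVSS"
_CDR_FILL = "ASTNQDEGH"                  # no C/W (anchors) and no R/K (FR3 motif)


def build_vhh_sequence(l1: int = 8, l2: int = 7, l3: int = 17,
                       rng: np.random.Generator | None = None) -> str:
    """Assemble a VHH-like sequence from fixed framework templates with
    planted CDR lengths (l1, l2, l3); motif-mode annotation recovers them.
    """
    if not (1 <= l1 <= 19):
        raise ValueError("l1 must lie in [1, 19]")
    if not (1 <= l2 <= 12):
        raise ValueError("l2 must lie in [1, 12]")
    if not (1 <= l3 <= 40):
        raise ValueError("l3 must lie in [1, 40]")
    if not (6 <= l1 + l2 < 26):
        raise ValueError("l1 + l2 must lie in [6, 25] so the second Cys "
                         "lands in its search window")

    def fill(k: int) -> str:
        if rng is None:
            return "".join(_CDR_FILL[i % len(_CDR_FILL)] for i in range(k))
        return "".join(_CDR_FILL[int(j)] for j in rng.integers(0, len(_CDR_FILL), size=k))

    seq = (_FR1A + "C" + "AAS" + fill(l1) + "GL" + "W" + _FR2B
           + fill(l2) + _FR3A + "C" + "AK" + fill(l3) + _FR4)
    return seq


# ---------------------------------------------------------------------------
# Toy two-domain complex

_ROD_SPACING = 3.8
_ROD_LEN = 15
_DOMAIN_GAP = 25.0
_ROD2_START = (_ROD_LEN - 1) * _ROD_SPACING + _DOMAIN_GAP  # 78.2

# contact anchor rows on the rod: (azimuth about the rod axis, anchor radius)
_ROW_N = (math.atan2(0.6, 1.1), math.hypot(1.1, 0.6))
_ROW_C = (math.atan2(0.6, -1.1), math.hypot(1.1, 0.6))
_ROW_O = (-math.pi / 2.0, 1.7)
_CONTACT_GAP = 3.3

_AB_COLS = 9
_AB_COL_SPACING = 3.8
_SHELL_CENTER_X = (_ROD_LEN - 1) * _ROD_SPACING / 2.0  # docked over rod 1

_ANTIGEN_NAMES = ["SER", "THR", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "GLY", "HIS"]
_ANTIBODY_NAMES = list(ONE_TO_THREE.values())


@dataclass
class ToyComplex:
    """Toy antigen (chain A, two rigid blocks) + antibody (chain B, three CDRs)."""

    model: StructureModel
    annotation: AntibodyAnnotation
    domains: DomainDefinition
    antigen_chain: str = "A"
    antibody_chain: str = "B"


def _rod_residue_atoms(chain: str, resnum: int, resname: str, i: int, x0: float):
    p = np.array([x0 + _ROD_SPACING * i, 0.0, 0.0])
    ca = p + np.array([0.0, 0.5 * (-1) ** i, 0.3 if i % 3 == 0 else 0.0])
    n = p + np.array([-1.4, 1.1, 0.6])
    c = p + np.array([1.4, -1.1, 0.6])
    o = p + np.array([0.0, 0.0, -1.7])
    for name, el, xyz in (("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)):
        yield (chain, resnum, "", resname, name, el, tuple(xyz))


def _cdr_residue_atoms(chain: str, resnum: int, resname: str, az: float,
                       radius: float, x: float):
    rad = np.array([0.0, math.cos(az), math.sin(az)])
    ca = np.array([x, 0.0, 0.0]) + radius * rad
    n = ca + np.array([-1.2, 0.0, 0.0]) + 1.6 * rad
    c = ca + np.array([1.3, 0.0, 0.0]) + 0.8 * rad
    o = ca + np.array([0.3, 0.0, 0.0]) + 2.4 * rad
    for name, el, xyz in (("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)):
        yield (chain, resnum, "", resname, name, el, tuple(xyz))


def _body_residue_atoms(chain: str, resnum: int, resname: str, i: int,
                        x: float, y: float, z: float):
    p = np.array([x, y, z])
    ca = p + np.array([0.0, 0.5 * (-1) ** i, 0.3 if i % 3 == 0 else 0.0])
    n = p + np.array([-1.4, 1.1, 0.6])
    c = p + np.array([1.4, -1.1, 0.6])
    o = p + np.array([0.0, 0.0, -1.7])
    for name, el, xyz in (("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)):
        yield (chain, resnum, "", resname, name, el, tuple(xyz))


def generate_toy_complex(seed: int = 0) -> ToyComplex:
    """Deterministic toy complex: antigen chain A holds two rigid 15-residue
    blocks 25 A apart (domain1 = residues 1-15, domain2 = 21-35); antibody
    chain B carries three 9-residue CDR rows wrapped around the first block
    at ~3.3 A contact gap, plus a 21-residue framework body.

    The construction is seed-independent (the seed argument is accepted for
    interface uniformity); all atoms are >= 1.5 A apart.
    """
    del seed
    atoms = []
    # antigen: two rods along x
    for i in range(_ROD_LEN):
        atoms.extend(_rod_residue_atoms("A", 1 + i, _ANTIGEN_NAMES[i % 10], i, 0.0))
    for i in range(_ROD_LEN):
        atoms.extend(_rod_residue_atoms("A", 21 + i, _ANTIGEN_NAMES[(i + 5) % 10],
                                        i, _ROD2_START))

    # antibody: framework body + three CDR shell rows
    col_x = [_SHELL_CENTER_X + _AB_COL_SPACING * (j - (_AB_COLS - 1) / 2.0)
             for j in range(_AB_COLS)]
    resnum = 1
    seq_order = []  # (kind, params) in sequence order

    for j in range(8):   # FR-A
        seq_order.append(("body", (j, _SHELL_CENTER_X + 3.8 * (j - 3.5), 0.0, 8.5)))
    for j in range(_AB_COLS):  # CDR1: N-anchored row
        seq_order.append(("cdr", (_ROW_N[0], _ROW_N[1] + _CONTACT_GAP, col_x[j])))
    for j in range(5):   # FR-B
        seq_order.append(("body", (j, _SHELL_CENTER_X + 3.8 * (j - 2.0), 3.8, 8.5)))
    for j in range(_AB_COLS):  # CDR2: C-anchored row
        seq_order.append(("cdr", (_ROW_C[0], _ROW_C[1] + _CONTACT_GAP, col_x[j])))
    for j in range(5):   # FR-C
        seq_order.append(("body", (j, _SHELL_CENTER_X + 3.8 * (j - 2.0), -3.8, 8.5)))
    for j in range(_AB_COLS):  # CDR3: O-anchored row
        seq_order.append(("cdr", (_ROW_O[0], _ROW_O[1] + _CONTACT_GAP, col_x[j])))
    for j in range(3):   # FR-D
        seq_order.append(("body", (j, _SHELL_CENTER_X + 3.8 * (j - 1.0), 0.0, 12.0)))

    for kind, params in seq_order:
        resname = _ANTIBODY_NAMES[(resnum - 1) % 20]
        if kind == "body":
            i, x, y, z = params
            atoms.extend(_body_residue_atoms("B", resnum, resname, i, x, y, z))
        else:
            az, radius, x = params
            atoms.extend(_cdr_residue_atoms("B", resnum, resname, az, radius, x))
        resnum += 1

    model = StructureModel.from_atoms(atoms)
    aa_seq = "".join(THREE_TO_ONE[_ANTIBODY_NAMES[i % 20]] for i in range(resnum - 1))
    annotation = AntibodyAnnotation(
        aa_seq=aa_seq, cdr1=(8, 17), cdr2=(22, 31), cdr3=(36, 45), source="manual")
    domains = DomainDefinition([("domain1", 1, 15), ("domain2", 21, 35)])
    return ToyComplex(model=model, annotation=annotation, domains=domains)


# ---------------------------------------------------------------------------
# Pose ensembles


@dataclass(frozen=True)
class PoseEnsembleSpec:
    n_clusters: int
    sizes: tuple = ()
    n_outliers: int = 0
    rot_sd_within: float = 1.0        # degrees
    trans_sd_within: float = 0.5      # Angstrom per axis
    min_between_separation: float = 30.0  # Angstrom, antibody-CA displacement
    coord_noise_sd: float = 0.0       # per-atom Gaussian noise, Angstrom
    seed: int = 0
    ensure_contact: bool = False      # dock every placement onto the antigen
    contact_target: int = 10          # min interacting CDR residues (contact mode)
    contact_cutoff: float = 4.0
    clash_cutoff: float = 2.0
    outlier_min_separation: float | None = None  # default: 3 * min_between_separation
    max_tries: int = 4000

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if len(self.sizes) != self.n_clusters:
            raise ValueError("len(sizes) must equal n_clusters")
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")
        if self.n_clusters > 1 and self.min_between_separation <= 0:
            raise ValueError("min_between_separation must be > 0 with > 1 cluster")

    @property
    def outlier_sep(self) -> float:
        if self.outlier_min_separation is not None:
            return self.outlier_min_separation
        return 3.0 * self.min_between_separation


def _count_cdr_contacts(ab_xyz, ab_resnums, cdr_resnums, ag_xyz, cutoff) -> int:
    mask = np.isin(ab_resnums, list(cdr_resnums))
    if not mask.any():
        return 0
    d = cdist(ab_xyz[mask], ag_xyz)
    hit = (d < cutoff).any(axis=1)
    return len({int(r) for r in ab_resnums[mask][hit]})


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


class _PoseFactory:
    """Shared machinery: draws rigid placements of the antibody against the
    fixed antigen and materialises poses."""

    def __init__(self, reference: ToyComplex, spec: PoseEnsembleSpec):
        self.ref = reference
        self.spec = spec
        model = reference.model
        self.ab_mask = model.chain_mask(reference.antibody_chain)
        self.ag_mask = model.chain_mask(reference.antigen_chain)
        if not self.ab_mask.any() or not self.ag_mask.any():
            raise ValueError("reference must contain both antibody and antigen chains")
        self.ab_xyz0 = model.xyz[self.ab_mask]
        self.ag_xyz = model.xyz[self.ag_mask]
        self.ab_resnums = model.resnums[self.ab_mask]
        self.ab_ca_mask = model.atom_names[self.ab_mask] == "CA"
        # CDR residue numbers via positional span mapping
        chain_res = [rn for _, rn, _, _, _ in model.residues(reference.antibody_chain)]
        idx = reference.annotation.cdr_index_set()
        self.cdr_resnums = {chain_res[i] for i in idx}
        self.ab_centroid = self.ab_xyz0.mean(axis=0)
        self.ag_centroid = self.ag_xyz.mean(axis=0)
        self.ag_extent = float(np.ptp(self.ag_xyz[:, 0]))

    # -- geometry helpers -------------------------------------------------

    def place(self, transform: RigidTransform) -> np.ndarray:
        return transform.apply(self.ab_xyz0)

    def ca(self, ab_xyz: np.ndarray) -> np.ndarray:
        return ab_xyz[self.ab_ca_mask]

    def separation(self, xyz_a: np.ndarray, xyz_b: np.ndarray) -> float:
        d = self.ca(xyz_a) - self.ca(xyz_b)
        return float(np.sqrt((d ** 2).sum(axis=1).mean()))

    def contacts(self, ab_xyz: np.ndarray) -> int:
        return _count_cdr_contacts(ab_xyz, self.ab_resnums, self.cdr_resnums,
                                   self.ag_xyz, self.spec.contact_cutoff)

    def clashes(self, ab_xyz: np.ndarray) -> bool:
        return _min_distance(ab_xyz, self.ag_xyz) < self.spec.clash_cutoff

    # -- placement draws --------------------------------------------------

    def draw_contact_placement(self, rng: np.random.Generator) -> RigidTransform:
        """Slide the docked reference along the antigen axis, optionally
        flipped 180 deg about the vertical axis (which preserves the CDR
        contact shell)."""
        lo = float(self.ag_xyz[:, 0].min()) - 16.0
        hi = float(self.ag_xyz[:, 0].max()) + 16.0
        c = float(rng.uniform(lo, hi))
        flip = bool(rng.integers(0, 2))
        pivot = np.array([_SHELL_CENTER_X, 0.0, 0.0])
        rot = np.diag([-1.0, -1.0, 1.0]) if flip else np.eye(3)
        t = np.array([c, 0.0, 0.0]) - rot @ pivot
        return RigidTransform(rot, t)

    def draw_free_placement(self, rng: np.random.Generator,
                            radius_range: tuple[float, float]) -> RigidTransform:
        quat = rng.normal(size=4)
        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        if np.linalg.det(rot) < 0:  # pragma: no cover - quat rotations are proper
            rot = -rot
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rho = float(rng.uniform(*radius_range))
        target = self.ag_centroid + rho * direction
        t = target - rot @ self.ab_centroid
        return RigidTransform(rot, t)

    def perturb(self, base_xyz: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        spec = self.spec
        xyz = base_xyz
        if spec.rot_sd_within > 0:
            rotvec = rng.normal(0.0, math.radians(spec.rot_sd_within), size=3)
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            cen = xyz.mean(axis=0)
            xyz = (xyz - cen) @ rot.T + cen
        if spec.trans_sd_within > 0:
            xyz = xyz + rng.normal(0.0, spec.trans_sd_within, size=3)
        if spec.coord_noise_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.coord_noise_sd, size=xyz.shape)
        return xyz

    def make_pose(self, pose_id: str, ab_xyz: np.ndarray) -> ComplexPose:
        model = self.ref.model.copy()
        model.xyz[self.ab_mask] = ab_xyz
        return ComplexPose(pose_id=pose_id, model=model,
                           antibody_chain=self.ref.antibody_chain,
                           antigen_chain=self.ref.antigen_chain)


def generate_pose_ensemble(
    reference: ToyComplex, spec: PoseEnsembleSpec
) -> tuple[list[ComplexPose], GroundTruth]:
    """Planted-cluster docked-pose ensemble around the fixed antigen.

    Cluster centres are rigid placements pairwise separated by at least
    ``min_between_separation`` (RMS antibody-CA displacement); members
    perturb their centre by small rotations/translations plus per-atom
    noise; outliers are placed at least ``outlier_sep`` from every centre
    and from each other.  With ``ensure_contact`` every placement keeps at
    least ``contact_target`` CDR residues within ``contact_cutoff`` of the
    antigen, so the full contact-filtering pipeline retains all poses.
    """
    factory = _PoseFactory(reference, spec)
    rng = np.random.default_rng(spec.seed)

    def draw(min_seps: list[tuple[np.ndarray, float]], need_contact: bool) -> np.ndarray:
        for _ in range(spec.max_tries):
            if spec.ensure_contact:
                transform = factory.draw_contact_placement(rng)
            else:
                base = max(30.0, spec.min_between_separation)
                transform = factory.draw_free_placement(rng, (base, 2.0 * base))
            xyz = factory.place(transform)
            if factory.clashes(xyz):
                continue
            if need_contact and factory.contacts(xyz) < spec.contact_target:
                continue
            if any(factory.separation(xyz, other) < sep for other, sep in min_seps):
                continue
            return xyz
        raise RuntimeError(
            "could not draw a placement satisfying separation/contact "
            "constraints; ensemble spec appears infeasible")

    def draw_outlier(min_seps: list[tuple[np.ndarray, float]]) -> np.ndarray:
        if spec.ensure_contact:
            return draw(min_seps, need_contact=True)
        for _ in range(spec.max_tries):
            base = max(30.0, spec.min_between_separation)
            transform = factory.draw_free_placement(
                rng, (3.0 * base + factory.ag_extent, 4.5 * base + factory.ag_extent))
            xyz = factory.place(transform)
            if factory.clashes(xyz):
                continue
            if any(factory.separation(xyz, other) < sep for other, sep in min_seps):
                continue
            return xyz
        raise RuntimeError("could not place an outlier far from every centre")

    centres: list[np.ndarray] = []
    for _ in range(spec.n_clusters):
        constraints = [(c, spec.min_between_separation) for c in centres]
        centres.append(draw(constraints, need_contact=spec.ensure_contact))

    poses: list[ComplexPose] = []
    labels: dict[str, int] = {}
    idx = 0
    for k, size in enumerate(spec.sizes):
        for _ in range(size):
            for _ in range(max(1, spec.max_tries)):
                xyz = factory.perturb(centres[k], rng)
                if factory.clashes(xyz):
                    continue
                if spec.ensure_contact and factory.contacts(xyz) < spec.contact_target:
                    continue
                break
            else:
                raise RuntimeError("could not perturb a cluster member without clashes")
            pid = f"pose_{idx:03d}"
            poses.append(factory.make_pose(pid, xyz))
            labels[pid] = k
            idx += 1

    outlier_pairwise = min(spec.outlier_sep, spec.min_between_separation) \
        if spec.n_clusters > 0 else spec.outlier_sep
    outlier_xyz: list[np.ndarray] = []
    for _ in range(spec.n_outliers):
        constraints = [(c, spec.outlier_sep) for c in centres]
        constraints += [(o, outlier_pairwise) for o in outlier_xyz]
        xyz = draw_outlier(constraints)
        if spec.coord_noise_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.coord_noise_sd, size=xyz.shape)
        outlier_xyz.append(xyz)
        pid = f"pose_{idx:03d}"
        poses.append(factory.make_pose(pid, xyz))
        labels[pid] = -1
        idx += 1

    return poses, GroundTruth(pose_labels=labels)


def write_pose_ensemble(poses, truth: GroundTruth, outdir) -> None:
    """One PDB per pose plus a manifest TSV and a ground-truth TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "manifest.tsv"), "w") as mf:
        mf.write("pose_id\tpath\tantibody_chain\tantigen_chain\n")
        for pose in poses:
            fname = f"{pose.pose_id}.pdb"
            write_pdb(pose.model, os.path.join(outdir, fname))
            mf.write(f"{pose.pose_id}\t{fname}\t{pose.antibody_chain}\t{pose.antigen_chain}\n")
    if truth.pose_labels is not None:
        with open(os.path.join(outdir, "ground_truth.tsv"), "w") as tf:
            tf.write("pose_id\ttrue_label\n")
            for pose in poses:
                tf.write(f"{pose.pose_id}\t{truth.pose_labels[pose.pose_id]}\n")
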