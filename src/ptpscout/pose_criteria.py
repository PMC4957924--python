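"""Geometric acceptance criteria for docked phosphatase-phosphopeptide poses.

A docked complex pose is accepted when, after least-squares superposition of
its phosphatase chain onto a reference complex:

(i)   the phosphotyrosine phosphorus sits inside the catalytic site
      (distance to the P-loop Calpha centroid <= a cutoff, default 7 A);
(ii)  the peptide's N-to-C orientation agrees with the reference
      (angle between the Calpha(pY-2)->Calpha(pY+2) vectors < 90 deg); and
(iii) at least two of the three signature hydrogen bonds form:
      Asp-48 carboxylate to the backbone N of pY (1) and of pY+1 (2), and
      the Arg-47 backbone N to the backbone O of pY-2 (3).

Poses are assumed hydrogen-free (typical for docked or crystallographic
models), so hydrogen bonds are judged on heavy-atom donor-acceptor distance
(default <= 3.5 A), with an optional donor-acceptor-antecedent angle term.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "PoseError",
    "Atom",
    "ComplexPose",
    "ReferenceComplex",
    "PoseParameters",
    "HBond",
    "PoseEvaluation",
    "SuperpositionResult",
    "superpose",
    "check_py_in_site",
    "check_orientation",
    "detect_hbonds",
    "evaluate_pose",
    "evaluate_poses",
    "PTR_NAMES",
]

#: residue names recognised as phosphotyrosine; extensible per call
PTR_NAMES = frozenset({"PTR", "PYT", "TYP"})


class PoseError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    resname: str
    resnum: int
    chain: str
    xyz: np.ndarray


@dataclass
class ComplexPose:
    """Atoms of one docked phosphatase-peptide complex."""

    atoms: list[Atom]
    phosphatase_chain: str
    peptide_chain: str
    py_resnum: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()
        chains = {a.chain for a in self.atoms}
        if self.phosphatase_chain not in chains or self.peptide_chain not in chains:
            raise PoseError(
                f"pose must contain phosphatase chain {self.phosphatase_chain!r} "
                f"and peptide chain {self.peptide_chain!r} (found {sorted(chains)})"
            )

    def _reindex(self) -> None:
        self._index = {(a.chain, a.resnum, a.name): a for a in self.atoms}

    @classmethod
    def from_pdb(
        cls,
        source: str | Path,
        phosphatase_chain: str = "A",
        peptide_chain: str = "B",
        py_resnum: int | None = None,
        ptr_names: frozenset[str] = PTR_NAMES,
    ) -> "ComplexPose":
        """Read a single-model PDB file (or PDB text) into a pose.

        When ``py_resnum`` is not given, the phosphotyrosine is located on
        the peptide chain by residue name (``ptr_names``), requiring exactly
        one match.
        """
        text = str(source)
        if "\n" not in text and Path(text).exists():
            structure = gemmi.read_pdb(text)
        else:
            structure = gemmi.read_pdb_string(text)
        if len(structure) == 0:
            raise PoseError("PDB contains no model")
        model = structure[0]
        atoms = [
            Atom(
                name=atom.name,
                resname=res.name,
                resnum=res.seqid.num,
                chain=chain.name,
                xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            )
            for chain in model
            for res in chain
            for atom in res
        ]
        if py_resnum is None:
            candidates = sorted(
                {
                    a.resnum
                    for a in atoms
                    if a.chain == peptide_chain and a.resname in ptr_names
                }
            )
            if len(candidates) != 1:
                raise PoseError(
                    f"expected exactly one phosphotyrosine residue on chain "
                    f"{peptide_chain!r}, found {candidates}"
                )
            py_resnum = candidates[0]
        return cls(atoms, phosphatase_chain, peptide_chain, py_resnum)

    def atom(self, chain: str, resnum: int, name: str) -> Atom | None:
        return self._index.get((chain, resnum, name))

    def ca_positions(self, chain: str) -> dict[int, np.ndarray]:
        return {
            a.resnum: a.xyz for a in self.atoms if a.chain == chain and a.name == "CA"
        }

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply x -> R x + t to every atom, in place."""
        for a in self.atoms:
            a.xyz = rotation @ a.xyz + translation

    def copy(self) -> "ComplexPose":
        return copy.deepcopy(self)


@dataclass
class ReferenceComplex:
    """Template complex (e.g. a crystallographic phosphatase-peptide structure)
    with the residue numbers that define the catalytic geometry."""

    pose: ComplexPose
    catalytic_residues: tuple[int, ...] = tuple(range(214, 222))
    arg47: int = 47
    asp48: int = 48

    def __post_init__(self) -> None:
        cas = self.pose.ca_positions(self.pose.phosphatase_chain)
        for resnum in (self.arg47, self.asp48):
            if resnum not in cas:
                raise PoseError(f"reference lacks Calpha of residue {resnum}")
        if not any(r in cas for r in self.catalytic_residues):
            raise PoseError("reference lacks the catalytic pocket residues")

    def pocket_centroid(self) -> np.ndarray:
        cas = self.pose.ca_positions(self.pose.phosphatase_chain)
        pts = [cas[r] for r in self.catalytic_residues if r in cas]
        return np.mean(pts, axis=0)

    def peptide_vector(self) -> np.ndarray:
        return _peptide_vector(self.pose)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int


def superpose(mobile: ComplexPose, reference: ReferenceComplex) -> SuperpositionResult:
    """Rigid-body least squares of shared phosphatase Calpha atoms (Kabsch).

    Atoms are paired by residue number on the phosphatase chains; at least 3
    shared Calpha are required.  The proper rotation (det = +1) and
    translation are applied to the mobile pose in place.
    """
    mob_ca = mobile.ca_positions(mobile.phosphatase_chain)
    ref_ca = reference.pose.ca_positions(reference.pose.phosphatase_chain)
    shared = sorted(set(mob_ca) & set(ref_ca))
    if len(shared) < 3:
        raise PoseError(f"only {len(shared)} shared phosphatase Calpha atoms (need >=3)")
    P = np.array([mob_ca[r] for r in shared])      # mobile
    Q = np.array([ref_ca[r] for r in shared])      # reference
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    mobile.transform(R, t)
    moved = np.array([mobile.ca_positions(mobile.phosphatase_chain)[r] for r in shared])
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(shared))


def check_py_in_site(
    pose: ComplexPose, reference: ReferenceComplex, cutoff: float = 7.0
) -> tuple[bool, float]:
    """Criterion (i): pY phosphorus within ``cutoff`` (inclusive) of the
    reference P-loop Calpha centroid.  Assumes the pose is superposed."""
    p_atom = pose.atom(pose.peptide_chain, pose.py_resnum, "P")
    if p_atom is None:
        raise PoseError(f"pY residue {pose.py_resnum} has no phosphorus atom")
    distance = float(np.linalg.norm(p_atom.xyz - reference.pocket_centroid()))
    return distance <= cutoff, distance


def _peptide_vector(pose: ComplexPose) -> np.ndarray:
    """Calpha(pY-2) -> Calpha(pY+2) vector; falls back to pY-1/pY+1."""
    for offset in (2, 1):
        a = pose.atom(pose.peptide_chain, pose.py_resnum - offset, "CA")
        b = pose.atom(pose.peptide_chain, pose.py_resnum + offset, "CA")
        if a is not None and b is not None:
            return b.xyz - a.xyz
    raise PoseError(
        "peptide too short for an orientation vector (needs Calpha at pY+-2 or pY+-1)"
    )


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def check_orientation(
    pose: ComplexPose, reference: ReferenceComplex | Sequence[ReferenceComplex]
) -> tuple[bool, float]:
    """Criterion (ii): N-to-C orientation agrees with the reference(s).

    Angle between the pose's pY-2 -> pY+2 Calpha vector and the reference
    peptide's must be strictly < 90 degrees.  With several references a
    majority vote decides; the reported angle is the one against the primary
    (first) reference.  Assumes the pose is superposed onto the primary
    reference.
    """
    refs = [reference] if isinstance(reference, ReferenceComplex) else list(reference)
    primary = refs[0]
    v = _peptide_vector(pose)
    angles = []
    for ref in refs:
        if ref is primary:
            angles.append(_angle_deg(v, ref.peptide_vector()))
        else:
            aligned = ref.pose.copy()
            superpose(aligned, primary)
            angles.append(_angle_deg(v, _peptide_vector(aligned)))
    votes = sum(a < 90.0 for a in angles)
    return votes * 2 > len(angles), angles[0]


@dataclass
class HBond:
    present: bool
    distance: float | None
    reason: str = ""


def _hbond(
    donor: Atom | None,
    acceptors: Sequence[Atom | None],
    antecedent: Atom | None,
    dmax: float,
    require_angle: bool,
    label: str,
) -> HBond:
    acceptors = [a for a in acceptors if a is not None]
    if donor is None or not acceptors:
        return HBond(False, None, f"{label}: required atom missing")
    best = min(acceptors, key=lambda a: np.linalg.norm(donor.xyz - a.xyz))
    distance = float(np.linalg.norm(donor.xyz - best.xyz))
    if distance > dmax:
        return HBond(False, distance, f"{label}: distance {distance:.2f} > {dmax}")
    if require_angle and antecedent is not None:
        angle = _angle_deg(donor.xyz - best.xyz, antecedent.xyz - best.xyz)
        if angle < 90.0:
            return HBond(False, distance, f"{label}: D-A-AA angle {angle:.1f} < 90")
    return HBond(True, distance)


def detect_hbonds(
    pose: ComplexPose,
    reference: ReferenceComplex,
    dmax: float = 3.5,
    require_angle: bool = False,
) -> tuple[HBond, HBond, HBond]:
    """Criterion (iii) bonds, heavy-atom distances, inclusive at ``dmax``.

    1: Asp-48 OD1/OD2 (side-chain carboxylate) to backbone N of pY.
    2: Asp-48 OD1/OD2 to backbone N of pY+1.
    3: Arg-47 backbone N to backbone O of pY-2.
    A missing atom makes that bond absent (with a reason), never an error.
    """
    pc, sc, py = pose.phosphatase_chain, pose.peptide_chain, pose.py_resnum
    od = [pose.atom(pc, reference.asp48, "OD1"), pose.atom(pc, reference.asp48, "OD2")]
    cg = pose.atom(pc, reference.asp48, "CG")
    hb1 = _hbond(pose.atom(sc, py, "N"), od, cg, dmax, require_angle, "hbond1")
    hb2 = _hbond(pose.atom(sc, py + 1, "N"), od, cg, dmax, require_angle, "hbond2")
    hb3 = _hbond(
        pose.atom(pc, reference.arg47, "N"),
        [pose.atom(sc, py - 2, "O")],
        pose.atom(sc, py - 2, "C"),
        dmax,
        require_angle,
        "hbond3",
    )
    return hb1, hb2, hb3


@dataclass
class PoseParameters:
    pocket_cutoff: float = 7.0      # A, criterion (i)
    hbond_max: float = 3.5          # A, donor-acceptor heavy atoms
    require_hbond_angle: bool = False


@dataclass
class PoseEvaluation:
    py_in_site: bool
    py_distance: float
    orientation_ok: bool
    orientation_angle: float
    hbond1: HBond
    hbond2: HBond
    hbond3: HBond
    superposition_rmsd: float
    accepted: bool

    @property
    def n_hbonds(self) -> int:
        return sum(h.present for h in (self.hbond1, self.hbond2, self.hbond3))


def evaluate_pose(
    pose: ComplexPose,
    reference: ReferenceComplex | Sequence[ReferenceComplex],
    params: PoseParameters | None = None,
) -> PoseEvaluation:
    """Run superposition and all three criteria; accept iff (i) and (ii) hold
    and at least two of the three hydrogen bonds form.  The input pose is not
    modified (a superposed copy is evaluated)."""
    params = params or PoseParameters()
    refs = [reference] if isinstance(reference, ReferenceComplex) else list(reference)
    primary = refs[0]
    aligned = pose.copy()
    sup = superpose(aligned, primary)
    py_ok, py_dist = check_py_in_site(aligned, primary, params.pocket_cutoff)
    ori_ok, angle = check_orientation(aligned, refs if len(refs) > 1 else primary)
    hb1, hb2, hb3 = detect_hbonds(
        aligned, primary, params.hbond_max, params.require_hbond_angle
    )
    n_hb = sum(h.present for h in (hb1, hb2, hb3))
    return PoseEvaluation(
        py_in_site=py_ok,
        py_distance=py_dist,
        orientation_ok=ori_ok,
        orientation_angle=angle,
        hbond1=hb1,
        hbond2=hb2,
        hbond3=hb3,
        superposition_rmsd=sup.rmsd,
        accepted=py_ok and ori_ok and n_hb >= 2,
    )


def evaluate_poses(
    poses: Sequence[tuple[str, ComplexPose]],
    reference: ReferenceComplex | Sequence[ReferenceComplex],
    params: PoseParameters | None = None,
) -> pd.DataFrame:
    """Evaluate ``(pose_id, pose)`` pairs; rows sorted accepted-first, then by
    pocket distance."""
    rows = []
    for pose_id, pose in poses:
        e = evaluate_pose(pose, reference, params)
        rows.append(
            {
                "pose_id": pose_id,
                "py_in_site": e.py_in_site,
                "py_distance": round(e.py_distance, 3),
                "orientation_ok": e.orientation_ok,
                "orientation_angle": round(e.orientation_angle, 2),
                "hbond1": e.hbond1.present,
                "hbond2": e.hbond2.present,
                "hbond3": e.hbond3.present,
                "n_hbonds": e.n_hbonds,
                "superposition_rmsd": round(e.superposition_rmsd, 4),
                "accepted": e.accepted,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values(
            ["accepted", "py_distance"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame
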