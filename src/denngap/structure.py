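"""Superposition-based triage of predicted GTPase–candidate-GAP complexes.

The triage transplants GTP from a nucleotide-bound reference GTPase
into a predicted complex by rigid superposition of the GTPase chains,
then asks whether the candidate GAP presents an arginine side chain
close to the γ-phosphate — the classical "arginine finger" geometry —
and whether two GTPase families engage the same or distinct surfaces
of the candidate.

Coordinates are handled in Å throughout.  PDB input/output goes
through :mod:`gemmi`; the rigid-body (Kabsch) superposition is
implemented here because it is the quantitative core of the triage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

GUANIDINIUM_ATOMS = ("NE", "NH1", "NH2", "CZ")
GAMMA_PHOSPHATE_ATOMS = ("PG", "O1G", "O2G", "O3G")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(ValueError):
    """Raised for unusable structural input."""


@dataclass(frozen=True)
class Atom:
    chain_id: str
    res_number: int
    res_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class ComplexModel:
    """Flat atom list plus per-chain sequences of a (predicted) complex."""

    atoms: list[Atom]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_atoms(self, chain_id: str) -> list[Atom]:
        got = [a for a in self.atoms if a.chain_id == chain_id]
        if not got:
            raise StructureError(f"chain {chain_id!r} not present")
        return got

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of the chain's polymer residues, in order."""
        seq, seen = [], set()
        for a in self.chain_atoms(chain_id):
            if a.res_number in seen or a.res_name not in _THREE_TO_ONE:
                continue
            seen.add(a.res_number)
            seq.append(_THREE_TO_ONE[a.res_name])
        return "".join(seq)

    def residue_numbers(self, chain_id: str) -> list[int]:
        nums, seen = [], set()
        for a in self.chain_atoms(chain_id):
            if a.res_number in seen or a.res_name not in _THREE_TO_ONE:
                continue
            seen.add(a.res_number)
            nums.append(a.res_number)
        return nums

    def ca_coords(self, chain_id: str) -> dict[int, np.ndarray]:
        return {
            a.res_number: np.asarray(a.xyz)
            for a in self.chain_atoms(chain_id)
            if a.atom_name == "CA" and a.res_name in _THREE_TO_ONE
        }

    def het_atoms(self, res_name: str) -> list[Atom]:
        return [a for a in self.atoms if a.res_name == res_name]


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid transform mapping reference onto target."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    matched_pairs: tuple[tuple[int, int], ...]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class LigandPlacement:
    """GTP atoms mapped into the target frame by a superposition."""

    atoms: tuple[tuple[str, tuple[float, float, float]], ...]

    @property
    def gamma_atoms(self) -> tuple[tuple[str, tuple[float, float, float]], ...]:
        return tuple(a for a in self.atoms if a[0] in GAMMA_PHOSPHATE_ATOMS)


@dataclass(frozen=True)
class FingerCall:
    chain_id: str
    res_number: int
    res_name: str
    min_distance: float
    passes: bool


@dataclass(frozen=True)
class InterfaceSet:
    chain_id: str
    residue_numbers: frozenset[int]
    cutoff: float


@dataclass(frozen=True)
class SurfaceComparison:
    jaccard: float
    classification: str


@dataclass(frozen=True)
class StrandAnnotation:
    """Ordered, non-overlapping secondary-structure strand intervals."""

    strands: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for label, start, end in self.strands:
            if start > end:
                raise StructureError(f"strand {label}: start {start} > end {end}")
            if start <= prev_end:
                raise StructureError(f"strand {label} overlaps the previous strand")
            prev_end = end

    def interval(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.strands:
            if lab == label:
                return start, end
        raise StructureError(f"strand label {label!r} not annotated")


# ---------------------------------------------------------------- PDB I/O

def read_structure(pdb_text: str) -> ComplexModel:
    """Parse PDB-format ATOM/HETATM records into a :class:`ComplexModel`.

    Alternate locations other than ``' '``/``'A'`` are dropped;
    insertion codes are rejected; hydrogens are kept (downstream
    interface detection filters them).
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"PDB parse failure: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) == 0:
        raise StructureError("no ATOM/HETATM records found")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.seqid.icode not in (" ", "\0", ""):
                raise StructureError(
                    f"insertion code {res.seqid.icode!r} at "
                    f"{chain.name}/{res.seqid.num} not supported"
                )
            for atom in res:
                if atom.altloc not in ("", " ", "\0", "A"):
                    continue
                xyz = (atom.pos.x, atom.pos.y, atom.pos.z)
                if not all(math.isfinite(v) for v in xyz):
                    raise StructureError(
                        f"non-finite coordinate at {chain.name}/{res.seqid.num}/{atom.name}"
                    )
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        res_number=res.seqid.num,
                        res_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        xyz=xyz,
                    )
                )
    if not atoms:
        raise StructureError("no ATOM/HETATM records found")
    return ComplexModel(atoms=atoms)


def write_structure(model: ComplexModel) -> str:
    """Serialise a :class:`ComplexModel` back to PDB text (3-decimal Å)."""
    st = gemmi.Structure()
    st.name = "model"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        key = (a.chain_id, a.res_number)
        if key not in residues:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_number, " ")
            if a.res_name not in _THREE_TO_ONE:
                res.het_flag = "H"
            else:
                res.het_flag = "A"
            chains[a.chain_id].add_residue(res)
            residues[key] = chains[a.chain_id][-1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.xyz)
        residues[key].add_atom(atom)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    return st.make_pdb_string()


def transform_model(
    model: ComplexModel, rotation: np.ndarray, translation: np.ndarray
) -> ComplexModel:
    """Apply a rigid motion x ↦ Rx + t to every atom (full precision)."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    return ComplexModel(
        atoms=[
            Atom(
                chain_id=a.chain_id,
                res_number=a.res_number,
                res_name=a.res_name,
                atom_name=a.atom_name,
                element=a.element,
                xyz=tuple(R @ np.asarray(a.xyz) + t),
            )
            for a in model.atoms
        ]
    )


# ------------------------------------------------------- residue matching

def match_residues(
    ref_sequence: str, target_sequence: str
) -> list[tuple[int, int]]:
    """Pair residues of two chains by global sequence alignment.

    Uses BLOSUM62 scores with gap open −10 and gap extend −0.5.  The
    returned pairs are 0-based indices into each sequence at aligned,
    non-gap positions.
    """
    if not ref_sequence or not target_sequence:
        raise StructureError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(ref_sequence, target_sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (r0, r1), (t0, t1) in zip(*aln.aligned):
        pairs.extend(zip(range(r0, r1), range(t0, t1)))
    if len(pairs) < 3:
        raise StructureError(
            f"only {len(pairs)} aligned residue pairs; need at least 3"
        )
    return pairs


# ----------------------------------------------------------- superposition

def kabsch(ref_xyz: np.ndarray, target_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid transform (rotation, translation, rmsd) ref → target.

    Standard SVD solution of the orthogonal Procrustes problem with the
    reflection excluded (det(R) = +1).  Degenerate (rank-deficient)
    point sets raise :class:`StructureError`.
    """
    P = np.asarray(ref_xyz, dtype=float)
    Q = np.asarray(target_xyz, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise StructureError("need matching point sets of at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    if np.linalg.matrix_rank(H, tol=1e-9 * max(1.0, np.abs(H).max())) < 2:
        raise StructureError("degenerate (collinear) point set; superposition ill-posed")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose(
    ref: ComplexModel,
    target: ComplexModel,
    pairs: Sequence[tuple[int, int]] | None,
    ref_chain: str,
    target_chain: str,
) -> Superposition:
    """Superpose reference GTPase Cα onto the target's GTPase chain.

    *pairs* holds 0-based sequence indices from :func:`match_residues`;
    when ``None`` the chains are aligned here.  Only pairs with Cα on
    both sides contribute.
    """
    if pairs is None:
        pairs = match_residues(
            ref.chain_sequence(ref_chain), target.chain_sequence(target_chain)
        )
    ref_nums = ref.residue_numbers(ref_chain)
    tgt_nums = target.residue_numbers(target_chain)
    ref_ca = ref.ca_coords(ref_chain)
    tgt_ca = target.ca_coords(target_chain)
    matched: list[tuple[int, int]] = []
    P, Q = [], []
    for i, j in pairs:
        rn, tn = ref_nums[i], tgt_nums[j]
        if rn in ref_ca and tn in tgt_ca:
            matched.append((rn, tn))
            P.append(ref_ca[rn])
            Q.append(tgt_ca[tn])
    if len(matched) < 3:
        raise StructureError(
            f"only {len(matched)} matched Cα pairs; need at least 3"
        )
    R, t, rmsd = kabsch(np.array(P), np.array(Q))
    return Superposition(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_pairs=len(matched),
        matched_pairs=tuple(matched),
    )


def transplant_ligand(ref: ComplexModel, sup: Superposition) -> LigandPlacement:
    """Map the reference GTP into the target frame via *sup*."""
    gtp = ref.het_atoms("GTP")
    if not gtp:
        raise StructureError("reference carries no GTP HETATM residue")
    if not any(a.atom_name == "PG" for a in gtp):
        raise StructureError("reference GTP lacks the γ-phosphorus atom PG")
    placed = tuple(
        (a.atom_name, tuple(map(float, sup.apply(np.asarray(a.xyz)))))
        for a in gtp
    )
    return LigandPlacement(atoms=placed)


# -------------------------------------------------------- finger detection

def detect_arginine_finger(
    model: ComplexModel,
    ligand: LigandPlacement,
    candidate_chain: str,
    cutoff: float = 4.5,
) -> list[FingerCall]:
    """Score every arginine of the candidate chain against the γ-phosphate.

    The call distance is the minimum over guanidinium atoms
    (NE, NH1, NH2, CZ) × γ-phosphate atoms (PG, O1G, O2G, O3G); a call
    passes when that distance is at most *cutoff* Å.  Calls are sorted
    ascending by distance.  Arginines with no guanidinium atom present
    are skipped with a warning.
    """
    gamma = ligand.gamma_atoms
    if not gamma:
        raise StructureError("ligand placement carries no γ-phosphate atoms")
    gamma_xyz = np.array([g[1] for g in gamma])
    chain = model.chain_atoms(candidate_chain)
    by_res: dict[int, list[Atom]] = {}
    for a in chain:
        if a.res_name == "ARG":
            by_res.setdefault(a.res_number, []).append(a)
    calls: list[FingerCall] = []
    for num, atoms in by_res.items():
        guan = np.array(
            [a.xyz for a in atoms if a.atom_name in GUANIDINIUM_ATOMS]
        )
        if guan.size == 0:
            logger.warning(
                "ARG %s/%d has no guanidinium atoms; skipped", candidate_chain, num
            )
            continue
        d = np.sqrt(
            ((guan[:, None, :] - gamma_xyz[None, :, :]) ** 2).sum(axis=2)
        ).min()
        calls.append(
            FingerCall(
                chain_id=candidate_chain,
                res_number=num,
                res_name="ARG",
                min_distance=float(d),
                passes=bool(d <= cutoff),
            )
        )
    calls.sort(key=lambda c: (c.min_distance, c.res_number))
    return calls


# ------------------------------------------------------ interface analysis

def interface_residues(
    model: ComplexModel, chain_a: str, chain_b: str, cutoff: float = 4.0
) -> InterfaceSet:
    """Residues of *chain_a* with a heavy atom within *cutoff* of *chain_b*."""
    a_atoms = [a for a in model.chain_atoms(chain_a) if a.element != "H"]
    b_atoms = [a for a in model.chain_atoms(chain_b) if a.element != "H"]
    if not a_atoms or not b_atoms:
        raise StructureError("interface chains must contain heavy atoms")
    tree = cKDTree(np.array([a.xyz for a in b_atoms]))
    hits = tree.query_ball_point(np.array([a.xyz for a in a_atoms]), r=cutoff)
    members = frozenset(
        a.res_number for a, near in zip(a_atoms, hits) if near
    )
    return InterfaceSet(chain_id=chain_a, residue_numbers=members, cutoff=cutoff)


def compare_surfaces(
    a: InterfaceSet,
    b: InterfaceSet,
    distinct_below: float = 0.1,
    shared_above: float = 0.5,
) -> SurfaceComparison:
    """Jaccard similarity of two interface sets on the same chain.

    ``distinct`` below *distinct_below*, ``shared`` above *shared_above*,
    ``overlapping`` in between.  Two empty sets compare as jaccard 0.
    """
    if a.chain_id != b.chain_id:
        raise StructureError(
            f"cannot compare surfaces on different chains {a.chain_id!r}/{b.chain_id!r}"
        )
    union = a.residue_numbers | b.residue_numbers
    jac = (
        0.0
        if not union
        else len(a.residue_numbers & b.residue_numbers) / len(union)
    )
    if jac < distinct_below:
        cls = "distinct"
    elif jac > shared_above:
        cls = "shared"
    else:
        cls = "overlapping"
    return SurfaceComparison(jaccard=jac, classification=cls)


def in_interstrand_loop(
    ann: StrandAnnotation,
    residue_number: int,
    upstream: str = "β4",
    downstream: str = "β5",
) -> bool:
    """True iff the residue lies strictly between two annotated strands."""
    _, up_end = ann.interval(upstream)
    down_start, _ = ann.interval(downstream)
    return up_end < residue_number < down_start


def read_strand_annotation(tsv_text: str) -> StrandAnnotation:
    """Parse a ``label<TAB>start<TAB>end`` annotation table."""
    rows = []
    for line in tsv_text.strip().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, start, end = line.split("\t")
        rows.append((label, int(start), int(end)))
    return StrandAnnotation(strands=tuple(rows))
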