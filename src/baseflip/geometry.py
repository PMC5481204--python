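"""Coordinate-based quantification of target-DNA distortion.

Operations for the structural half of a base-flipping analysis: parse a
macromolecular coordinate file (PDB or mmCIF), find Watson-Crick base
pairs geometrically, fit helical axes to runs of pair centres, measure
the bend of a duplex as the deflection between its two arm axes
(straight duplex = 0 deg), flag unpaired nucleotides whose bases have
left the helix, and list stabilising protein-DNA polar contacts
(hydrogen bonds and salt bridges), classified by heavy-atom distance —
no hydrogen positions are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "NucleotideRef",
    "BasePair",
    "HelicalAxis",
    "Contact",
    "GeometryReport",
    "PairingCriteria",
    "ContactCutoffs",
    "load_structure",
    "find_base_pairs",
    "fit_helical_axis",
    "bend_angle",
    "detect_flipped_bases",
    "protein_dna_contacts",
    "pair_distance",
]

_PURINES = {"A", "G", "DA", "DG", "ADE", "GUA"}
_PYRIMIDINES = {"C", "T", "U", "DC", "DT", "DU", "CYT", "THY", "URA"}
_NUCLEOTIDES = _PURINES | _PYRIMIDINES
# phosphate-group oxygens eligible for salt bridges
_PHOSPHATE_O = {"OP1", "OP2", "O1P", "O2P", "O5'", "O3'"}
# positively charged side-chain nitrogens
_BASIC_N = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}


@dataclass(frozen=True)
class NucleotideRef:
    """Handle to one nucleotide: chain id, sequence number, residue name."""

    chain: str
    seqid: int
    name: str

    def __str__(self) -> str:
        return f"{self.chain}/{self.seqid}/{self.name}"


@dataclass(frozen=True)
class BasePair:
    """A Watson-Crick pair and its N1(purine)-N3(pyrimidine) distance."""

    purine: NucleotideRef
    pyrimidine: NucleotideRef
    distance: float

    def involves(self, ref: NucleotideRef) -> bool:
        return ref in (self.purine, self.pyrimidine)


@dataclass(frozen=True)
class HelicalAxis:
    """A fitted axis: point on the line, unit direction, rms residual (A)."""

    point: np.ndarray
    direction: np.ndarray
    rms_residual: float

    def distance_to(self, xyz: np.ndarray) -> float:
        d = np.asarray(xyz, dtype=float) - self.point
        return float(np.linalg.norm(d - np.dot(d, self.direction) * self.direction))


@dataclass(frozen=True)
class Contact:
    """One polar protein-DNA contact."""

    protein_atom: str
    dna_atom: str
    distance: float
    kind: str  # "h-bond" | "salt-bridge"


@dataclass
class GeometryReport:
    """Derived geometry of one structure."""

    bend_angle: float | None
    arms: tuple | None
    base_pairs: list[BasePair]
    flipped_bases: list[NucleotideRef]
    contacts: list[Contact]

    def to_dict(self) -> dict:
        return {
            "bend_angle_deg": self.bend_angle,
            "arms": self.arms,
            "base_pairs": [
                {"purine": str(p.purine), "pyrimidine": str(p.pyrimidine),
                 "distance_A": round(p.distance, 3)}
                for p in self.base_pairs
            ],
            "flipped_bases": [str(r) for r in self.flipped_bases],
            "contacts": [
                {"protein_atom": c.protein_atom, "dna_atom": c.dna_atom,
                 "distance_A": round(c.distance, 3), "class": c.kind}
                for c in self.contacts
            ],
        }

    def contact_table(self) -> str:
        lines = ["protein_atom\tdna_atom\tdistance_A\tclass"]
        for c in self.contacts:
            lines.append(f"{c.protein_atom}\t{c.dna_atom}\t{c.distance:.2f}\t{c.kind}")
        return "\n".join(lines)


@dataclass(frozen=True)
class PairingCriteria:
    """Geometric Watson-Crick pairing criteria (heavy atoms only)."""

    max_wc_distance: float = 3.5  # N1(pur)-N3(pyr), Angstrom


@dataclass(frozen=True)
class ContactCutoffs:
    """Heavy-atom distance cutoffs for polar contact classes (Angstrom)."""

    hbond: float = 3.5
    salt_bridge: float = 4.0


class StructureModel:
    """Parsed coordinates with nucleotide/protein classification helpers.

    Thin wrapper over a gemmi Structure (first model).  Heterogens and
    waters are retained but flagged; nucleotides missing their
    glycosidic nitrogen are flagged incomplete rather than rejected.
    """

    def __init__(self, structure: gemmi.Structure):
        self.structure = structure
        self.model = structure[0]

    # -- residue classification ------------------------------------------
    @staticmethod
    def is_nucleotide(residue: gemmi.Residue) -> bool:
        return residue.name.strip().upper() in _NUCLEOTIDES

    @staticmethod
    def is_purine(residue: gemmi.Residue) -> bool:
        return residue.name.strip().upper() in _PURINES

    @staticmethod
    def is_amino_acid(residue: gemmi.Residue) -> bool:
        info = gemmi.find_tabulated_residue(residue.name)
        return bool(info and info.is_amino_acid())

    @staticmethod
    def is_water_or_hetero(residue: gemmi.Residue) -> bool:
        return residue.is_water() or residue.het_flag == "H"

    # -- lookups ----------------------------------------------------------
    def residue(self, chain: str, seqid: int) -> gemmi.Residue:
        try:
            ch = self.model[chain]
        except (KeyError, IndexError, ValueError, RuntimeError) as exc:
            raise KeyError(f"no chain {chain!r}: {exc}") from None
        for res in ch:
            if res.seqid.num == seqid:
                return res
        raise KeyError(f"no residue {seqid} in chain {chain}")

    def atom_position(self, chain: str, seqid: int, atom: str) -> np.ndarray:
        res = self.residue(chain, seqid)
        for a in res:
            if a.name == atom:
                return np.array(a.pos.tolist())
        raise KeyError(f"no atom {atom!r} in {chain}/{seqid}/{res.name}")

    def nucleotides(self) -> list[NucleotideRef]:
        out = []
        for chain in self.model:
            for res in chain:
                if self.is_nucleotide(res):
                    out.append(NucleotideRef(chain.name, res.seqid.num, res.name))
        return out

    def glycosidic_nitrogen(self, ref: NucleotideRef) -> np.ndarray | None:
        """N9 (purine) / N1 (pyrimidine) position, or None if incomplete."""
        res = self.residue(ref.chain, ref.seqid)
        wanted = "N9" if self.is_purine(res) else "N1"
        for a in res:
            if a.name == wanted:
                return np.array(a.pos.tolist())
        return None

    def wc_nitrogen(self, ref: NucleotideRef) -> np.ndarray | None:
        """Watson-Crick edge nitrogen: N1 (purine) / N3 (pyrimidine)."""
        res = self.residue(ref.chain, ref.seqid)
        wanted = "N1" if self.is_purine(res) else "N3"
        for a in res:
            if a.name == wanted:
                return np.array(a.pos.tolist())
        return None

    def glycosidic_direction(self, ref: NucleotideRef) -> np.ndarray | None:
        """Unit vector C1' -> glycosidic nitrogen, or None if incomplete."""
        res = self.residue(ref.chain, ref.seqid)
        c1 = next((a for a in res if a.name == "C1'"), None)
        gn = self.glycosidic_nitrogen(ref)
        if c1 is None or gn is None:
            return None
        v = gn - np.array(c1.pos.tolist())
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else None

    def incomplete_nucleotides(self) -> list[NucleotideRef]:
        return [r for r in self.nucleotides() if self.glycosidic_nitrogen(r) is None]


def load_structure(path: str) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in coordinate file {path}")
    st.setup_entities()
    return StructureModel(st)


def find_base_pairs(
    structure: StructureModel, criteria: PairingCriteria | None = None
) -> list[BasePair]:
    """Geometric Watson-Crick pairs.

    A purine pairs a pyrimidine when the N1-N3 distance is within the
    cutoff and the glycosidic bonds point towards each other
    (antiparallel strands).  Greedy assignment by ascending distance,
    ties broken by residue order; each nucleotide joins at most one
    pair.
    """
    criteria = criteria or PairingCriteria()
    purines, pyrimidines = [], []
    for ref in structure.nucleotides():
        res = structure.residue(ref.chain, ref.seqid)
        wc = structure.wc_nitrogen(ref)
        gd = structure.glycosidic_direction(ref)
        if wc is None or gd is None:
            continue
        (purines if structure.is_purine(res) else pyrimidines).append((ref, wc, gd))

    candidates = []
    for ref_r, wc_r, gd_r in purines:
        for ref_y, wc_y, gd_y in pyrimidines:
            d = float(np.linalg.norm(wc_r - wc_y))
            if d <= criteria.max_wc_distance and np.dot(gd_r, gd_y) < 0.0:
                candidates.append((d, ref_r, ref_y))
    candidates.sort(key=lambda c: (c[0], str(c[1]), str(c[2])))

    used: set[NucleotideRef] = set()
    pairs = []
    for d, ref_r, ref_y in candidates:
        if ref_r in used or ref_y in used:
            continue
        used.update((ref_r, ref_y))
        pairs.append(BasePair(ref_r, ref_y, d))
    pairs.sort(key=lambda p: (p.purine.chain, p.purine.seqid))
    return pairs


def pair_center(structure: StructureModel, pair: BasePair) -> np.ndarray:
    """Midpoint of the two glycosidic nitrogens of a pair."""
    a = structure.glycosidic_nitrogen(pair.purine)
    b = structure.glycosidic_nitrogen(pair.pyrimidine)
    return 0.5 * (a + b)


def fit_helical_axis(centers: np.ndarray) -> HelicalAxis:
    """Total-least-squares line through ordered base-pair centres.

    The direction is oriented along the input order (5'->3' along the
    reference strand when centres are given in strand order).
    """
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 pair centers to fit an axis")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    resid = pts - centroid
    perp = resid - np.outer(resid @ direction, direction)
    rms = float(np.sqrt((perp**2).sum(axis=1).mean()))
    return HelicalAxis(point=centroid, direction=direction, rms_residual=rms)


def _arm_centers(
    structure: StructureModel,
    pairs: list[BasePair],
    chain: str,
    seqids: tuple[int, int],
) -> np.ndarray:
    lo, hi = min(seqids), max(seqids)
    selected = []
    for p in pairs:
        for ref in (p.purine, p.pyrimidine):
            if ref.chain == chain and lo <= ref.seqid <= hi:
                selected.append((ref.seqid, pair_center(structure, p)))
                break
    selected.sort(key=lambda t: t[0])
    return np.array([c for _, c in selected])


def bend_angle(
    structure: StructureModel,
    arm_a: tuple[str, tuple[int, int]],
    arm_b: tuple[str, tuple[int, int]],
    pairs: list[BasePair] | None = None,
) -> float:
    """Deflection angle (deg) between the helical axes of two duplex arms.

    Each arm is ``(chain_id, (first_seqid, last_seqid))`` on the
    reference strand, both given in the same 5'->3' sense, so a straight
    duplex scores ~0 deg and an angle of 90 deg means the helix turns by
    a right angle at the junction.
    """
    pairs = pairs if pairs is not None else find_base_pairs(structure)
    axes = []
    for chain, seqids in (arm_a, arm_b):
        centers = _arm_centers(structure, pairs, chain, seqids)
        if len(centers) < 3:
            raise ValueError(
                f"arm {chain}:{seqids} has {len(centers)} paired steps; need >= 3"
            )
        axes.append(fit_helical_axis(centers))
    cosang = float(np.clip(np.dot(axes[0].direction, axes[1].direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def detect_flipped_bases(
    structure: StructureModel,
    pairs: list[BasePair] | None = None,
    axis_threshold: float = 8.0,
    n_axis_neighbors: int = 6,
) -> list[NucleotideRef]:
    """Nucleotides that are unpaired and extra-helical.

    A base is flagged flipped when it belongs to no Watson-Crick pair
    and its glycosidic nitrogen lies more than ``axis_threshold`` (A)
    from the local helical axis, fitted to the ``n_axis_neighbors``
    nearest base-pair centres of its surroundings.
    """
    pairs = pairs if pairs is not None else find_base_pairs(structure)
    if len(pairs) < 3:
        return []
    centers = np.array([pair_center(structure, p) for p in pairs])
    paired = {ref for p in pairs for ref in (p.purine, p.pyrimidine)}
    flipped = []
    for ref in structure.nucleotides():
        if ref in paired:
            continue
        gn = structure.glycosidic_nitrogen(ref)
        if gn is None:
            continue
        order = np.argsort(np.linalg.norm(centers - gn, axis=1))
        local = centers[order[: max(3, n_axis_neighbors)]]
        # keep construction order so the axis has a defined direction
        local = local[np.argsort(order[: max(3, n_axis_neighbors)])]
        axis = fit_helical_axis(local)
        if axis.distance_to(gn) > axis_threshold:
            flipped.append(ref)
    return flipped


def protein_dna_contacts(
    structure: StructureModel, cutoffs: ContactCutoffs | None = None
) -> list[Contact]:
    """Polar protein-DNA contacts, sorted by distance.

    Any protein N/O within the h-bond cutoff of a DNA O/N counts as a
    hydrogen bond (donor/acceptor roles inferred from heavy atoms only);
    basic side-chain nitrogens (Lys NZ, Arg NH1/NH2/NE) near phosphate
    oxygens within the salt-bridge cutoff are upgraded to salt bridges.
    """
    cutoffs = cutoffs or ContactCutoffs()
    protein_atoms, dna_atoms = [], []
    for chain in structure.model:
        for res in chain:
            if StructureModel.is_amino_acid(res):
                for a in res:
                    if a.element.name in ("N", "O"):
                        protein_atoms.append((chain.name, res, a))
            elif StructureModel.is_nucleotide(res):
                for a in res:
                    if a.element.name in ("N", "O"):
                        dna_atoms.append((chain.name, res, a))
    if not protein_atoms or not dna_atoms:
        return []

    p_xyz = np.array([a.pos.tolist() for _, _, a in protein_atoms])
    d_xyz = np.array([a.pos.tolist() for _, _, a in dna_atoms])
    max_cut = max(cutoffs.hbond, cutoffs.salt_bridge)
    tree = cKDTree(d_xyz)
    contacts = []
    for i, js in enumerate(tree.query_ball_point(p_xyz, max_cut)):
        p_chain, p_res, p_atom = protein_atoms[i]
        for j in js:
            d_chain, d_res, d_atom = dna_atoms[j]
            dist = float(np.linalg.norm(p_xyz[i] - d_xyz[j]))
            is_basic = (p_res.name, p_atom.name) in _BASIC_N
            is_phosphate = d_atom.name in _PHOSPHATE_O
            if is_basic and is_phosphate and dist <= cutoffs.salt_bridge:
                kind = "salt-bridge"
            elif dist <= cutoffs.hbond:
                kind = "h-bond"
            else:
                continue
            contacts.append(
                Contact(
                    protein_atom=f"{p_chain}/{p_res.seqid.num}/{p_res.name}/{p_atom.name}",
                    dna_atom=f"{d_chain}/{d_res.seqid.num}/{d_res.name}/{d_atom.name}",
                    distance=dist,
                    kind=kind,
                )
            )
    contacts.sort(key=lambda c: c.distance)
    return contacts


def pair_distance(structure: StructureModel, selector_a: str, selector_b: str) -> float:
    """Euclidean distance (A) between two atoms given as 'chain/seqid/atom'."""

    def resolve(sel: str) -> np.ndarray:
        parts = sel.split("/")
        if len(parts) != 3:
            raise ValueError(f"bad atom selector {sel!r}; expected 'chain/seqid/atom'")
        chain, seqid, atom = parts
        try:
            return structure.atom_position(chain, int(seqid), atom)
        except KeyError as exc:
            raise ValueError(f"cannot resolve selector {sel!r}: {exc}") from exc

    return float(np.linalg.norm(resolve(selector_a) - resolve(selector_b)))
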