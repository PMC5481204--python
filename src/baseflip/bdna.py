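"""Synthetic idealised B-DNA duplex builder (test/validation fixtures).

Generates minimal synthetic coordinate models of a B-form duplex — the
atoms the geometry operations consume (phosphate group, C1', glycosidic
and Watson-Crick nitrogens) placed on an ideal helix (3.38 A rise,
36 deg twist) — plus helpers to bend the duplex at a junction, flip a
base out of the helix, and plant a protein side-chain atom near the
backbone.  These are deliberately skeletal synthetic stand-ins for real
structures: sufficient for pairing, axis, bend, flip and contact
geometry, with no sugar ring, base ring carbons or hydrogens.
"""

from __future__ import annotations

import numpy as np
import gemmi

from .geometry import StructureModel

__all__ = [
    "make_duplex",
    "make_bent_duplex",
    "flip_base_out",
    "displace_residue",
    "add_probe_atom",
    "transform_structure",
    "write_pdb",
    "RISE",
    "TWIST",
]

RISE = 3.38  # A per base-pair step
TWIST = 36.0  # deg per step

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}

# Local template for the strand-1 side of a pair (x < 0); the partner
# nucleotide is the x-mirror.  Pair centre (glycosidic-N midpoint) sits
# on the helix axis; WC nitrogens are 2.9 A apart.
_TEMPLATE = {
    "P": (-8.0, -2.0, -1.0),
    "OP1": (-8.9, -1.3, -1.7),
    "OP2": (-8.2, -3.4, -1.2),
    "C1'": (-5.2, -1.0, 0.0),
    "GLYC_N": (-3.8, 0.0, 0.0),  # N9 (purine) / N1 (pyrimidine)
    "WC_N": (-1.45, 0.8, 0.0),  # N1 (purine) / N3 (pyrimidine)
}


def _nucleotide_atoms(base: str, mirror: bool) -> list[tuple[str, np.ndarray]]:
    purine = base in ("A", "G")
    atoms = []
    for key, xyz in _TEMPLATE.items():
        name = key
        if key == "GLYC_N":
            name = "N9" if purine else "N1"
        elif key == "WC_N":
            name = "N1" if purine else "N3"
        p = np.array(xyz, dtype=float)
        if mirror:
            p[0] = -p[0]
        atoms.append((name, p))
    return atoms


def _step_transform(index: int, rise: float, twist: float):
    angle = np.radians(twist * index)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, np.array([0.0, 0.0, rise * index])


def make_duplex(
    sequence: str,
    chain_a: str = "A",
    chain_b: str = "B",
    rise: float = RISE,
    twist: float = TWIST,
) -> StructureModel:
    """Ideal straight B-form duplex for ``sequence`` (5'->3' of strand A).

    Strand B is the reverse complement, numbered 5'->3' in its own
    chain; residue j of B pairs residue n+1-j of A.
    """
    sequence = sequence.upper()
    if not sequence or any(b not in _COMPLEMENT for b in sequence):
        raise ValueError("sequence must be non-empty over A/C/G/T")
    n = len(sequence)
    st = gemmi.Structure()
    st.name = "synthetic-bdna"
    model = gemmi.Model("1")
    ch_a, ch_b = gemmi.Chain(chain_a), gemmi.Chain(chain_b)

    def add_residue(chain, name, seqid, atoms, rot, shift):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        for atom_name, local in atoms:
            a = gemmi.Atom()
            a.name = atom_name
            a.element = gemmi.Element(atom_name[0])
            pos = rot @ local + shift
            a.pos = gemmi.Position(*pos)
            res.add_atom(a)
        chain.add_residue(res)

    for i, base in enumerate(sequence):
        rot, shift = _step_transform(i, rise, twist)
        add_residue(ch_a, _RESNAME[base], i + 1, _nucleotide_atoms(base, False), rot, shift)
    for j in range(n):
        i = n - 1 - j  # pair index along the helix
        base = _COMPLEMENT[sequence[i]]
        rot, shift = _step_transform(i, rise, twist)
        add_residue(ch_b, _RESNAME[base], j + 1, _nucleotide_atoms(base, True), rot, shift)

    model.add_chain(ch_a)
    model.add_chain(ch_b)
    st.add_model(model)
    st.setup_entities()
    return StructureModel(st)


def transform_structure(
    structure: StructureModel,
    rotation: np.ndarray,
    translation: np.ndarray,
    chains: set[str] | None = None,
    seqid_range: tuple[int, int] | None = None,
    chain_for_range: str | None = None,
) -> None:
    """Apply ``x -> R x + t`` in place, optionally to a subset of residues.

    When ``seqid_range`` is given it restricts the transform per chain:
    on ``chain_for_range`` (reference strand numbering) the range is
    used as-is; on other chains all residues pairing into that helical
    region must be selected by the caller through ``chains``.
    """
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    for chain in structure.model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if seqid_range is not None and (
                chain_for_range is None or chain.name == chain_for_range
            ):
                lo, hi = seqid_range
                if not lo <= res.seqid.num <= hi:
                    continue
            for a in res:
                p = np.array(a.pos.tolist())
                a.pos = gemmi.Position(*(rotation @ p + translation))


def make_bent_duplex(
    sequence: str, bend_deg: float, junction: int | None = None, gap: float = 4.0
) -> StructureModel:
    """Two ideal arms meeting at ``junction`` with a rigid bend.

    The duplex is built straight, then every pair beyond the junction
    (strand-A numbering) is rotated by ``bend_deg`` about an in-plane
    axis through the junction point, so the deflection between the two
    arm axes equals ``bend_deg`` by construction.  The rotated arm is
    additionally translated ``gap`` A along its own axis, opening the
    junction so bases on the compressed side of the bend cannot clash
    (and thus cannot spuriously cross-pair).
    """
    n = len(sequence)
    junction = junction if junction is not None else n // 2
    dup = make_duplex(sequence)
    pivot = np.array([0.0, 0.0, RISE * (junction - 0.5)])
    theta = np.radians(bend_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])  # about x
    shift = gap * (rot @ np.array([0.0, 0.0, 1.0]))

    for chain in dup.model:
        for res in chain:
            if chain.name == "A":
                pair_index = res.seqid.num
            else:  # strand B residue j pairs helical position n+1-j
                pair_index = n + 1 - res.seqid.num
            if pair_index <= junction:
                continue
            for a in res:
                p = np.array(a.pos.tolist())
                a.pos = gemmi.Position(*(rot @ (p - pivot) + pivot + shift))
    return dup


def displace_residue(
    structure: StructureModel, chain: str, seqid: int, vector: np.ndarray
) -> None:
    """Shift every atom of one residue by ``vector`` (in place)."""
    vector = np.asarray(vector, dtype=float)
    res = structure.residue(chain, seqid)
    for a in res:
        p = np.array(a.pos.tolist())
        a.pos = gemmi.Position(*(p + vector))


def flip_base_out(
    structure: StructureModel, chain: str, seqid: int, radius: float = 12.0
) -> None:
    """Rotate a base out of the helix (construction frame, axis = z).

    The base atoms (glycosidic and WC nitrogens) are pushed radially to
    ``radius`` A from the z axis, emulating an extra-helical flipped
    conformation; backbone atoms (P, OP1, OP2, C1') stay.
    """
    res = structure.residue(chain, seqid)
    is_purine = any(a.name == "N9" for a in res)
    base_atoms = {"N9", "N1"} if is_purine else {"N1", "N3"}
    for a in res:
        if a.name not in base_atoms:
            continue
        p = np.array(a.pos.tolist())
        r_xy = np.linalg.norm(p[:2])
        if r_xy == 0:
            p[:2] = (radius, 0.0)
        else:
            p[:2] *= radius / r_xy
        a.pos = gemmi.Position(*p)


def add_probe_atom(
    structure: StructureModel,
    position: np.ndarray,
    chain: str = "P",
    resname: str = "LYS",
    atom_name: str = "NZ",
    seqid: int = 1,
) -> None:
    """Add a single protein side-chain atom (e.g. Lys NZ) at ``position``."""
    ch = gemmi.Chain(chain)
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(seqid, " ")
    a = gemmi.Atom()
    a.name = atom_name
    a.element = gemmi.Element(atom_name[0])
    a.pos = gemmi.Position(*np.asarray(position, dtype=float))
    res.add_atom(a)
    ch.add_residue(res)
    structure.model.add_chain(ch)


def write_pdb(structure: StructureModel, path: str) -> None:
    """Write the model as a minimal PDB file."""
    structure.structure.setup_entities()
    structure.structure.write_pdb(str(path))
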