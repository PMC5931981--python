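"""Macromolecular model I/O and small-molecule mass arithmetic.

Structures are read from PDB-format text into a lightweight in-memory
model (:class:`StructureModel`) that keeps author residue numbering and
separates polymer chains from hetero groups (ligands, metals, waters).
Parsing and serialisation are delegated to :mod:`gemmi`; this module only
applies the classification and alternate-location policies documented
below.

Masses are monoisotopic (most abundant isotope per element), which is
what a narrow-window LC-MS extracted-ion chromatogram selects on.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as _pt_mass
from scipy import constants as _const

__all__ = [
    "Atom",
    "Residue",
    "ChainModel",
    "StructureModel",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "write_fasta",
    "monoisotopic_mass",
    "mz_minus_h",
    "PDBError",
    "FormulaError",
]

# Standard 20 plus common crystallographic variants that still represent
# a polymer position.
AMINO3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Single-atom hetero groups treated as metal sites.  Covers the divalent
# magnesium essential for catalysis plus the monovalent cations discussed
# for related family members.
METAL_NAMES = {"MG", "MN", "ZN", "CA", "NA", "K", "CS", "FE", "NI", "CO", "CU"}

_ELECTRON_MASS_DA = _const.physical_constants["electron mass in u"][0]
_H_MASS_DA = _pt_mass.nist_mass["H"][0][0]


class PDBError(ValueError):
    """Raised for unreadable or empty PDB input."""


class FormulaError(ValueError):
    """Raised for malformed or unknown elemental formulas."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)
    kind: str = "other"  # amino_acid | ligand | metal | water | other

    @property
    def one_letter(self) -> str:
        return AMINO3TO1.get(self.name3, "X")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name3}{self.number}{self.icode}".rstrip()


@dataclass
class ChainModel:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues if r.kind == "amino_acid")

    def amino_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "amino_acid"]

    def anchor_coords(self, anchor: str = "CA") -> tuple[np.ndarray, list[int]]:
        """Coordinates of the anchor atom per amino-acid residue.

        Returns the (n, 3) coordinate array and the indices (into
        :meth:`amino_residues`) of residues that possess the anchor.
        """
        coords, idx = [], []
        for i, res in enumerate(self.amino_residues()):
            atom = res.get_atom(anchor)
            if atom is not None:
                coords.append(atom.coords)
                idx.append(i)
        return np.asarray(coords, dtype=float).reshape(-1, 3), idx


@dataclass
class StructureModel:
    id: str
    chains: list[ChainModel] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def hetero_by_name(self, name3: str, chain_id: str | None = None) -> list[Residue]:
        out = [r for r in self.hetero if r.name3 == name3]
        if chain_id is not None:
            out = [r for r in out if r.chain_id == chain_id]
        return out

    def all_residues(self) -> Iterable[Residue]:
        for c in self.chains:
            yield from c.residues
        yield from self.hetero


def _classify(name3: str, het: bool, n_atoms: int) -> str:
    if name3 in WATER_NAMES:
        return "water"
    if not het:
        return "amino_acid" if name3 in AMINO3TO1 else "other"
    if name3 in METAL_NAMES and n_atoms == 1:
        return "metal"
    if name3 in AMINO3TO1:
        # HETATM-coded modified amino acids (e.g. selenomethionine) stay
        # in the polymer.
        return "amino_acid"
    return "ligand"


def read_pdb(source: str | TextIO, structure_id: str | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Alternate locations: the first altloc encountered per atom name within
    a residue is kept, all others dropped.  Author numbering is preserved.
    HETATM groups are classified as water / metal / ligand by residue name;
    everything read from ATOM records with a standard residue name is an
    amino acid.
    """
    text = source if isinstance(source, str) else source.read()
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBError(f"unreadable PDB input: {exc}") from exc
    if len(st) == 0 or sum(ch.count_atom_sites() for ch in st[0]) == 0:
        raise PDBError("no atoms in PDB input")

    model = StructureModel(id=structure_id or st.name or "model")
    gmodel = st[0]
    for gchain in gmodel:
        chain = ChainModel(id=gchain.name)
        for gres in gchain:
            het = gres.het_flag == "H"
            kind = _classify(gres.name, het, len(gres))
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                name3=gres.name,
                kind=kind,
            )
            seen: set[str] = set()
            for ga in gres:
                if ga.name in seen:
                    continue  # keep the first altloc per atom name
                seen.add(ga.name)
                res.atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        altloc=(ga.altloc or "").strip("\x00"),
                    )
                )
            if kind == "amino_acid":
                chain.residues.append(res)
            else:
                model.hetero.append(res)
        if chain.residues:
            model.chains.append(chain)
    return model


def write_pdb(model: StructureModel, dest: TextIO | None = None) -> str:
    """Serialise a :class:`StructureModel` as PDB-format text via gemmi."""
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")

    def _add(gchain: gemmi.Chain, res: Residue, het: bool) -> None:
        gres = gemmi.Residue()
        gres.name = res.name3
        gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
        gres.het_flag = "H" if het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.serial = a.serial
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        gchain.add_residue(gres)

    hetero_by_chain: dict[str, list[Residue]] = {}
    for res in model.hetero:
        hetero_by_chain.setdefault(res.chain_id, []).append(res)

    for chain in model.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            _add(gchain, res, het=res.kind != "amino_acid")
        for res in hetero_by_chain.pop(chain.id, []):
            _add(gchain, res, het=True)
        gmodel.add_chain(gchain)
    for chain_id, residues in hetero_by_chain.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            _add(gchain, res, het=True)
        gmodel.add_chain(gchain)

    st.add_model(gmodel)
    st.setup_entities()
    text = st.make_pdb_string()
    if dest is not None:
        dest.write(text)
    return text


_FASTA_SEQ_RE = re.compile(r"^[A-Za-z]*$")


def read_fasta(source: str | TextIO) -> list[tuple[str, str, str]]:
    """Read FASTA records as ``(id, description, sequence)`` tuples.

    Sequences are upper-cased; duplicate record ids and non-letter sequence
    characters are rejected.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not _FASTA_SEQ_RE.match(seq):
            raise ValueError(f"record {rec.id!r}: sequence contains non-letter characters")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append((rec.id, desc, seq.upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str, str]], dest: TextIO | None = None) -> str:
    buf = io.StringIO()
    seqrecs = [
        SeqRecord(Seq(seq), id=rid, description=desc) for rid, desc, seq in records
    ]
    SeqIO.write(seqrecs, buf, "fasta")
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element, digits = m.group(1), m.group(2)
        if element not in _pt_mass.nist_mass:
            raise FormulaError(f"unknown element symbol {element!r}")
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"element {element}: count must be >= 1")
        counts[element] = counts.get(element, 0) + count
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a neutral elemental formula, in Da.

    Uses the most-abundant-isotope masses from the NIST table bundled with
    pyteomics (e.g. 1.0078250319 for H, 12.0 for C).
    """
    counts = _parse_formula(formula)
    return float(sum(_pt_mass.nist_mass[el][0][0] * n for el, n in counts.items()))


def mz_minus_h(formula: str) -> float:
    """m/z of the deprotonated [M-H]- ion of a neutral molecule.

    Equals the monoisotopic mass minus one hydrogen atom plus one electron
    (the charge carrier is loss of a proton, not of a hydrogen atom).
    """
    counts = _parse_formula(formula)
    if counts.get("H", 0) < 1:
        raise FormulaError(f"formula {formula!r} has no hydrogen to deprotonate")
    return monoisotopic_mass(formula) - _H_MASS_DA + _ELECTRON_MASS_DA
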