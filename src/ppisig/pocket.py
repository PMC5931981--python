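"""Binding-pocket geometry: contacts, metal coordination, ring orientation.

All criteria are heavy-atom distance rules, the natural choice for crystal
structures solved without hydrogens.  Hydrogen-bond assignment is purely
distance-based (donor/acceptor N,O pairs); salt bridges are recognised by
residue/atom identity (Arg/Lys guanidinium or ammonium nitrogens against
oxygens of phosphate- or sulfate-bearing ligands), not by charge models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import Atom, Residue, StructureModel
from .superpose import SuperpositionResult

__all__ = [
    "ContactRecord",
    "CoordinationShell",
    "RingOrientation",
    "pocket_residues",
    "hbond_contacts",
    "metal_shell",
    "ring_orientation_diff",
    "nearest_distance",
]

DEFAULT_POCKET_CUTOFF = 4.0  # Angstrom
DEFAULT_HBOND_CUTOFF = 3.5   # Angstrom
DEFAULT_SHELL_CUTOFF = 2.8   # Angstrom

BACKBONE_ATOMS = {"N", "O", "C", "CA"}
_POSITIVE_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
}
RING_ATOM_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6")


@dataclass
class ContactRecord:
    residue: Residue
    residue_atom: str
    ligand_atom: str
    distance: float
    contact_class: str  # hbond | ionic | vdw | metal_coord
    via_backbone: bool


@dataclass
class CoordinationShell:
    center: Atom
    ligands: list[tuple[Atom, float, str]] = field(default_factory=list)

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    @property
    def octahedricity(self) -> float:
        """RMS deviation (degrees) of cis ligand-center-ligand angles from 90.

        Angles closer to 180 than to 90 are treated as trans pairs and
        excluded.  Zero for shells with fewer than two ligands.
        """
        if len(self.ligands) < 2:
            return 0.0
        c = self.center.coords
        vecs = [a.coords - c for a, _, _ in self.ligands]
        devs = []
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                cosang = np.dot(vecs[i], vecs[j]) / (
                    np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if abs(ang - 90.0) <= abs(ang - 180.0):
                    devs.append(ang - 90.0)
        if not devs:
            return 0.0
        return float(np.sqrt(np.mean(np.square(devs))))


@dataclass
class RingOrientation:
    tilt_deg: float       # angle between best-fit plane normals, folded to [0, 90]
    rotation_deg: float   # in-plane rotation about the common normal, [0, 360)
    atom_mapping: tuple[str, ...] = RING_ATOM_NAMES
    # Sign convention: positive rotation is counter-clockwise viewed down
    # ring a's plane normal (normal oriented by the C1->C2->... winding).


def _heavy_coords(atoms: list[Atom]) -> tuple[np.ndarray, list[Atom]]:
    heavy = [a for a in atoms if a.is_heavy]
    return np.array([a.coords for a in heavy]).reshape(-1, 3), heavy


def pocket_residues(
    struct: StructureModel, ligand: Residue, cutoff: float = DEFAULT_POCKET_CUTOFF
) -> list[tuple[Residue, float]]:
    """Amino-acid residues with any heavy atom within ``cutoff`` of the ligand.

    Waters and other hetero groups are excluded; results are sorted by
    minimum heavy-atom distance.
    """
    lig_xyz, _ = _heavy_coords(ligand.atoms)
    if lig_xyz.shape[0] == 0:
        raise ValueError(f"ligand {ligand.label} has no heavy atoms")
    out = []
    for chain in struct.chains:
        for res in chain.amino_residues():
            res_xyz, _ = _heavy_coords(res.atoms)
            if res_xyz.shape[0] == 0:
                continue
            d = float(cdist(res_xyz, lig_xyz).min())
            if d <= cutoff:
                out.append((res, d))
    out.sort(key=lambda t: t[1])
    return out


def hbond_contacts(
    struct: StructureModel, ligand: Residue, dmax: float = DEFAULT_HBOND_CUTOFF
) -> list[ContactRecord]:
    """Polar contacts between ligand N/O atoms and protein N/O atoms.

    Distance rule only.  A contact is classed ``ionic`` instead of ``hbond``
    when an Arg/Lys side-chain nitrogen meets an oxygen of a ligand that
    carries phosphorus or sulfur (phosphate/sulfate-type anion); everything
    else within ``dmax`` is ``hbond``.
    """
    lig_polar = [a for a in ligand.atoms if a.is_heavy and a.element.upper() in ("N", "O")]
    if not [a for a in ligand.atoms if a.is_heavy]:
        raise ValueError(f"ligand {ligand.label} has no heavy atoms")
    lig_has_ps = any(a.element.upper() in ("P", "S") for a in ligand.atoms)
    contacts: list[ContactRecord] = []
    for res, _ in pocket_residues(struct, ligand, cutoff=dmax):
        for ra in res.atoms:
            if not ra.is_heavy or ra.element.upper() not in ("N", "O"):
                continue
            for la in lig_polar:
                d = float(np.linalg.norm(ra.coords - la.coords))
                if d > dmax:
                    continue
                ionic = (
                    lig_has_ps
                    and la.element.upper() == "O"
                    and ra.name in _POSITIVE_SIDECHAIN_N.get(res.name3, ())
                )
                contacts.append(
                    ContactRecord(
                        residue=res,
                        residue_atom=ra.name,
                        ligand_atom=la.name,
                        distance=d,
                        contact_class="ionic" if ionic else "hbond",
                        via_backbone=ra.name in BACKBONE_ATOMS,
                    )
                )
    contacts.sort(key=lambda c: c.distance)
    return contacts


def metal_shell(
    struct: StructureModel, metal: Residue, cutoff: float = DEFAULT_SHELL_CUTOFF
) -> CoordinationShell:
    """First coordination shell of a metal site.

    Collects every N/O heavy atom within ``cutoff`` of the metal, from
    protein, ligands and waters alike, tagged with the kind of residue it
    belongs to.
    """
    if metal.kind != "metal":
        raise ValueError(f"{metal.label} is not classified as a metal site")
    center = metal.atoms[0]
    shell = CoordinationShell(center=center)
    for res in struct.all_residues():
        if res is metal:
            continue
        for a in res.atoms:
            if not a.is_heavy or a.element.upper() not in ("N", "O"):
                continue
            d = float(np.linalg.norm(a.coords - center.coords))
            if d <= cutoff:
                shell.ligands.append((a, d, res.kind))
    shell.ligands.sort(key=lambda t: t[1])
    return shell


def _ring_coords(ring: list[Atom] | dict[str, np.ndarray], which: str) -> np.ndarray:
    if isinstance(ring, dict):
        lookup = {k: np.asarray(v, float) for k, v in ring.items()}
    else:
        lookup = {a.name: a.coords for a in ring}
    try:
        return np.array([lookup[name] for name in RING_ATOM_NAMES])
    except KeyError as exc:
        raise ValueError(f"ring {which}: missing atom {exc.args[0]!r} (need C1..C6)") from exc


def _winding_normal(coords: np.ndarray, which: str) -> np.ndarray:
    """Best-fit plane normal, oriented by the C1->C2->...->C6 winding."""
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] / sv[0] < 1e-8:
        raise ValueError(f"ring {which}: atoms are collinear, no plane defined")
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    winding = np.zeros(3)
    for k in range(len(centered)):
        winding += np.cross(centered[k], centered[(k + 1) % len(centered)])
    if np.dot(normal, winding) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def ring_orientation_diff(
    ring_a: list[Atom] | dict[str, np.ndarray],
    ring_b: list[Atom] | dict[str, np.ndarray],
    frame: SuperpositionResult | None = None,
) -> RingOrientation:
    """Tilt and in-plane rotation between two six-membered rings.

    ``frame`` (a superposition of structure b onto structure a's frame, or
    None for identity) is applied to ring b first.  Tilt is the angle
    between the best-fit plane normals, folded to [0, 90].  Rotation is
    measured after aligning ring b's normal onto ring a's by the minimal
    rotation: it is the circular mean of the per-atom angular offsets about
    the common normal under the name-based C1<->C1 ... C6<->C6 pairing.
    """
    xa = _ring_coords(ring_a, "a")
    xb = _ring_coords(ring_b, "b")
    if frame is not None:
        xb = frame.apply(xb)

    na = _winding_normal(xa, "a")
    nb = _winding_normal(xb, "b")
    cos_t = float(np.clip(np.dot(na, nb), -1.0, 1.0))
    tilt_raw = np.degrees(np.arccos(cos_t))
    tilt = min(tilt_raw, 180.0 - tilt_raw)

    # Minimal rotation bringing ring b's normal onto ring a's (flip the
    # normal first if the rings are wound in opposite senses).
    if cos_t < 0:
        nb, cos_t = -nb, -cos_t
    axis = np.cross(nb, na)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        r_align = np.eye(3)
    else:
        axis = axis / s
        ang = np.arctan2(s, cos_t)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        r_align = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)

    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa - ca
    vb = (xb - cb) @ r_align.T

    # circular mean of per-atom angular offsets about the common normal
    sin_sum = cos_sum = 0.0
    for k in range(len(va)):
        pa = va[k] - np.dot(va[k], na) * na
        pb = vb[k] - np.dot(vb[k], na) * na
        ang = np.arctan2(np.dot(na, np.cross(pa, pb)), np.dot(pa, pb))
        sin_sum += np.sin(ang)
        cos_sum += np.cos(ang)
    rotation = np.degrees(np.arctan2(sin_sum, cos_sum)) % 360.0
    return RingOrientation(tilt_deg=float(tilt), rotation_deg=float(rotation))


def nearest_distance(
    group_a: list[Atom], group_b: list[Atom]
) -> tuple[float, tuple[Atom, Atom]]:
    """Minimum heavy-atom distance between two atom groups, with the pair."""
    xa, ha = _heavy_coords(group_a)
    xb, hb = _heavy_coords(group_b)
    if xa.shape[0] == 0 or xb.shape[0] == 0:
        raise ValueError("both atom groups must contain at least one heavy atom")
    d = cdist(xa, xb)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), (ha[int(i)], hb[int(j)])
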