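"""Synthetic structures, rings and sequences with planted ground truth.

Every generator takes an explicit seed and is bit-reproducible.  The
artifacts are deliberately simple — an ideal helical trace with one
pseudo-side-chain atom per residue, regular hexagon rings, uniform-random
sequence backgrounds — but each carries exactly the feature the
corresponding analysis stage measures (a planted contact distance, a metal
shell, a ring tilt/rotation, a key-residue signature), recorded in a
:class:`GroundTruth` sidecar so recovery can be scored without re-deriving
anything.

What these artifacts do NOT emulate: realistic side-chain rotamers,
secondary-structure packing, crystallographic disorder, or homolog
sequence divergence beyond independent uniform backgrounds.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .discovery import (
    DEFAULT_ACCEPTOR_SITE,
    DEFAULT_DONOR_DOMAIN,
    DEFAULT_KEY_POSITIONS,
    ReferenceAnnotation,
)
from .model_io import AMINO3TO1, Atom, ChainModel, Residue, StructureModel

__all__ = [
    "GroundTruth",
    "synth_structure",
    "perturb_structure",
    "synth_ring_pair",
    "synth_reference",
    "synth_signature_set",
    "insert_segment",
]

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {one: three for three, one in AMINO3TO1.items() if three not in ("MSE", "SEC", "PYL")}

# Planted reference layout (author numbering): the five key donor-site
# residues, the GRGD motif instance they sit in, the DXXE magnesium motif
# variant, and the seven acceptor-site residues.
_REFERENCE_PLANT = {
    11: "D", 76: "I", 78: "N", 89: "S", 116: "L", 141: "Q", 145: "R",
    171: "K", 173: "D", 176: "E", 204: "T",
    221: "F", 229: "R", 230: "A", 231: "G", 232: "R", 233: "G", 234: "D",
    266: "M",
}
_REFERENCE_LENGTH = 300

# Residues are considered "planted" (never resampled) at these positions;
# everywhere else the background is resampled until no accidental GXGD-like
# motif appears outside the planted site.
_GXGD_RE = re.compile(r"(?=(G[A-Z]GD))")


@dataclass
class GroundTruth:
    kind: str      # superposition | ring | contacts | shell | signature | screen
    payload: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "payload": self.payload}, indent=2, default=_jsonable)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _helix_ca(n: int, rng: np.random.Generator) -> np.ndarray:
    """Helical Calpha trace along z (radius 2.3 A, rise 1.5 A, 100 deg/res).

    A small seeded jitter (0.4 A per coordinate) breaks the exact screw
    self-symmetry of the ideal helix, which would otherwise make residue
    correspondence ambiguous under register shifts.
    """
    i = np.arange(n)
    theta = np.radians(100.0) * i
    ideal = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    return ideal + rng.normal(scale=0.4, size=ideal.shape)


def synth_structure(
    n_residues: int,
    *,
    ligand_atoms: int = 4,
    plant_metal: bool = False,
    n_waters: int = 6,
    water_radius: float = 2.1,
    pocket_residue: int | None = None,
    pocket_distance: float | None = None,
    seed: int = 0,
) -> tuple[StructureModel, GroundTruth]:
    """Helical chain with optional planted ligand, metal shell and pocket contact.

    The chain is an ideal helix of ``n_residues`` Calpha atoms, each with
    one pseudo-side-chain atom ("CB") 2.4 A radially outward.  Optional
    plants, all with exact recorded geometry:

    * a ligand ("LIG", ``ligand_atoms`` oxygen atoms ~1.5 A apart).  When
      ``pocket_residue``/``pocket_distance`` are given the ligand is placed
      so its nearest atom sits exactly ``pocket_distance`` from that
      residue's side-chain atom (and > 6 A from every other residue);
      otherwise it sits 20 A off the helix axis.
    * a magnesium site with ``n_waters`` waters on octahedral axes at
      ``water_radius``, far from everything else.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    if pocket_distance is not None and pocket_distance < 1.0:
        raise ValueError("planted pocket distance below 1 A is infeasible")
    rng = np.random.default_rng(seed)
    ca = _helix_ca(n_residues, rng)
    axis_xy = ca[:, :2]

    chain = ChainModel(id="A")
    serial = 1
    names = rng.choice(list(AMINO20), size=n_residues)
    for i in range(n_residues):
        radial = np.array([*axis_xy[i], 0.0])
        radial[:2] /= np.linalg.norm(radial[:2])
        cb = ca[i] + 2.4 * radial
        res = Residue(
            chain_id="A", number=i + 1, icode="", name3=_ONE_TO_THREE.get(names[i], "ALA"),
            kind="amino_acid",
        )
        res.atoms.append(Atom(serial, "CA", "C", ca[i].copy()))
        serial += 1
        res.atoms.append(Atom(serial, "CB", "C", cb))
        serial += 1
        chain.residues.append(res)

    model = StructureModel(id=f"synth{seed}", chains=[chain])
    truth = GroundTruth(kind="contacts", payload={"seed": seed, "n_residues": n_residues})

    if ligand_atoms > 0:
        if pocket_residue is not None and pocket_distance is not None:
            target = chain.residues[pocket_residue - 1].get_atom("CB")
            direction = np.array([*axis_xy[pocket_residue - 1], 0.0])
            direction[:2] /= np.linalg.norm(direction[:2])
            anchor = target.coords + pocket_distance * direction
            # remaining ligand atoms extend outward, away from the chain
            offsets = [anchor + (1.5 * (k + 1)) * direction for k in range(ligand_atoms - 1)]
            coords = [anchor, *offsets]
            truth.payload["pocket_residue"] = pocket_residue
            truth.payload["pocket_distance"] = pocket_distance
        else:
            base = np.array([20.0, 0.0, float(np.median(ca[:, 2]))])
            coords = [base + np.array([1.5 * k, 0.0, 0.0]) for k in range(ligand_atoms)]
        lig = Residue(chain_id="A", number=901, icode="", name3="LIG", kind="ligand")
        for k, xyz in enumerate(coords):
            lig.atoms.append(Atom(serial, f"O{k + 1}", "O", np.asarray(xyz)))
            serial += 1
        model.hetero.append(lig)

    if plant_metal:
        center = np.array([-25.0, 0.0, float(np.median(ca[:, 2]))])
        mg = Residue(chain_id="A", number=902, icode="", name3="MG", kind="metal")
        mg.atoms.append(Atom(serial, "MG", "MG", center.copy()))
        serial += 1
        model.hetero.append(mg)
        # random orthonormal frame -> octahedral water directions
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        dirs = [q[:, 0], -q[:, 0], q[:, 1], -q[:, 1], q[:, 2], -q[:, 2]][:n_waters]
        for k, d in enumerate(dirs):
            wat = Residue(chain_id="A", number=910 + k, icode="", name3="HOH", kind="water")
            wat.atoms.append(Atom(serial, "O", "O", center + water_radius * d))
            serial += 1
            model.hetero.append(wat)
        truth.payload["metal"] = {
            "coordination_number": len(dirs),
            "radius": water_radius,
            "octahedral": True,
        }
    return model, truth


def perturb_structure(s: StructureModel, sigma: float, seed: int = 0) -> StructureModel:
    """Copy with i.i.d. Gaussian noise of scale ``sigma`` on every coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(s)
    for res in out.all_residues():
        for atom in res.atoms:
            atom.coords = atom.coords + rng.normal(scale=sigma, size=3) if sigma > 0 else atom.coords
    return out


def _rotation_about(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def synth_ring_pair(
    tilt: float, rotation: float, seed: int = 0, radius: float = 1.46
) -> tuple[list[Atom], list[Atom], GroundTruth]:
    """Two coincident regular hexagons differing by exactly (tilt, rotation).

    Ring a is a regular hexagon C1..C6 in a random (seeded) orientation;
    ring b is the copy rotated by ``rotation`` degrees about ring a's plane
    normal (counter-clockwise viewed down the normal) and then tilted by
    ``tilt`` degrees about an in-plane axis.  Centers coincide.
    """
    if not 0.0 <= tilt <= 90.0:
        raise ValueError("tilt must lie in [0, 90]")
    if not 0.0 <= rotation < 360.0:
        raise ValueError("rotation must lie in [0, 360)")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    e1, e2, normal = q[:, 0], q[:, 1], q[:, 2]
    center = rng.normal(scale=5.0, size=3)

    ang = np.radians(60.0 * np.arange(6))
    ring_a_xyz = center + radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
    # winding C1->C6 is counter-clockwise about +normal by construction
    r_spin = _rotation_about(normal, rotation)
    r_tilt = _rotation_about(e1, tilt)
    ring_b_xyz = center + (ring_a_xyz - center) @ (r_tilt @ r_spin).T

    ring_a = [Atom(k + 1, f"C{k + 1}", "C", ring_a_xyz[k]) for k in range(6)]
    ring_b = [Atom(k + 11, f"C{k + 1}", "C", ring_b_xyz[k]) for k in range(6)]
    truth = GroundTruth(kind="ring", payload={"tilt": tilt, "rotation": rotation, "seed": seed})
    return ring_a, ring_b, truth


def _background(rng: np.random.Generator, length: int, planted: dict[int, str]) -> str:
    """Random sequence honouring ``planted`` {1-based pos: residue}.

    Any GXGD-type motif occurrence not fully contained in the planted
    positions is broken by resampling a free position, so motif ground
    truth stays unambiguous.
    """

    def _accidental(s: str) -> list[int]:
        out = []
        for m in _GXGD_RE.finditer(s):
            start = m.start() + 1
            if any((start + off) not in planted for off in range(4)):
                out.append(start)
        return out

    for _ in range(200):
        seq = list(rng.choice(list(AMINO20), size=length))
        for pos, res in planted.items():
            seq[pos - 1] = res
        hits = _accidental("".join(seq))
        if not hits:
            return "".join(seq)
        # surgically break each accidental motif at a free position
        for start in hits:
            for off in range(4):
                if (start + off) not in planted:
                    seq[start + off - 1] = str(rng.choice(list("AEHNQ")))
                    break
        if not _accidental("".join(seq)):
            return "".join(seq)
    raise RuntimeError("could not generate a motif-clean background")


def synth_reference(seed: int = 7) -> ReferenceAnnotation:
    """Synthetic stand-in reference annotation.

    Carries the reference enzyme's key residues, motif context and
    acceptor-site residues at the correct author positions over a random
    background; it is NOT the real protein sequence.
    """
    rng = np.random.default_rng(seed)
    seq = _background(rng, _REFERENCE_LENGTH, _REFERENCE_PLANT)
    return ReferenceAnnotation(
        sequence=seq,
        offset=1,
        donor_domain=DEFAULT_DONOR_DOMAIN,
        key_positions=DEFAULT_KEY_POSITIONS,
        acceptor_site=dict(DEFAULT_ACCEPTOR_SITE),
    )


_BREAKABLE_RULES = (171, 221, 229, 232, 266)


def _mutate_background(
    rng: np.random.Generator, base: str, planted: dict[int, str], rate: float
) -> str:
    """Homolog-like copy of ``base``: planted positions fixed, free positions
    mutated with probability ``rate``, accidental GXGD-type motifs broken."""
    seq = list(base)
    for pos, res in planted.items():
        seq[pos - 1] = res
    for i in range(len(seq)):
        if (i + 1) in planted:
            continue
        if rng.random() < rate:
            choices = [c for c in AMINO20 if c != seq[i]]
            seq[i] = str(rng.choice(choices))

    def _accidental(s: str) -> list[int]:
        return [
            m.start() + 1
            for m in _GXGD_RE.finditer(s)
            if any((m.start() + 1 + off) not in planted for off in range(4))
        ]

    for _ in range(50):
        hits = _accidental("".join(seq))
        if not hits:
            return "".join(seq)
        for start in hits:
            for off in range(4):
                if (start + off) not in planted:
                    seq[start + off - 1] = str(rng.choice(list("AEHNQ")))
                    break
    raise RuntimeError("could not generate a motif-clean homolog")


def synth_signature_set(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    divergence: float = 0.3,
    acceptor_substitutions: dict[int, str] | None = None,
) -> tuple[list[tuple[str, str, str]], ReferenceAnnotation, list[dict[str, Any]]]:
    """Labelled homolog set for the screening pipeline.

    Candidates are homolog-like copies of the synthetic reference: free
    positions mutate independently with probability ``divergence`` (default
    0.3, i.e. ~70% sequence identity, a typical within-family distance),
    while planted positions are fixed.  Positives carry the full
    five-residue signature (K/F/R/R/M at the 171/221/229/232/266-
    equivalents) inside an intact RXGRGD context plus the reference
    acceptor residues (or ``acceptor_substitutions``).  Each negative
    breaks exactly one key-residue rule (mutated to alanine), cycling
    through the five rules.  Returns (FASTA records, reference annotation,
    labels); labels record the planted class and, for negatives, the broken
    rule.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ref = synth_reference(seed=7)
    records: list[tuple[str, str, str]] = []
    labels: list[dict[str, Any]] = []

    plant = dict(_REFERENCE_PLANT)
    if acceptor_substitutions:
        plant.update(acceptor_substitutions)

    for i in range(n_pos):
        seq = _mutate_background(rng, ref.sequence, plant, divergence)
        rid = f"pos{i + 1:03d}"
        records.append((rid, "planted full signature", seq))
        labels.append({"id": rid, "label": "PPi", "broken_rule": None})

    for i in range(n_neg):
        broken = _BREAKABLE_RULES[i % len(_BREAKABLE_RULES)]
        neg_plant = dict(plant)
        neg_plant[broken] = "A"
        seq = _mutate_background(rng, ref.sequence, neg_plant, divergence)
        rid = f"neg{i + 1:03d}"
        records.append((rid, f"rule {broken} broken", seq))
        labels.append({"id": rid, "label": "broken", "broken_rule": broken})

    return records, ref, labels


def insert_segment(seq: str, at: int, length: int, seed: int = 0) -> str:
    """Insert ``length`` random residues before 1-based position ``at``.

    Used to check that alignment-based position mapping shifts planted
    sites by exactly the insertion length.
    """
    rng = np.random.default_rng(seed)
    ins = "".join(rng.choice(list("AEHNQ"), size=length))
    return seq[: at - 1] + ins + seq[at - 1:]
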