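#!/usr/bin/env python
"""Structural measurements on user-supplied PDB entries.

Reproduces, from locally supplied coordinate files, the published
measurements on the PPi-dependent inositol kinase structures:

* chain A vs chain B superposition of the PCP complex (5YSP): expected
  ~0.6 A over ~274 Calpha pairs;
* structure-based alignment of the PCP complex against the ATP-dependent
  homolog (4XF7) or the unliganded structure (1VK4): the published
  cross-family comparison reports 2.2 A over 254 Calpha atoms (computed
  there with Dali, whose trimming differs from the iterative superposition
  used here, so both untrimmed and trimmed values are printed);
* pocket residues around PCP, the Mg coordination shell, the catalytic
  distances to the inositol O1 hydroxyl, and the inositol ring
  tilt/rotation between the two enzymes.

The files are NOT downloaded: pass paths to local copies, e.g.

    python analysis/05_accession_structures.py --pcp 5ysp.pdb --mi3k 4xf7.pdb
"""

import argparse
from pathlib import Path

from ppisig.model_io import read_pdb
from ppisig.pocket import (
    hbond_contacts,
    metal_shell,
    nearest_distance,
    pocket_residues,
    ring_orientation_diff,
)
from ppisig.superpose import structure_alignment


def load(path):
    return read_pdb(Path(path).read_text(), structure_id=Path(path).stem)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pcp", help="PCP-complex structure (e.g. 5YSP), PDB format")
    ap.add_argument("--mi3k", help="ATP-dependent homolog substrate complex (e.g. 4XF7)")
    ap.add_argument("--apo", help="unliganded structure (e.g. 1VK4)")
    args = ap.parse_args()
    if not args.pcp:
        ap.error("at least --pcp is required")

    pcp = load(args.pcp)
    chain_a = pcp.chain("A")

    if len(pcp.chains) > 1:
        chain_b = pcp.chains[1]
        corr, sup = structure_alignment(chain_a, chain_b)
        print(f"[{pcp.id}] chain A vs {chain_b.id}: rmsd {sup.rmsd:.2f} A over {sup.n_pairs} pairs "
              f"({len(sup.rejected)} trimmed)")

    for lig in pcp.hetero_by_name("PCP", chain_id="A") or pcp.hetero_by_name("PCP"):
        print(f"\npocket residues within 4.0 A of {lig.label}:")
        for res, d in pocket_residues(pcp, lig, 4.0):
            print(f"  {res.label:>12s}  {d:5.2f} A")
        for cutoff in (3.7, 4.0, 4.3):
            names = sorted({r.number for r, _ in pocket_residues(pcp, lig, cutoff)})
            print(f"  at {cutoff:.1f} A: residues {names}")

    for mg in [r for r in pcp.hetero if r.kind == "metal" and r.name3 == "MG"]:
        shell = metal_shell(pcp, mg, 2.8)
        kinds = [kind for _, _, kind in shell.ligands]
        print(f"\n{mg.label} shell: CN {shell.coordination_number} "
              f"({kinds.count('water')} waters, {kinds.count('ligand')} ligand O), "
              f"octahedricity {shell.octahedricity:.1f} deg")

    inositols = pcp.hetero_by_name("INS", chain_id="A") or pcp.hetero_by_name("INS")
    if inositols:
        ins = inositols[0]
        o1 = [a for a in ins.atoms if a.name == "O1"]
        asp234 = [r for r in chain_a.amino_residues() if r.number == 234]
        if o1 and asp234:
            carboxy = [a for a in asp234[0].atoms if a.name in ("OD1", "OD2", "CG")]
            d, pair = nearest_distance(carboxy, o1)
            print(f"\nD234 carboxylate .. inositol O1: {d:.1f} A ({pair[0].name})")
        pcp_lig = pcp.hetero_by_name("PCP", chain_id="A") or pcp.hetero_by_name("PCP")
        if o1 and pcp_lig:
            d_all, pair = nearest_distance(pcp_lig[0].atoms, o1)
            print(f"PCP nearest atom .. inositol O1: {d_all:.1f} A ({pair[0].name}); "
                  f"proximal phosphoryl is the one containing {pair[0].name}")
            p_atoms = [a for a in pcp_lig[0].atoms if a.element.upper() == "P"]
            if p_atoms:
                d_p, pair_p = nearest_distance(p_atoms, o1)
                print(f"PCP nearest P .. inositol O1: {d_p:.1f} A ({pair_p[0].name})")

    if args.mi3k:
        mi3k = load(args.mi3k)
        corr, sup = structure_alignment(chain_a, mi3k.chains[0])
        print(f"\n[{pcp.id}] vs [{mi3k.id}]: rmsd {sup.rmsd:.2f} A over {sup.n_pairs} pairs "
              f"({len(sup.rejected)} trimmed)")
        ins_b = mi3k.hetero_by_name("INS")
        if inositols and ins_b:
            inv = type(sup)(sup.rotation.T, -sup.rotation.T @ sup.translation, sup.rmsd, sup.n_pairs)
            ro = ring_orientation_diff(inositols[0].atoms, ins_b[0].atoms, frame=inv)
            print(f"inositol ring: tilt {ro.tilt_deg:.1f} deg, rotation {ro.rotation_deg:.1f} deg")

    if args.apo:
        apo = load(args.apo)
        corr, sup = structure_alignment(chain_a, apo.chains[0])
        print(f"\n[{pcp.id}] vs [{apo.id}]: rmsd {sup.rmsd:.2f} A over {sup.n_pairs} pairs")


if __name__ == "__main__":
    main()
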