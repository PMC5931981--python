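# Methods

## Scope and model

The package reconstructs, as testable computations, the chain of evidence
by which a PPi-dependent member of the ribokinase family can be recognised
and new members predicted:

1. **Rigid-body comparison** of family structures (Cα superposition with
   outlier trimming) and a structure-guided residue correspondence that
   substitutes for a structure-based sequence alignment.
2. **Donor- and acceptor-site geometry**: which residues line the
   pyrophosphate-analog pocket, how the catalytic magnesium is
   coordinated, how far the catalytic aspartate and the proximal
   phosphoryl group sit from the acceptor hydroxyl, and how the acceptor
   ring is reoriented between homologs (tilt and in-plane rotation).
3. **A rule-based signature** for phosphate-donor classification: five key
   residues (K171, F221, R229, R232, M266 in reference author numbering),
   the GXGD second-residue size rule (small → ATP, Ile/Leu → ADP,
   Arg → PPi), and the extended RXGRGD motif required for a PPi call.
4. **A screening pipeline** that aligns candidate homologs to the
   annotated reference, maps the key positions through the alignment,
   evaluates the signature, and compares the seven annotated
   acceptor-site positions.

## Parameters that matter

| parameter | default | why |
| --- | --- | --- |
| pair cutoff (residue correspondence) | 3.8 Å | conventional Cα–Cα contact scale |
| reject cutoff (trimming) | 3.5 Å | Cα deviation beyond which a pair is not considered equivalent |
| pocket cutoff | 4.0 Å | standard heavy-atom contact heuristic |
| H-bond cutoff | 3.5 Å | donor–acceptor heavy-atom distance; no angle term (no hydrogens in the input structures) |
| metal-shell cutoff | 2.8 Å | first-shell O/N coordination distance for Mg²⁺ and the common monovalent cations |
| alignment scoring | BLOSUM62, gap open 11 / extend 1 | BLAST-like defaults, matching how such candidate sets are usually retrieved |
| donor-domain coverage threshold | 0.8 | the screen is keyed on the donor domain (author positions 169–286); fragments that do not span it cannot be classified |
| signature mode | strict | the discriminative claim is about the literal five residues; a relaxed mode (basic / bulky-hydrophobic classes) is provided for exploratory screens |

All cutoffs are keyword arguments; nothing is hard-wired.

## Numerical choices

* **Superposition** is the Kabsch least-squares fit via
  `scipy.spatial.transform.Rotation.align_vectors`, which restricts to
  proper rotations (det +1); collinear point sets are rejected as
  degenerate.  `trimmed_superpose` applies the documented batch rule
  (reject everything beyond the cutoff, refit, repeat).  Inside the
  iterative `structure_alignment`, the per-cycle fit instead discards the
  single worst pair at a time until all deviations pass: a
  sequence-alignment seed between diverged homologs can contain a minority
  of wildly wrong pairs that dominate a batch least-squares frame and
  would otherwise reject everything.
* **Residue correspondence** pairs mutual nearest Cα atoms within the pair
  cutoff, then keeps the longest order-preserving subset (O(k²) longest
  increasing subsequence; ties broken by the smaller summed pair distance,
  making the result deterministic).
* **Ring orientation**: each ring's plane is the best-fit plane (smallest
  singular direction of the centered atoms) with its normal oriented by
  the C1→C2→…→C6 winding.  Tilt is the angle between the two normals,
  folded to [0°, 90°].  Rotation is measured after mapping ring b's plane
  onto ring a's by the minimal rotation between normals: it is the
  circular mean of per-atom angular offsets about the common normal under
  the name-based C1↔C1…C6↔C6 pairing, with counter-clockwise (viewed down
  ring a's normal) positive.  This definition is exactly inverse to the
  generator's spin-then-tilt construction, so planted angles are recovered
  to machine precision; it also gives the antisymmetry rotation(a,b) ≡
  −rotation(b,a) (mod 360°).
* **Octahedricity** is the RMS deviation from 90° of the cis
  ligand–metal–ligand angles (angles nearer 180° are treated as trans
  pairs and excluded); it is invariant under rigid motion and ligand
  order.
* **Masses** use the most-abundant-isotope table bundled with pyteomics;
  the [M−H]⁻ m/z is the neutral monoisotopic mass minus a hydrogen atom
  plus an electron (i.e. minus a proton), since the anion keeps the
  hydrogen's electron.
* **Alternate locations**: the first altloc encountered per atom name is
  kept.  Author residue numbering is preserved end to end — all annotated
  positions are author numbers.
* **Degenerate inputs**: empty FASTA streams yield empty lists; a ligand
  without heavy atoms, collinear rings, all-pairs-trimmed superpositions
  and out-of-range mapped positions raise errors; an unmapped key position
  is not an error but marks the profile incomplete (such a profile can
  never be classified PPi).

## Synthetic data: what it does and does not emulate

The generators produce artifacts whose ground truth is exact by
construction, recorded in a `GroundTruth` sidecar:

* **Structures** are helical Cα traces (radius 2.3 Å, rise 1.5 Å/residue,
  100°/residue) with one pseudo-side-chain atom per residue 2.4 Å radially
  outward, plus optional planted features: a ligand whose nearest atom
  sits at an exact distance from a chosen residue, and a magnesium site
  with an exact octahedral water shell.  A small seeded jitter (0.4 Å per
  coordinate) is added to the trace because a mathematically ideal helix
  has an exact screw self-symmetry, which makes residue correspondence
  ambiguous under register shifts — a degeneracy real protein folds do not
  have.
* **Ring pairs** are regular hexagons differing by exactly the requested
  (tilt, rotation) about controlled axes, in a random common orientation.
* **Sequence sets** are homolog-like descendants of a synthetic reference:
  planted positions (key residues, motif context, acceptor site) are held
  fixed while free positions mutate independently (default 30% per site,
  i.e. ~70% identity — a typical within-family distance).  Purely
  independent random backgrounds would defeat alignment-based position
  mapping, which presumes common ancestry; mutated copies keep the mapping
  faithful while still randomising everything that is not planted.  Any
  GXGD-type motif arising by chance outside the planted site is broken by
  resampling a free position, so motif ground truth is unambiguous.
  Negatives each break exactly one named key-residue rule (to alanine).

Because the backgrounds are uniform and indels are only introduced where a
test plants them, passing these tests demonstrates the correctness of the
algorithms and rules, not robustness to real evolutionary divergence
(compositional bias, repeats, long indels, domain rearrangements).

The bundled reference annotation
(`ppisig/data/tm0415_reference_synthetic.yaml`) is a synthetic stand-in of
this kind: correct author-numbered landmarks over a generated background,
not the real protein sequence.  Users reproduce real-sequence screens by
supplying their own YAML in the same layout.

## Design choices where the design was open

* **Donor classification order**: the PPi rule (five residues + RXGRGD) is
  checked first; only when it fails does the GXGD second residue decide
  ATP vs ADP; everything else is indeterminate.  Classification is
  rule-based on purpose — no profile/HMM scoring — because the claim being
  operationalised is about a small set of literal residues.
* **NXXE/DXXE**: the magnesium-binding motif variant is reported but never
  used for classification, since the Asn→Asp substitution also occurs in
  ATP-dependent members and is likely unrelated to donor choice.
* **Acceptor-site verdict**: "conserved" is operationalised as identity at
  all seven annotated positions; the per-position detail is always emitted
  so users can re-score under weaker criteria.
* **Ionic vs H-bond classing** is by identity tables (Arg/Lys side-chain
  nitrogens against oxygens of P/S-bearing ligands), not charge
  calculation.
* **Lid-size classes** come from user-supplied strand/helix counts;
  assigning secondary structure from coordinates is out of scope, and
  off-table count combinations map to the nearest landmark class with an
  explicit note.
* **Structure-based alignment** is an iterative superposition, not a
  distance-matrix (Dali-style) alignment; on distant folds whose
  equivalence is not rigid the pair counts can differ from Dali's by a few
  percent, which is why the accession driver prints both trimmed and
  untrimmed values.

## Problem sizes

Test and acceptance runs use synthetic problems sized for exactness and
statistical stability: 4-point sets against a brute-force rotation-grid
oracle; N = 2000 atoms for the σ√3 noise law (sampling error ≈ 1.3%,
asserted at 5%); 10,000-mers for motif-scan oracle equivalence; alignment
oracle checks exhaustive to length 2 and randomised to length 7; screening
sets of 10 and 200 labelled candidates of length ~300.

## Known limitations

* PDB-format input only (no mmCIF), single model, no symmetry expansion.
* Hydrogens, if present, are carried but ignored by all geometry.
* No flexible superposition, TM-score, or Dali scoring.
* The screen consumes a user-provided FASTA; database retrieval (and hence
  database-dependent hit counts) is outside the package.
* Hit/conservation verdicts depend on the annotated position set; sites
  interacting through backbone atoms only are invisible to the
  sequence-level acceptor comparison.
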