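"""Homolog screening: alignment, position mapping, and donor classification.

Given an annotated reference enzyme (sequence in author numbering, the
donor-domain interval, the five key donor-site positions and the
acceptor-site positions) and a FASTA of candidate homologs, each candidate
is globally aligned to the reference, the key positions are mapped through
the alignment, the donor-specificity signature is evaluated, and the
acceptor-binding site is compared residue by residue.  The output is a
per-candidate record set plus summary counts.

Pairwise alignment is a BLAST-flavoured global alignment (BLOSUM62,
affine gaps 11/1) computed with Biopython's PairwiseAligner.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .signature import (
    DonorClass,
    LidClass,
    MotifHit,
    RuleResult,
    SignatureProfile,
    classify_donor,
    evaluate_signature,
)

__all__ = [
    "AlignmentResult",
    "ReferenceAnnotation",
    "AcceptorSiteComparison",
    "CandidateRecord",
    "ScreenReport",
    "ScreenConfig",
    "global_align",
    "map_reference_positions",
    "compare_acceptor_site",
    "screen_candidates",
    "write_report",
    "read_report_json",
    "load_reference",
    "default_reference_path",
]

logger = logging.getLogger(__name__)

_ALIGN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX")

DEFAULT_DONOR_DOMAIN = (169, 286)
DEFAULT_KEY_POSITIONS = (171, 221, 229, 232, 266)
DEFAULT_ACCEPTOR_SITE = {11: "D", 76: "I", 78: "N", 89: "S", 116: "L", 141: "Q", 145: "R"}


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    map_ab: dict[int, int | None] = field(default_factory=dict)
    map_ba: dict[int, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.map_ab:
            self._build_maps()

    def _build_maps(self) -> None:
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            if ca != "-":
                self.map_ab[ia] = ib if cb != "-" else None
            if cb != "-":
                self.map_ba[ib] = ia if ca != "-" else None


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # convention: a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences, affine gaps.

    Gap cost convention is BLAST-like: a run of k gap characters costs
    ``gap_open + k * gap_extend``.  The first optimal alignment in
    Biopython's deterministic traversal order is returned.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    bad = (set(a) | set(b)) - _ALIGN_ALPHABET
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alns = aligner.align(a, b)
    top = alns[0]
    return AlignmentResult(aligned_a=str(top[0]), aligned_b=str(top[1]), score=float(alns.score))


@dataclass
class ReferenceAnnotation:
    """Annotated reference enzyme, in author numbering.

    ``offset`` is the author number of the first residue of ``sequence``.
    ``acceptor_site`` maps author positions of acceptor-binding residues to
    the reference residue expected there.
    """

    sequence: str
    offset: int = 1
    donor_domain: tuple[int, int] = DEFAULT_DONOR_DOMAIN
    key_positions: tuple[int, ...] = DEFAULT_KEY_POSITIONS
    acceptor_site: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ACCEPTOR_SITE))

    def __post_init__(self) -> None:
        last = self.offset + len(self.sequence) - 1
        for pos in (*self.key_positions, *self.acceptor_site, *self.donor_domain):
            if not self.offset <= pos <= last:
                raise ValueError(
                    f"annotated position {pos} outside sequence range "
                    f"[{self.offset}, {last}]"
                )
        for pos, res in self.acceptor_site.items():
            actual = self.residue_at(pos)
            if actual != res:
                raise ValueError(
                    f"acceptor annotation {res}{pos} disagrees with sequence ({actual})"
                )

    def index_of(self, author_pos: int) -> int:
        """1-based index in ``sequence`` of an author position."""
        return author_pos - self.offset + 1

    def residue_at(self, author_pos: int) -> str:
        return self.sequence[self.index_of(author_pos) - 1]


def load_reference(path: str | Path) -> ReferenceAnnotation:
    """Load a reference annotation from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ReferenceAnnotation(
        sequence=data["sequence"].replace("\n", "").strip().upper(),
        offset=int(data.get("offset", 1)),
        donor_domain=tuple(data.get("donor_domain", DEFAULT_DONOR_DOMAIN)),
        key_positions=tuple(data.get("key_positions", DEFAULT_KEY_POSITIONS)),
        acceptor_site={int(k): v for k, v in data.get(
            "acceptor_site", DEFAULT_ACCEPTOR_SITE).items()},
    )


def default_reference_path() -> Path:
    """Path of the bundled synthetic reference annotation.

    The bundled file is a synthetic stand-in: it carries the reference
    enzyme's key and acceptor residues at the correct author positions over
    a generated background, not the real protein sequence (which users can
    supply in the same YAML layout).
    """
    return Path(__file__).parent / "data" / "tm0415_reference_synthetic.yaml"


def map_reference_positions(
    aln: AlignmentResult, positions: Iterable[int], offset: int
) -> dict[int, int | None]:
    """Map reference author positions through an alignment to target positions.

    ``aln`` must be reference-vs-target; ``offset`` is the author number of
    the reference sequence's first residue.  Positions aligned to a gap map
    to None.
    """
    n_ref = len(aln.aligned_a.replace("-", ""))
    out: dict[int, int | None] = {}
    for pos in positions:
        idx = pos - offset + 1
        if not 1 <= idx <= n_ref:
            raise ValueError(f"author position {pos} outside the reference range")
        out[pos] = aln.map_ab[idx]
    return out


@dataclass
class AcceptorSiteComparison:
    positions: list[tuple[int, str, str | None, bool]]  # (ref pos, ref res, observed or None, identical)
    verdict: str                                        # conserved | divergent
    substitutions: list[str] = field(default_factory=list)


def compare_acceptor_site(
    ref: ReferenceAnnotation, candidate: str, aln: AlignmentResult
) -> AcceptorSiteComparison:
    """Residue-by-residue comparison of the acceptor-binding site.

    The verdict is ``conserved`` only when every annotated acceptor
    position is identical in the candidate; any substitution or gap makes
    it ``divergent``.  Substitutions are reported in ``X<refpos>Y``
    notation (gap as ``X<refpos>-``).
    """
    candidate = candidate.upper()
    mapped = map_reference_positions(aln, ref.acceptor_site, ref.offset)
    rows: list[tuple[int, str, str | None, bool]] = []
    subs: list[str] = []
    for pos in sorted(ref.acceptor_site):
        ref_res = ref.acceptor_site[pos]
        tgt = mapped[pos]
        obs = candidate[tgt - 1] if tgt is not None else None
        same = obs == ref_res
        rows.append((pos, ref_res, obs, same))
        if not same:
            subs.append(f"{ref_res}{pos}{obs if obs is not None else '-'}")
    verdict = "conserved" if all(r[3] for r in rows) else "divergent"
    return AcceptorSiteComparison(positions=rows, verdict=verdict, substitutions=subs)


@dataclass
class ScreenConfig:
    min_coverage: float = 0.8
    mode: str = "strict"          # key-residue mode for donor classification
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass
class CandidateRecord:
    id: str
    length: int
    coverage: float                               # donor-domain coverage fraction
    identity: float                               # fractional identity over aligned donor domain
    profile: SignatureProfile | None
    donor_class: DonorClass
    acceptor: AcceptorSiteComparison | None
    lid: LidClass | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class ScreenReport:
    records: list[CandidateRecord]

    @property
    def n_input(self) -> int:
        return len(self.records)

    @property
    def n_ppi(self) -> int:
        return sum(1 for r in self.records if r.donor_class.value == "PPi")

    @property
    def n_conserved(self) -> int:
        return sum(1 for r in self.records if r.acceptor and r.acceptor.verdict == "conserved")

    @property
    def n_divergent(self) -> int:
        return sum(1 for r in self.records if r.acceptor and r.acceptor.verdict == "divergent")

    def summary(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_ppi": self.n_ppi,
            "n_conserved": self.n_conserved,
            "n_divergent": self.n_divergent,
        }


def _donor_domain_stats(
    ref: ReferenceAnnotation, candidate: str, aln: AlignmentResult
) -> tuple[float, float]:
    lo, hi = ref.donor_domain
    positions = range(lo, hi + 1)
    mapped = map_reference_positions(aln, positions, ref.offset)
    n = len(list(positions))
    covered = [p for p in positions if mapped[p] is not None]
    coverage = len(covered) / n
    if not covered:
        return 0.0, 0.0
    ident = sum(
        1 for p in covered if candidate[mapped[p] - 1] == ref.residue_at(p)
    ) / len(covered)
    return coverage, ident


def screen_candidates(
    ref: ReferenceAnnotation,
    candidates: Sequence[tuple[str, str, str]],
    config: ScreenConfig | None = None,
) -> ScreenReport:
    """Screen candidate homologs for the PPi-dependence signature.

    ``candidates`` are ``(id, description, sequence)`` records.  Candidates
    whose alignment covers less than ``config.min_coverage`` of the
    reference donor domain are flagged ``low_coverage`` and left
    unclassified.  Malformed records are flagged and skipped, never fatal.
    """
    config = config or ScreenConfig()
    records: list[CandidateRecord] = []
    for rid, _desc, seq in candidates:
        try:
            aln = global_align(ref.sequence, seq, config.matrix, config.gap_open, config.gap_extend)
        except ValueError as exc:
            logger.warning("candidate %s skipped: %s", rid, exc)
            records.append(
                CandidateRecord(
                    id=rid, length=len(seq), coverage=0.0, identity=0.0,
                    profile=None, donor_class=DonorClass("indeterminate", [str(exc)]),
                    acceptor=None, flags=["malformed"],
                )
            )
            continue
        coverage, identity = _donor_domain_stats(ref, seq, aln)
        if coverage < config.min_coverage:
            logger.info("candidate %s: donor-domain coverage %.2f below threshold", rid, coverage)
            records.append(
                CandidateRecord(
                    id=rid, length=len(seq), coverage=coverage, identity=identity,
                    profile=None,
                    donor_class=DonorClass("indeterminate", ["donor domain coverage below threshold"]),
                    acceptor=None, flags=["low_coverage"],
                )
            )
            continue
        key_map = map_reference_positions(aln, ref.key_positions, ref.offset)
        profile = evaluate_signature(seq, key_map)
        donor = classify_donor(profile, mode=config.mode)
        acceptor = compare_acceptor_site(ref, seq, aln)
        flags = ["incomplete_map"] if profile.incomplete else []
        records.append(
            CandidateRecord(
                id=rid, length=len(seq), coverage=coverage, identity=identity,
                profile=profile, donor_class=donor, acceptor=acceptor, flags=flags,
            )
        )
        logger.info(
            "candidate %s: coverage %.2f identity %.2f donor %s acceptor %s",
            rid, coverage, identity, donor.value,
            acceptor.verdict if acceptor else "-",
        )
    return ScreenReport(records=records)


_TSV_COLUMNS = [
    "id", "length", "coverage", "identity_donor_domain",
    "rule_K171", "rule_F221", "rule_R229", "rule_R232", "rule_M266",
    "gxgd", "gxgd_second", "rxgrgd", "nxxe_variant",
    "donor_class", "acceptor_verdict", "acceptor_substitutions", "flags",
]


def _rule_cell(profile: SignatureProfile | None, pos: int) -> str:
    if profile is None:
        return "-"
    r = profile.rule(pos)
    if not r.resolved:
        return "unmapped"
    return f"{r.observed}:{'pass' if r.strict_pass else ('relaxed' if r.relaxed_pass else 'fail')}"


def write_report(report: ScreenReport, format: str = "tsv", dest: TextIO | None = None) -> str:
    """Serialise a screen report as TSV (one row per candidate) or JSON."""
    if format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for r in report.records:
            p = r.profile
            lines.append("\t".join([
                r.id, str(r.length), f"{r.coverage:.3f}", f"{r.identity:.3f}",
                _rule_cell(p, 171), _rule_cell(p, 221), _rule_cell(p, 229),
                _rule_cell(p, 232), _rule_cell(p, 266),
                (p.gxgd.matched if p and p.gxgd else "absent"),
                (p.gxgd_second or "-") if p else "-",
                ("present" if p and p.rxgrgd else "absent"),
                p.nxxe_variant if p else "-",
                r.donor_class.value,
                r.acceptor.verdict if r.acceptor else "-",
                ",".join(r.acceptor.substitutions) if r.acceptor else "-",
                ",".join(r.flags) or "-",
            ]))
        text = "\n".join(lines) + "\n"
    elif format == "json":
        payload = {
            "summary": report.summary(),
            "records": [asdict(r) for r in report.records],
        }
        text = json.dumps(payload, indent=2)
    else:
        raise ValueError(f"unknown report format {format!r}")
    if dest is not None:
        dest.write(text)
    return text


def _profile_from_dict(d: dict | None) -> SignatureProfile | None:
    if d is None:
        return None
    return SignatureProfile(
        rules=[RuleResult(**r) for r in d["rules"]],
        gxgd=MotifHit(**d["gxgd"]) if d["gxgd"] else None,
        gxgd_second=d["gxgd_second"],
        rxgrgd=d["rxgrgd"],
        nxxe_variant=d["nxxe_variant"],
        incomplete=d["incomplete"],
    )


def read_report_json(text: str) -> ScreenReport:
    """Inverse of ``write_report(..., format="json")``."""
    payload = json.loads(text)
    records = []
    for d in payload["records"]:
        acceptor = None
        if d["acceptor"] is not None:
            acceptor = AcceptorSiteComparison(
                positions=[tuple(p) for p in d["acceptor"]["positions"]],
                verdict=d["acceptor"]["verdict"],
                substitutions=list(d["acceptor"]["substitutions"]),
            )
        records.append(
            CandidateRecord(
                id=d["id"], length=d["length"], coverage=d["coverage"],
                identity=d["identity"],
                profile=_profile_from_dict(d["profile"]),
                donor_class=DonorClass(**d["donor_class"]),
                acceptor=acceptor,
                lid=LidClass(**d["lid"]) if d["lid"] else None,
                flags=list(d["flags"]),
            )
        )
    return ScreenReport(records=records)
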