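"""Motif scanning and the five-key-residue donor-specificity signature.

The discriminative logic for phosphate-donor classification in the
ribokinase family:

* the GXGD motif, whose second residue tracks the donor — small (A, C, V,
  S, T) in ATP-dependent members, Ile/Leu in ADP-dependent members, and
  Arg in the PPi-dependent branch;
* the extended RXGRGD motif (GRGD being the GXGD instance, with a second
  arginine two residues upstream) proposed as the PPi signature;
* five key residues, in the reference enzyme's author numbering: K171,
  F221, R229, R232 and M266 — three basic residues that grip the
  pyrophosphate and two bulky hydrophobics that occlude the adenine
  pocket;
* the NXXE magnesium-binding motif, which appears as the DXXE variant in
  the PPi-dependent reference (reported as information only, not used for
  classification);
* a lid-domain size classification from secondary-structure counts, an
  evolutionary marker across the family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MotifPattern",
    "MotifHit",
    "KeyResidueRule",
    "RuleResult",
    "SignatureProfile",
    "DonorClass",
    "LidClass",
    "GXGD",
    "RXGRGD",
    "KEY_RESIDUE_RULES",
    "scan_motif",
    "find_rxgrgd",
    "find_nxxe_variant",
    "evaluate_signature",
    "classify_donor",
    "lid_classify",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
# X is tolerated in scanned sequences; it never satisfies a residue set.
SCAN_ALPHABET = VALID_RESIDUES | {"X"}

ATP_SECOND_RESIDUES = set("ACVST")   # small residues leaving room for adenine+ribose
ADP_SECOND_RESIDUES = set("IL")      # fill the space ADP leaves relative to ATP


@dataclass(frozen=True)
class MotifPattern:
    """Ordered pattern of residue sets; ``None`` is a wildcard position."""

    name: str
    elements: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError("motif pattern must have length >= 2")
        for el in self.elements:
            if el is not None and len(el) == 0:
                raise ValueError("motif pattern contains an empty residue set")

    def __len__(self) -> int:
        return len(self.elements)

    def matches(self, fragment: str) -> bool:
        return len(fragment) == len(self.elements) and all(
            el is None or ch in el for ch, el in zip(fragment, self.elements)
        )

    def regex(self) -> str:
        parts = []
        for el in self.elements:
            if el is None:
                parts.append("[A-Z]")
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        return "".join(parts)


def _pattern(name: str, spec: str) -> MotifPattern:
    """Build a pattern from a compact string; 'X' is the wildcard."""
    return MotifPattern(
        name=name,
        elements=tuple(None if ch == "X" else frozenset(ch) for ch in spec),
    )


GXGD = _pattern("GXGD", "GXGD")
RXGRGD = _pattern("RXGRGD", "RXGRGD")


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start: int        # 1-based
    matched: str


@dataclass(frozen=True)
class KeyResidueRule:
    ref_position: int            # reference author number
    strict_allowed: frozenset[str]
    relaxed_allowed: frozenset[str]

    def __post_init__(self) -> None:
        if not self.strict_allowed <= self.relaxed_allowed:
            raise ValueError("strict set must be a subset of the relaxed set")


_BASIC = frozenset("KR")
_BULKY_HYDROPHOBIC = frozenset("FWYMLI")

# Strict mode demands the literal reference residue; relaxed mode accepts
# the conservative class (basic for the PPi-gripping positions, bulky
# hydrophobic for the pocket-occluding positions).
KEY_RESIDUE_RULES: tuple[KeyResidueRule, ...] = (
    KeyResidueRule(171, frozenset("K"), _BASIC),
    KeyResidueRule(221, frozenset("F"), _BULKY_HYDROPHOBIC),
    KeyResidueRule(229, frozenset("R"), _BASIC),
    KeyResidueRule(232, frozenset("R"), _BASIC),
    KeyResidueRule(266, frozenset("M"), _BULKY_HYDROPHOBIC),
)


@dataclass
class RuleResult:
    ref_position: int
    mapped_position: int | None   # 1-based position in the scanned sequence
    observed: str | None          # residue, or None when unmapped (gap)
    strict_pass: bool
    relaxed_pass: bool

    @property
    def resolved(self) -> bool:
        return self.mapped_position is not None


@dataclass
class SignatureProfile:
    rules: list[RuleResult]
    gxgd: MotifHit | None
    gxgd_second: str | None
    rxgrgd: bool
    nxxe_variant: str             # "NXXE" | "DXXE" | "absent"
    incomplete: bool = False

    def rule(self, ref_position: int) -> RuleResult:
        for r in self.rules:
            if r.ref_position == ref_position:
                return r
        raise KeyError(ref_position)

    def all_pass(self, mode: str = "strict") -> bool:
        if mode not in ("strict", "relaxed"):
            raise ValueError("mode must be 'strict' or 'relaxed'")
        return all(
            (r.strict_pass if mode == "strict" else r.relaxed_pass) for r in self.rules
        )


@dataclass
class DonorClass:
    value: str                    # PPi | ATP | ADP | indeterminate
    rationale: list[str] = field(default_factory=list)


@dataclass
class LidClass:
    value: str                    # loop_only | small | medium_beta | large_5s2h | largest_5s4h
    n_strands: int
    n_helices: int
    note: str = ""


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - SCAN_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-residue letters: {sorted(bad)}")
    return seq


def scan_motif(seq: str, pattern: MotifPattern) -> list[MotifHit]:
    """All (possibly overlapping) matches of ``pattern``, 1-based, ascending."""
    seq = _check_sequence(seq)
    rx = re.compile("(?=(" + pattern.regex() + "))")
    return [
        MotifHit(pattern.name, m.start() + 1, m.group(1)) for m in rx.finditer(seq)
    ]


def find_rxgrgd(seq: str) -> list[MotifHit]:
    """Matches of the extended PPi signature motif R-x-G-R-G-D."""
    return scan_motif(seq, RXGRGD)


def find_nxxe_variant(seq: str, lo: int = 1, hi: int | None = None) -> str:
    """First N/D-x-x-E occurrence in ``seq[lo..hi]`` (1-based, inclusive).

    Returns "NXXE", "DXXE" or "absent".  Informational: the Asn-to-Asp
    substitution occurs in some ATP-dependent members too and is not used
    for donor classification.
    """
    seq = _check_sequence(seq)
    hi = len(seq) if hi is None else min(hi, len(seq))
    m = re.compile("(?=([ND])[A-Z]{2}E)").search(seq, max(lo - 1, 0), hi)
    if m is None:
        return "absent"
    return "NXXE" if m.group(1) == "N" else "DXXE"


def _select_gxgd(seq: str, hits: list[MotifHit], mapped_232: int | None) -> MotifHit | None:
    if not hits:
        return None
    if mapped_232 is not None:
        # The 232-equivalent is the second residue of the motif, so the
        # containing hit starts one position before it.
        for h in hits:
            if h.start <= mapped_232 < h.start + len(h.matched):
                return h
    # Fall back to the hit nearest the C-terminal third, where the donor
    # domain lies; later hit wins ties.
    third = 2 * len(seq) / 3
    return min(hits, key=lambda h: (max(third - h.start, 0.0), -h.start))


def evaluate_signature(
    seq: str, position_map: dict[int, int | None]
) -> SignatureProfile:
    """Evaluate the five key-residue rules and motif flags on a sequence.

    ``position_map`` sends each reference author position (171, 221, 229,
    232, 266) to its 1-based equivalent in ``seq``, or None where the
    position is unmapped (aligned to a gap).  Unresolved rules fail both
    modes and flag the profile incomplete.
    """
    seq = _check_sequence(seq)
    rules: list[RuleResult] = []
    incomplete = False
    for rule in KEY_RESIDUE_RULES:
        if rule.ref_position not in position_map:
            raise ValueError(f"position map lacks reference position {rule.ref_position}")
        pos = position_map[rule.ref_position]
        if pos is None:
            incomplete = True
            rules.append(RuleResult(rule.ref_position, None, None, False, False))
            continue
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"mapped position {pos} for reference {rule.ref_position} "
                f"is outside the sequence (length {len(seq)})"
            )
        obs = seq[pos - 1]
        rules.append(
            RuleResult(
                rule.ref_position,
                pos,
                obs,
                strict_pass=obs in rule.strict_allowed,
                relaxed_pass=obs in rule.relaxed_allowed,
            )
        )

    gxgd_hits = scan_motif(seq, GXGD)
    mapped_232 = position_map.get(232)
    gxgd = _select_gxgd(seq, gxgd_hits, mapped_232)
    gxgd_second = seq[gxgd.start] if gxgd is not None else None  # start is 1-based
    rxgrgd_hits = find_rxgrgd(seq)

    mapped_171 = position_map.get(171)
    nxxe = find_nxxe_variant(
        seq,
        lo=mapped_171 if mapped_171 else 1,
        hi=mapped_232 if mapped_232 else None,
    )

    return SignatureProfile(
        rules=rules,
        gxgd=gxgd,
        gxgd_second=gxgd_second,
        rxgrgd=bool(rxgrgd_hits),
        nxxe_variant=nxxe,
        incomplete=incomplete,
    )


def classify_donor(profile: SignatureProfile, mode: str = "strict") -> DonorClass:
    """Predict the phosphate donor from a signature profile.

    PPi requires all five key-residue rules to pass (in ``mode``) together
    with the RXGRGD motif.  Otherwise the GXGD second residue decides: a
    small residue indicates ATP, Ile/Leu indicates ADP, and anything else
    (or no motif) is indeterminate.
    """
    if profile.all_pass(mode) and profile.rxgrgd:
        return DonorClass(
            "PPi", [f"all five key residues pass ({mode} mode)", "RXGRGD motif present"]
        )
    rationale = []
    if profile.incomplete:
        rationale.append("profile incomplete: some key positions unmapped")
    if profile.gxgd_second is not None:
        if profile.gxgd_second in ATP_SECOND_RESIDUES:
            rationale.append(f"GXGD second residue {profile.gxgd_second} is small")
            return DonorClass("ATP", rationale)
        if profile.gxgd_second in ADP_SECOND_RESIDUES:
            rationale.append(f"GXGD second residue {profile.gxgd_second} is Ile/Leu")
            return DonorClass("ADP", rationale)
        rationale.append(
            f"GXGD second residue {profile.gxgd_second} matches no donor rule"
        )
    else:
        rationale.append("no GXGD motif found")
    return DonorClass("indeterminate", rationale)


_LID_ORDER = ("loop_only", "small", "medium_beta", "large_5s2h", "largest_5s4h")


def lid_classify(n_strands: int, n_helices: int) -> LidClass:
    """Size class of the lid subdomain from secondary-structure counts.

    Landmark classes: no secondary structure (loops only); one to three
    strands (small); four strands (medium, all-beta); five strands with two
    helices (large); five strands with four or more helices (largest).
    Combinations off the landmark table map to the nearest class by strand
    count, with a note.
    """
    if n_strands < 0 or n_helices < 0:
        raise ValueError("secondary-structure counts must be non-negative")
    note = ""
    if n_strands == 0 and n_helices == 0:
        value = "loop_only"
    elif 1 <= n_strands <= 3:
        value = "small"
    elif n_strands == 4 and n_helices <= 1:
        value = "medium_beta"
    elif n_strands == 5 and n_helices == 2:
        value = "large_5s2h"
    elif n_strands == 5 and n_helices >= 4:
        value = "largest_5s4h"
    else:
        # off-table: nearest landmark by strand count
        if n_strands == 0:
            value = "loop_only"
        elif n_strands == 4:
            value = "medium_beta"
        elif n_strands >= 5:
            value = "large_5s2h" if n_helices <= 3 else "largest_5s4h"
        else:
            value = "small"
        note = f"off-table combination ({n_strands} strands, {n_helices} helices); nearest class used"
    return LidClass(value=value, n_strands=n_strands, n_helices=n_helices, note=note)
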