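"""Substrate-specificity calling from SDP residues.

A 9-residue SDP vector is matched position-by-position against the
typical-transporter patterns. A protein whose residues sit inside every
allowed set is a FULL match; small deviations (up to ``near_max``
mismatches, two by default because the observed novel-type rows deviate at
one or two positions) are reported as NEAR with the mismatching positions
spelled out; anything further is NO. A gap at an SDP counts as a mismatch,
never as a wildcard.

ar/R-based annotation rules (e.g. the water-typical F-H-T-R filter) are
data, not code: they live in a packaged JSON registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align_extract import ResidueProfile
from .refdata import SubstratePattern, load_arr_rules

NEAR_MAX_DEFAULT = 2


@dataclass(frozen=True)
class MatchReport:
    """Outcome of matching one SDP vector against one substrate pattern."""

    query_id: str
    substrate: str
    n_match: int
    mismatches: tuple[tuple[str, str, frozenset[str]], ...]
    call: str  # FULL | NEAR | NO

    def __post_init__(self) -> None:
        if len(self.mismatches) != 9 - self.n_match:
            raise ValueError("mismatch list inconsistent with n_match")
        if (self.call == "FULL") != (self.n_match == 9):
            raise ValueError("FULL call requires all nine positions to match")


@dataclass(frozen=True)
class AnnotationNote:
    """A fired annotation rule for one query."""

    query_id: str
    rule_id: str
    note: str


def match_sdp_vector(query_id: str, residues: Sequence[str],
                     pattern: SubstratePattern,
                     near_max: int = NEAR_MAX_DEFAULT) -> MatchReport:
    """Match any 9-residue vector (gaps allowed) against a pattern."""
    if len(residues) != 9:
        raise ValueError(f"need 9 SDP residues, got {len(residues)}")
    mismatches = []
    for i, (residue, allowed) in enumerate(zip(residues, pattern.allowed),
                                           start=1):
        if residue not in allowed:
            mismatches.append((f"SDP{i}", residue, allowed))
    n_match = 9 - len(mismatches)
    if n_match == 9:
        call = "FULL"
    elif len(mismatches) <= near_max:
        call = "NEAR"
    else:
        call = "NO"
    return MatchReport(query_id=query_id, substrate=pattern.substrate,
                       n_match=n_match, mismatches=tuple(mismatches),
                       call=call)


def match_pattern(profile: ResidueProfile, pattern: SubstratePattern,
                  near_max: int = NEAR_MAX_DEFAULT) -> MatchReport:
    """Match an extracted residue profile against one substrate pattern."""
    return match_sdp_vector(profile.query_id, profile.sdp, pattern, near_max)


def call_substrates(profiles: Iterable[ResidueProfile],
                    patterns: Sequence[SubstratePattern],
                    near_max: int = NEAR_MAX_DEFAULT) -> list[MatchReport]:
    """One report per (profile, pattern)."""
    return [match_pattern(p, pat, near_max) for p in profiles for pat in patterns]


def full_call_summary(reports: Iterable[MatchReport]) -> dict[str, int]:
    """Number of FULL calls per substrate."""
    summary: dict[str, int] = {}
    for r in reports:
        summary.setdefault(r.substrate, 0)
        if r.call == "FULL":
            summary[r.substrate] += 1
    return summary


def apply_arr_rules(profile: ResidueProfile,
                    rules: Sequence[Mapping] | None = None
                    ) -> list[AnnotationNote]:
    """Fire every registered ar/R + NPA annotation rule whose predicate
    holds for the profile."""
    rules = rules if rules is not None else load_arr_rules()
    notes = []
    for rule in rules:
        if "arr" in rule and tuple(profile.arr) != tuple(rule["arr"]):
            continue
        if "npa_lb" in rule and profile.npa_lb != rule["npa_lb"]:
            continue
        if "npa_le" in rule and profile.npa_le != rule["npa_le"]:
            continue
        notes.append(AnnotationNote(query_id=profile.query_id,
                                    rule_id=rule["rule_id"],
                                    note=rule["note"]))
    return notes


def reports_to_rows(reports: Iterable[MatchReport]) -> list[dict]:
    """Flatten match reports for TSV export."""
    return [
        {
            "query_id": r.query_id,
            "substrate": r.substrate,
            "call": r.call,
            "n_match": r.n_match,
            "mismatches": ";".join(
                f"{pos}:{obs}!in{{{''.join(sorted(allowed))}}}"
                for pos, obs, allowed in r.mismatches
            ),
        }
        for r in reports
    ]
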