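"""G-bulge candidate funnel: shared targetome transcripts with G-bulge
sites and no confounding canonical sites.

The funnel intersects the ranked targetomes of two capture probes, keeps
shared transcripts carrying at least one G-bulge site for the base
register, and excludes any transcript that also carries a canonical seed
match (6mer or stronger by default, for either isomiR register, anywhere in
the transcript by default) - canonical sites would confound attribution of
any regulation to the G-bulge motif.  Every exclusion is audited with the
offending matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .registers import (
    CANONICAL_CLASSES,
    MirnaRegister,
    SiteClass,
    canonical_patterns,
    gbulge_patterns,
    map_bulge_span,
)
from .scanner import SiteMatch, TranscriptRecord, scan

__all__ = ["CandidateReport", "targetome_overlap", "gbulge_candidates"]

_SEVENMER_FLOOR = (SiteClass.EIGHTMER, SiteClass.SEVENMER_M8, SiteClass.SEVENMER_A1)


def targetome_overlap(
    targetome_a: Sequence[str], targetome_b: Sequence[str], depth: int
) -> tuple[set[str], float]:
    """Shared IDs and overlap fraction of the two top-``depth`` sets."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if depth > len(targetome_a) or depth > len(targetome_b):
        raise ValueError("depth exceeds a targetome length")
    top_a = set(targetome_a[:depth])
    top_b = set(targetome_b[:depth])
    shared = top_a & top_b
    return shared, len(shared) / depth


@dataclass
class CandidateReport:
    shared_transcripts: list[str]
    gbulge_matches: dict[str, list[SiteMatch]]
    canonical_matches: dict[str, list[SiteMatch]]
    excluded: dict[str, str]  # transcript -> reason
    final_candidates: list[str]
    bulge_span_base: tuple[int, int] = (5, 6)
    bulge_span_extended: tuple[int, int] = (6, 7)

    def counts(self) -> dict[str, int]:
        reasons = list(self.excluded.values())
        return {
            "shared": len(self.shared_transcripts),
            "final": len(self.final_candidates),
            "excluded_canonical": reasons.count("canonical_site"),
            "excluded_no_gbulge": reasons.count("no_gbulge_site"),
        }

    def to_json(self) -> str:
        def match_dict(m: SiteMatch) -> dict:
            return {
                "mirna": m.mirna_name,
                "site_class": m.site_class.value,
                "start": m.start,
                "end": m.end,
                "region": m.region,
            }

        payload = {
            "counts": self.counts(),
            "bulge_guide_span": {
                "base_register": list(self.bulge_span_base),
                "extended_register": list(self.bulge_span_extended),
            },
            "final_candidates": self.final_candidates,
            "transcripts": {
                tid: {
                    "gbulge_matches": [match_dict(m) for m in self.gbulge_matches.get(tid, [])],
                    "canonical_matches": [match_dict(m) for m in self.canonical_matches.get(tid, [])],
                    "excluded": tid in self.excluded,
                    "reason": self.excluded.get(tid),
                }
                for tid in self.shared_transcripts
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def gbulge_candidates(
    shared_ids: Iterable[str],
    transcripts: Sequence[TranscriptRecord],
    base_reg: MirnaRegister,
    extended_reg: MirnaRegister,
    canonical_scope: str = "whole",
    canonical_floor: str = "sixmer",
) -> CandidateReport:
    """Audit-ready G-bulge candidate report over the shared transcript set.

    ``canonical_scope`` restricts where canonical sites cause exclusion
    (``"whole"`` transcript, most conservative, or ``"utr3"``);
    ``canonical_floor`` sets the weakest excluding class (``"sixmer"`` for
    any canonical match including both 6mer variants, ``"sevenmer"`` for
    7mer-A1 and stronger).  G-bulge detection always scans the whole
    transcript for the base register.
    """
    if canonical_scope not in ("whole", "utr3"):
        raise ValueError("canonical_scope must be 'whole' or 'utr3'")
    if canonical_floor == "sixmer":
        excluding = set(CANONICAL_CLASSES)
    elif canonical_floor == "sevenmer":
        excluding = set(_SEVENMER_FLOOR)
    else:
        raise ValueError("canonical_floor must be 'sixmer' or 'sevenmer'")

    shared = sorted(set(shared_ids))
    by_id = {t.transcript_id: t for t in transcripts}
    missing = sorted(set(shared) - set(by_id))
    if missing:
        raise ValueError(f"shared transcripts missing from FASTA: {missing}")
    subset = [by_id[tid] for tid in shared]

    gb = scan(subset, gbulge_patterns(base_reg), region="whole")
    canon_pats = canonical_patterns(base_reg) + canonical_patterns(extended_reg)
    canon = [
        m
        for m in scan(subset, canon_pats, region=canonical_scope)
        if m.site_class in excluding
    ]

    gb_by: dict[str, list[SiteMatch]] = {}
    for m in gb:
        gb_by.setdefault(m.transcript_id, []).append(m)
    canon_by: dict[str, list[SiteMatch]] = {}
    for m in canon:
        canon_by.setdefault(m.transcript_id, []).append(m)

    excluded: dict[str, str] = {}
    final: list[str] = []
    for tid in shared:
        if tid not in gb_by:
            excluded[tid] = "no_gbulge_site"
        elif tid in canon_by:
            excluded[tid] = "canonical_site"
        else:
            final.append(tid)
    return CandidateReport(
        shared_transcripts=shared,
        gbulge_matches=gb_by,
        canonical_matches=canon_by,
        excluded=excluded,
        final_candidates=final,
        bulge_span_base=(5, 6),
        bulge_span_extended=map_bulge_span(base_reg, extended_reg, (5, 6)),
    )
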