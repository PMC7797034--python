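"""Transcript I/O and target-site scanning.

Transcripts are single-stranded sense sequences in transcript coordinates
(0-based, half-open).  3'UTR annotation rides along as BED whose chrom column
holds the transcript ID.  Scanning reports every occurrence of every supplied
pattern, with one exception: when several nested motifs match at the same
anchor position (same start, same miRNA) only the strongest class is kept,
so a planted 8mer is not additionally reported as a 7mer-m8 at the same
start.  A site straddling the UTR boundary is assigned by its start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .registers import CLASS_PRIORITY, SiteClass, SitePattern, normalize_rna

__all__ = [
    "TranscriptRecord",
    "SiteMatch",
    "read_transcripts",
    "scan",
    "site_count_table",
    "matches_to_frame",
    "write_matches_tsv",
]

REGIONS = ("utr3", "non_utr3", "whole")


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    sequence: str
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.utr3 is not None:
            start, end = self.utr3
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"{self.transcript_id}: 3'UTR interval {self.utr3} outside "
                    f"[0, {len(self.sequence)})"
                )

    @property
    def utr3_seq(self) -> str | None:
        if self.utr3 is None:
            return None
        return self.sequence[self.utr3[0] : self.utr3[1]]


@dataclass(frozen=True)
class SiteMatch:
    transcript_id: str
    mirna_name: str
    site_class: SiteClass
    start: int
    end: int
    region: str  # utr3 | non_utr3 | whole


def _read_bed(bed_path) -> dict[str, tuple[int, int]]:
    intervals: dict[str, tuple[int, int]] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: BED needs >= 3 columns")
            tid = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: malformed interval") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{bed_path}:{lineno}: malformed interval [{start}, {end})")
            intervals[tid] = (start, end)
    return intervals


def read_transcripts(fasta_path, bed_path=None) -> list[TranscriptRecord]:
    """Read transcript FASTA (DNA accepted, stored as RNA) plus optional BED.

    Every BED chrom value must name a FASTA record and every interval must
    fit inside the transcript; transcripts absent from the BED get no UTR.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate transcript ID {rec.id!r} in {fasta_path}")
        records[rec.id] = normalize_rna(str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    utr = _read_bed(bed_path) if bed_path is not None else {}
    missing = sorted(set(utr) - set(records))
    if missing:
        raise ValueError(f"BED IDs absent from FASTA: {missing}")
    out = []
    for tid, seq in records.items():
        interval = utr.get(tid)
        if interval is not None and interval[1] > len(seq):
            raise ValueError(
                f"{tid}: BED interval end {interval[1]} exceeds transcript length {len(seq)}"
            )
        out.append(TranscriptRecord(tid, seq, interval))
    return out


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


_PRIORITY_RANK = {cls: i for i, cls in enumerate(CLASS_PRIORITY)}


def scan(
    transcripts: Iterable[TranscriptRecord],
    patterns: Sequence[SitePattern],
    region: str = "whole",
) -> list[SiteMatch]:
    """All pattern occurrences, strongest class per (start, miRNA) anchor.

    ``region`` selects which matches to return: ``"utr3"`` and
    ``"non_utr3"`` filter by the start position relative to the annotated
    3'UTR; ``"whole"`` returns everything.  Matches on annotated transcripts
    are labelled utr3/non_utr3; unannotated transcripts yield ``whole``.
    Output is sorted by (transcript_id, start, mirna_name) and deterministic.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if not patterns:
        raise ValueError("empty pattern list")
    matches: list[SiteMatch] = []
    for tr in transcripts:
        best: dict[tuple[int, str], SitePattern] = {}
        for pat in patterns:
            for pos in _find_all(tr.sequence, pat.motif):
                key = (pos, pat.mirna_name)
                prev = best.get(key)
                if prev is None or _PRIORITY_RANK[pat.site_class] < _PRIORITY_RANK[prev.site_class]:
                    best[key] = pat
        for (pos, mirna), pat in best.items():
            if tr.utr3 is None:
                reg_label = "whole"
            else:
                reg_label = "utr3" if tr.utr3[0] <= pos < tr.utr3[1] else "non_utr3"
            if region != "whole" and reg_label != region:
                continue
            matches.append(
                SiteMatch(tr.transcript_id, mirna, pat.site_class, pos, pos + len(pat.motif), reg_label)
            )
    matches.sort(key=lambda m: (m.transcript_id, m.start, m.mirna_name, m.site_class.value))
    return matches


def matches_to_frame(matches: Sequence[SiteMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in matches],
            "mirna": [m.mirna_name for m in matches],
            "site_class": [m.site_class.value for m in matches],
            "start": [m.start for m in matches],
            "end": [m.end for m in matches],
            "region": [m.region for m in matches],
        }
    )


def site_count_table(matches: Sequence[SiteMatch]) -> pd.DataFrame:
    """Exact multiplicities per (transcript, miRNA, class, region)."""
    frame = matches_to_frame(matches)
    if frame.empty:
        return pd.DataFrame(
            columns=["transcript_id", "mirna", "site_class", "region", "count"]
        )
    counts = (
        frame.groupby(["transcript_id", "mirna", "site_class", "region"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return counts


def write_matches_tsv(matches: Sequence[SiteMatch], path) -> None:
    matches_to_frame(matches).to_csv(path, sep="\t", index=False)
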