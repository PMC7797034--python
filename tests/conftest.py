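"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive motifs and site calls from first
principles (dict-based complementation, per-anchor window classification)
so they share no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirclip.registers import MirnaRegister, SiteClass, build_register
from mirclip.scanner import TranscriptRecord

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_motifs(guide: str) -> dict[SiteClass, str]:
    """Independent construction of every target-side motif from a guide.

    Seed spans use 1-based guide positions: 8mer/7mer-m8 pair g2-g8,
    7mer-A1/6mer pair g2-g7, offset 6mer pairs g3-g8; A1 classes append an
    A opposite g1; G-bulge classes insert a G between the target
    nucleotides opposite g6 and g5 (motif runs t8..t2 5'->3').
    """
    m8 = naive_revcomp(guide[1:8])
    gb = m8[:3] + "G" + m8[3:]
    return {
        SiteClass.EIGHTMER: m8 + "A",
        SiteClass.SEVENMER_M8: m8,
        SiteClass.SEVENMER_A1: naive_revcomp(guide[1:7]) + "A",
        SiteClass.SIXMER: naive_revcomp(guide[1:7]),
        SiteClass.OFFSET_SIXMER: naive_revcomp(guide[2:8]),
        SiteClass.GBULGE_7M8: gb,
        SiteClass.GBULGE_8MER: gb + "A",
    }


# same strongest-first convention as the package (a reporting convention,
# not a derived quantity)
ORACLE_PRIORITY = (
    SiteClass.EIGHTMER,
    SiteClass.GBULGE_8MER,
    SiteClass.SEVENMER_M8,
    SiteClass.GBULGE_7M8,
    SiteClass.SEVENMER_A1,
    SiteClass.SIXMER,
    SiteClass.OFFSET_SIXMER,
)


def brute_scan(
    transcripts: list[TranscriptRecord],
    registers: list[MirnaRegister],
    region: str = "whole",
) -> set[tuple]:
    """Windowed brute-force site caller: strongest class per (start, miRNA)."""
    out = set()
    for tr in transcripts:
        seq = tr.sequence
        for reg in registers:
            motifs = naive_motifs(reg.guide_seq)
            for pos in range(len(seq)):
                for cls in ORACLE_PRIORITY:
                    m = motifs[cls]
                    if seq[pos : pos + len(m)] == m and pos + len(m) <= len(seq):
                        if tr.utr3 is None:
                            label = "whole"
                        else:
                            label = "utr3" if tr.utr3[0] <= pos < tr.utr3[1] else "non_utr3"
                        if region == "whole" or label == region:
                            out.add((tr.transcript_id, reg.name, cls, pos, pos + len(m), label))
                        break
    return out


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=length, p=probs))


@pytest.fixture(scope="session")
def mir132() -> MirnaRegister:
    return build_register("miR-132", "UAACAGUCUACAGCCAUGGUCG", 0)


@pytest.fixture(scope="session")
def mir122() -> MirnaRegister:
    return build_register("miR-122", "UGGAGUGUGACAAUGGUGUUUG", 0)


@pytest.fixture(scope="session")
def register_pair():
    from mirclip.simulate import default_registers

    return default_registers()
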