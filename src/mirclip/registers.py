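"""miRNA guides, 5' isomiR registers and target-side site patterns.

A mature miRNA is represented as a :class:`MirnaRegister`: a guide sequence
(5'->3', RNA alphabet) together with a named 5' register offset.  Two isomiRs
cut from the same hairpin arm differ only in how many extra nucleotides they
carry at the 5' end; a +1 "extended" register prepends one nucleotide to the
base register, which shifts every guide position by one (extended g(k+1) =
base g(k)) and therefore shifts the seed and all site classes on the target.

Canonical site classes follow the usual taxonomy: an 8mer pairs guide
positions g2-g8 with an adenosine opposite g1, a 7mer-m8 pairs g2-g8, a
7mer-A1 pairs g2-g7 with the opposite-A, a 6mer pairs g2-g7 and an offset
6mer pairs g3-g8.  G-bulge classes are the 7mer-m8/8mer motifs with one
guanosine in the target bulged out between the nucleotides opposite g5 and
g6.  All target-side motifs are written 5'->3' on the target, i.e. the
reverse complement of the paired guide span; the nucleotide opposite g1 sits
at the 3' end of the motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

__all__ = [
    "SiteClass",
    "MirnaRegister",
    "SitePattern",
    "build_register",
    "canonical_patterns",
    "gbulge_patterns",
    "all_patterns",
    "classify_site",
    "cross_register_class",
    "map_bulge_span",
    "normalize_rna",
    "reverse_complement",
    "read_registers_tsv",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_RNA = frozenset("ACGU")

MIN_GUIDE_LEN = 16
MAX_GUIDE_LEN = 30


def normalize_rna(sequence: str) -> str:
    """Uppercase, convert T to U and validate the ACGU alphabet."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - _RNA
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (ACGU alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SiteClass(Enum):
    EIGHTMER = "8mer"
    SEVENMER_M8 = "7mer-m8"
    SEVENMER_A1 = "7mer-A1"
    SIXMER = "6mer"
    OFFSET_SIXMER = "offset-6mer"
    GBULGE_7M8 = "gbulge-7m8"
    GBULGE_8MER = "gbulge-8mer"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CANONICAL_CLASSES = (
    SiteClass.EIGHTMER,
    SiteClass.SEVENMER_M8,
    SiteClass.SEVENMER_A1,
    SiteClass.SIXMER,
    SiteClass.OFFSET_SIXMER,
)
GBULGE_CLASSES = (SiteClass.GBULGE_7M8, SiteClass.GBULGE_8MER)

# Strength/precedence order used when several classes could be called at the
# same anchor; only nested motifs can co-match at one anchor, so the order
# matters only within the 8mer > 7mer > 6mer families.
CLASS_PRIORITY = (
    SiteClass.EIGHTMER,
    SiteClass.GBULGE_8MER,
    SiteClass.SEVENMER_M8,
    SiteClass.GBULGE_7M8,
    SiteClass.SEVENMER_A1,
    SiteClass.SIXMER,
    SiteClass.OFFSET_SIXMER,
)

# Classes whose motif starts at the nucleotide opposite g7 (one position
# 3'-ward of the t8 anchor shared by the other classes).
_A1_ANCHORED = frozenset({SiteClass.SEVENMER_A1, SiteClass.SIXMER})


@dataclass(frozen=True)
class MirnaRegister:
    """A guide sequence with a named 5' register offset.

    ``register_offset`` counts extra 5' nucleotides relative to a declared
    base register of the same hairpin arm: the 5'-extended isoform of a base
    register has offset +1 and satisfies extended g(k+1) = base g(k).
    """

    name: str
    guide_seq: str
    register_offset: int = 0

    def __post_init__(self) -> None:
        if not (MIN_GUIDE_LEN <= len(self.guide_seq) <= MAX_GUIDE_LEN):
            raise ValueError(
                f"guide length {len(self.guide_seq)} outside "
                f"[{MIN_GUIDE_LEN}, {MAX_GUIDE_LEN}] for {self.name!r}"
            )
        bad = set(self.guide_seq) - _RNA
        if bad:
            raise ValueError(f"guide {self.name!r} has non-ACGU characters: {sorted(bad)}")
        if not (-2 <= self.register_offset <= 2):
            raise ValueError(f"register_offset {self.register_offset} outside [-2, 2]")

    def guide(self, k: int) -> str:
        """Nucleotide at guide position g_k (1-based from the 5' end)."""
        if not (1 <= k <= len(self.guide_seq)):
            raise IndexError(f"guide position g{k} out of range")
        return self.guide_seq[k - 1]


@dataclass(frozen=True)
class SitePattern:
    """A target-side motif for one site class of one miRNA register.

    ``motif`` is written 5'->3' on the target.  ``paired_guide_span`` gives
    the inclusive guide positions whose reverse complement the motif carries
    (the terminal A of A1 classes and the bulged G are extras on top of the
    span).  ``bulge_insert_index`` is the 0-based index within ``motif``
    where the bulged target G sits, for G-bulge classes only.
    """

    mirna_name: str
    site_class: SiteClass
    motif: str
    paired_guide_span: tuple[int, int]
    bulge_insert_index: int | None = None


def build_register(name: str, sequence: str, register_offset: int = 0) -> MirnaRegister:
    """Normalization front door: accepts DNA or RNA, upper or lower case."""
    if not sequence or not sequence.strip():
        raise ValueError("empty guide sequence")
    return MirnaRegister(name, normalize_rna(sequence), register_offset)


def _span_motif(reg: MirnaRegister, g_start: int, g_end: int, terminal_a: bool = False) -> str:
    motif = reverse_complement(reg.guide_seq[g_start - 1 : g_end])
    return motif + "A" if terminal_a else motif


def canonical_patterns(reg: MirnaRegister) -> list[SitePattern]:
    """The five canonical seed-match patterns for one register."""
    if len(reg.guide_seq) < 9:
        raise ValueError("guide too short for seed patterns (need >= 9 nt)")
    return [
        SitePattern(reg.name, SiteClass.EIGHTMER, _span_motif(reg, 2, 8, True), (2, 8)),
        SitePattern(reg.name, SiteClass.SEVENMER_M8, _span_motif(reg, 2, 8), (2, 8)),
        SitePattern(reg.name, SiteClass.SEVENMER_A1, _span_motif(reg, 2, 7, True), (2, 7)),
        SitePattern(reg.name, SiteClass.SIXMER, _span_motif(reg, 2, 7), (2, 7)),
        SitePattern(reg.name, SiteClass.OFFSET_SIXMER, _span_motif(reg, 3, 8), (3, 8)),
    ]


def gbulge_patterns(reg: MirnaRegister) -> list[SitePattern]:
    """G-bulge patterns: a target G bulged between the nts opposite g5 and g6.

    Written 5'->3' on the target the 7mer-m8 motif reads t8 t7 t6 t5 t4 t3
    t2, so the insertion point between (opposite-g6, opposite-g5) is motif
    index 3.
    """
    if len(reg.guide_seq) < 9:
        raise ValueError("guide too short for seed patterns (need >= 9 nt)")
    m8 = _span_motif(reg, 2, 8)
    bulged = m8[:3] + "G" + m8[3:]
    return [
        SitePattern(reg.name, SiteClass.GBULGE_7M8, bulged, (2, 8), bulge_insert_index=3),
        SitePattern(reg.name, SiteClass.GBULGE_8MER, bulged + "A", (2, 8), bulge_insert_index=3),
    ]


def all_patterns(reg: MirnaRegister) -> list[SitePattern]:
    """Canonical plus G-bulge patterns for one register."""
    return canonical_patterns(reg) + gbulge_patterns(reg)


@lru_cache(maxsize=256)
def _pattern_map(reg: MirnaRegister) -> dict[SiteClass, SitePattern]:
    return {p.site_class: p for p in all_patterns(reg)}


def classify_site(window: str, reg: MirnaRegister, anchor: int = 0) -> SiteClass:
    """Strongest site class whose motif matches ``window`` at ``anchor``.

    The anchor is the position of the nucleotide opposite g8 (for A1-only
    classes the motif starts one nucleotide later, handled internally), i.e.
    the 5'-most target nucleotide of a 7mer-m8 match.  Returns
    ``SiteClass.NONE`` when nothing matches.
    """
    bad = set(window) - _RNA
    if bad:
        raise ValueError(f"non-ACGU characters in target window: {sorted(bad)}")
    patterns = _pattern_map(reg)
    for cls in CLASS_PRIORITY:
        start = anchor + (1 if cls in _A1_ANCHORED else 0)
        motif = patterns[cls].motif
        if start >= 0 and window[start : start + len(motif)] == motif:
            return cls
    return SiteClass.NONE


def cross_register_class(
    site_class: SiteClass,
    observed: MirnaRegister,
    other: MirnaRegister,
    flank_5p: str = "",
    flank_3p: str = "",
) -> SiteClass:
    """Class of the same physical target site under the other 5' register.

    The site was observed as ``site_class`` under ``observed``; ``flank_5p``
    and ``flank_3p`` are the target nucleotides immediately 5' and 3' of the
    observed motif (3' flank is needed when the other register is the
    extended one, 5' flank when it is the base one).  The result is computed
    by rebuilding the target window, re-anchoring for the other register and
    re-running :func:`classify_site` - not by a lookup table.
    """
    delta = other.register_offset - observed.register_offset
    if abs(delta) != 1:
        raise ValueError("registers must differ by exactly one 5' nucleotide")
    if site_class in (SiteClass.NONE,):
        return SiteClass.NONE
    flank_5p = normalize_rna(flank_5p) if flank_5p else ""
    flank_3p = normalize_rna(flank_3p) if flank_3p else ""
    motif = _pattern_map(observed)[site_class].motif
    window = flank_5p + motif + flank_3p
    # position of the nucleotide opposite observed g8 within the window
    anchor_obs = len(flank_5p) - (1 if site_class in _A1_ANCHORED else 0)
    anchor_other = anchor_obs + delta
    patterns = _pattern_map(other)
    for cls in CLASS_PRIORITY:
        start = anchor_other + (1 if cls in _A1_ANCHORED else 0)
        m = patterns[cls].motif
        if 0 <= start and start + len(m) <= len(window) and window[start : start + len(m)] == m:
            return cls
    return SiteClass.NONE


def map_bulge_span(observed: MirnaRegister, other: MirnaRegister,
                   span: tuple[int, int] = (5, 6)) -> tuple[int, int]:
    """Map the guide positions flanking a bulged target G between registers.

    A bulge between the nucleotides opposite (g5, g6) of a base register lies
    between those opposite (g6, g7) of its +1-extended isoform.
    """
    delta = other.register_offset - observed.register_offset
    if abs(delta) != 1:
        raise ValueError("registers must differ by exactly one 5' nucleotide")
    return (span[0] + delta, span[1] + delta)


def read_registers_tsv(path) -> list[MirnaRegister]:
    """Read registers from a 3-column TSV: name, sequence, register_offset.

    A header line is tolerated (detected by a non-integer third column).
    """
    registers: list[MirnaRegister] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            name, seq, off = parts[0], parts[1], parts[2]
            try:
                offset = int(off)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: register_offset {off!r} is not an integer")
            registers.append(build_register(name, seq, offset))
    if not registers:
        raise ValueError(f"no registers found in {path}")
    return registers
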