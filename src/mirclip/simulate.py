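"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generator emulates a probe-capture enrichment experiment end to end:

* a transcriptome of i.i.d.-composition transcripts with 3'UTR annotation,
  scrubbed of all seed/G-bulge matches for the configured register pair and
  then re-seeded with planted sites at recorded positions;
* negative-binomial count matrices with input / AGO-IP / capture samples in
  which site-bearing transcripts are enriched in the capture condition;
* transfection-response log2 fold-change tables with site-class-dependent
  effect sizes (G-bulge sites destabilize nothing at the mRNA level);
* small-RNA read sets mixing two 5' isoforms of one hairpin at a
  configured ratio.

Scrubbing the background of *all* register-pair site classes (not only the
planted ones) makes planted-site recall and precision exactly testable: the
recorded truth lists every match a scanner should find.  Planting is
verified by an internal naive matcher and re-sampled (bounded retries) when
flanking bases would upgrade, extend or bridge a planted motif.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import CountMatrix
from .registers import (
    MirnaRegister,
    SiteClass,
    SitePattern,
    all_patterns,
    build_register,
    CLASS_PRIORITY,
)
from .scanner import SiteMatch, TranscriptRecord

__all__ = [
    "PlantedSite",
    "SyntheticTruth",
    "default_registers",
    "make_site_plan",
    "generate_transcriptome",
    "generate_counts",
    "generate_response",
    "generate_small_rna",
    "synthetic_hairpin",
    "minimal_truth",
    "simulate_bundle",
    "write_fasta",
]

# Default register pair: a base guide starting with U and its +1 5'-extended
# isoform, the configuration under which every cross-register theorem is
# exercised (mirrors the miR-124 / iso-miR-124 situation).
DEFAULT_BASE_GUIDE = "UAAGGCACGCGGUGAAUGCC"
DEFAULT_EXTENDED_GUIDE = "U" + DEFAULT_BASE_GUIDE

# mRNA-level response per site class: canonical seed matches destabilize
# with strength ordered by class; G-bulge sites leave mRNA levels untouched
# (their regulation is translational/protein-level).
DEFAULT_RESPONSE_EFFECTS = {
    SiteClass.EIGHTMER: -0.35,
    SiteClass.SEVENMER_M8: -0.25,
    SiteClass.SEVENMER_A1: -0.15,
    SiteClass.SIXMER: -0.08,
    SiteClass.OFFSET_SIXMER: -0.05,
    SiteClass.GBULGE_7M8: 0.0,
    SiteClass.GBULGE_8MER: 0.0,
}

_ALPHA = np.frombuffer(b"ACGU", dtype=np.uint8)


def default_registers() -> tuple[MirnaRegister, MirnaRegister]:
    base = build_register("mir-base", DEFAULT_BASE_GUIDE, 0)
    extended = build_register("mir-ext", DEFAULT_EXTENDED_GUIDE, 1)
    return base, extended


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    mirna_name: str
    site_class: SiteClass
    start: int
    end: int
    region: str


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to recompute every expected downstream result."""

    seed: int
    params: dict
    transcript_ids: list[str] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    expected_matches: list[SiteMatch] = field(default_factory=list)
    enrichment_factors: dict[str, float] = field(default_factory=dict)
    true_logfc: dict[str, float] = field(default_factory=dict)
    isomir: dict = field(default_factory=dict)

    def sites_by_transcript(self) -> dict[str, list[PlantedSite]]:
        out: dict[str, list[PlantedSite]] = {}
        for s in self.sites:
            out.setdefault(s.transcript_id, []).append(s)
        return out

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "transcript_ids": self.transcript_ids,
            "sites": [
                {**asdict(s), "site_class": s.site_class.value} for s in self.sites
            ],
            "expected_matches": [
                {
                    "transcript_id": m.transcript_id,
                    "mirna": m.mirna_name,
                    "site_class": m.site_class.value,
                    "start": m.start,
                    "end": m.end,
                    "region": m.region,
                }
                for m in self.expected_matches
            ],
            "enrichment_factors": self.enrichment_factors,
            "true_logfc": self.true_logfc,
            "isomir": self.isomir,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _composition(gc: float) -> np.ndarray:
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_chars(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return _ALPHA[rng.choice(4, size=n, p=probs)]


def _reference_matches(seq: str, registers: list[MirnaRegister]) -> list[tuple[str, SiteClass, int, int]]:
    """Naive matcher: strongest class per (start, register), all positions."""
    out = []
    for reg in registers:
        pats = {p.site_class: p for p in all_patterns(reg)}
        for pos in range(len(seq)):
            for cls in CLASS_PRIORITY:
                motif = pats[cls].motif
                if seq.startswith(motif, pos):
                    out.append((reg.name, cls, pos, pos + len(motif)))
                    break
    return out


def _scrub(
    rng: np.random.Generator,
    arr: np.ndarray,
    motifs: list[str],
    probs: np.ndarray,
    max_rounds: int = 200,
) -> np.ndarray:
    """Re-sample every window matching any motif until none remain."""
    for _ in range(max_rounds):
        seq = arr.tobytes().decode("ascii")
        dirty: set[int] = set()
        for motif in motifs:
            pos = seq.find(motif)
            while pos != -1:
                dirty.update(range(pos, pos + len(motif)))
                pos = seq.find(motif, pos + 1)
        if not dirty:
            return arr
        idx = np.fromiter(sorted(dirty), dtype=np.int64)
        arr[idx] = _random_chars(rng, len(idx), probs)
    raise RuntimeError("background scrubbing did not converge")


def make_site_plan(
    n: int,
    planted_fraction: float = 0.25,
    site_class: SiteClass = SiteClass.SEVENMER_M8,
    mirna: str | None = None,
    region: str = "utr3",
) -> dict[int, list[tuple[str | None, SiteClass, str]]]:
    """Plan giving the first ``round(n * fraction)`` transcripts one site each."""
    k = int(round(n * planted_fraction))
    return {i: [(mirna, site_class, region)] for i in range(k)}


def generate_transcriptome(
    n: int,
    length_range: tuple[int, int] = (1000, 3000),
    gc: float = 0.45,
    utr_fraction: float = 0.4,
    site_plan: dict[int, list[tuple[str | None, SiteClass, str]]] | None = None,
    registers: tuple[MirnaRegister, MirnaRegister] | None = None,
    clip_enrichment: float = 3.0,
    seed: int = 0,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Background transcripts with planted sites and a full scan truth.

    Site-bearing transcripts get ``clip_enrichment`` as their capture
    enrichment factor (>= 1); all others get 1.  Same seed, same bytes.
    """
    if registers is None:
        registers = default_registers()
    base, extended = registers
    reg_by_name = {base.name: base, extended.name: extended}
    probs = _composition(gc)
    motifs = [p.motif for r in registers for p in all_patterns(r)]
    pattern_maps = {r.name: {p.site_class: p for p in all_patterns(r)} for r in registers}
    site_plan = site_plan or {}
    rng = np.random.default_rng(seed)

    records: list[TranscriptRecord] = []
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n": n,
            "length_range": list(length_range),
            "gc": gc,
            "utr_fraction": utr_fraction,
            "clip_enrichment": clip_enrichment,
            "registers": {r.name: {"guide_seq": r.guide_seq, "register_offset": r.register_offset} for r in registers},
        },
    )
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        tid = f"TX{i:0{width}d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        u0 = int(round(length * (1 - utr_fraction)))
        utr = (u0, length)
        plan = site_plan.get(i, [])
        seq, planted = _build_transcript(
            rng, tid, length, utr, plan, probs, motifs, pattern_maps, reg_by_name, registers
        )
        records.append(TranscriptRecord(tid, seq, utr))
        truth.transcript_ids.append(tid)
        truth.sites.extend(planted)
        truth.enrichment_factors[tid] = clip_enrichment if planted else 1.0
        for name, cls, pos, end in _reference_matches(seq, list(registers)):
            region = "utr3" if u0 <= pos < length else "non_utr3"
            truth.expected_matches.append(SiteMatch(tid, name, cls, pos, end, region))
    truth.expected_matches.sort(key=lambda m: (m.transcript_id, m.start, m.mirna_name, m.site_class.value))
    return records, truth


def _build_transcript(
    rng, tid, length, utr, plan, probs, motifs, pattern_maps, reg_by_name, registers
) -> tuple[str, list[PlantedSite]]:
    base_name = registers[0].name
    for _ in range(40):
        arr = _scrub(rng, _random_chars(rng, length, probs), motifs, probs)
        planted: list[PlantedSite] = []
        spans: list[tuple[int, int]] = []
        feasible = True
        for mirna, cls, region in plan:
            name = mirna or base_name
            motif = pattern_maps[name][cls].motif
            lo, hi = (utr if region == "utr3" else (0, utr[0]))
            lo, hi = lo + 1, hi - len(motif) - 1
            if hi <= lo:
                raise ValueError(f"{tid}: motif of length {len(motif)} does not fit region {region}")
            pos = None
            for _ in range(50):
                cand = int(rng.integers(lo, hi))
                if all(cand + len(motif) + 2 <= s or cand >= e + 2 for s, e in spans):
                    pos = cand
                    break
            if pos is None:
                feasible = False
                break
            arr[pos : pos + len(motif)] = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
            spans.append((pos, pos + len(motif)))
            planted.append(PlantedSite(tid, name, cls, pos, pos + len(motif), region))
        if not feasible:
            continue
        # flanking bases may upgrade/extend a planted motif or bridge into the
        # background; re-draw just the flanks a few times before resampling
        for _ in range(12):
            seq = arr.tobytes().decode("ascii")
            ref = _reference_matches(seq, list(registers))
            ref_keys = {(name, cls, pos) for name, cls, pos, _ in ref}
            planted_ok = all((s.mirna_name, s.site_class, s.start) in ref_keys for s in planted)
            contained = all(
                any(s <= pos and end <= e for s, e in spans) for _, _, pos, end in ref
            )
            if planted_ok and contained:
                return seq, planted
            for s, e in spans:
                for j in (s - 1, e):
                    if 0 <= j < length:
                        arr[j] = _random_chars(rng, 1, probs)[0]
    raise RuntimeError(f"{tid}: could not place planted sites cleanly")


def minimal_truth(
    transcript_ids: list[str],
    enrichment_factors: dict[str, float] | None = None,
    sites_by_tid: dict[str, SiteClass | list[SiteClass]] | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Truth without sequences, for counts- or response-only experiments."""
    truth = SyntheticTruth(seed=seed, params={"n": len(transcript_ids), "sequence_free": True})
    truth.transcript_ids = list(transcript_ids)
    factors = enrichment_factors or {}
    truth.enrichment_factors = {tid: float(factors.get(tid, 1.0)) for tid in transcript_ids}
    for tid, classes in (sites_by_tid or {}).items():
        if isinstance(classes, SiteClass):
            classes = [classes]
        for cls in classes:
            truth.sites.append(PlantedSite(tid, "mir-base", cls, -1, -1, "utr3"))
    return truth


def generate_counts(
    truth: SyntheticTruth,
    n_input_reps: int = 3,
    n_clip_reps: int = 3,
    n_ago_reps: int = 0,
    baseline_log_mean: float = float(np.log(150.0)),
    baseline_log_sd: float = 1.0,
    lib_sizes: dict[str, float] | None = None,
    dispersion: float = 0.1,
    probe_label: str = "probe",
    seed: int = 0,
) -> CountMatrix:
    """NB count matrix: mean = baseline * library size * enrichment.

    Enrichment is the per-transcript capture factor for mir_clip samples,
    its square root for ago_ip samples (partial enrichment at the IP step)
    and 1 for inputs.  ``dispersion`` is the NB dispersion phi (variance =
    mu + phi mu^2); phi = 0 gives Poisson counts.  Baselines are lognormal.
    """
    rng = np.random.default_rng(seed)
    ids = truth.transcript_ids
    if not ids:
        raise ValueError("truth has no transcripts")
    factors = np.array([truth.enrichment_factors.get(t, 1.0) for t in ids])
    baselines = rng.lognormal(baseline_log_mean, baseline_log_sd, size=len(ids))
    samples = (
        [(f"input_{i+1}", "input", 1.0) for i in range(n_input_reps)]
        + [(f"ago_ip_{i+1}", "ago_ip", 0.5) for i in range(n_ago_reps)]
        + [(f"mir_clip_{i+1}", "mir_clip", 1.0) for i in range(n_clip_reps)]
    )
    lib_sizes = lib_sizes or {}
    data = {}
    cond = {}
    for name, condition, _ in samples:
        size = float(lib_sizes.get(name, 1.0))
        if size <= 0:
            raise ValueError(f"non-positive library size for {name}")
        if condition == "mir_clip":
            enr = factors
        elif condition == "ago_ip":
            enr = np.sqrt(factors)
        else:
            enr = 1.0
        mu = baselines * size * enr
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        data[name] = counts
        cond[name] = condition
    counts_df = pd.DataFrame(data, index=pd.Index(ids, name="transcript_id"))
    return CountMatrix(counts_df, pd.Series(cond), probe_label=probe_label)


def generate_response(
    truth: SyntheticTruth,
    effect_by_class: dict[SiteClass, float] | None = None,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> pd.Series:
    """Per-transcript transfection logFC: summed site effects plus noise.

    Effects are additive over planted sites (including sites for both
    registers on one transcript); the noiseless value is recorded in
    ``truth.true_logfc``.
    """
    effects = DEFAULT_RESPONSE_EFFECTS if effect_by_class is None else effect_by_class
    rng = np.random.default_rng(seed)
    by_tid = truth.sites_by_transcript()
    noiseless = {
        tid: float(sum(effects.get(s.site_class, 0.0) for s in by_tid.get(tid, [])))
        for tid in truth.transcript_ids
    }
    truth.true_logfc = noiseless
    values = np.array([noiseless[t] for t in truth.transcript_ids])
    values = values + rng.normal(0.0, noise_sd, size=len(values))
    return pd.Series(values, index=pd.Index(truth.transcript_ids, name="gene"), name="log_fc")


# -- small-RNA reads ---------------------------------------------------------

SYNTHETIC_HAIRPIN_ID = "syn-pre-mir"
# Synthetic pre-miRNA hairpin: an arbitrary 5p/loop segment followed by the
# extended-register guide on the 3p arm.  Constructed, not a database entry.
_HAIRPIN_5P = "CGGACCUUGAUUUAAAUGUCCAUACAA"
_HAIRPIN_TAIL = "AAGAGCG"


def synthetic_hairpin() -> tuple[str, str, int, int]:
    """(hairpin_id, sequence, extended 5' start, base 5' start).

    The base-register mature sequence starts one nucleotide 3' of the
    extended isoform, mirroring heterogeneous 5' processing.
    """
    seq = _HAIRPIN_5P + DEFAULT_EXTENDED_GUIDE + _HAIRPIN_TAIL
    ext_start = len(_HAIRPIN_5P)
    return SYNTHETIC_HAIRPIN_ID, seq, ext_start, ext_start + 1


def generate_small_rna(
    hairpin_seq: str,
    offset_a: int,
    offset_b: int,
    ratio: float,
    n_reads: int,
    length_range: tuple[int, int] = (20, 23),
    seed: int = 0,
) -> list[str]:
    """Exact-substring reads from two 5' starts at abundance ratio b:a = r.

    Each read starts at ``offset_b`` with probability r / (1 + r), else at
    ``offset_a``; lengths are uniform over ``length_range``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    lo, hi = length_range
    for off in (offset_a, offset_b):
        if not (0 <= off and off + hi <= len(hairpin_seq)):
            raise ValueError(f"offset {off} with max read length {hi} outside hairpin")
    rng = np.random.default_rng(seed)
    picks_b = rng.random(n_reads) < ratio / (1.0 + ratio)
    lengths = rng.integers(lo, hi + 1, size=n_reads)
    reads = []
    for is_b, length in zip(picks_b, lengths):
        start = offset_b if is_b else offset_a
        reads.append(hairpin_seq[start : start + int(length)])
    return reads


# -- bundle ------------------------------------------------------------------


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_bundle(
    outdir,
    seed: int = 0,
    n_transcripts: int = 1000,
    planted_fraction: float = 0.25,
    planted_class: SiteClass = SiteClass.SEVENMER_M8,
    length_range: tuple[int, int] = (1000, 3000),
    gc: float = 0.45,
    clip_enrichment: float = 3.0,
    n_input_reps: int = 3,
    n_clip_reps: int = 3,
    dispersion: float = 0.1,
    noise_sd: float = 0.4,
    isomir_true_ratio: float = 3.4,
    n_reads: int = 100_000,
    n_libraries: int = 4,
) -> dict:
    """Write a complete synthetic input bundle plus the truth JSON.

    Emits transcript FASTA + 3'UTR BED + registers TSV, count matrices and
    sample sheets for two capture probes sharing one truth, a transfection
    logFC table, the planted-gene set, small-RNA read libraries with the
    synthetic hairpin, and ``truth.json``.  Fully deterministic under seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    base, extended = default_registers()
    plan = make_site_plan(n_transcripts, planted_fraction, planted_class)
    records, truth = generate_transcriptome(
        n_transcripts,
        length_range=length_range,
        gc=gc,
        site_plan=plan,
        registers=(base, extended),
        clip_enrichment=clip_enrichment,
        seed=child[0],
    )
    paths = {}
    paths["fasta"] = outdir / "transcripts.fa"
    write_fasta([(r.transcript_id, r.sequence) for r in records], paths["fasta"])
    paths["bed"] = outdir / "utr3.bed"
    with open(paths["bed"], "w") as fh:
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.utr3[0]}\t{r.utr3[1]}\tutr3\t0\t+\n")
    paths["registers"] = outdir / "registers.tsv"
    with open(paths["registers"], "w") as fh:
        fh.write("name\tsequence\tregister_offset\n")
        for r in (base, extended):
            fh.write(f"{r.name}\t{r.guide_seq}\t{r.register_offset}\n")

    for probe_i, probe in enumerate(("probe1", "probe2")):
        cm = generate_counts(
            truth,
            n_input_reps=n_input_reps,
            n_clip_reps=n_clip_reps,
            dispersion=dispersion,
            probe_label=probe,
            seed=child[1 + probe_i],
        )
        counts_path = outdir / f"counts_{probe}.tsv"
        cm.counts.to_csv(counts_path, sep="\t")
        sheet = pd.DataFrame(
            {
                "sample_id": cm.counts.columns,
                "condition": [cm.conditions[s] for s in cm.counts.columns],
                "replicate": [s.rsplit("_", 1)[1] for s in cm.counts.columns],
                "probe": probe,
            }
        )
        sheet_path = outdir / f"samples_{probe}.tsv"
        sheet.to_csv(sheet_path, sep="\t", index=False)
        paths[f"counts_{probe}"] = counts_path
        paths[f"samples_{probe}"] = sheet_path

    logfc = generate_response(truth, noise_sd=noise_sd, seed=child[3])
    paths["logfc"] = outdir / "logfc.tsv"
    logfc.to_frame().to_csv(paths["logfc"], sep="\t")
    planted_ids = sorted({s.transcript_id for s in truth.sites})
    paths["geneset"] = outdir / "geneset_planted.txt"
    Path(paths["geneset"]).write_text("".join(t + "\n" for t in planted_ids))

    hp_id, hp_seq, ext_start, base_start = synthetic_hairpin()
    paths["hairpin"] = outdir / "hairpin.fa"
    write_fasta([(hp_id, hp_seq)], paths["hairpin"])
    read_paths = []
    for lib in range(n_libraries):
        reads = generate_small_rna(
            hp_seq,
            offset_a=base_start,
            offset_b=ext_start,
            ratio=isomir_true_ratio,
            n_reads=n_reads,
            seed=child[4] + lib,
        )
        rp = outdir / f"reads_lib{lib+1}.fa"
        write_fasta([(f"read{j}", s) for j, s in enumerate(reads)], rp)
        read_paths.append(rp)
    paths["reads"] = read_paths
    truth.isomir = {
        "hairpin_id": hp_id,
        "ratio_extended_over_base": isomir_true_ratio,
        "base_start": base_start,
        "extended_start": ext_start,
        "arm_window": [ext_start - 2, base_start + 3],
        "n_reads": n_reads,
        "n_libraries": n_libraries,
    }
    paths["truth"] = outdir / "truth.json"
    truth.save(paths["truth"])
    return {"paths": paths, "truth": truth}
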