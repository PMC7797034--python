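"""k-mer motif enrichment and transfection-response shift statistics.

Motif enrichment compares observed motif occurrences in a sequence set
(typically targetome 3'UTRs) against an expected count under a background
model.  Two backgrounds are implemented, because the right null is a
modelling choice: per-sequence mononucleotide shuffling (composition
preserved exactly, default) and a cohort of background sequences scaled by
total scannable length.  Significance is a one-sided Poisson upper tail at
the expected count.

Response shift quantifies whether a named gene subset moves as a group in a
per-transcript log2 fold-change table (e.g. after miRNA transfection),
using the median shift vs the complement and a two-sided Wilcoxon rank-sum
test.  The rank-sum test is implemented here: the exact permutation
distribution (subset-sum dynamic program over midranks, correct with ties)
when both sides have <= 12 observations, and a tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from scipy.stats import norm as normal_dist
from scipy.stats import poisson, rankdata
from statsmodels.stats.multitest import multipletests

from .registers import SitePattern

__all__ = [
    "count_overlapping",
    "expected_occurrences",
    "kmer_enrichment",
    "ranksum_test",
    "response_shift",
    "ecdf_points",
    "ddcp_fold_change",
]

_BYTE = {c: ord(c) for c in "ACGU"}

EXACT_RANKSUM_MAX = 12


def count_overlapping(sequence: str, motif: str) -> int:
    """Number of (possibly overlapping) occurrences of motif in sequence."""
    n, pos = 0, sequence.find(motif)
    while pos != -1:
        n += 1
        pos = sequence.find(motif, pos + 1)
    return n


def _count_in_rows(mat: np.ndarray, motif: str) -> np.ndarray:
    """Occurrence counts of motif in each row of a (B, L) uint8 matrix."""
    L = mat.shape[1]
    k = len(motif)
    if L < k:
        return np.zeros(mat.shape[0], dtype=np.int64)
    width = L - k + 1
    hit = mat[:, :width] == _BYTE[motif[0]]
    for i in range(1, k):
        hit &= mat[:, i : i + width] == _BYTE[motif[i]]
    return hit.sum(axis=1)


def expected_occurrences(
    sequences: Sequence[str],
    motif: str,
    background: str = "shuffle",
    B: int = 100,
    seed: int | None = None,
    cohort: Sequence[str] | None = None,
) -> float:
    """Expected total motif count over the sequence set under a null model.

    ``shuffle``: mean count over B mononucleotide-preserving shuffles of
    each sequence (seeded, reproducible).  ``cohort``: count in the cohort
    sequences scaled by the ratio of total scannable positions.
    """
    k = len(motif)
    if background == "shuffle":
        if B < 10:
            raise ValueError("shuffle background needs B >= 10")
        if all(len(s) < k for s in sequences):
            warnings.warn("motif longer than every sequence; expected count is 0", stacklevel=2)
            return 0.0
        rng = np.random.default_rng(seed)
        total = 0.0
        for seq in sequences:
            if len(seq) < k:
                continue
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            mat = np.tile(arr, (B, 1))
            rng.permuted(mat, axis=1, out=mat)
            total += _count_in_rows(mat, motif).mean()
        return float(total)
    if background == "cohort":
        if not cohort:
            raise ValueError("cohort background needs background sequences")
        target_positions = sum(max(0, len(s) - k + 1) for s in sequences)
        cohort_positions = sum(max(0, len(s) - k + 1) for s in cohort)
        if target_positions == 0:
            warnings.warn("motif longer than every sequence; expected count is 0", stacklevel=2)
            return 0.0
        if cohort_positions == 0:
            raise ValueError("motif longer than every cohort sequence")
        cohort_count = sum(count_overlapping(s, motif) for s in cohort)
        return float(cohort_count * target_positions / cohort_positions)
    raise ValueError(f"unknown background {background!r}; expected 'shuffle' or 'cohort'")


def kmer_enrichment(
    sequences: Sequence[str],
    patterns: Sequence[SitePattern],
    background: str = "shuffle",
    B: int = 100,
    seed: int | None = None,
    cohort: Sequence[str] | None = None,
    region_label: str = "utr3",
) -> pd.DataFrame:
    """Observed/expected enrichment per pattern with a Poisson upper-tail p.

    BH-adjusted q-values across the supplied pattern family are reported
    descriptively; ranking and gating use the raw p.
    """
    if not patterns:
        raise ValueError("empty pattern list")
    if not sequences:
        raise ValueError("empty sequence set")
    rows = []
    for pat in patterns:
        observed = sum(count_overlapping(s, pat.motif) for s in sequences)
        expected = expected_occurrences(
            sequences, pat.motif, background=background, B=B, seed=seed, cohort=cohort
        )
        fold = observed / expected if expected > 0 else float("inf") if observed else float("nan")
        if expected > 0:
            p = float(poisson.sf(observed - 1, expected))
        else:
            p = 1.0 if observed == 0 else float(np.finfo(float).tiny)
        rows.append(
            {
                "mirna": pat.mirna_name,
                "site_class": pat.site_class.value,
                "motif": pat.motif,
                "region": region_label,
                "observed": observed,
                "expected": expected,
                "fold": fold,
                "p_value": max(p, np.finfo(float).tiny),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def _exact_ranksum_tails(ranks: np.ndarray, n1: int, w_obs: float) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) over all n1-subsets, by subset-sum DP.

    Midranks are doubled so ties (.5 ranks) stay integral; the DP counts,
    for every subset size and rank-sum, the number of subsets achieving it.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    w2 = int(np.rint(w_obs * 2))
    total = int(r2.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        for m in range(n1, 0, -1):
            dp[m, r:] += dp[m - 1, : total + 1 - r]
    dist = dp[n1]
    nsub = dist.sum()
    p_le = dist[: w2 + 1].sum() / nsub
    p_ge = dist[w2:].sum() / nsub
    return float(p_le), float(p_ge)


def ranksum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Exact permutation p (2 * min tail, capped at 1) when both samples have
    <= 12 observations; otherwise a tie-corrected normal approximation
    without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    if n1 <= EXACT_RANKSUM_MAX and n2 <= EXACT_RANKSUM_MAX:
        p_le, p_ge = _exact_ranksum_tails(ranks, n1, w)
        return w, min(1.0, 2.0 * min(p_le, p_ge))
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (w - mu) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * normal_dist.sf(abs(z))))


def response_shift(
    log_fc: pd.Series, subsets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Median logFC shift of each gene subset vs its complement.

    Subset members missing from the table are dropped (count reported); a
    subset equal to the whole table is rejected since it leaves no
    complement to compare against.
    """
    log_fc = log_fc.dropna()
    universe = set(log_fc.index)
    rows = []
    for name, genes in subsets.items():
        genes = set(genes)
        present = sorted(genes & universe)
        n_missing = len(genes - universe)
        if not present:
            raise ValueError(f"subset {name!r} has no genes in the logFC table")
        if set(present) == universe:
            raise ValueError(f"subset {name!r} is identical to the universe")
        complement = sorted(universe - set(present))
        x = log_fc.loc[present].to_numpy()
        y = log_fc.loc[complement].to_numpy()
        _, p = ranksum_test(x, y)
        rows.append(
            {
                "subset": name,
                "n_genes": len(present),
                "n_missing": n_missing,
                "median_log_fc": float(np.median(x)),
                "delta_median_vs_complement": float(np.median(x) - np.median(y)),
                "rank_sum_p": p,
            }
        )
    return pd.DataFrame(rows)


def ecdf_points(values: Sequence[float]) -> pd.DataFrame:
    """Empirical CDF points (x sorted ascending, F(x) = i/n) for plotting."""
    x = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"x": x, "ecdf": np.arange(1, len(x) + 1) / len(x)})


def ddcp_fold_change(
    cp_target_treated: float,
    cp_hk_treated: float,
    cp_target_calib: float,
    cp_hk_calib: float,
) -> float:
    """Relative qPCR fold change by the 2^-ddCp method.

    ddCp = (Cp_target,treated - Cp_housekeeping,treated)
         - (Cp_target,calibrator - Cp_housekeeping,calibrator).
    """
    values = [cp_target_treated, cp_hk_treated, cp_target_calib, cp_hk_calib]
    if not all(np.isfinite(values)):
        raise ValueError("Cp values must be finite")
    ddcp = (cp_target_treated - cp_hk_treated) - (cp_target_calib - cp_hk_calib)
    return float(2.0 ** (-ddcp))
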