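"""Per-sample alpha diversity, coverage, rarefaction and the paired-design
community checks.

Conventions: Shannon entropy and the evenness denominator use the natural
log (so evenness is the Pielou index, 1 for a perfectly even community); the
log base is configurable. Good's coverage is reported as a percentage.
Rarefaction uses the exact hypergeometric expectation rather than random
subsampling, so curves are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.special import gammaln
from scipy.stats import norm

from .tables import OtuTable, SamplePairing

__all__ = [
    "shannon",
    "evenness",
    "chao1",
    "goods_coverage",
    "rarefaction_curve",
    "RarefactionCurve",
    "diversity_profile",
    "pairing_cluster_check",
    "paired_signed_rank",
]


def _positive(counts: np.ndarray) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (c < 0).any():
        raise ValueError("negative counts")
    if c.sum() <= 0:
        raise ValueError("all-zero count vector")
    return c[c > 0]


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity S = -sum p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base`` to change it.
    """
    c = _positive(counts)
    p = c / c.sum()
    s = float(-(p * np.log(p)).sum())
    return s / np.log(base) if base else s


def evenness(counts: np.ndarray, base: float | None = None) -> float:
    """Pielou evenness E = S / log(R), R = number of taxa observed.

    Undefined (returned as NaN) when R <= 1, since log(1) = 0.
    """
    c = _positive(counts)
    r = c.size
    if r <= 1:
        return float("nan")
    return shannon(counts, base) / (np.log(r) / (np.log(base) if base else 1.0))


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2), with the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when there are no doubletons."""
    c = _positive(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0  # == F1(F1-1)/(2(F2+1)) with F2 = 0


def goods_coverage(counts: np.ndarray) -> float:
    """Good's coverage (1 - n/N) x 100: percentage of reads not from
    singleton taxa (n singleton taxa, N total reads)."""
    c = _positive(counts)
    n_singletons = int((c == 1).sum())
    total = c.sum()
    return float((1.0 - n_singletons / total) * 100.0)


@dataclass
class RarefactionCurve:
    """Expected richness at each subsampling depth, with a saturation flag.

    ``final_slope`` is the increment in expected taxon count per read over the
    last grid interval; ``saturated`` means it fell below the threshold.
    """

    depths: np.ndarray
    expected_otus: np.ndarray
    final_slope: float
    saturated: bool
    slope_threshold: float


def rarefaction_curve(
    counts: np.ndarray, step: int = 50, slope_threshold: float = 1e-5
) -> RarefactionCurve:
    """Exact expected richness when subsampling d reads without replacement.

    E[S_d] = sum_i [1 - C(N - N_i, d) / C(N, d)], evaluated on the grid
    step, 2*step, ..., N (the total is always included, so the curve ends at
    the observed richness).
    """
    if step < 1:
        raise ValueError("step must be a positive integer")
    c = _positive(counts).astype(np.int64)
    N = int(c.sum())
    if step > N:
        raise ValueError(f"step {step} exceeds total reads {N}")
    depths = np.arange(step, N + 1, step, dtype=np.int64)
    if depths[-1] != N:
        depths = np.append(depths, N)
    # log C(N - Ni, d) - log C(N, d), term -> 0 (prob 1 absent) handled by mask
    lgN = gammaln(N + 1)
    expected = np.empty(depths.size)
    rem = N - c  # reads not from taxon i
    for k, d in enumerate(depths):
        ok = rem >= d
        logp = np.full(c.size, -np.inf)
        if ok.any():
            logp[ok] = (
                gammaln(rem[ok] + 1)
                - gammaln(rem[ok] - d + 1)
                - lgN
                + gammaln(N - d + 1)
            )
        expected[k] = float((1.0 - np.exp(logp)).sum())
    if depths.size >= 2:
        final_slope = float(
            (expected[-1] - expected[-2]) / (depths[-1] - depths[-2])
        )
    else:
        final_slope = 0.0
    return RarefactionCurve(
        depths, expected, final_slope, final_slope < slope_threshold, slope_threshold
    )


def diversity_profile(
    table: OtuTable, step: int = 50, slope_threshold: float = 1e-5
) -> pd.DataFrame:
    """Per-sample diversity summary: richness, Shannon (nats), evenness,
    Chao1, Good's coverage (%), read and singleton counts, saturation."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        curve = rarefaction_curve(c, step=step, slope_threshold=slope_threshold)
        rows.append(
            {
                "sample_id": sid,
                "richness": int((c > 0).sum()),
                "shannon": shannon(c),
                "evenness": evenness(c),
                "chao1": chao1(c),
                "goods_coverage": goods_coverage(c),
                "n_reads": int(c.sum()),
                "n_singletons": int((c == 1).sum()),
                "rarefaction_final_slope": curve.final_slope,
                "saturated": curve.saturated,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def pairing_cluster_check(table: OtuTable, pairing: SamplePairing) -> float:
    """Fraction of patients whose two samples merge with each other first
    under complete-linkage Euclidean clustering.

    Rows are normalized by their total count and square-root transformed
    before clustering. A patient counts as "paired" when its tumor and
    healthy samples form a direct merge in the dendrogram (each is the
    other's first partner), the dendrogram analogue of mutual nearest
    neighbors.
    """
    if len(pairing.pairs) < 2:
        raise ValueError("need at least 2 patients")
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    missing = [
        s
        for t, h in pairing.pairs.values()
        for s in (t, h)
        if s not in idx
    ]
    if missing:
        raise ValueError(f"paired samples missing from the table: {missing}")
    totals = table.sample_totals().astype(float)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total count")
    Z = linkage(np.sqrt(table.counts / totals[:, None]), method="complete")
    direct = {
        (int(min(a, b)), int(max(a, b)))
        for a, b, *_ in Z
        if a < table.n_samples and b < table.n_samples
    }
    paired = sum(
        (min(idx[t], idx[h]), max(idx[t], idx[h])) in direct
        for t, h in pairing.pairs.values()
    )
    return paired / len(pairing.pairs)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic under random signs.

    Dynamic program over the distribution of W+ = sum of ranks with positive
    sign; midranks are doubled so the support is integral, which handles ties
    exactly.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def paired_signed_rank(
    values_a: np.ndarray, values_b: np.ndarray, exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped. Returns ``(W, p)`` where W is the signed
    rank sum (sum of ranks of positive differences minus sum for negative
    ones), so swapping the inputs flips its sign. The p-value is exact (sign
    enumeration, midranks) for up to ``exact_max_n`` nonzero differences and
    a tie-corrected normal approximation beyond.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 5:
        raise ValueError(f"need >= 5 nonzero differences, have {d.size}")
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(d.size)
    # midranks over ties in |d|
    sorted_abs = absd[order]
    i = 0
    while i < d.size:
        j = i
        while j + 1 < d.size and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = w_plus - w_minus
    n = d.size
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(absd, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return statistic, min(1.0, p)
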