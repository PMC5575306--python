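"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities by direct enumeration or textbook
formulas, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from statistics import median


def seq_window_stats(sub: str) -> tuple[float, float]:
    """(gc_fraction, obs/exp CpG) of a sequence by direct string counting."""
    sub = sub.upper()
    n_c = sub.count("C")
    n_g = sub.count("G")
    n_cpg = sub.count("CG")
    n_eff = len(sub) - sub.count("N")
    gc = (n_c + n_g) / n_eff if n_eff else 0.0
    oe = n_cpg * n_eff / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc, oe


def brute_force_cgis(
    seq: str,
    window: int = 200,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
) -> list[tuple[int, int]]:
    """Exhaustive scan: test every window, merge overlapping/adjacent
    qualifying windows, re-test merged spans (strict length > min_length)."""
    if len(seq) <= min_length:
        return []
    qualifying = []
    for s in range(0, len(seq) - window + 1):
        gc, oe = seq_window_stats(seq[s : s + window])
        if gc >= min_gc and oe > min_obs_exp:
            qualifying.append(s)
    regions = []
    i = 0
    while i < len(qualifying):
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1] - qualifying[j] <= window:
            j += 1
        s, e = qualifying[i], qualifying[j] + window
        if e - s > min_length:
            gc, oe = seq_window_stats(seq[s:e])
            if gc >= min_gc and oe > min_obs_exp:
                regions.append((s, e))
        i = j + 1
    return regions


def brute_force_promoter_class(
    seq: str,
    window: int = 500,
    step: int = 5,
    hcp_oe: float = 0.75,
    hcp_gc: float = 0.55,
    lcp_oe: float = 0.48,
) -> str:
    windows = (
        [seq]
        if len(seq) < window
        else [seq[s : s + window] for s in range(0, len(seq) - window + 1, step)]
    )
    stats = [seq_window_stats(w) for w in windows]
    if any(oe >= hcp_oe and gc >= hcp_gc for gc, oe in stats):
        return "HCP"
    if all(oe < lcp_oe for _, oe in stats):
        return "LCP"
    return "ICP"


def interval_base_set(intervals) -> set[tuple[str, int]]:
    """(chrom, base) set covered by a collection of (chrom, start, end)."""
    out = set()
    for chrom, s, e in intervals:
        out.update((chrom, b) for b in range(s, e))
    return out


def median_of_ratios(matrix) -> list[float]:
    """Independent median-of-ratios size factors by direct arithmetic."""
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    factors = []
    geo = []
    for i in range(n_rows):
        if all(matrix[i][j] > 0 for j in range(n_cols)):
            geo.append(
                (i, math.exp(sum(math.log(matrix[i][j]) for j in range(n_cols)) / n_cols))
            )
    for j in range(n_cols):
        ratios = [matrix[i][j] / g for i, g in geo]
        factors.append(median(ratios))
    return factors


def two_sample_t(x, y) -> float:
    """Textbook pooled-variance two-sample Student t."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    return (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def paired_t_scalar(diffs) -> float:
    n = len(diffs)
    m = sum(diffs) / n
    s = math.sqrt(sum((d - m) ** 2 for d in diffs) / (n - 1))
    return m / (s / math.sqrt(n))


def chi2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for the 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def pearson_r(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def average_linkage_heights(dist: list[list[float]]) -> list[float]:
    """Merge heights of brute-force average-linkage agglomeration.

    ``dist`` is a full symmetric distance matrix; returns the sorted list of
    heights at which clusters merge.
    """
    clusters: list[list[int]] = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sum(dist[a][b] for a in clusters[i] for b in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)
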