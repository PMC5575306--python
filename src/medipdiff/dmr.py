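"""DMR calling: paired t statistic, fixed |t| threshold, permutation FDR.

For each testable 1 kb window the paired t statistic is computed on the
per-subject differences of normalized counts (treated - control); windows
with |t| strictly greater than the threshold (default 7) are DMRs, hyper-
or hypomethylated in the treated group by the sign of the mean difference.

The genome-level false-discovery rate is estimated by permutation: within
each non-DMR window the 2n sample values are independently shuffled across
all sample slots (breaking both pairing and group), the paired t is
recomputed and threshold exceedances counted. The mean exceedance, rescaled
by N_testable / N_nonDMR to compensate for permuting only non-DMR windows,
estimates the expected number of false positives; FDR = expected FP /
observed DMR count, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import GenomicInterval
from .quantify import PairedCountMatrix, WindowGrid

DEFAULT_T_THRESHOLD = 7.0


@dataclass(frozen=True)
class DMRCall:
    """One differentially methylated window."""

    window: GenomicInterval
    index: int
    t_stat: float
    direction: str  # 'hyper' or 'hypo', treated vs control
    mean_diff: float


@dataclass
class PermutationResult:
    """Permutation FDR estimate with its per-permutation exceedance counts."""

    n_permutations: int
    exceedances: np.ndarray
    expected_false_positives: float
    fdr_estimate: float | None
    seed: int
    scaled: bool


def paired_t_array(treated: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t over rows: t = mean(d) / (sd(d)/sqrt(n)), sd with n-1.

    Rows with zero sd get t = 0 when the mean difference is also zero and
    signed infinity otherwise (flagged degenerate windows).
    Returns (t, mean_diff).
    """
    d = np.asarray(treated, dtype=float) - np.asarray(control, dtype=float)
    n = d.shape[1]
    if n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    m = d.mean(axis=1)
    s = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    zero_sd = s == 0
    t[zero_sd & (m == 0)] = 0.0
    t[zero_sd & (m > 0)] = np.inf
    t[zero_sd & (m < 0)] = -np.inf
    return t, m


def paired_t(counts: PairedCountMatrix) -> pd.DataFrame:
    """Per-window paired t on normalized counts for the matrix's design.

    Returns a frame indexed like the count matrix with columns ``t`` and
    ``mean_diff``; untestable (all-zero) windows get NaN.
    """
    norm = counts.normalized
    T = norm[counts.treated_samples].to_numpy()
    C = norm[counts.control_samples].to_numpy()
    t, m = paired_t_array(T, C)
    mask = counts.testable_mask()
    t = np.where(mask, t, np.nan)
    m = np.where(mask, m, np.nan)
    return pd.DataFrame({"t": t, "mean_diff": m}, index=counts.raw.index)


def call_dmrs(
    t_frame: pd.DataFrame,
    grid: WindowGrid,
    threshold: float = DEFAULT_T_THRESHOLD,
) -> list[DMRCall]:
    """Windows with |t| strictly greater than *threshold*.

    A window at exactly the threshold is not a DMR. Direction is 'hyper'
    when the treated mean exceeds the control mean, else 'hypo'. Infinite t
    (zero variance, nonzero mean) exceeds any threshold and is called.
    """
    t = t_frame["t"].to_numpy()
    m = t_frame["mean_diff"].to_numpy()
    hits = np.nonzero(np.abs(t) > threshold)[0]
    calls = []
    for i in hits:
        calls.append(
            DMRCall(
                window=grid.window_interval(int(i)),
                index=int(i),
                t_stat=float(t[i]),
                direction="hyper" if m[i] > 0 else "hypo",
                mean_diff=float(m[i]),
            )
        )
    return calls


def dmrs_to_frame(calls: list[DMRCall], fdr: float | None = None) -> pd.DataFrame:
    """BED6+-style table of DMR calls (chrom, start, end, name, t, direction, fdr)."""
    rows = [
        (
            c.window.chrom,
            c.window.start,
            c.window.end,
            f"dmr_{c.index}",
            c.t_stat,
            c.direction,
            np.nan if fdr is None else fdr,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "t", "direction", "fdr"]
    )


def permutation_fdr(
    counts: PairedCountMatrix,
    dmr_calls: list[DMRCall],
    *,
    threshold: float = DEFAULT_T_THRESHOLD,
    n_permutations: int = 10_000,
    seed: int = 0,
    scale_to_testable: bool = True,
) -> PermutationResult:
    """Estimate the genome-level FDR of a DMR call set by permutation.

    Within each non-DMR testable window the 2n normalized values are
    independently permuted across all sample slots per permutation; the
    paired t is recomputed and |t| > *threshold* exceedances counted.
    ``expected FP = mean exceedance * (N_testable / N_nonDMR)`` (the scaling
    compensates for permuting only non-DMR windows; disable with
    *scale_to_testable*), and ``FDR = min(1, expected FP / N_DMR)``.

    With zero observed DMRs the FDR is not applicable (``None``).
    Reproducible under a fixed *seed*.
    """
    mask = counts.testable_mask()
    testable_idx = np.nonzero(mask)[0]
    dmr_idx = np.array(sorted({c.index for c in dmr_calls}), dtype=int)
    non_dmr_idx = np.setdiff1d(testable_idx, dmr_idx)
    if len(non_dmr_idx) < 100:
        raise ValueError("permutation FDR needs at least 100 non-DMR windows")
    n_pairs = len(counts.design)
    norm = counts.normalized
    cols = counts.treated_samples + counts.control_samples
    V = norm.loc[:, cols].to_numpy()[non_dmr_idx]
    rng = np.random.default_rng(seed)
    exceed = np.empty(n_permutations, dtype=np.int64)
    for b in range(n_permutations):
        order = np.argsort(rng.random(V.shape), axis=1)
        P = np.take_along_axis(V, order, axis=1)
        t, _ = paired_t_array(P[:, :n_pairs], P[:, n_pairs:])
        exceed[b] = int(np.count_nonzero(np.abs(t) > threshold))
    scale = len(testable_idx) / len(non_dmr_idx) if scale_to_testable else 1.0
    efp = float(exceed.mean() * scale)
    if len(dmr_idx) == 0:
        fdr = None
    else:
        fdr = min(1.0, efp / len(dmr_idx))
    return PermutationResult(
        n_permutations=n_permutations,
        exceedances=exceed,
        expected_false_positives=efp,
        fdr_estimate=fdr,
        seed=seed,
        scaled=scale_to_testable,
    )


def cluster_samples(
    dmr_matrix: pd.DataFrame,
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchical clustering of samples on DMR-window signal.

    Distance = 1 - Pearson correlation between sample columns; average
    linkage. Windows with non-finite values (degenerate infinite-t windows)
    are dropped from the distance computation. Returns the scipy linkage
    matrix and flat labels from cutting the tree at two clusters.

    Raises ``ValueError`` naming the sample if any column is constant.
    """
    X = dmr_matrix.to_numpy(dtype=float)
    finite = np.isfinite(X).all(axis=1)
    X = X[finite]
    if X.shape[0] < 2 or X.shape[1] < 4:
        raise ValueError("clustering needs >= 2 DMR windows and >= 4 samples")
    stds = X.std(axis=0)
    for name, sd in zip(dmr_matrix.columns, stds):
        if sd == 0:
            raise ValueError(f"sample {name!r} has constant signal; correlation undefined")
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(labels, index=dmr_matrix.columns, name="cluster")
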