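"""Window-level MeDIP signal: counting, normalization and descriptive profiles.

The genome is tiled with non-overlapping 1 kb windows (the final partial
window of each chromosome is kept). Aligned fragments are deduplicated per
sample — fragments with identical (chrom, start, end) collapse to one
representative — and a fragment increments every window it overlaps by at
least 1 bp. Per-sample size factors use the median-of-ratios method;
``normalized = raw / size_factor`` columnwise.

Profiles (metagene, CpG-island) are computed on per-base depth obtained by
spreading each window's normalized count uniformly over its bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CGI, Gene, _base_indicators, _cumsum0
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

SEX_CHROM_NAMES = ("X", "Y", "chrX", "chrY")


@dataclass
class WindowGrid:
    """Non-overlapping tiling of each chromosome with fixed-width windows."""

    window_bp: int
    genome_lengths: dict[str, int]
    chroms: list[str] = field(init=False)
    offsets: dict[str, int] = field(init=False)
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        self.chroms = list(self.genome_lengths)
        self.offsets = {}
        pos = 0
        for c in self.chroms:
            L = self.genome_lengths[c]
            if L <= 0:
                raise ValueError(f"nonpositive chromosome length for {c!r}")
            self.offsets[c] = pos
            pos += -(-L // self.window_bp)  # ceil division
        self.n_windows = pos

    def n_windows_chrom(self, chrom: str) -> int:
        return -(-self.genome_lengths[chrom] // self.window_bp)

    def window_interval(self, index: int) -> GenomicInterval:
        for c in self.chroms:
            n = self.n_windows_chrom(c)
            if index < self.offsets[c] + n:
                i = index - self.offsets[c]
                s = i * self.window_bp
                return GenomicInterval(c, s, min(s + self.window_bp, self.genome_lengths[c]))
        raise IndexError(index)

    def windows_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of grid windows overlapping [start, end) on *chrom*."""
        if chrom not in self.offsets:
            raise KeyError(chrom)
        n = self.n_windows_chrom(chrom)
        lo = max(0, start // self.window_bp)
        hi = min(n - 1, (end - 1) // self.window_bp)
        if hi < lo:
            return np.array([], dtype=np.int64)
        return np.arange(lo, hi + 1) + self.offsets[chrom]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            L = self.genome_lengths[c]
            starts = np.arange(0, L, self.window_bp)
            ends = np.minimum(starts + self.window_bp, L)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def window_lengths(self) -> np.ndarray:
        df = self.to_frame()
        return (df["end"] - df["start"]).to_numpy()


@dataclass
class PairedCountMatrix:
    """Windows x samples counts with a paired treated/control design.

    ``design`` lists (subject, treated_sample, control_sample) triples whose
    sample names are columns of ``raw``. ``normalized`` is
    ``raw / size_factor`` columnwise.
    """

    grid: "WindowGrid"
    raw: pd.DataFrame
    size_factors: pd.Series
    design: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if len(self.design) < 2:
            raise ValueError("paired design needs at least 2 subject pairs")
        for _, t, c in self.design:
            if t not in self.raw.columns or c not in self.raw.columns:
                raise ValueError(f"design sample(s) {t!r}/{c!r} missing from matrix")

    @property
    def normalized(self) -> pd.DataFrame:
        return self.raw.div(self.size_factors, axis=1)

    @property
    def treated_samples(self) -> list[str]:
        return [t for _, t, _ in self.design]

    @property
    def control_samples(self) -> list[str]:
        return [c for _, _, c in self.design]

    def testable_mask(self) -> np.ndarray:
        """Windows with a nonzero count in at least one sample."""
        return self.raw.to_numpy().sum(axis=1) > 0


def make_windows(
    genome_lengths: Mapping[str, int],
    window_bp: int = 1000,
    *,
    exclude_sex_chroms: bool = False,
    sex_chrom_names: Sequence[str] = SEX_CHROM_NAMES,
) -> WindowGrid:
    """Tile every chromosome with *window_bp* windows (partial last window kept)."""
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100")
    lengths = dict(genome_lengths)
    if exclude_sex_chroms:
        lengths = {c: L for c, L in lengths.items() if c not in set(sex_chrom_names)}
    return WindowGrid(window_bp, lengths)


def dedup(placements: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (chrom, start, end) placements within each sample.

    Placements with the same coordinates in different samples are kept.
    Order-independent: output is sorted.
    """
    out = placements.drop_duplicates(subset=["sample_id", "chrom", "start", "end"])
    return out.sort_values(["sample_id", "chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def count_in_windows(
    placements: pd.DataFrame,
    grid: WindowGrid,
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Raw windows x samples count matrix.

    A placement increments every window it overlaps by >= 1 bp (a fragment
    spanning a window boundary counts in both windows). Placements on
    chromosomes absent from the grid are skipped with a warning; the
    per-chromosome skip counts are returned alongside the matrix.
    """
    if samples is None:
        samples = sorted(placements["sample_id"].unique())
    counts = np.zeros((grid.n_windows, len(samples)), dtype=np.int64)
    skip_log: dict[str, int] = {}
    w = grid.window_bp
    for j, sample in enumerate(samples):
        sub = placements[placements["sample_id"] == sample]
        for chrom, chrom_df in sub.groupby("chrom", sort=False):
            if chrom not in grid.offsets:
                skip_log[chrom] = skip_log.get(chrom, 0) + len(chrom_df)
                continue
            off = grid.offsets[chrom]
            n = grid.n_windows_chrom(chrom)
            s = chrom_df["start"].to_numpy()
            e = chrom_df["end"].to_numpy()
            w0 = np.clip(s // w, 0, n - 1)
            w1 = np.clip((e - 1) // w, 0, n - 1)
            k = 0
            while True:
                active = w0 + k <= w1
                if not active.any():
                    break
                np.add.at(counts[:, j], off + w0[active] + k, 1)
                k += 1
    if skip_log:
        logger.warning("skipped placements on unknown chromosomes: %s", skip_log)
    df = grid.to_frame()
    raw = pd.DataFrame(counts, columns=list(samples))
    return pd.concat([df, raw], axis=1), skip_log


def size_factors(raw: pd.DataFrame | np.ndarray) -> pd.Series:
    """Median-of-ratios size factors.

    ``s_j = median_i( k_ij / geomean_j(k_ij) )`` over windows *i* where
    every sample has a positive count. Raises if no such window exists.
    """
    if isinstance(raw, pd.DataFrame):
        cols = list(raw.columns)
        k = raw.to_numpy(dtype=float)
    else:
        k = np.asarray(raw, dtype=float)
        cols = list(range(k.shape[1]))
    pos = np.all(k > 0, axis=1)
    if not pos.any():
        raise ValueError(
            "no window has a positive count in every sample; size factors are "
            "undefined — check depth, or drop empty samples"
        )
    logk = np.log(k[pos])
    log_geomean = logk.mean(axis=1)
    sf = np.exp(np.median(logk - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=cols, name="size_factor")


def normalize_counts(raw: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Columnwise ``raw / size_factor``."""
    return raw.div(sf, axis=1)


def coupling(grid: WindowGrid, assembly: Mapping[str, str]) -> np.ndarray:
    """Per-window CpG counts (the local CpG-density coupling vector)."""
    out = np.zeros(grid.n_windows, dtype=np.int64)
    for chrom in grid.chroms:
        seq = assembly[chrom]
        _, _, cpg, _ = _base_indicators(seq)
        cs = _cumsum0(cpg)
        n = grid.n_windows_chrom(chrom)
        w = grid.window_bp
        starts = np.arange(n) * w
        ends = np.minimum(starts + w, len(seq))
        off = grid.offsets[chrom]
        out[off : off + n] = cs[np.maximum(ends - 1, starts)] - cs[starts]
    return out


def _per_base_depth(window_values: np.ndarray, grid: WindowGrid) -> dict[str, np.ndarray]:
    """Spread each window's value uniformly over its bases, per chromosome."""
    depth = {}
    for chrom in grid.chroms:
        L = grid.genome_lengths[chrom]
        off = grid.offsets[chrom]
        n = grid.n_windows_chrom(chrom)
        idx = np.arange(L) // grid.window_bp
        starts = np.arange(n) * grid.window_bp
        lens = np.minimum(starts + grid.window_bp, L) - starts
        depth[chrom] = window_values[off + idx] / lens[idx]
    return depth


def _bin_means(vector: np.ndarray, n_bins: int) -> np.ndarray:
    """Means of *n_bins* equal (fractional) slices of *vector*; NaN-aware."""
    edges = np.linspace(0, len(vector), n_bins + 1).round().astype(int)
    out = np.full(n_bins, np.nan)
    for i in range(n_bins):
        seg = vector[edges[i] : edges[i + 1]]
        if len(seg) and not np.all(np.isnan(seg)):
            out[i] = np.nanmean(seg)
    return out


@dataclass
class MetageneProfile:
    """Binned average depth across a gene set: flank + body + flank bins."""

    values: np.ndarray
    n_flank_bins: int
    n_body_bins: int
    group: str
    n_genes: int


def metagene_profile(
    window_values: np.ndarray,
    grid: WindowGrid,
    genes: Sequence[Gene],
    *,
    group: str = "all",
    flank_bp: int = 2200,
    n_flank_bins: int = 20,
    n_body_bins: int = 50,
) -> MetageneProfile:
    """Average per-base depth in oriented bins around a gene set.

    20 upstream bins over *flank_bp* (110 bp each by default), 50 equal
    fractional gene-body bins, 20 downstream bins. Genes on the minus
    strand are reversed before binning, so bin 0 is always the far 5' end.
    Flank bases beyond chromosome edges are ignored (NaN).
    """
    if not genes:
        raise ValueError(f"gene group {group!r} is empty")
    depth = _per_base_depth(np.asarray(window_values, dtype=float), grid)
    n_total = 2 * n_flank_bins + n_body_bins
    acc = np.zeros((len(genes), n_total))
    for gi, g in enumerate(genes):
        d = depth[g.chrom]
        L = len(d)
        lo, hi = g.start - flank_bp, g.end + flank_bp
        vec = np.full(hi - lo, np.nan)
        s, e = max(0, lo), min(L, hi)
        vec[s - lo : e - lo] = d[s:e]
        if g.strand == "-":
            vec = vec[::-1]
        up = vec[:flank_bp]
        body = vec[flank_bp : flank_bp + (g.end - g.start)]
        down = vec[flank_bp + (g.end - g.start) :]
        acc[gi, :n_flank_bins] = _bin_means(up, n_flank_bins)
        acc[gi, n_flank_bins : n_flank_bins + n_body_bins] = _bin_means(body, n_body_bins)
        acc[gi, n_flank_bins + n_body_bins :] = _bin_means(down, n_flank_bins)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(acc, axis=0)
    return MetageneProfile(values, n_flank_bins, n_body_bins, group, len(genes))


def cgi_profile(
    window_values: np.ndarray,
    grid: WindowGrid,
    cgis: Sequence[CGI | GenomicInterval],
    *,
    shore_bp: int = 2000,
    n_bins: int = 20,
) -> np.ndarray:
    """Average depth in 20 upstream-shore + 20 island + 20 downstream-shore bins.

    Shore bins cover the fixed *shore_bp* flank of each island; island bins
    are 20 equal fractional slices.
    """
    islands = [c.interval if isinstance(c, CGI) else c for c in cgis]
    if not islands:
        raise ValueError("no CpG islands given")
    depth = _per_base_depth(np.asarray(window_values, dtype=float), grid)
    acc = np.zeros((len(islands), 3 * n_bins))
    for i, iv in enumerate(islands):
        d = depth[iv.chrom]
        L = len(d)
        lo, hi = iv.start - shore_bp, iv.end + shore_bp
        vec = np.full(hi - lo, np.nan)
        s, e = max(0, lo), min(L, hi)
        vec[s - lo : e - lo] = d[s:e]
        acc[i, :n_bins] = _bin_means(vec[:shore_bp], n_bins)
        acc[i, n_bins : 2 * n_bins] = _bin_means(vec[shore_bp : shore_bp + iv.length], n_bins)
        acc[i, 2 * n_bins :] = _bin_means(vec[shore_bp + iv.length :], n_bins)
    with np.errstate(invalid="ignore"):
        return np.nanmean(acc, axis=0)


def subtelomeric_test(
    window_values: np.ndarray, grid: WindowGrid, span_bp: int = 7_000_000
) -> pd.DataFrame:
    """Two-sample Student t: subtelomeric windows vs the rest, per chromosome.

    Subtelomeres are taken at both chromosome ends (*span_bp* each);
    chromosomes not longer than ``2 * span_bp`` are skipped. Degenerate
    variance yields a missing P.
    """
    vals = np.asarray(window_values, dtype=float)
    rows = []
    for chrom in grid.chroms:
        L = grid.genome_lengths[chrom]
        if L <= 2 * span_bp:
            continue
        off = grid.offsets[chrom]
        n = grid.n_windows_chrom(chrom)
        starts = np.arange(n) * grid.window_bp
        ends = np.minimum(starts + grid.window_bp, L)
        sub_mask = (starts < span_bp) | (ends > L - span_bp)
        sub = vals[off : off + n][sub_mask]
        rest = vals[off : off + n][~sub_mask]
        if sub.std(ddof=1) == 0 and rest.std(ddof=1) == 0:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(sub, rest, equal_var=True)
        rows.append((chrom, sub.mean(), rest.mean(), t, p))
    return pd.DataFrame(
        rows, columns=["chrom", "mean_subtelomeric", "mean_rest", "t", "p_value"]
    )


def saturation(
    placements: pd.DataFrame,
    grid: WindowGrid,
    fractions: Iterable[float] = (0.1, 0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Reproducibility of the window profile under subsampling.

    The placements of one sample are split randomly in two halves; for each
    fraction ``f`` both halves are subsampled to ``f`` of their reads, the
    window counts recomputed, and the Pearson correlation between the two
    halves reported. Correlations are undefined (NaN) when either half has
    constant counts.
    """
    fractions = list(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if len(placements) < 1000:
        raise ValueError("saturation analysis needs >= 1000 placements")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(placements))
    half = len(perm) // 2
    a_idx, b_idx = perm[:half], perm[half:]
    p = placements.reset_index(drop=True)

    def _counts(idx: np.ndarray) -> np.ndarray:
        sub = p.loc[idx].assign(sample_id="s")
        mat, _ = count_in_windows(sub, grid, samples=["s"])
        return mat["s"].to_numpy()

    rows = []
    for f in fractions:
        na, nb = max(1, round(f * len(a_idx))), max(1, round(f * len(b_idx)))
        ca, cb = _counts(a_idx[:na]), _counts(b_idx[:nb])
        if ca.std() == 0 or cb.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(ca, cb)[0, 1])
        rows.append((f, na + nb, r))
    return pd.DataFrame(rows, columns=["fraction", "n_reads", "pearson_r"])
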