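"""Synthetic study generator with known ground truth.

Emulates the study design this pipeline targets: a small multi-chromosome
genome with CpG-island-dense and CpG-poor regions, six paired
treated/control samples, MeDIP fragment counts whose expectation scales
with regional methylation x local CpG density x sample depth, planted
hyper-/hypomethylated 1 kb windows, and gene expression negatively coupled
to promoter methylation.

Every stage is driven by one integer seed (child streams are spawned per
stage), so all outputs are bit-reproducible.

Count noise is negative binomial with dispersion 0.05 by default in
:func:`simulate_counts` (MeDIP counts are overdispersed); the default study
scene built by :func:`simulate_study` uses Poisson noise, the regime in
which a 2-fold effect is recoverable at the strict ``|t| > 7`` rule with
six pairs (see the methods note for the power analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Gene
from .intervals import GenomicInterval
from .quantify import PairedCountMatrix, WindowGrid, coupling as coupling_vector
from .quantify import make_windows, size_factors

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study."""

    planted_cgis: list[GenomicInterval]
    dmr_indices: np.ndarray
    dmr_direction: np.ndarray  # 'hyper' / 'hypo' per planted window
    nominal_fold: float
    realized_fold: np.ndarray  # treated/control methylation ratio per planted window
    meth_control: np.ndarray
    meth_treated: np.ndarray
    expr_coupling: float
    seed: int

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_planted_cgis": len(self.planted_cgis),
            "n_planted_dmrs": int(len(self.dmr_indices)),
            "nominal_fold": self.nominal_fold,
            "n_hyper": int((self.dmr_direction == "hyper").sum()),
            "n_hypo": int((self.dmr_direction == "hypo").sum()),
            "expr_coupling": self.expr_coupling,
        }


@dataclass
class SyntheticScene:
    """A complete simulated study: inputs plus truth."""

    assembly: dict[str, str]
    grid: WindowGrid
    coupling: np.ndarray
    counts: PairedCountMatrix
    genes: list[Gene]
    expression: pd.DataFrame
    truth: SyntheticTruth
    params: dict = field(default_factory=dict)


def simulate_genome(
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    cgi_per_mb: float = 10.0,
    seed: int | np.random.Generator = 0,
    *,
    background_gc: float = 0.40,
    cpg_survival: float = 0.2,
    cgi_gc: float = 0.65,
    cgi_len_range: tuple[int, int] = (700, 1500),
    min_separation: int = 5000,
    max_retries: int = 1000,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Simulate a genome with CpG-depleted background and planted CG-rich blocks.

    Background bases are drawn i.i.d. at *background_gc* GC, then all CpG
    dinucleotides are destroyed (G replaced by A/T) except a *cpg_survival*
    fraction, giving CpG obs/exp near 0.2. Planted blocks are i.i.d. at
    *cgi_gc* GC (obs/exp near 1), placed non-overlapping with at least
    *min_separation* bp between blocks and from chromosome edges; block
    positions are redrawn on collision with bounded retries.

    Returns the assembly (chrom -> sequence string) and the planted block
    intervals.
    """
    if chrom_len < 50_000:
        raise ValueError("chrom_len must be >= 50 kb")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pc = background_gc / 2
    pa = (1 - background_gc) / 2
    assembly: dict[str, str] = {}
    planted: list[GenomicInterval] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        codes = rng.choice(4, size=chrom_len, p=[pa, pc, pc, pa])
        # deplete CpGs: C=1, G=2
        cg_pos = np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0]
        destroy = cg_pos[rng.random(len(cg_pos)) >= cpg_survival]
        codes[destroy + 1] = np.where(rng.random(len(destroy)) < 0.5, 0, 3)
        n_blocks = int(round(cgi_per_mb * chrom_len / 1e6))
        placed: list[tuple[int, int]] = []
        for _ in range(n_blocks):
            blen = int(rng.integers(cgi_len_range[0], cgi_len_range[1] + 1))
            for _try in range(max_retries):
                s = int(rng.integers(min_separation, chrom_len - min_separation - blen))
                clear = all(
                    not (s - min_separation < pe and ps < s + blen + min_separation)
                    for ps, pe in placed
                )
                if clear:
                    placed.append((s, s + blen))
                    break
            else:
                raise RuntimeError("could not place CGI blocks; lower cgi_per_mb")
        gp = cgi_gc / 2
        ga = (1 - cgi_gc) / 2
        for s, e in placed:
            codes[s:e] = rng.choice(4, size=e - s, p=[ga, gp, gp, ga])
            planted.append(GenomicInterval(chrom, s, e))
        assembly[chrom] = _BASES[codes].tobytes().decode("ascii")
    planted.sort(key=lambda iv: (iv.chrom, iv.start))
    return assembly, planted


def simulate_methylome(
    coupling: np.ndarray,
    n_dmr: int = 100,
    effect_fold: float = 2.0,
    hyper_fraction: float = 0.4,
    seed: int | np.random.Generator = 0,
    *,
    beta_a: float = 2.0,
    beta_b: float = 2.0,
    hyper_meth_range: tuple[float, float] = (0.2, 0.5),
    hypo_meth_range: tuple[float, float] = (0.3, 0.95),
    cpg_weight: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-window methylation for control/treated with planted DMRs.

    Control methylation is Beta(*beta_a*, *beta_b*) per window (optionally
    shrunk toward the local CpG density with weight *cpg_weight*). Treated
    equals control except at the planted windows, where it is multiplied
    (hyper) or divided (hypo) by *effect_fold*, clipped to [0, 1].

    DMRs are planted only where the effect is realizable and measurable:
    windows with CpG coupling at or above the median of CpG-containing
    windows, control methylation within *hyper_meth_range* for hyper
    windows (so the doubled level stays <= 1) and within *hypo_meth_range*
    for hypo windows (a region can only lose methylation it has).

    Returns (meth_control, meth_treated, dmr_indices, dmr_direction).
    """
    if effect_fold <= 1:
        raise ValueError("effect_fold must be > 1")
    n_windows = len(coupling)
    if n_dmr >= 0.1 * n_windows:
        raise ValueError("n_dmr must be below 10% of windows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    control = rng.beta(beta_a, beta_b, size=n_windows)
    if cpg_weight > 0:
        pos = coupling[coupling > 0]
        rel = np.clip(coupling / (np.mean(pos) if len(pos) else 1.0), 0, 1)
        control = np.clip(control * (1 - cpg_weight + cpg_weight * rel), 0, 1)
    treated = control.copy()
    if n_dmr == 0:
        return control, treated, np.array([], dtype=int), np.array([], dtype="<U5")
    pos = coupling[coupling > 0]
    med = np.median(pos) if len(pos) else 0
    eligible = coupling >= max(med, 1)
    n_hyper = int(round(hyper_fraction * n_dmr))
    n_hypo = n_dmr - n_hyper
    hyper_pool = np.nonzero(
        eligible & (control >= hyper_meth_range[0]) & (control <= hyper_meth_range[1])
    )[0]
    if len(hyper_pool) < n_hyper:
        raise ValueError("not enough eligible windows for hyper DMRs")
    hyper_idx = rng.choice(hyper_pool, size=n_hyper, replace=False)
    hypo_pool = np.nonzero(
        eligible & (control >= hypo_meth_range[0]) & (control <= hypo_meth_range[1])
    )[0]
    hypo_pool = np.setdiff1d(hypo_pool, hyper_idx)
    if len(hypo_pool) < n_hypo:
        raise ValueError("not enough eligible windows for hypo DMRs")
    hypo_idx = rng.choice(hypo_pool, size=n_hypo, replace=False)
    treated[hyper_idx] = np.clip(control[hyper_idx] * effect_fold, 0, 1)
    treated[hypo_idx] = control[hypo_idx] / effect_fold
    idx = np.concatenate([hyper_idx, hypo_idx])
    direction = np.array(["hyper"] * n_hyper + ["hypo"] * n_hypo)
    order = np.argsort(idx)
    return control, treated, idx[order], direction[order]


def simulate_counts(
    meth_control: np.ndarray,
    meth_treated: np.ndarray,
    coupling: np.ndarray,
    grid: WindowGrid,
    *,
    depth: float = 400.0,
    n_pairs: int = 6,
    dispersion: float = 0.05,
    background: float = 1.0,
    depth_sigma: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> PairedCountMatrix:
    """Paired MeDIP count matrix.

    Expected count of window *i* in sample *j* is
    ``depth_j * meth_i(group(j)) * coupling_i / mean(coupling) + background``
    with per-sample depths drawn log-normal around *depth* (sigma
    *depth_sigma*) to exercise size-factor normalization. Noise is negative
    binomial with the given *dispersion* (variance ``m + dispersion*m^2``),
    or Poisson when dispersion is 0.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = coupling[coupling > 0]
    c_rel = coupling / (np.mean(pos) if len(pos) else 1.0)
    depths = depth * np.exp(rng.normal(0.0, depth_sigma, size=2 * n_pairs))
    rate_t = meth_treated * c_rel
    rate_c = meth_control * c_rel
    cols = [f"T{i + 1}" for i in range(n_pairs)] + [f"C{i + 1}" for i in range(n_pairs)]
    mean = np.empty((len(coupling), 2 * n_pairs))
    for j in range(n_pairs):
        mean[:, j] = depths[j] * rate_t + background
        mean[:, n_pairs + j] = depths[n_pairs + j] * rate_c + background
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        raw = rng.poisson(lam)
    else:
        raw = rng.poisson(mean)
    raw_df = pd.DataFrame(raw, columns=cols)
    sf = size_factors(raw_df)
    design = [(f"subject{i + 1}", f"T{i + 1}", f"C{i + 1}") for i in range(n_pairs)]
    return PairedCountMatrix(grid=grid, raw=raw_df, size_factors=sf, design=design)


def placements_from_counts(
    counts: PairedCountMatrix,
    fragment_bp: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """BED-like fragment placements realizing the raw count matrix.

    Each count becomes one fragment placed uniformly inside its window (so
    re-counting the placements reproduces the matrix exactly; duplicates by
    coordinate can occur and would be collapsed by dedup, as in real data).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = counts.grid
    frame = grid.to_frame()
    rows = []
    for sample in counts.raw.columns:
        k = counts.raw[sample].to_numpy()
        idx = np.repeat(np.arange(len(k)), k)
        ws = frame["start"].to_numpy()[idx]
        we = frame["end"].to_numpy()[idx]
        span = np.maximum(we - ws - fragment_bp, 1)
        starts = ws + (rng.random(len(idx)) * span).astype(np.int64)
        ends = np.minimum(starts + fragment_bp, we)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": frame["chrom"].to_numpy()[idx],
                    "start": starts,
                    "end": ends,
                    "sample_id": sample,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_genes(
    genome_lengths: Mapping[str, int],
    n_genes: int = 300,
    seed: int | np.random.Generator = 0,
    *,
    gene_len_range: tuple[int, int] = (1200, 2400),
    gap_range: tuple[int, int] = (2400, 4000),
    edge_margin: int = 3000,
    exon_range: tuple[int, int] = (2, 4),
) -> list[Gene]:
    """Place non-overlapping genes (with room for their promoters) on the genome."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes: list[Gene] = []
    chroms = list(genome_lengths)
    gi = 0
    for chrom in chroms:
        L = genome_lengths[chrom]
        cursor = edge_margin + int(rng.integers(0, gap_range[0]))
        while gi < n_genes:
            glen = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
            if cursor + glen + edge_margin > L:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = cursor, cursor + glen
            n_ex = int(rng.integers(exon_range[0], exon_range[1] + 1))
            inner = np.sort(
                rng.choice(
                    np.arange(start + 50, end - 50), size=2 * (n_ex - 1), replace=False
                )
            )
            bounds = [start, *inner.tolist(), end]
            exons = [(bounds[k], bounds[k + 1]) for k in range(0, len(bounds) - 1, 2)]
            genes.append(Gene(f"gene{gi + 1:04d}", chrom, start, end, strand, exons))
            gi += 1
            cursor = end + int(rng.integers(gap_range[0], gap_range[1] + 1))
        if gi >= n_genes:
            break
    if gi < n_genes:
        raise ValueError(
            f"assembly too small for {n_genes} genes (placed {gi}); "
            "reduce n_genes or enlarge the genome"
        )
    return genes


def _promoter_true_methylation(
    gene: Gene,
    meth: np.ndarray,
    grid: WindowGrid,
    upstream: int = 2200,
    downstream: int = 500,
) -> float:
    t = gene.tss
    if gene.strand == "+":
        s, e = t - upstream, t + downstream
    else:
        s, e = t - downstream, t + upstream
    s = max(0, s)
    e = min(grid.genome_lengths[gene.chrom], e)
    idx = grid.windows_overlapping(gene.chrom, s, e)
    return float(meth[idx].mean()) if len(idx) else float("nan")


def simulate_expression(
    meth_control: np.ndarray,
    meth_treated: np.ndarray,
    genes: Sequence[Gene],
    grid: WindowGrid,
    dmr_indices: np.ndarray,
    dmr_direction: np.ndarray,
    *,
    coupling_coeff: float = 5.0,
    baseline_mean: float = 6.0,
    baseline_sd: float = 1.0,
    noise_sd: float = 1.0,
    n_pairs: int = 6,
    p_de: float = 0.7,
    silent_fraction: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gene x sample expression negatively coupled to promoter methylation.

    ``log2 expression = baseline_g - coupling_coeff * promoter_methylation
    + N(0, noise_sd)`` per sample, using the group's methylome. A
    *silent_fraction* of genes is undetected in both groups (flagged
    ``silent``). Genes whose promoter hosts a planted DMR are flagged
    differentially expressed with probability *p_de* (hypermethylated
    promoter -> 'down', hypomethylated -> 'up'); all others 'none'.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    cols_t = [f"T{i + 1}" for i in range(n_pairs)]
    cols_c = [f"C{i + 1}" for i in range(n_pairs)]
    dmr_set = {int(i): d for i, d in zip(dmr_indices, dmr_direction)}
    rows = {}
    flags = {}
    silent_draw = rng.random(len(genes)) < silent_fraction
    for k, g in enumerate(genes):
        m_c = _promoter_true_methylation(g, meth_control, grid)
        m_t = _promoter_true_methylation(g, meth_treated, grid)
        log_t = baseline[k] - coupling_coeff * m_t + rng.normal(0, noise_sd, n_pairs)
        log_c = baseline[k] - coupling_coeff * m_c + rng.normal(0, noise_sd, n_pairs)
        expr = np.concatenate([2.0**log_t, 2.0**log_c])
        de = "none"
        prom_idx = grid.windows_overlapping(
            g.chrom,
            max(0, g.tss - 2200) if g.strand == "+" else max(0, g.tss - 500),
            g.tss + 500 if g.strand == "+" else g.tss + 2200,
        )
        hosted = [dmr_set[int(i)] for i in prom_idx if int(i) in dmr_set]
        if hosted and rng.random() < p_de:
            de = "down" if hosted[0] == "hyper" else "up"
        if silent_draw[k]:
            expr[:] = 0.0
        rows[g.gene_id] = expr
        flags[g.gene_id] = de
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols_t + cols_c)
    df["mean_treated"] = df[cols_t].mean(axis=1)
    df["mean_control"] = df[cols_c].mean(axis=1)
    df["mean_expr"] = df[cols_t + cols_c].mean(axis=1)
    df["de_flag"] = pd.Series(flags)
    df["silent"] = silent_draw
    df.index.name = "gene_id"
    return df


def simulate_study(
    seed: int = 0,
    *,
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    window_bp: int = 1000,
    cgi_per_mb: float = 10.0,
    n_dmr: int = 100,
    effect_fold: float = 2.0,
    hyper_fraction: float = 0.4,
    n_pairs: int = 6,
    depth: float = 400.0,
    dispersion: float = 0.0,
    background: float = 1.0,
    n_genes: int = 300,
    expr_coupling: float = 5.0,
) -> SyntheticScene:
    """Build the default desk-scale study scene (the `default` preset).

    Two 1 Mb chromosomes tiled with 1 kb windows (2,000 windows), 100
    planted DMRs at 2-fold effect (40% hyper), six treated/control pairs,
    Poisson count noise, 300 genes with expression negatively coupled to
    promoter methylation. Runs in seconds on one CPU and is fully
    reproducible from *seed*.
    """
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_meth, rng_counts, rng_genes, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    assembly, planted_cgis = simulate_genome(
        n_chrom, chrom_len, cgi_per_mb, seed=rng_genome
    )
    genome_lengths = {c: len(s) for c, s in assembly.items()}
    grid = make_windows(genome_lengths, window_bp)
    coup = coupling_vector(grid, assembly)
    meth_c, meth_t, dmr_idx, dmr_dir = simulate_methylome(
        coup, n_dmr, effect_fold, hyper_fraction, seed=rng_meth
    )
    counts = simulate_counts(
        meth_c,
        meth_t,
        coup,
        grid,
        depth=depth,
        n_pairs=n_pairs,
        dispersion=dispersion,
        background=background,
        seed=rng_counts,
    )
    genes = simulate_genes(genome_lengths, n_genes, seed=rng_genes)
    expression = simulate_expression(
        meth_c,
        meth_t,
        genes,
        grid,
        dmr_idx,
        dmr_dir,
        coupling_coeff=expr_coupling,
        n_pairs=n_pairs,
        seed=rng_expr,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        realized = np.where(
            meth_c[dmr_idx] > 0, meth_t[dmr_idx] / meth_c[dmr_idx], np.inf
        )
    truth = SyntheticTruth(
        planted_cgis=planted_cgis,
        dmr_indices=dmr_idx,
        dmr_direction=dmr_dir,
        nominal_fold=effect_fold,
        realized_fold=realized,
        meth_control=meth_c,
        meth_treated=meth_t,
        expr_coupling=expr_coupling,
        seed=seed,
    )
    params = dict(
        seed=seed,
        n_chrom=n_chrom,
        chrom_len=chrom_len,
        window_bp=window_bp,
        cgi_per_mb=cgi_per_mb,
        n_dmr=n_dmr,
        effect_fold=effect_fold,
        hyper_fraction=hyper_fraction,
        n_pairs=n_pairs,
        depth=depth,
        dispersion=dispersion,
        background=background,
        n_genes=n_genes,
        expr_coupling=expr_coupling,
    )
    return SyntheticScene(
        assembly=assembly,
        grid=grid,
        coupling=coup,
        counts=counts,
        genes=genes,
        expression=expression,
        truth=truth,
        params=params,
    )
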