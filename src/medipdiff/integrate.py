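"""Methylation-expression integration.

Relates window-level methylation signal to gene expression: expression
quartiles, genome-wide correlation between promoter methylation and
log2 expression, the 2x2 chi-square overlap test between differentially
methylated and differentially expressed gene sets, and the 2^-ddCt qPCR
fold-change utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FeatureAnnotation
from .dmr import DMRCall


def expression_quartiles(
    mean_expr: pd.Series, silent: pd.Series | None = None
) -> list[pd.Index]:
    """Split genes into four groups by ranked mean expression, low to high.

    Silently expressed genes (flagged in *silent*) are removed first. Ties
    are broken by stable gene-id order, so equal means still yield a
    deterministic equal split. Quartile boundaries fall at the 25/50/75
    rank percentiles.
    """
    expr = mean_expr
    if silent is not None:
        expr = expr[~silent.reindex(expr.index, fill_value=False)]
    if len(expr) == 0:
        raise ValueError("all genes are silent; no quartiles to form")
    if len(expr) < 8:
        raise ValueError("need at least 8 non-silent genes for quartiles")
    order = expr.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], kind="mergesort")
    n = len(order)
    edges = [round(n * k / 4) for k in range(5)]
    return [pd.Index(order["gene_id"].iloc[edges[k] : edges[k + 1]]) for k in range(4)]


def methylation_expression_correlation(
    promoter_methylation: pd.Series,
    expression: pd.Series,
    *,
    log_transform: bool = True,
) -> tuple[float, float]:
    """Pearson correlation of promoter methylation with (log2) expression.

    Genes are matched by id (inner join); expression is transformed to
    ``log2(x + 1)`` by default. Returns (r, two-sided P). Raises on fewer
    than 10 shared genes or zero variance in either vector.
    """
    joined = pd.concat(
        [promoter_methylation.rename("meth"), expression.rename("expr")],
        axis=1,
        join="inner",
    ).dropna()
    if len(joined) < 10:
        raise ValueError("need >= 10 genes with both methylation and expression")
    x = joined["meth"].to_numpy(dtype=float)
    y = joined["expr"].to_numpy(dtype=float)
    if log_transform:
        y = np.log2(y + 1.0)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in methylation or expression vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class OverlapTable:
    """2x2 contingency of differential methylation x differential expression."""

    dm_and_de: int
    dm_only: int
    de_only: int
    neither: int

    @property
    def universe_size(self) -> int:
        return self.dm_and_de + self.dm_only + self.de_only + self.neither

    def as_array(self) -> np.ndarray:
        return np.array([[self.dm_and_de, self.dm_only], [self.de_only, self.neither]])


@dataclass(frozen=True)
class OverlapResult:
    table: OverlapTable
    chi2: float
    p_value: float
    fisher_p: float | None = None


def overlap_chi_square(dm_genes, de_genes, universe) -> OverlapResult:
    """Chi-square independence test (df=1, no continuity correction) for the
    overlap between differentially methylated and differentially expressed
    gene sets within *universe*.

    If any expected cell is below 1 a warning is issued and the Fisher
    exact P is reported alongside.
    """
    universe = set(universe)
    dm = set(dm_genes)
    de = set(de_genes)
    if not dm <= universe or not de <= universe:
        raise ValueError("dm_genes and de_genes must be subsets of the universe")
    a = len(dm & de)
    b = len(dm - de)
    c = len(de - dm)
    d = len(universe) - a - b - c
    table = OverlapTable(a, b, c, d)
    arr = table.as_array()
    chi2, p, _, expected = stats.chi2_contingency(arr, correction=False)
    fisher_p = None
    if (expected < 1).any():
        warnings.warn(
            "expected cell count below 1; chi-square is unreliable, "
            "reporting Fisher exact alternative"
        )
        fisher_p = float(stats.fisher_exact(arr)[1])
    return OverlapResult(table, float(chi2), float(p), fisher_p)


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method.

    ``ddCt = (Ct_target,T - Ct_ref,T) - (Ct_target,C - Ct_ref,C)`` and the
    fold change is ``2 ** -ddCt``.
    """
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def dm_de_genes(
    dmr_calls: list[DMRCall],
    annotation: FeatureAnnotation,
    de_genes,
) -> dict[str, set[str]]:
    """Partition differentially methylated genes by DMR location.

    A gene is promoter-DM if >= 1 DMR overlaps its promoter and body-DM if
    >= 1 DMR overlaps its TSS-TTS span; 'promoter_only', 'body_only' and
    'both' partition the DM gene set. 'dm_and_de' intersects DM genes with
    the supplied differentially expressed set.
    """
    prom_by_gene = {p.gene_id: p.interval for p in annotation.promoters}
    prom_dm: set[str] = set()
    body_dm: set[str] = set()
    for call in dmr_calls:
        w = call.window
        for g in annotation.genes:
            if g.chrom != w.chrom:
                continue
            prom = prom_by_gene.get(g.gene_id)
            if prom is not None and w.start < prom.end and prom.start < w.end:
                prom_dm.add(g.gene_id)
            if w.start < g.end and g.start < w.end:
                body_dm.add(g.gene_id)
    dm_all = prom_dm | body_dm
    return {
        "promoter_only": prom_dm - body_dm,
        "body_only": body_dm - prom_dm,
        "both": prom_dm & body_dm,
        "dm": dm_all,
        "dm_and_de": dm_all & set(de_genes),
    }


def promoter_methylation(
    window_values: np.ndarray,
    grid,
    annotation: FeatureAnnotation,
    coupling: np.ndarray | None = None,
) -> pd.Series:
    """Mean window signal over each gene's promoter.

    The value of every grid window overlapping the promoter is averaged,
    weighted by the overlapping bp. When the CpG-density *coupling* vector
    is given, each window's signal is first divided by its CpG count
    (windows without CpGs are skipped), yielding a relative methylation
    score that controls for local CpG density — MeDIP enrichment scales
    with both methylation and CpG density, so the raw signal confounds the
    two.
    """
    vals = np.asarray(window_values, dtype=float)
    if coupling is not None:
        coupling = np.asarray(coupling, dtype=float)
    out = {}
    for p in annotation.promoters:
        iv = p.interval
        idx = grid.windows_overlapping(iv.chrom, iv.start, iv.end)
        if len(idx) == 0:
            out[p.gene_id] = np.nan
            continue
        weights = []
        for i in idx:
            w = grid.window_interval(int(i))
            weights.append(min(w.end, iv.end) - max(w.start, iv.start))
        weights = np.asarray(weights, dtype=float)
        v = vals[idx]
        if coupling is not None:
            c = coupling[idx]
            keep = c > 0
            if not keep.any():
                out[p.gene_id] = np.nan
                continue
            v, weights = v[keep] / c[keep], weights[keep]
        out[p.gene_id] = float(np.average(v, weights=weights))
    return pd.Series(out, name="promoter_methylation")
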