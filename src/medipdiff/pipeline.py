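"""End-to-end orchestration: counting -> normalization -> paired t -> FDR ->
annotation -> integration, with a reproducibility manifest.

Every run is deterministic given its configuration (which includes the
seed); all output files carry the configuration hash in a leading comment
line, so two runs with equal hashes are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from .annotation import FeatureAnnotation, Gene, assign_to_feature, build_annotation, enrichment_ratio
from .dmr import (
    DMRCall,
    PermutationResult,
    call_dmrs,
    cluster_samples,
    dmrs_to_frame,
    paired_t,
    permutation_fdr,
)
from .integrate import (
    dm_de_genes,
    methylation_expression_correlation,
    overlap_chi_square,
    promoter_methylation,
)
from .quantify import (
    PairedCountMatrix,
    WindowGrid,
    count_in_windows,
    dedup,
    make_windows,
    size_factors,
)

logger = logging.getLogger("medipdiff")


@dataclass
class RunConfig:
    """Analysis parameters; serialized into the reproducibility manifest."""

    window_bp: int = 1000
    t_threshold: float = 7.0
    permutations: int = 10_000
    promoter_up: int = 2200
    promoter_down: int = 500
    shore_bp: int = 2000
    subtelomere_bp: int = 7_000_000
    seed: int = 0
    sex_chrom_exclude: bool = True
    sex_chrom_names: tuple[str, ...] = ("X", "Y", "chrX", "chrY")
    single_end_extension: int = 200

    def __post_init__(self) -> None:
        for name in ("window_bp", "permutations", "promoter_up", "promoter_down", "shore_bp", "subtelomere_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sex_chrom_names"] = list(d["sex_chrom_names"])
        return json.dumps(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of everything a run produced."""

    config: RunConfig
    grid: WindowGrid
    counts: PairedCountMatrix
    t_frame: pd.DataFrame
    dmr_calls: list[DMRCall]
    permutation: PermutationResult | None
    annotation: FeatureAnnotation | None
    dmr_labels: list[str] | None
    enrichment: pd.Series | None
    integration: dict | None
    stage_log: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "config": json.loads(self.config.to_json()),
            "config_hash": self.config.config_hash,
            "stages": self.stage_log,
        }


def _filter_sex_chroms(names: Sequence[str], config: RunConfig) -> set[str]:
    if not config.sex_chrom_exclude:
        return set()
    return {n for n in names if n in set(config.sex_chrom_names)}


def run_pipeline(
    config: RunConfig,
    *,
    assembly: Mapping[str, str],
    genes: Sequence[Gene] | None = None,
    placements: pd.DataFrame | None = None,
    counts: PairedCountMatrix | None = None,
    design: list[tuple[str, str, str]] | None = None,
    expression: pd.DataFrame | None = None,
    de_genes: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full windowed differential-methylation analysis.

    Inputs are either fragment *placements* (with *design*) or a prebuilt
    count matrix. Annotation requires *genes*; integration additionally
    requires *expression* (and optionally an explicit DE gene list,
    otherwise the table's ``de_flag`` column). Stages whose inputs are
    missing are skipped with a log entry; stage failures raise with the
    stage named.
    """
    log: dict = {}
    excluded = _filter_sex_chroms(list(assembly), config)
    work_assembly = {c: s for c, s in assembly.items() if c not in excluded}
    log["sex_chroms_excluded"] = sorted(excluded)

    genome_lengths = {c: len(s) for c, s in work_assembly.items()}
    grid = make_windows(genome_lengths, config.window_bp)
    log["n_windows"] = grid.n_windows

    if counts is None:
        if placements is None or design is None:
            raise ValueError("stage 'counting': need placements+design or a count matrix")
        placements = placements[~placements["chrom"].isin(excluded)]
        before = len(placements)
        placements = dedup(placements)
        log["placements_in"] = before
        log["placements_unique"] = len(placements)
        samples = [s for _, t, c in design for s in (t, c)]
        mat, skip = count_in_windows(placements, grid, samples=sorted(set(samples)))
        log["skipped_chrom_placements"] = skip
        raw = mat[sorted(set(samples))]
        sf = size_factors(raw)
        counts = PairedCountMatrix(grid=grid, raw=raw, size_factors=sf, design=design)
    else:
        grid = counts.grid
    log["n_samples"] = counts.raw.shape[1]
    log["testable_windows"] = int(counts.testable_mask().sum())

    t_frame = paired_t(counts)
    calls = call_dmrs(t_frame, grid, threshold=config.t_threshold)
    log["n_dmrs"] = len(calls)
    log["n_hyper"] = sum(c.direction == "hyper" for c in calls)
    log["n_hypo"] = sum(c.direction == "hypo" for c in calls)

    perm = None
    if calls:
        perm = permutation_fdr(
            counts,
            calls,
            threshold=config.t_threshold,
            n_permutations=config.permutations,
            seed=config.seed,
        )
        log["fdr_estimate"] = perm.fdr_estimate

    ann = None
    labels = None
    enr = None
    if genes is not None:
        ann = build_annotation(
            work_assembly,
            genes,
            promoter_upstream=config.promoter_up,
            promoter_downstream=config.promoter_down,
            shore_bp=config.shore_bp,
        )
        log["n_cgis"] = len(ann.cgis)
        if calls:
            labels = [assign_to_feature(c.window, ann) for c in calls]
            enr = enrichment_ratio(labels, ann)
    else:
        log["annotation"] = "skipped (no gene models)"

    integration = None
    if expression is not None and ann is not None:
        from .quantify import coupling as coupling_vector

        coup = coupling_vector(grid, work_assembly)
        norm = counts.normalized
        integ: dict = {}
        for group, cols in (
            ("treated", counts.treated_samples),
            ("control", counts.control_samples),
        ):
            meth = promoter_methylation(
                norm[cols].mean(axis=1).to_numpy(), grid, ann, coupling=coup
            )
            expr_col = "mean_treated" if group == "treated" else "mean_control"
            if "silent" in expression.columns:
                detected = expression.loc[~expression["silent"], expr_col]
            else:
                detected = expression[expr_col]
            try:
                r, p = methylation_expression_correlation(meth, detected)
                integ[f"correlation_{group}"] = {"r": r, "p": p}
            except ValueError as exc:
                integ[f"correlation_{group}"] = {"error": str(exc)}
        if de_genes is None and "de_flag" in expression.columns:
            de_genes = list(expression.index[expression["de_flag"] != "none"])
        if de_genes is not None and calls:
            sets = dm_de_genes(calls, ann, de_genes)
            integ["dm_gene_sets"] = {k: sorted(v) for k, v in sets.items()}
            universe = set(expression.index) & {g.gene_id for g in ann.genes}
            dm_u = sets["dm"] & universe
            de_u = set(de_genes) & universe
            if dm_u and de_u:
                res = overlap_chi_square(dm_u, de_u, universe)
                integ["overlap_test"] = {
                    "chi2": res.chi2,
                    "p": res.p_value,
                    "table": dataclasses.asdict(res.table),
                    "fisher_p": res.fisher_p,
                }
        integration = integ
    elif expression is None:
        log["integration"] = "skipped (no expression input)"

    result = PipelineResult(
        config=config,
        grid=grid,
        counts=counts,
        t_frame=t_frame,
        dmr_calls=calls,
        permutation=perm,
        annotation=ann,
        dmr_labels=labels,
        enrichment=enr,
        integration=integration,
        stage_log=log,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the result bundle as text files, each tagged with the config hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = result.config.config_hash
    fdr = result.permutation.fdr_estimate if result.permutation else None
    dmr_df = dmrs_to_frame(result.dmr_calls, fdr=fdr)
    mio.write_bed(dmr_df, out / "dmrs.bed", header_comment=f"config_hash={h}")
    coords = result.grid.to_frame()
    norm = pd.concat([coords, result.counts.normalized], axis=1)
    mio.write_counts(norm, out / "normalized_counts.tsv", header_comment=f"config_hash={h}")
    sf = result.counts.size_factors.rename_axis("sample").reset_index()
    mio.write_counts(sf, out / "size_factors.tsv", header_comment=f"config_hash={h}")
    if result.enrichment is not None:
        enr = result.enrichment.rename_axis("feature").reset_index()
        mio.write_counts(enr, out / "enrichment.tsv", header_comment=f"config_hash={h}")
    if result.integration is not None:
        (out / "integration.json").write_text(
            json.dumps({"config_hash": h, **_jsonable(result.integration)}, indent=2, sort_keys=True)
        )
    (out / "manifest.json").write_text(json.dumps(_jsonable(result.manifest()), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
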