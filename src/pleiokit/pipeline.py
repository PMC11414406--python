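"""End-to-end orchestration of the expression pleiotropy analysis.

Chains the stages over a two-background count study: TPM -> gene-set filter
-> log2 + batch correction -> per-strain means -> module detection (per
background) -> per-knockout NB differential expression -> DEG calling ->
conserved/nonconserved partition -> per-knockout pleiotropy report.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import coexpression, diffexpr, pleiotropy, preprocessing
from .diffexpr import DEThresholds
from .preprocessing import CountStudy

logger = logging.getLogger(__name__)


def run_expression_pipeline(
    study: CountStudy,
    thresholds: DEThresholds = DEThresholds(),
    exclude_ids=(),
    clustering_params: coexpression.ClusteringParams | None = None,
    analysis_background: str = "BY",
    other_background: str = "RM",
    rule: str = "significant_both",
) -> dict:
    """Run the full knockout-pleiotropy analysis on a count study.

    DEGs are called per knockout in both backgrounds; the analysis
    background's DEGs are partitioned by their conservation in the other
    background, and pleiotropy values are counted over the analysis
    background's coexpression modules.

    Returns a dict with the per-TF ``report`` DataFrame, the
    ``assignment`` (ModuleAssignment), the filtered ``gene_set``, and the
    per-(TF, background) contrast ``tables``.
    """
    clustering_params = clustering_params or coexpression.ClusteringParams()
    tpm = preprocessing.compute_tpm(study)
    wt = {
        bg: study.wildtype_samples(bg)
        for bg in (analysis_background, other_background)
    }
    gene_set = preprocessing.define_gene_set(tpm, wt, exclude_ids=exclude_ids)
    logger.info("gene set: %d of %d genes", len(gene_set), study.counts.shape[0])

    meta = study.samples.loc[study.counts.columns]
    log2 = preprocessing.log2_transform(
        preprocessing.ExpressionMatrix(tpm.values.loc[gene_set], "tpm")
    )
    # correct batches within each background; genotype structure protected
    corrected = {}
    for bg in (analysis_background, other_background):
        cols = meta.index[meta["background"] == bg]
        sub = preprocessing.ExpressionMatrix(log2.values[cols], "log2tpm")
        corrected[bg] = preprocessing.remove_batch_effects(
            sub, meta.loc[cols, "batch"], groups=meta.loc[cols, "genotype"]
        )
    expr_a = preprocessing.strain_means(corrected[analysis_background], meta)
    assignment = coexpression.detect_modules(expr_a, clustering_params)
    logger.info("detected %d modules", assignment.module_count)

    tfs = sorted(g for g in meta["genotype"].unique() if g != "WT")
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for bg in (analysis_background, other_background):
        bg_meta = meta[meta["background"] == bg]
        for tf in tfs:
            cols = bg_meta.index[bg_meta["genotype"].isin(["WT", tf])]
            counts = study.counts.loc[gene_set, cols]
            sf = diffexpr.estimate_size_factors(counts)
            tables[(tf, bg)] = diffexpr.fit_contrast(
                counts, sf, bg_meta.loc[cols, "genotype"], reference="WT"
            )

    summaries = [
        pleiotropy.summarize_tf(
            tf,
            tables[(tf, analysis_background)],
            tables[(tf, other_background)],
            assignment,
            thresholds,
            rule=rule,
        )
        for tf in tfs
    ]
    report = pleiotropy.report_frame(summaries)
    return {
        "report": report,
        "assignment": assignment,
        "gene_set": gene_set,
        "tables": tables,
    }
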