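"""Module-dispersion pleiotropy and the conserved/nonconserved partition.

The pleiotropy value of a knockout is the number of coexpression modules in
which its DEGs disperse: counting modules instead of genes removes the
redundancy of coregulated gene sets.  A DEG called in background A is
"conserved" when the same gene is also a DEG in background B, otherwise
"nonconserved"; the partition is exact and the two categories' pleiotropy
values are compared across knockouts.  Downstream characterizations --
fold-change distribution contrasts, TF-target enrichment and GO-term
enrichment -- operate on the flat (TF, gene) pair table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, hypergeom, ks_2samp

from .coexpression import ModuleAssignment
from .diffexpr import DEThresholds, call_degs

logger = logging.getLogger(__name__)

CONSERVATION_RULES = ("significant_both", "significant_both_same_direction")


def pleiotropy_value(deg_genes: Iterable[str], assignment: ModuleAssignment) -> int:
    """Number of distinct modules (id > 0) containing at least one DEG.

    Unassigned DEGs (module id 0) are ignored.  Raises if a DEG is missing
    from the module assignment's gene universe, naming the gene.
    """
    genes = list(deg_genes)
    labels = assignment.labels
    for g in genes:
        if g not in labels.index:
            raise KeyError(f"gene {g!r} absent from the module assignment")
    ids = labels.loc[genes]
    return int(ids[ids > 0].nunique())


def classify_conservation(
    degs_a: pd.DataFrame,
    degs_b: pd.DataFrame,
    thresholds: DEThresholds = DEThresholds(),
    thresholds_b: DEThresholds | None = None,
    rule: str = "significant_both",
) -> pd.Series:
    """Categorize background-A DEGs as conserved or nonconserved.

    A DEG of background A is conserved iff it is also a DEG in background B
    at ``thresholds_b`` (defaulting to the same thresholds).  The optional
    rule ``significant_both_same_direction`` additionally requires the fold
    changes to agree in sign.  Returns a Series over A's DEG genes with
    values ``"conserved"``/``"nonconserved"``; the two categories partition
    the A-DEG set exactly.
    """
    if rule not in CONSERVATION_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {CONSERVATION_RULES}")
    thresholds_b = thresholds_b or thresholds
    a = call_degs(degs_a, thresholds)
    b = call_degs(degs_b, thresholds_b)
    a_degs = a.index[a["is_deg"]]
    missing = a_degs.difference(b.index)
    if len(missing):
        raise KeyError(
            f"A-DEG gene {missing[0]!r} missing from background B's analyzed universe"
        )
    conserved = b.loc[a_degs, "is_deg"].to_numpy()
    if rule == "significant_both_same_direction":
        same_dir = (
            a.loc[a_degs, "direction"].to_numpy() == b.loc[a_degs, "direction"].to_numpy()
        )
        conserved = conserved & same_dir
    return pd.Series(
        np.where(conserved, "conserved", "nonconserved"), index=a_degs, name="category"
    )


@dataclass
class TFSummary:
    """Per-knockout pleiotropy report row."""

    tf: str
    n_deg: int
    pleiotropy_overall: int
    n_conserved: int
    n_nonconserved: int
    pleiotropy_conserved: int
    pleiotropy_nonconserved: int

    @property
    def conserved_fraction(self) -> float:
        return self.n_conserved / self.n_deg if self.n_deg else float("nan")


def summarize_tf(
    tf: str,
    degs_a: pd.DataFrame,
    degs_b: pd.DataFrame,
    assignment: ModuleAssignment,
    thresholds: DEThresholds = DEThresholds(),
    thresholds_b: DEThresholds | None = None,
    rule: str = "significant_both",
) -> TFSummary:
    """Full conserved/nonconserved pleiotropy report for one knockout."""
    categories = classify_conservation(degs_a, degs_b, thresholds, thresholds_b, rule)
    degs = categories.index
    cons = categories.index[categories == "conserved"]
    noncons = categories.index[categories == "nonconserved"]
    return TFSummary(
        tf=tf,
        n_deg=len(degs),
        pleiotropy_overall=pleiotropy_value(degs, assignment),
        n_conserved=len(cons),
        n_nonconserved=len(noncons),
        pleiotropy_conserved=pleiotropy_value(cons, assignment),
        pleiotropy_nonconserved=pleiotropy_value(noncons, assignment),
    )


def report_frame(summaries: Iterable[TFSummary]) -> pd.DataFrame:
    rows = [
        {
            "tf": s.tf,
            "n_deg": s.n_deg,
            "pleiotropy_overall": s.pleiotropy_overall,
            "n_conserved": s.n_conserved,
            "n_nonconserved": s.n_nonconserved,
            "pleiotropy_conserved": s.pleiotropy_conserved,
            "pleiotropy_nonconserved": s.pleiotropy_nonconserved,
            "conserved_fraction": s.conserved_fraction,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows).set_index("tf")


def threshold_sweep(
    contrasts: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    assignment: ModuleAssignment,
    grid_b: Sequence[DEThresholds],
    thresholds_a: DEThresholds = DEThresholds(),
    rule: str = "significant_both",
) -> pd.DataFrame:
    """Robustness sweep over background-B DEG thresholds.

    For each B-threshold setting, re-partitions every knockout's A-DEGs and
    reports median conserved/nonconserved pleiotropy and median conserved
    fraction across knockouts.  Loosening B thresholds can only grow each
    knockout's conserved set (monotone by construction of the DEG rule).
    """
    if not grid_b:
        raise ValueError("threshold grid is empty")
    rows = []
    for tb in grid_b:
        summaries = [
            summarize_tf(tf, a, b, assignment, thresholds_a, tb, rule)
            for tf, (a, b) in contrasts.items()
        ]
        rep = report_frame(summaries)
        rows.append(
            {
                "fc_threshold_b": tb.fc_threshold,
                "padj_threshold_b": tb.padj_threshold,
                "median_pleiotropy_conserved": rep["pleiotropy_conserved"].median(),
                "median_pleiotropy_nonconserved": rep["pleiotropy_nonconserved"].median(),
                "median_conserved_fraction": rep["conserved_fraction"].median(),
            }
        )
    return pd.DataFrame(rows)


def fc_distribution_test(pairs: pd.DataFrame, regulator_class: str) -> dict:
    """Two-sample KS test of conserved vs nonconserved fold changes.

    ``pairs`` needs columns ``log2fc``, ``category`` and
    ``regulator_class``; the test is restricted to pairs of the requested
    class.  Reports the KS statistic and two-sided p plus each category's
    median fold-change sign.
    """
    sub = pairs[pairs["regulator_class"] == regulator_class]
    cons = sub.loc[sub["category"] == "conserved", "log2fc"].to_numpy()
    noncons = sub.loc[sub["category"] == "nonconserved", "log2fc"].to_numpy()
    if cons.size == 0 or noncons.size == 0:
        raise ValueError(
            f"empty conserved or nonconserved category for class {regulator_class!r}; "
            "consider looser DEG thresholds"
        )
    res = ks_2samp(cons, noncons, alternative="two-sided", method="auto")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_sign_conserved": int(np.sign(np.median(cons))),
        "median_sign_nonconserved": int(np.sign(np.median(noncons))),
        "n_conserved": int(cons.size),
        "n_nonconserved": int(noncons.size),
    }


def target_enrichment(
    pairs: pd.DataFrame,
    targets: Mapping[str, set],
    n_universe_pairs: int,
    n_universe_targets: int,
    compare: tuple[str, str] = ("conserved", "nonconserved"),
    method: str = "chi2",
) -> dict:
    """Proportion of (TF, gene) pairs that are annotated regulatory targets.

    Reports the target proportion per category, overall, and in the genomic
    background (``n_universe_targets / n_universe_pairs``), plus a 2x2 test
    (chi-square without continuity correction by default; ``method="fisher"``
    for small tables) between the two requested categories.  Percentages are
    rounded to 1 decimal to match conventional reporting.
    """
    is_target = pairs.apply(
        lambda row: row["gene"] in targets.get(row["tf"], set()), axis=1
    )
    pairs = pairs.assign(is_target=is_target)
    proportions = {}
    counts = {}
    for cat in list(pairs["category"].unique()) + ["overall"]:
        sub = pairs if cat == "overall" else pairs[pairs["category"] == cat]
        if len(sub) == 0:
            raise ValueError(f"category {cat!r} is empty; proportion undefined")
        counts[cat] = (int(sub["is_target"].sum()), len(sub))
        proportions[cat] = round(100.0 * sub["is_target"].mean(), 1)
    proportions["background"] = round(100.0 * n_universe_targets / n_universe_pairs, 1)
    for cat in compare:
        if cat not in counts:
            raise ValueError(f"category {cat!r} is empty; proportion undefined")
    k1, n1 = counts[compare[0]]
    k2, n2 = counts[compare[1]]
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if method == "fisher":
        _, p = fisher_exact(table)
    else:
        _, p, _, _ = chi2_contingency(table, correction=False)
    return {"proportions_pct": proportions, "counts": counts, "test_p": float(p)}


def go_enrichment(
    deg_genes: Iterable[str],
    annotation: Mapping[str, set],
    universe: Iterable[str],
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment over a DEG set.

    Per term: fold enrichment ``(k/n) / (K/N)`` and upper-tail
    ``P(X >= k)``; a term is enriched iff fold > 2 and p < 0.05 (defaults).
    Terms with zero members in the universe are skipped with a log entry.
    Also see :func:`fraction_in_enriched_terms`.
    """
    universe = set(universe)
    degs = set(deg_genes)
    if not degs <= universe:
        raise ValueError("DEG set must be contained in the universe")
    N, n = len(universe), len(degs)
    rows = []
    for term, members in annotation.items():
        members = set(members) & universe
        K = len(members)
        if K == 0:
            logger.info("term %r has no universe members; skipped", term)
            continue
        if n == 0:
            continue
        k = len(members & degs)
        fold = (k / n) / (K / N) if k else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n)) if k else 1.0
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fold_enrichment": fold,
                "p_value": p,
                "enriched": fold > fold_threshold and p < p_threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "fold_enrichment", "p_value", "enriched"]
    )


def fraction_in_enriched_terms(
    deg_genes: Iterable[str], enrichment: pd.DataFrame, annotation: Mapping[str, set]
) -> float:
    """Fraction of DEGs belonging to at least one enriched term."""
    degs = set(deg_genes)
    if not degs:
        return float("nan")
    enriched_terms = enrichment.loc[enrichment["enriched"], "term"]
    covered = set()
    for term in enriched_terms:
        covered |= set(annotation[term]) & degs
    return len(covered) / len(degs)
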