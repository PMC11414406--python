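"""Derived-allele polarization and new/old age classification of eQTLs.

Markers segregating between the two focal backgrounds (BY and RM) are
polarized against the ancestral Taiwanese lineage and the outgroup species:
the allele carried unanimously by all Taiwanese strains and the outgroup is
ancestral, the other focal allele derived.  An eQTL is "new" when its
derived allele is confined to the BY lineage or to the RM lineage, and
"old" when the derived allele is already present in the Chinese lineage
(the ancestral population of the species); everything else stays
unclassified.  New and old classes are then contrasted on the number of
genes whose expression each eQTL affects (its pleiotropy) and on the
expression variance it explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

logger = logging.getLogger(__name__)

LINEAGES = ("BY_lineage", "RM_lineage", "CHN", "TW", "other", "outgroup")
#: lineages that must be represented for a panel to be usable
REQUIRED_LINEAGES = ("BY_lineage", "RM_lineage", "CHN", "TW", "outgroup")


@dataclass
class AllelePanel:
    """Marker allele states across a lineage-labelled strain panel.

    Attributes
    ----------
    genotypes:
        DataFrame markers x strains of allele symbols (NaN = missing call).
    lineages:
        Series strain -> lineage label, one of :data:`LINEAGES`.
    focal_alleles:
        DataFrame indexed by marker with columns ``BY`` and ``RM`` giving
        the focal backgrounds' alleles (biallelic and distinct per marker).
    """

    genotypes: pd.DataFrame
    lineages: pd.Series
    focal_alleles: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = set(self.lineages.unique()) - set(LINEAGES)
        if unknown:
            raise ValueError(f"unknown lineage labels: {sorted(unknown)}")
        for lin in REQUIRED_LINEAGES:
            if not (self.lineages == lin).any():
                raise ValueError(f"panel has no strain in required lineage {lin!r}")
        missing = self.genotypes.columns.difference(self.lineages.index)
        if len(missing):
            raise ValueError(f"strains without lineage labels: {list(missing[:5])}")

    def strains_of(self, lineage: str) -> list[str]:
        return list(self.lineages.index[self.lineages == lineage])


@dataclass(frozen=True)
class Polarization:
    ancestral: str | None
    derived: str | None
    reason: str  # "ok" or why unresolved

    @property
    def resolved(self) -> bool:
        return self.reason == "ok"


def polarize(panel: AllelePanel, marker: str) -> Polarization:
    """Determine ancestral and derived alleles for one marker.

    The ancestral allele is the one carried unanimously by every Taiwanese
    strain and the outgroup; the derived allele is the other focal allele.
    Unresolved when Taiwanese strains disagree among themselves or with the
    outgroup, when a required call is missing, or when the unanimous allele
    matches neither focal allele.
    """
    by, rm = panel.focal_alleles.loc[marker, ["BY", "RM"]]
    if pd.isna(by) or pd.isna(rm):
        return Polarization(None, None, "missing_focal_allele")
    if by == rm:
        raise ValueError(f"marker {marker!r} is not polymorphic between BY and RM")
    row = panel.genotypes.loc[marker]
    tw = row[panel.strains_of("TW")]
    og = row[panel.strains_of("outgroup")]
    if tw.isna().any():
        return Polarization(None, None, "missing_tw_call")
    if og.isna().any():
        return Polarization(None, None, "missing_outgroup_call")
    tw_alleles = set(tw)
    og_alleles = set(og)
    if len(tw_alleles) > 1:
        return Polarization(None, None, "tw_not_unanimous")
    if len(og_alleles) > 1 or tw_alleles != og_alleles:
        return Polarization(None, None, "tw_outgroup_disagree")
    ancestral = tw_alleles.pop()
    if ancestral == by:
        return Polarization(ancestral, rm, "ok")
    if ancestral == rm:
        return Polarization(ancestral, by, "ok")
    return Polarization(None, None, "ancestral_not_focal")


def classify_age(panel: AllelePanel, marker: str, polarization: Polarization | None = None) -> str:
    """Age class of a marker: ``"new"``, ``"old"`` or ``"unclassified"``.

    New: the derived allele occurs only in BY-lineage strains, or only in
    RM-lineage strains, among all non-outgroup panel strains.  Old: the
    derived allele occurs in at least one Chinese-lineage strain.  A derived
    allele seen in both focal lineages, or only in "other" clades, stays
    unclassified.  Pure function of allele presence patterns; a marker with
    missing calls in CHN strains is unclassified (absence of evidence).
    """
    pol = polarization or polarize(panel, marker)
    if not pol.resolved:
        return "unclassified"
    row = panel.genotypes.loc[marker]
    chn = row[panel.strains_of("CHN")]
    if chn.isna().any():
        return "unclassified"
    carriers = {
        lin
        for lin in ("BY_lineage", "RM_lineage", "CHN", "TW", "other")
        for s in panel.strains_of(lin)
        if row.get(s) == pol.derived
    }
    if "CHN" in carriers:
        return "old"
    if carriers == {"BY_lineage"} or carriers == {"RM_lineage"}:
        return "new"
    return "unclassified"


def classify_panel(panel: AllelePanel, eqtl_table: pd.DataFrame) -> pd.DataFrame:
    """Polarize and age-classify every eQTL marker.

    ``eqtl_table`` is indexed by marker with columns ``n_affected_genes``
    and ``variance_explained``.  Adds ``ancestral``, ``derived``,
    ``age_class`` and ``reason`` columns.
    """
    rows = []
    for marker in eqtl_table.index:
        pol = polarize(panel, marker)
        age = classify_age(panel, marker, pol)
        rows.append(
            {
                "marker": marker,
                "ancestral": pol.ancestral,
                "derived": pol.derived,
                "age_class": age,
                "reason": pol.reason,
            }
        )
    extra = pd.DataFrame(rows).set_index("marker")
    return eqtl_table.join(extra)


def rank_sum_test(x: Iterable[float], y: Iterable[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by full enumeration of rank-sum assignments when both samples
    have at most 10 observations (valid with ties); otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if x.size <= 10 and y.size <= 10:
        ranks = rankdata(np.concatenate([x, y]))
        n = ranks.size
        observed = ranks[: x.size].sum()
        sums = np.array(
            [ranks[list(c)].sum() for c in combinations(range(n), x.size)]
        )
        p_low = np.mean(sums <= observed + 1e-9)
        p_high = np.mean(sums >= observed - 1e-9)
        return float(min(1.0, 2.0 * min(p_low, p_high)))
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def compare_by_age(records: pd.DataFrame) -> dict:
    """Contrast new vs old eQTLs on pleiotropy and variance explained.

    ``records`` must carry ``age_class``, ``n_affected_genes`` and
    ``variance_explained``.  Reports two-sided rank-sum p-values for each
    quantity plus, per class, the fraction of eQTLs affecting >= 2 genes
    and exactly 1 gene.
    """
    new = records[records["age_class"] == "new"]
    old = records[records["age_class"] == "old"]
    if len(new) == 0 or len(old) == 0:
        raise ValueError("need at least one eQTL in each of the new and old classes")
    out = {
        "n_new": len(new),
        "n_old": len(old),
        "affected_genes_p": rank_sum_test(new["n_affected_genes"], old["n_affected_genes"]),
        "variance_explained_p": rank_sum_test(
            new["variance_explained"], old["variance_explained"]
        ),
        "median_affected_new": float(new["n_affected_genes"].median()),
        "median_affected_old": float(old["n_affected_genes"].median()),
        "median_variance_new": float(new["variance_explained"].median()),
        "median_variance_old": float(old["variance_explained"].median()),
    }
    for label, sub in (("new", new), ("old", old)):
        out[f"frac_multigene_{label}"] = float((sub["n_affected_genes"] >= 2).mean())
        out[f"frac_single_gene_{label}"] = float((sub["n_affected_genes"] == 1).mean())
    return out
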