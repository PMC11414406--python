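"""Knockout pleiotropy on correlated cell-morphology traits.

Observations (one row per strain x biological replicate x technical
replicate) are quantile-normalized across traits, traits are grouped by
affinity propagation on negative squared Euclidean distances between their
knockout-averaged profiles, per-trait knockout effects are tested with a
mixed-model likelihood-ratio test, and the pleiotropy value is the number
of trait clusters containing at least one significantly altered trait.

Two altered-trait threshold profiles exist side by side because the source
conventions differ: ``"methods"`` (p < 0.01 and a two-sided fold-change
gate) and ``"results"`` (p < 0.05 only).  Every call must name its profile
explicitly; there is no silent default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2, pearsonr
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: metadata columns preceding the trait columns in an observation table
OBS_COLUMNS = ("background", "genotype", "bio_rep", "tech_rep", "batch")


@dataclass
class TraitStudy:
    """Replicated trait observations for knockouts and wild-type controls.

    ``observations`` has the metadata columns of :data:`OBS_COLUMNS`
    followed by one column per trait.  Every knockout batch contains the
    wild-type control measured in the same batch.
    """

    observations: pd.DataFrame
    trait_ids: list[str]

    def __post_init__(self) -> None:
        for col in OBS_COLUMNS:
            if col not in self.observations.columns:
                raise ValueError(f"observations lack column {col!r}")
        missing = [t for t in self.trait_ids if t not in self.observations.columns]
        if missing:
            raise ValueError(f"missing trait columns: {missing[:5]}")
        if self.observations[self.trait_ids].isna().any().any():
            raise ValueError("missing trait values are not supported")

    def traits(self) -> pd.DataFrame:
        return self.observations[self.trait_ids]


@dataclass
class TraitClusterAssignment:
    """Trait -> cluster id map with per-cluster exemplar traits."""

    labels: pd.Series
    exemplars: dict[int, str]

    @property
    def cluster_count(self) -> int:
        return int(self.labels.nunique())


def quantile_normalize(traits: pd.DataFrame) -> pd.DataFrame:
    """Map every trait column onto the mean order statistics across columns.

    After normalization all columns share an identical sorted value
    multiset; ties receive the average of the reference values at their
    rank positions.  A constant column maps to the median reference value
    (logged), since all its ranks tie at the midpoint.
    """
    mat = traits.to_numpy(float)
    n = mat.shape[0]
    reference = np.sort(mat, axis=0).mean(axis=1)
    ranks = traits.rank(method="average").to_numpy()
    out = np.interp(ranks - 1.0, np.arange(n), reference)
    constant = mat.std(axis=0) == 0
    if constant.any():
        logger.info(
            "%d constant trait columns mapped to the median reference value",
            int(constant.sum()),
        )
    return pd.DataFrame(out, index=traits.index, columns=traits.columns)


def trait_profiles(study: TraitStudy, background: str, normalize: bool = True) -> pd.DataFrame:
    """Trait x strain matrix of replicate-averaged (normalized) values.

    These knockout-averaged coordinates are the points fed to trait
    clustering, computed per background.
    """
    obs = study.observations[study.observations["background"] == background]
    if obs.empty:
        raise ValueError(f"no observations for background {background!r}")
    values = obs[study.trait_ids]
    if normalize:
        values = quantile_normalize(values)
    grouped = values.groupby(obs["genotype"].to_numpy()).mean()
    return grouped.T  # traits x strains


def affinity_propagation(
    points: pd.DataFrame,
    damping: float = 0.9,
    preference: float | None = None,
    max_iter: int = 2000,
    convergence_iter: int = 50,
) -> TraitClusterAssignment:
    """Cluster traits by affinity propagation on -squared Euclidean distance.

    The shared preference defaults to the median similarity; exemplars are
    actual traits.  Deterministic given the inputs and damping.  Raises on
    non-convergence, advising higher damping.
    """
    X = points.to_numpy(float)
    if X.shape[0] < 1:
        raise ValueError("no points to cluster")
    if X.shape[0] == 1:
        labels = pd.Series([0], index=points.index)
        return TraitClusterAssignment(labels=labels, exemplars={0: points.index[0]})
    diff = X[:, None, :] - X[None, :, :]
    S = -np.sum(diff**2, axis=2)
    ap = AffinityPropagation(
        damping=damping,
        preference=preference,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        affinity="precomputed",
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap.fit(S)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                "affinity propagation did not converge; increase damping or max_iter"
            ) from exc
    if len(ap.cluster_centers_indices_) == 0:
        raise RuntimeError(
            "affinity propagation found no exemplars; increase damping or max_iter"
        )
    labels = pd.Series(ap.labels_, index=points.index)
    exemplars = {
        int(c): points.index[i] for c, i in enumerate(ap.cluster_centers_indices_)
    }
    return TraitClusterAssignment(labels=labels, exemplars=exemplars)


@dataclass(frozen=True)
class AlteredProfile:
    """Named altered-trait threshold profile; no silent default exists."""

    name: str
    p_threshold: float
    fc_threshold: float | None  # None: no fold-change gate


PROFILES: Mapping[str, AlteredProfile] = {
    "methods": AlteredProfile("methods", p_threshold=0.01, fc_threshold=1.0),
    "results": AlteredProfile("results", p_threshold=0.05, fc_threshold=None),
}


def _fc_gate(fc: float, threshold: float) -> bool:
    # two-sided: a decrease of the same magnitude counts as much as an increase
    if fc <= 0:
        return True
    return max(fc, 1.0 / fc) > threshold


def _lrt_one_trait(values: np.ndarray, mutation: np.ndarray, groups: np.ndarray) -> float:
    """Mixed-model LRT p for the mutation effect on one trait.

    Full model: value ~ 1 + mutation with a random intercept per biological
    replicate, fit by maximum likelihood (an LRT on a fixed effect requires
    ML, not REML).  Null drops the mutation term.  Singular or non-converged
    fits fall back to a fixed-effects ANOVA (logged).
    """
    exog_full = np.column_stack([np.ones_like(mutation, dtype=float), mutation])
    exog_null = exog_full[:, :1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.MixedLM(values, exog_full, groups=groups).fit(reml=False)
            null = sm.MixedLM(values, exog_null, groups=groups).fit(reml=False)
        stat = 2.0 * (full.llf - null.llf)
        if not np.isfinite(stat):
            raise ValueError("non-finite likelihood")
    except (np.linalg.LinAlgError, ValueError):
        logger.info("mixed model failed; falling back to fixed-effects ANOVA")
        full = sm.OLS(values, exog_full).fit()
        null = sm.OLS(values, exog_null).fit()
        stat = 2.0 * (full.llf - null.llf)
    return float(chi2.sf(max(stat, 0.0), df=1))


def detect_altered_traits(
    study: TraitStudy,
    tf: str,
    background: str,
    profile: AlteredProfile,
    normalize: bool = True,
) -> pd.DataFrame:
    """Test every trait for alteration in a knockout vs its batch controls.

    Uses all biological and technical replicates of the knockout plus the
    wild-type observations from the same batches.  Returns a DataFrame per
    trait with ``lrt_p``, ``fc`` (knockout mean / wild-type mean),
    ``is_altered`` and the profile name applied.
    """
    obs = study.observations
    obs = obs[obs["background"] == background]
    ko = obs[obs["genotype"] == tf]
    if ko.empty:
        raise ValueError(f"no observations for knockout {tf!r} in {background!r}")
    wt = obs[(obs["genotype"] == "WT") & obs["batch"].isin(ko["batch"].unique())]
    if wt.empty:
        raise ValueError(f"no same-batch wild-type controls for {tf!r}")
    if ko["bio_rep"].nunique() < 2 or wt["bio_rep"].nunique() < 2:
        raise ValueError("need >= 2 biological replicates for knockout and wild type")
    data = pd.concat([ko, wt])
    values = data[study.trait_ids]
    if normalize:
        values = quantile_normalize(values)
    mutation = (data["genotype"] == tf).to_numpy(float)
    groups = (
        data["genotype"].astype(str) + ":" + data["bio_rep"].astype(str)
    ).to_numpy()
    rows = []
    for trait in study.trait_ids:
        v = values[trait].to_numpy(float)
        p = _lrt_one_trait(v, mutation, groups)
        ko_mean = v[mutation == 1].mean()
        wt_mean = v[mutation == 0].mean()
        fc = ko_mean / wt_mean if wt_mean != 0 else np.inf
        altered = p < profile.p_threshold
        if profile.fc_threshold is not None:
            altered = altered and _fc_gate(fc, profile.fc_threshold)
        rows.append({"trait": trait, "lrt_p": p, "fc": fc, "is_altered": altered})
    out = pd.DataFrame(rows).set_index("trait")
    out["profile"] = profile.name
    return out


def trait_pleiotropy_value(
    altered_traits: Iterable[str], clusters: TraitClusterAssignment
) -> int:
    """Number of distinct trait clusters containing >= 1 altered trait."""
    altered = list(altered_traits)
    for t in altered:
        if t not in clusters.labels.index:
            raise KeyError(f"trait {t!r} absent from the cluster assignment")
    return int(clusters.labels.loc[altered].nunique())


def replicate_reproducibility(
    study: TraitStudy, tf: str, background: str, normalize: bool = True
) -> pd.DataFrame:
    """Pearson R of fold-change vectors between biological replicate pairs.

    Per biological replicate, the trait-wise fold change is the mean over
    technical replicates divided by the same-batch wild-type mean.  A pair
    with a zero-variance fold-change vector is reported with missing R.
    """
    obs = study.observations[study.observations["background"] == background]
    ko = obs[obs["genotype"] == tf]
    if ko["bio_rep"].nunique() < 2:
        raise ValueError("need >= 2 biological replicates")
    wt = obs[(obs["genotype"] == "WT") & obs["batch"].isin(ko["batch"].unique())]
    values = pd.concat([ko, wt])
    traits = values[study.trait_ids]
    if normalize:
        traits = quantile_normalize(traits)
    values = pd.concat([values[list(OBS_COLUMNS)], traits], axis=1)
    fcs = {}
    for rep, sub in values[values["genotype"] == tf].groupby("bio_rep"):
        batch_wt = values[
            (values["genotype"] == "WT") & values["batch"].isin(sub["batch"].unique())
        ]
        fcs[rep] = (
            sub[study.trait_ids].mean() / batch_wt[study.trait_ids].mean()
        ).to_numpy()
    reps = sorted(fcs)
    rows = []
    for i, r1 in enumerate(reps):
        for r2 in reps[i + 1 :]:
            a, b = fcs[r1], fcs[r2]
            if np.std(a) == 0 or np.std(b) == 0:
                r = np.nan
            else:
                r = pearsonr(a, b).statistic
            rows.append({"rep_a": r1, "rep_b": r2, "pearson_r": r})
    return pd.DataFrame(rows)
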