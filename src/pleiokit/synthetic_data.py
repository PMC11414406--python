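"""Synthetic two-background knockout studies with planted ground truth.

Three generators emulate the statistical structure the analysis assumes:

* :func:`generate_expression_study` -- negative-binomial read counts for a
  panel of TF knockouts plus wild type in two genetic backgrounds, with
  planted coexpression modules (per-strain latent factor scores times gene
  loadings on the log scale), additive per-batch offsets, and knockout
  effects split into a background-shared ("conserved") set concentrated in
  the TF's home module and background-specific sets scattered genome-wide.
* :func:`generate_morphology_study` -- block-correlated trait observations
  with replicate structure and planted mean shifts in knockout groups.
* :func:`generate_allele_panel` -- a biallelic marker panel over a
  lineage-labelled strain collection in which planted "new" derived alleles
  are confined to one focal lineage while "old" derived alleles segregate
  in the Chinese lineage; affected-gene counts and variance explained are
  drawn so new markers are more pleiotropic but weaker.

One global seed drives a hierarchical stream with one substream per dataset
kind, so regenerating one dataset never perturbs the others, and a fixed
seed fixes every emitted artifact bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .eqtl_age import AllelePanel
from .morphology import TraitStudy
from .preprocessing import CountStudy

_STREAMS = ("expression", "morphology", "panel")

DEFAULT_LINEAGE_SIZES: Mapping[str, int] = {
    "BY_lineage": 2,
    "RM_lineage": 2,
    "CHN": 5,
    "TW": 3,
    "other": 21,
    "outgroup": 1,
}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generators.

    Expression defaults describe a desk-scale two-background knockout
    study: 600 genes in 6 planted modules, 20 TF knockouts with 2
    biological replicates each (replication level of the emulated study),
    30 DEGs per knockout of which 15% are shared between backgrounds at a
    planted |log2 fold change| of 2.  Morphology defaults use the study's
    184 traits in 28 clusters with 3 biological x 3 technical replicates.
    The allele panel mirrors the 33-strain lineage panel (2 BY, 2 RM, 5
    Chinese, 3 Taiwanese, 21 other, 1 outgroup strain).
    """

    # expression
    n_genes: int = 600
    n_modules: int = 6
    genes_per_module: int = 80
    n_tfs: int = 20
    n_backgrounds: int = 2  # fixed
    replicates_per_group: int = 2
    batch_sd: float = 0.3  # additive log2-scale per-batch offset SD
    module_amplitude: float = 0.3  # log2-scale SD of strain-level module variation
    nb_dispersion: float = 0.05
    deg_per_tf: int = 30
    conserved_fraction: float = 0.15
    effect_log2fc: float = 2.0
    regulator_class_map: Mapping[str, str] | None = None
    # morphology
    n_traits: int = 184
    n_trait_clusters: int = 28
    trait_alteration_sd_units: float = 5.0
    trait_within_cluster_r: float = 0.7
    traits_altered_per_tf: int = 20
    trait_replicate_sd: float = 0.2
    trait_batch_sd: float = 0.1
    bio_replicates: int = 3
    tech_replicates: int = 3
    # allele panel
    n_markers: int = 500
    n_segregant_strains: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_SIZES)
    )
    age_mix: float = 0.55  # fraction of markers planted as "new"
    new_affected_mean: float = 3.0
    old_affected_mean: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_backgrounds != 2:
            raise ValueError("n_backgrounds is fixed at 2")
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValueError("n_modules * genes_per_module must not exceed n_genes")
        if not 0 <= self.conserved_fraction <= 1:
            raise ValueError("conserved_fraction must lie in [0, 1]")
        if not 0 <= self.age_mix <= 1:
            raise ValueError("age_mix must lie in [0, 1]")
        for name in (
            "n_genes",
            "n_modules",
            "genes_per_module",
            "n_tfs",
            "deg_per_tf",
            "n_traits",
            "n_trait_clusters",
            "n_markers",
            "bio_replicates",
            "tech_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_trait_clusters > self.n_traits:
            raise ValueError("n_trait_clusters must not exceed n_traits")
        for v in ("batch_sd", "nb_dispersion", "trait_alteration_sd_units"):
            if getattr(self, v) < 0:
                raise ValueError(f"{v} must be nonnegative")

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i:02d}" for i in range(1, self.n_tfs + 1)]

    @property
    def conserved_per_tf(self) -> int:
        # deterministic rounding: ties go up (0.15 * 30 = 4.5 -> 5)
        return _round_half_up(self.conserved_fraction * self.deg_per_tf)

    def regulator_classes(self) -> dict[str, str]:
        """TF -> activator/repressor/unknown map.

        When not supplied, roughly 42% of TFs are activators and 13%
        repressors (the annotated composition of the emulated TF panel);
        the rest are unknown.
        """
        if self.regulator_class_map is not None:
            return dict(self.regulator_class_map)
        n_act = _round_half_up(0.42 * self.n_tfs)
        n_rep = _round_half_up(0.13 * self.n_tfs)
        classes = {}
        for i, tf in enumerate(self.tf_names):
            if i < n_act:
                classes[tf] = "activator"
            elif i < n_act + n_rep:
                classes[tf] = "repressor"
            else:
                classes[tf] = "unknown"
        return classes


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    Only the fields relevant to the generated dataset kind are populated.
    Invariants: each conserved set is a subset of the TF's DEG set in both
    backgrounds; new derived alleles are confined to one focal lineage.
    """

    module_labels: pd.Series | None = None
    deg_sets: dict | None = None  # (tf, background) -> {gene: signed log2fc}
    conserved_sets: dict | None = None  # tf -> frozenset of genes
    trait_cluster_labels: pd.Series | None = None
    altered_traits: dict | None = None  # tf -> frozenset of traits
    marker_ages: pd.Series | None = None
    marker_affected_counts: pd.Series | None = None
    marker_variance: pd.Series | None = None


def _substream(seed: int, kind: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(kind)])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_expression_study(config: SimulationConfig) -> tuple[CountStudy, PlantedTruth]:
    """Simulate a replicated two-background knockout count study.

    Counts are negative binomial with log2 mean = gene baseline + module
    loading x per-strain factor score + planted knockout effect + per-batch
    offset.  Each (TF, background) DEG set has ``deg_per_tf`` genes, of
    which ``round(conserved_fraction * deg_per_tf)`` (half up) are shared
    between backgrounds and drawn from the TF's home module; the remainder
    are background-specific and scattered over all genes.  Conserved
    effects of activators are planted negative (targets drop on knockout),
    of repressors positive.  With ``effect_log2fc == 0`` no effects are
    planted and all DEG sets are empty.
    """
    if config.replicates_per_group < 2:
        raise ValueError("replicates_per_group must be >= 2 (the DE stage needs replication)")
    rng = _substream(config.seed, "expression")
    G = config.n_genes
    genes = pd.Index([f"g{i:04d}" for i in range(1, G + 1)], name="gene")
    lengths = pd.Series(
        np.clip(rng.lognormal(np.log(1500.0), 0.35, G), 200, None).astype(int),
        index=genes,
        name="length",
    )
    baseline = rng.normal(7.0, 1.5, G)  # log2 expected counts

    # planted module structure: shuffled assignment, id 0 for leftover genes
    labels = np.zeros(G, dtype=int)
    order = rng.permutation(G)
    for m in range(config.n_modules):
        members = order[m * config.genes_per_module : (m + 1) * config.genes_per_module]
        labels[members] = m + 1
    module_labels = pd.Series(labels, index=genes, name="module")
    # strain-level coexpression variation sits below the DE fold-change gate
    # (~1.2x) yet above replicate noise, so modules are detectable across
    # strains without whole modules turning into knockout fold changes
    loadings = np.where(
        labels > 0, config.module_amplitude * rng.uniform(0.8, 1.2, G), 0.0
    )

    backgrounds = ("BY", "RM")
    tfs = config.tf_names
    classes = config.regulator_classes()
    genotypes = ["WT"] + tfs
    R = config.replicates_per_group

    # planted knockout effects
    deg_sets: dict[tuple[str, str], dict[str, float]] = {}
    conserved_sets: dict[str, frozenset] = {}
    if config.effect_log2fc != 0.0:
        n_cons = config.conserved_per_tf
        if n_cons > config.genes_per_module:
            raise ValueError("conserved set larger than a planted module")
        all_positions = np.arange(G)
        for tf in tfs:
            home = rng.integers(1, config.n_modules + 1)
            home_positions = np.flatnonzero(labels == home)
            cons_pos = rng.choice(home_positions, size=n_cons, replace=False)
            pool = np.setdiff1d(all_positions, cons_pos)
            n_specific = config.deg_per_tf - n_cons
            specific = rng.choice(pool, size=2 * n_specific, replace=False)
            if classes[tf] == "activator":
                cons_signs = -np.ones(n_cons)
            elif classes[tf] == "repressor":
                cons_signs = np.ones(n_cons)
            else:
                cons_signs = rng.choice([-1.0, 1.0], size=n_cons)
            cons_effects = {
                genes[p]: s * config.effect_log2fc for p, s in zip(cons_pos, cons_signs)
            }
            conserved_sets[tf] = frozenset(cons_effects)
            for bi, bg in enumerate(backgrounds):
                spec_pos = specific[bi * n_specific : (bi + 1) * n_specific]
                spec_signs = rng.choice([-1.0, 1.0], size=n_specific)
                effects = dict(cons_effects)
                effects.update(
                    {
                        genes[p]: s * config.effect_log2fc
                        for p, s in zip(spec_pos, spec_signs)
                    }
                )
                deg_sets[(tf, bg)] = effects

    # sample sheet and per-strain factor scores
    sample_rows = []
    for bg in backgrounds:
        for gt in genotypes:
            for r in range(1, R + 1):
                sample_rows.append(
                    {
                        "sample": f"{bg}_{gt}_r{r}",
                        "background": bg,
                        "genotype": gt,
                        "replicate": r,
                        "batch": f"{bg}_b{r}",
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample")
    batches = sorted(samples["batch"].unique())
    batch_offset = dict(zip(batches, rng.normal(0.0, config.batch_sd, len(batches))))
    factor_scores = {
        (bg, gt): rng.normal(0.0, 1.0, config.n_modules)
        for bg in backgrounds
        for gt in genotypes
    }

    log2mu = np.empty((G, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        f = factor_scores[(row["background"], row["genotype"])]
        col = baseline + batch_offset[row["batch"]]
        col = col + np.where(labels > 0, loadings * f[np.maximum(labels - 1, 0)], 0.0)
        if row["genotype"] != "WT" and deg_sets:
            for gene, eff in deg_sets[(row["genotype"], row["background"])].items():
                col[genes.get_loc(gene)] += eff
        log2mu[:, j] = col
    counts = _nb_draw(rng, 2.0**log2mu, config.nb_dispersion)
    study = CountStudy(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        gene_lengths=lengths,
        samples=samples,
    )
    truth = PlantedTruth(
        module_labels=module_labels,
        deg_sets=deg_sets,
        conserved_sets=conserved_sets,
    )
    return study, truth


def generate_morphology_study(config: SimulationConfig) -> tuple[TraitStudy, PlantedTruth]:
    """Simulate block-correlated trait observations with planted shifts.

    Traits fall into ``n_trait_clusters`` blocks sharing a latent factor
    per observation (within-block correlation ``trait_within_cluster_r``,
    zero between blocks).  Knockout alterations shift selected traits by
    ``trait_alteration_sd_units`` total SDs in the knockout's observations
    of both backgrounds; with 0 SD units no alterations are planted.
    Biological replicates carry a shared random intercept and batches an
    additive offset, so the downstream mixed model sees the structure it
    assumes.
    """
    rng = _substream(config.seed, "morphology")
    T = config.n_traits
    traits = [f"T{i:03d}" for i in range(1, T + 1)]
    cluster_labels = pd.Series(
        rng.permutation(np.arange(T) % config.n_trait_clusters + 1),
        index=traits,
        name="trait_cluster",
    )
    rho = config.trait_within_cluster_r

    tfs = config.tf_names
    altered: dict[str, frozenset] = {}
    if config.trait_alteration_sd_units != 0.0:
        for tf in tfs:
            n_alt = min(config.traits_altered_per_tf, T)
            chosen = rng.choice(T, size=n_alt, replace=False)
            altered[tf] = frozenset(traits[i] for i in chosen)

    rows = []
    meta = []
    backgrounds = ("BY", "RM")
    for bg in backgrounds:
        for gt in ["WT"] + tfs:
            bio_intercepts = rng.normal(0.0, config.trait_replicate_sd, config.bio_replicates)
            for bio in range(1, config.bio_replicates + 1):
                for tech in range(1, config.tech_replicates + 1):
                    factors = rng.normal(0.0, 1.0, config.n_trait_clusters)
                    noise = rng.normal(0.0, 1.0, T)
                    vals = (
                        10.0
                        + np.sqrt(rho) * factors[cluster_labels.to_numpy() - 1]
                        + np.sqrt(1.0 - rho) * noise
                        + bio_intercepts[bio - 1]
                    )
                    if gt in altered:
                        idx = [traits.index(t) for t in altered[gt]]
                        vals[idx] += config.trait_alteration_sd_units
                    rows.append(vals)
                    meta.append(
                        {
                            "background": bg,
                            "genotype": gt,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "batch": f"{bg}_b{bio}",
                        }
                    )
    obs = pd.concat(
        [pd.DataFrame(meta), pd.DataFrame(np.asarray(rows), columns=traits)], axis=1
    )
    # additive per-batch offsets, removable by the preprocessing stage
    for batch, sub in obs.groupby("batch"):
        obs.loc[sub.index, traits] += rng.normal(0.0, config.trait_batch_sd)
    study = TraitStudy(observations=obs, trait_ids=traits)
    truth = PlantedTruth(trait_cluster_labels=cluster_labels, altered_traits=altered)
    return study, truth


def generate_allele_panel(
    config: SimulationConfig,
) -> tuple[AllelePanel, pd.DataFrame, PlantedTruth]:
    """Simulate a lineage-labelled allele panel with planted marker ages.

    Every marker is biallelic between the focal backgrounds.  A planted
    "new" marker's derived allele appears only in the BY-lineage strains or
    only in the RM-lineage strains; a planted "old" marker's derived allele
    appears in all Chinese-lineage strains, in one focal lineage, and in a
    random subset of "other" strains.  Taiwanese strains and the outgroup
    always carry the ancestral allele, so the polarization rule applies
    cleanly.  Affected-gene counts are shifted Poisson draws (new markers
    more pleiotropic) and variance explained Beta draws (old markers
    stronger).
    """
    sizes = dict(config.n_segregant_strains)
    for lin in ("BY_lineage", "RM_lineage", "CHN", "TW", "outgroup"):
        if sizes.get(lin, 0) < 1:
            raise ValueError(f"panel needs at least one strain in lineage {lin!r}")
    rng = _substream(config.seed, "panel")
    strains, lineage_labels = [], []
    for lin, n in sizes.items():
        for i in range(1, n + 1):
            strains.append(f"{lin}_{i}")
            lineage_labels.append(lin)
    lineages = pd.Series(lineage_labels, index=strains, name="lineage")

    M = config.n_markers
    markers = [f"m{i:04d}" for i in range(1, M + 1)]
    n_new = _round_half_up(config.age_mix * M)
    ages = np.array(["new"] * n_new + ["old"] * (M - n_new))
    rng.shuffle(ages)

    bases = np.array(list("ACGT"))
    geno = pd.DataFrame(index=markers, columns=strains, dtype=object)
    focal = pd.DataFrame(index=markers, columns=["BY", "RM"], dtype=object)
    affected = np.empty(M, dtype=int)
    variance = np.empty(M)
    for i, marker in enumerate(markers):
        anc, der = rng.choice(bases, size=2, replace=False)
        origin = rng.choice(["BY_lineage", "RM_lineage"])
        geno.loc[marker] = anc
        geno.loc[marker, lineages.index[lineages == origin]] = der
        if ages[i] == "old":
            geno.loc[marker, lineages.index[lineages == "CHN"]] = der
            others = lineages.index[lineages == "other"]
            carry = rng.random(len(others)) < 0.3
            geno.loc[marker, others[carry]] = der
        focal.loc[marker, "BY"] = der if origin == "BY_lineage" else anc
        focal.loc[marker, "RM"] = der if origin == "RM_lineage" else anc
        if ages[i] == "new":
            affected[i] = 1 + rng.poisson(config.new_affected_mean - 1.0)
            variance[i] = rng.beta(2.0, 28.0)
        else:
            affected[i] = 1 + rng.poisson(config.old_affected_mean - 1.0)
            variance[i] = rng.beta(5.0, 15.0)
    variance = np.clip(variance, 1e-6, 1.0)

    panel = AllelePanel(genotypes=geno, lineages=lineages, focal_alleles=focal)
    eqtl_table = pd.DataFrame(
        {"n_affected_genes": affected, "variance_explained": variance},
        index=pd.Index(markers, name="marker"),
    )
    truth = PlantedTruth(
        marker_ages=pd.Series(ages, index=markers, name="age"),
        marker_affected_counts=eqtl_table["n_affected_genes"].copy(),
        marker_variance=eqtl_table["variance_explained"].copy(),
    )
    return panel, eqtl_table, truth
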