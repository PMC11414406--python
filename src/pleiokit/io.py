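"""Tab-separated readers/writers for the pipeline's tabular artifacts.

Everything is plain TSV with a single header row; planted truth is written
as a YAML sidecar so simulations can be archived next to their outputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .eqtl_age import AllelePanel
from .morphology import TraitStudy
from .preprocessing import CountStudy
from .synthetic_data import PlantedTruth


def write_count_study(study: CountStudy, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.counts.to_csv(outdir / "counts.tsv", sep="\t")
    study.gene_lengths.rename("length").to_csv(outdir / "gene_lengths.tsv", sep="\t")
    study.samples.to_csv(outdir / "samples.tsv", sep="\t")


def read_count_study(indir: str | Path) -> CountStudy:
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(indir / "gene_lengths.tsv", sep="\t", index_col=0)["length"]
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col=0)
    return CountStudy(counts=counts, gene_lengths=lengths, samples=samples)


def write_trait_study(study: TraitStudy, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.observations.to_csv(outdir / "traits.tsv", sep="\t", index=False)


def read_trait_study(indir: str | Path) -> TraitStudy:
    obs = pd.read_csv(Path(indir) / "traits.tsv", sep="\t")
    from .morphology import OBS_COLUMNS

    trait_ids = [c for c in obs.columns if c not in OBS_COLUMNS]
    return TraitStudy(observations=obs, trait_ids=trait_ids)


def write_allele_panel(
    panel: AllelePanel, eqtl_table: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel.genotypes.rename_axis("marker").to_csv(outdir / "panel.tsv", sep="\t")
    panel.lineages.rename("lineage").rename_axis("strain").to_csv(
        outdir / "lineages.tsv", sep="\t"
    )
    panel.focal_alleles.rename_axis("marker").to_csv(
        outdir / "focal_alleles.tsv", sep="\t"
    )
    eqtl_table.to_csv(outdir / "eqtl.tsv", sep="\t")


def read_allele_panel(indir: str | Path) -> tuple[AllelePanel, pd.DataFrame]:
    indir = Path(indir)
    geno = pd.read_csv(indir / "panel.tsv", sep="\t", index_col=0, dtype=str)
    lineages = pd.read_csv(indir / "lineages.tsv", sep="\t", index_col=0)["lineage"]
    focal = pd.read_csv(indir / "focal_alleles.tsv", sep="\t", index_col=0, dtype=str)
    eqtl = pd.read_csv(indir / "eqtl.tsv", sep="\t", index_col=0)
    return AllelePanel(genotypes=geno, lineages=lineages, focal_alleles=focal), eqtl


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Serialize planted truth as a key-value YAML sidecar."""
    doc: dict = {}
    if truth.module_labels is not None:
        doc["module_labels"] = {g: int(m) for g, m in truth.module_labels.items()}
    if truth.deg_sets:
        doc["deg_sets"] = {
            f"{tf}|{bg}": {g: float(e) for g, e in effects.items()}
            for (tf, bg), effects in truth.deg_sets.items()
        }
    if truth.conserved_sets:
        doc["conserved_sets"] = {tf: sorted(s) for tf, s in truth.conserved_sets.items()}
    if truth.trait_cluster_labels is not None:
        doc["trait_cluster_labels"] = {
            t: int(c) for t, c in truth.trait_cluster_labels.items()
        }
    if truth.altered_traits:
        doc["altered_traits"] = {tf: sorted(s) for tf, s in truth.altered_traits.items()}
    if truth.marker_ages is not None:
        doc["marker_ages"] = {m: str(a) for m, a in truth.marker_ages.items()}
    if truth.marker_affected_counts is not None:
        doc["marker_affected_counts"] = {
            m: int(c) for m, c in truth.marker_affected_counts.items()
        }
    if truth.marker_variance is not None:
        doc["marker_variance"] = {m: float(v) for m, v in truth.marker_variance.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
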