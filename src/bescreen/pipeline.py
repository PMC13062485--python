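"""End-to-end orchestration: annotate -> qc -> score -> harmonize.

The pipeline is deterministic given its inputs and seed; every output table
carries a provenance header (package version and a hash of the run
configuration), and INFO-level logging records the guide counts surviving
each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .edit_annotation import EditingWindow, annotations_to_frame
from .fitness_scoring import (
    ControlBounds,
    LOF_CATEGORIES,
    NEUTRAL_CATEGORIES,
    category_comparisons,
    depletion_enrichment_test,
    negative_control_ids,
    score_guides,
)
from .harmonization import harmonize
from .library_io import (
    CountMatrix,
    ValidationError,
    write_clinical_map,
    write_count_table,
    write_gene_models,
    write_library,
    write_sample_sheet,
    write_table,
)
from .screen_counts import (
    correlations_to_frame,
    default_replicate_pairs,
    filter_zero_guides,
    median_normalize,
    replicate_correlation,
)
from .synthetic_data import (
    DEFAULT_ARCHETYPES,
    SimConfig,
    SimulatedScreen,
    simulate_screen,
)

logger = logging.getLogger(__name__)


def _default_sim() -> dict:
    """Default run-all study design: three cell lines, four effect archetypes."""
    return {
        "cell_lines": ["CL1", "CL2", "CL3"],
        "archetypes": {k: list(v) for k, v in DEFAULT_ARCHETYPES.items()},
    }


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on a simulated screen."""

    seed: int = 0
    out_dir: str = "bescreen_out"
    epsilon: float = 0.05
    q: float = 0.05
    p_low: float = 0.05
    p_high: float = 0.01
    k_clusters: int = 4
    nlfc_threshold: float = 1.0
    window_d_min: int = 13
    window_d_max: int = 18
    sim: dict = field(default_factory=_default_sim)  # SimConfig field overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        cell_lines = sim.pop("cell_lines", None)
        archetypes = sim.pop("archetypes", None)
        kwargs = dict(sim)
        if cell_lines is not None:
            kwargs["cell_lines"] = tuple(cell_lines)
        if archetypes is not None:
            kwargs["archetypes"] = {k: tuple(v) for k, v in archetypes.items()}
        kwargs["window"] = EditingWindow(self.window_d_min, self.window_d_max)
        kwargs["seed"] = self.seed
        return SimConfig(**kwargs)

    def hash(self) -> str:
        # out_dir is where results land, not part of the analysis definition
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ScreenResult:
    """Scored single-cell-line screen: fitness table, bounds, QC, contrasts."""

    cell_line: str
    fitness: pd.DataFrame  # x_rep*, lfc, p_value, tier; indexed by guide
    bounds: ControlBounds
    qc: pd.DataFrame
    contrasts: dict
    lof_enrichment: Optional[dict]


def run_screen(
    counts: CountMatrix,
    guide_meta: pd.DataFrame,
    essential_genes: Sequence[str],
    epsilon: float = 0.05,
    q: float = 0.05,
) -> ScreenResult:
    """Score one cell line's screen from its raw count matrix.

    Applies zero-count filtering, median normalization, LFC + empirical-p
    scoring against the negative controls, hit tiering, the standard ROC
    contrasts, and the Fisher depletion-enrichment test of loss-of-function
    (nonsense/splice) guides in essential genes against neutral guides.
    """
    cell_lines = {s.cell_line for s in counts.samples}
    if len(cell_lines) != 1:
        raise ValidationError("run_screen expects a single-cell-line count matrix")
    cell_line = cell_lines.pop()

    filtered = filter_zero_guides(counts)
    qc = correlations_to_frame(
        replicate_correlation(filtered, default_replicate_pairs(filtered))
    )
    norm = median_normalize(filtered)
    neg_ids = negative_control_ids(guide_meta)
    fitness, bounds = score_guides(norm, neg_ids, epsilon=epsilon, q=q)
    contrasts = category_comparisons(fitness, guide_meta, essential_genes)

    meta = guide_meta.loc[guide_meta.index.intersection(fitness.index)]
    essential = set(essential_genes)
    targeting = meta["control_class"] == "targeting"
    in_ess = meta["gene"].isin(essential)
    lof_ids = meta.index[targeting & in_ess & meta["category"].isin(LOF_CATEGORIES)]
    neutral_ids = meta.index[
        (targeting & in_ess & meta["category"].isin(NEUTRAL_CATEGORIES))
        | meta["control_class"].isin(["aavs1_control", "nontargeting_control"])
    ]
    lof_enrichment = None
    if len(lof_ids) and len(neutral_ids):
        test = depletion_enrichment_test(fitness["lfc"], lof_ids, neutral_ids, bounds)
        lof_enrichment = {
            "k_category_depleted": test.k_category_depleted,
            "n_category": test.n_category,
            "k_reference_depleted": test.k_reference_depleted,
            "n_reference": test.n_reference,
            "p_value": test.p_value,
        }
    return ScreenResult(
        cell_line=cell_line,
        fitness=fitness,
        bounds=bounds,
        qc=qc,
        contrasts=contrasts,
        lof_enrichment=lof_enrichment,
    )


def run_harmonize(
    lfc_by_cell_line: Mapping[str, pd.Series],
    guide_meta: pd.DataFrame,
    k_clusters: int = 4,
    threshold: float = 1.0,
) -> dict:
    """Harmonize >= 2 scored cell lines and run gene + clinical enrichment."""
    if len(lfc_by_cell_line) < 2:
        raise ValidationError("harmonization needs at least 2 cell lines")
    neg_ids = negative_control_ids(guide_meta)
    pos_ids = guide_meta.index[guide_meta["control_class"] == "istop_control"]
    result = harmonize(
        lfc_by_cell_line, neg_ids, pos_ids,
        categories=guide_meta["gene"], k_clusters=k_clusters, threshold=threshold,
    )
    from .harmonization import cluster_enrichment

    labels = result["labels"]
    result["gene_enrichment"] = result.pop("enrichment")
    clinical = guide_meta["clinical_class"].reindex(labels.index).replace("NA", pd.NA)
    result["clinical_enrichment"] = cluster_enrichment(labels, clinical)
    return result


def run_all(config: RunConfig) -> dict:
    """Simulate a screen per the config, run every stage, write all outputs.

    Returns a summary dict (per-cell-line contrasts, bounds, harmonization
    availability) that is also written as ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = [f"bescreen {__version__}", f"config_hash={config.hash()}"]

    sim = simulate_screen(config.sim_config(), seed=config.seed)
    write_simulated_inputs(sim, out / "inputs")

    annot = annotations_to_frame(sim.annotations)
    write_table(annot, out / "annotations.tsv", header_lines=provenance)
    meta = sim.guide_meta()

    report: dict = {"version": __version__, "config_hash": config.hash(),
                    "cell_lines": {}}
    lfc_by_cl: dict[str, pd.Series] = {}
    for cl, counts in sim.counts.items():
        res = run_screen(counts, meta, sim.essential_genes,
                         epsilon=config.epsilon, q=config.q)
        lfc_by_cl[cl] = res.fitness["lfc"]
        write_table(res.qc, out / f"qc_{cl}.tsv", header_lines=provenance)
        fit = res.fitness.reset_index()
        fit = fit.rename(columns={fit.columns[0]: "guide_id"})
        write_table(fit, out / f"scores_{cl}.tsv", header_lines=provenance)
        report["cell_lines"][cl] = {
            "bounds": {"lo": res.bounds.lo, "hi": res.bounds.hi, "q": res.bounds.q},
            "contrasts": res.contrasts,
            "lof_enrichment": res.lof_enrichment,
            "n_guides_scored": int(len(res.fitness)),
        }

    if len(lfc_by_cl) >= 2:
        harm = run_harmonize(lfc_by_cl, meta, k_clusters=config.k_clusters,
                             threshold=config.nlfc_threshold)
        nlfc = harm["nlfc"].values.reset_index()
        nlfc = nlfc.rename(columns={nlfc.columns[0]: "guide_id"})
        write_table(nlfc, out / "nlfc_matrix.tsv", header_lines=provenance)
        labels = harm["labels"].reset_index()
        labels = labels.rename(columns={labels.columns[0]: "guide_id"})
        write_table(labels, out / "clusters.tsv", header_lines=provenance)
        write_table(harm["gene_enrichment"], out / "gene_enrichment.tsv",
                    header_lines=provenance)
        write_table(harm["clinical_enrichment"], out / "clinical_enrichment.tsv",
                    header_lines=provenance)
        try:
            from .plotting import plot_nlfc_heatmap

            plot_nlfc_heatmap(harm["selected"], harm["labels"],
                              out / "nlfc_heatmap.png")
        except Exception as exc:  # plotting must never sink a run
            logger.warning("heatmap not rendered: %s", exc)
        report["harmonization"] = {
            "n_significant": int(len(harm["selected"])),
            "k_clusters": config.k_clusters,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    validate_outputs(out, n_cell_lines=len(sim.counts))
    return report


def write_simulated_inputs(sim: SimulatedScreen, out: str | Path) -> None:
    """Write a simulated screen in the pipeline's on-disk input formats."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_models(sim.models, out / "transcripts.fa", out / "transcripts.tsv")
    write_library(sim.guides, out / "library.tsv")
    write_clinical_map(sim.clinical_map, out / "clinical.tsv")
    truth = sim.truth.reset_index()
    write_table(truth, out / "truth.tsv")
    for cl, cm in sim.counts.items():
        write_count_table(cm, out / f"counts_{cl}.tsv")
        write_sample_sheet(cm.samples, out / f"samples_{cl}.tsv")


_SCHEMAS = {
    "annotations.tsv": ["guide_id", "category", "k_editable", "n_outcomes",
                        "worst_protein_change", "clinical_class"],
    "qc_{cl}.tsv": ["sample_a", "sample_b", "pearson_r"],
    "scores_{cl}.tsv": ["guide_id", "lfc", "p_value", "tier"],
    "nlfc_matrix.tsv": ["guide_id"],
    "clusters.tsv": ["guide_id", "cluster"],
    "gene_enrichment.tsv": ["cluster", "label", "k", "K", "n", "N", "p_value"],
    "clinical_enrichment.tsv": ["cluster", "label", "k", "K", "n", "N", "p_value"],
}


def validate_outputs(out_dir: str | Path, n_cell_lines: int) -> None:
    """Check that every expected output exists with its declared columns."""
    from .library_io import read_table

    out = Path(out_dir)

    def check(name: str, cols: list[str]) -> None:
        path = out / name
        if not path.exists():
            raise ValidationError(f"missing output {name}")
        df = read_table(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{name}: missing columns {missing}")

    report = json.loads((out / "report.json").read_text())
    check("annotations.tsv", _SCHEMAS["annotations.tsv"])
    for cl in report["cell_lines"]:
        check(f"qc_{cl}.tsv", _SCHEMAS["qc_{cl}.tsv"])
        check(f"scores_{cl}.tsv", _SCHEMAS["scores_{cl}.tsv"])
    if n_cell_lines >= 2:
        for name in ("nlfc_matrix.tsv", "clusters.tsv", "gene_enrichment.tsv",
                     "clinical_enrichment.tsv"):
            check(name, _SCHEMAS[name])
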