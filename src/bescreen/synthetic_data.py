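"""Synthetic base-editing screens with planted ground truth.

Generates (i) simplified gene models — coding transcripts with valid
ATG...stop CDSs, optional GT/AG introns, UTRs, occasional non-coding
isoforms, plus a non-coding safe-harbor locus; (ii) a guide library tiling
every NGG site on both strands, with the four control classes of a
base-editing screen (iSTOP positives, AAVS1-targeting, non-targeting and
empty-window negatives); and (iii) two-replicate, two-timepoint count
tables from a negative-binomial model with log-normal guide-abundance
heterogeneity and planted per-cell-line fitness effects expressed directly
on the LFC scale (the endpoint mean is the T0 mean times 2^effect, so
recovery is closed-form checkable).

Defaults emulate the screen design at reduced scale: a few hundred guides
over 8 genes, 500x sequencing depth per guide, negative-binomial
dispersion 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .edit_annotation import (
    EditingWindow,
    GuideAnnotation,
    annotations_to_frame,
    classify_guide,
)
from .library_io import (
    ClinicalMap,
    CountMatrix,
    GuideRecord,
    Placement,
    SampleMeta,
    TranscriptModel,
    ValidationError,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated screen."""

    n_genes: int = 10
    n_essential: int = 4
    guides_per_gene: int = 40
    cds_codons: int = 300
    utr_len: int = 30
    intron_prob: float = 0.6
    intron_len: int = 90
    noncoding_isoform_prob: float = 0.25
    guides_per_noncoding: int = 4
    n_aavs1: int = 100
    n_nontargeting: int = 100
    n_istop: int = 40
    n_empty_window: int = 30
    aavs1_len: int = 1200
    depth: float = 500.0  # sequencing coverage per guide
    nb_dispersion: float = 0.2
    abundance_sigma: float = 0.25
    lof_effect: float = -2.0  # planted LFC of loss-of-function guides
    on_target_beta: tuple[float, float] = (2.0, 2.0)
    scale_by_on_target: bool = False
    cell_lines: tuple[str, ...] = ("CL1",)
    #: optional archetype profiles: name -> per-cell-line effect vector;
    #: essential genes are assigned archetypes round-robin
    archetypes: Optional[dict[str, tuple[float, ...]]] = None
    window: EditingWindow = EditingWindow()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_essential <= self.n_genes):
            raise ValidationError("need 0 < n_essential <= n_genes")
        if self.depth <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("depth and nb_dispersion must be positive")
        if self.archetypes is not None:
            for name, prof in self.archetypes.items():
                if len(prof) != len(self.cell_lines):
                    raise ValidationError(
                        f"archetype {name}: profile length != number of cell lines"
                    )


@dataclass
class SimulatedScreen:
    """A complete simulated screen with its ground truth."""

    config: SimConfig
    models: list[TranscriptModel]
    guides: list[GuideRecord]
    annotations: list[GuideAnnotation]
    clinical_map: ClinicalMap
    truth: pd.DataFrame  # index guide_id; gene, control_class, category,
    #                      archetype, effect_<cell_line>...
    counts: dict[str, CountMatrix]  # per cell line
    essential_genes: list[str]

    @property
    def transcripts(self) -> dict[str, TranscriptModel]:
        return {m.transcript_id: m for m in self.models}

    def guide_meta(self) -> pd.DataFrame:
        """Per-guide metadata frame used by the scoring contrasts."""
        annot = annotations_to_frame(self.annotations).set_index("guide_id")
        meta = pd.DataFrame(
            {
                "gene": [g.gene for g in self.guides],
                "control_class": [g.control_class for g in self.guides],
                "on_target_score": [g.on_target_score for g in self.guides],
            },
            index=pd.Index([g.guide_id for g in self.guides], name="guide_id"),
        )
        return meta.join(annot[["category", "clinical_class", "worst_protein_change"]])


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31 - 1) for s in state]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons - 2:
        codon = "".join(rng.choice(_BASES, size=3))
        if codon not in _STOPS and codon != "ATG":
            codons.append(codon)
    return "ATG" + "".join(codons) + rng.choice(_STOPS)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def simulate_gene_models(config: SimConfig, seed: Optional[int] = None) -> list[TranscriptModel]:
    """Generate coding transcript models (plus the non-coding safe-harbor locus).

    Every coding CDS starts ATG, ends with a stop, contains no premature
    stop and has length divisible by 3; introns are GT...AG and inserted at
    codon boundaries so splicing restores the CDS exactly.  Some genes carry
    an additional non-coding isoform.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    models: list[TranscriptModel] = []
    for gi in range(config.n_genes):
        gene = f"GENE{gi + 1:02d}"
        cds = _random_cds(rng, config.cds_codons)
        utr5 = _random_seq(rng, config.utr_len)
        utr3 = _random_seq(rng, config.utr_len)
        if rng.random() < config.intron_prob:
            # intron at a random internal codon boundary
            codon_break = int(rng.integers(10, config.cds_codons - 10))
            cut = 3 * codon_break
            intron = "GT" + _random_seq(rng, config.intron_len - 4) + "AG"
            seq = utr5 + cds[:cut] + intron + cds[cut:] + utr3
            exon1_end = len(utr5) + cut
            exon2_start = exon1_end + len(intron)
            exons = ((0, exon1_end), (exon2_start, len(seq)))
        else:
            seq = utr5 + cds + utr3
            exons = ((0, len(seq)),)
        models.append(
            TranscriptModel(
                transcript_id=f"{gene}_t1",
                gene=gene,
                is_coding=True,
                sequence=seq,
                exons=exons,
                cds_start=len(utr5),
                cds_end=len(seq) - len(utr3),
            )
        )
        if rng.random() < config.noncoding_isoform_prob:
            nc_seq = _random_seq(rng, 400)
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene}_nc1",
                    gene=gene,
                    is_coding=False,
                    sequence=nc_seq,
                    exons=((0, len(nc_seq)),),
                )
            )
    aavs1 = _random_seq(rng, config.aavs1_len)
    models.append(
        TranscriptModel(
            transcript_id="AAVS1_t1",
            gene="AAVS1",
            is_coding=False,
            sequence=aavs1,
            exons=((0, len(aavs1)),),
        )
    )
    return models


def essential_gene_names(config: SimConfig) -> list[str]:
    return [f"GENE{i + 1:02d}" for i in range(config.n_essential)]


def _tile_sites(tx: TranscriptModel) -> list[tuple[str, str, str, int]]:
    """All (protospacer, pam, strand, offset) guide sites on both strands."""
    seq = tx.sequence
    sites = []
    for i in range(0, len(seq) - 23 + 1):
        if seq[i + 21:i + 23] == "GG":
            sites.append((seq[i:i + 20], seq[i + 20:i + 23], "sense", i))
    for o in range(3, len(seq) - 20 + 1):
        if seq[o - 3:o - 1] == "CC":
            sites.append((_revcomp(seq[o:o + 20]), _revcomp(seq[o - 3:o]),
                          "antisense", o))
    return sites


def simulate_library(
    models: Sequence[TranscriptModel],
    config: SimConfig,
    seed: Optional[int] = None,
) -> tuple[list[GuideRecord], list[GuideAnnotation]]:
    """Tile guides over the transcript models and designate control classes.

    Within essential genes, guides whose predicted outcome is a premature
    stop (or splice disruption) are drawn on to fill the iSTOP positive
    controls, and guides without a window cytosine fill the empty-window
    negatives; AAVS1-targeting and random non-targeting guides complete the
    negative-control set.  Returns the library together with its
    annotations (computed without a clinical map).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    transcripts = {m.transcript_id: m for m in models}
    essential = set(essential_gene_names(config))
    guides: list[GuideRecord] = []
    annotations: list[GuideAnnotation] = []
    counter = 0

    def add_guide(proto, pam, gene, placements, control_class, score) -> GuideAnnotation:
        nonlocal counter
        counter += 1
        rec = GuideRecord(
            guide_id=f"g{counter:05d}",
            protospacer=proto,
            pam=pam,
            gene=gene,
            placements=placements,
            control_class=control_class,
            on_target_score=score,
        )
        ann = classify_guide(rec, transcripts, config.window)
        guides.append(rec)
        annotations.append(ann)
        return ann

    def beta_score() -> float:
        a, b = config.on_target_beta
        return float(rng.beta(a, b))

    for model in models:
        if model.gene == "AAVS1":
            continue
        sites = _tile_sites(model)
        if not model.is_coding:
            n_take = min(config.guides_per_noncoding, len(sites))
            idx = rng.choice(len(sites), size=n_take, replace=False)
            for j in sorted(idx):
                proto, pam, strand, off = sites[j]
                add_guide(proto, pam, model.gene,
                          (Placement(model.transcript_id, strand, off),),
                          "targeting", beta_score())
            continue

        if len(sites) < config.guides_per_gene:
            raise ValidationError(
                f"{model.gene}: only {len(sites)} guide sites for "
                f"{config.guides_per_gene} requested guides"
            )
        # classify every candidate site once, so controls can be designated
        site_info = []
        for proto, pam, strand, off in sites:
            probe = GuideRecord(
                guide_id="probe", protospacer=proto, pam=pam, gene=model.gene,
                placements=(Placement(model.transcript_id, strand, off),),
                control_class="targeting", on_target_score=None,
            )
            ann = classify_guide(probe, transcripts, config.window)
            site_info.append((proto, pam, strand, off, ann.category))

        used: set[int] = set()
        if model.gene in essential:
            lof_sites = [j for j, s in enumerate(site_info)
                         if s[4] in ("nonsense", "splice")]
            empty_sites = [j for j, s in enumerate(site_info) if s[4] == "empty_window"]
            # leave at least half of the LoF-capable sites as targeting
            # guides so essential-gene category contrasts stay populated
            per_gene_istop = min(
                max(1, config.n_istop // config.n_essential),
                max(1, len(lof_sites) // 2),
            )
            per_gene_empty = max(1, config.n_empty_window // config.n_essential)
            for pool, n_want, cls in (
                (lof_sites, per_gene_istop, "istop_control"),
                (empty_sites, per_gene_empty, "empty_window_control"),
            ):
                if not pool:
                    continue
                for j in rng.choice(pool, size=min(n_want, len(pool)), replace=False):
                    proto, pam, strand, off, _ = site_info[j]
                    add_guide(proto, pam, model.gene,
                              (Placement(model.transcript_id, strand, off),),
                              cls, beta_score())
                    used.add(int(j))

        remaining = [j for j in range(len(site_info)) if j not in used]
        n_take = min(config.guides_per_gene, len(remaining))
        for j in sorted(rng.choice(remaining, size=n_take, replace=False)):
            proto, pam, strand, off, _ = site_info[j]
            add_guide(proto, pam, model.gene,
                      (Placement(model.transcript_id, strand, off),),
                      "targeting", beta_score())

    aavs1 = transcripts["AAVS1_t1"]
    aavs1_sites = _tile_sites(aavs1)
    n_take = min(config.n_aavs1, len(aavs1_sites))
    for j in sorted(rng.choice(len(aavs1_sites), size=n_take, replace=False)):
        proto, pam, strand, off = aavs1_sites[j]
        add_guide(proto, pam, "AAVS1",
                  (Placement("AAVS1_t1", strand, off),),
                  "aavs1_control", beta_score())

    for _ in range(config.n_nontargeting):
        proto = _random_seq(rng, 20)
        pam = rng.choice(_BASES) + "GG"
        add_guide(proto, pam, None, (), "nontargeting_control", beta_score())

    return guides, annotations


def simulate_clinical_map(
    guides: Sequence[GuideRecord],
    annotations: Sequence[GuideAnnotation],
    seed: int,
) -> ClinicalMap:
    """Plant a clinical-class map over the predicted protein changes.

    Nonsense changes are mostly pathogenic/likely pathogenic; missense
    changes are mostly uncertain or benign; a fraction of changes stays
    absent from the map (NA downstream).
    """
    rng = np.random.default_rng(seed)
    entries: dict[tuple[str, str], str] = {}
    for g, a in zip(guides, annotations):
        if g.gene is None or a.worst_protein_change is None:
            continue
        key = (g.gene, a.worst_protein_change)
        if key in entries:
            continue
        u = rng.random()
        if a.worst_protein_change.endswith("*"):
            cls = "PLP" if u < 0.5 else ("VUS" if u < 0.7 else None)
        else:
            cls = "BLB" if u < 0.25 else ("VUS" if u < 0.6 else
                                          ("PLP" if u < 0.65 else None))
        if cls is not None:
            entries[key] = cls
    return ClinicalMap(entries)


def simulate_truth(
    guides: Sequence[GuideRecord],
    annotations: Sequence[GuideAnnotation],
    config: SimConfig,
) -> pd.DataFrame:
    """Planted per-cell-line expected LFC for every guide.

    iSTOP controls, loss-of-function (nonsense/splice) guides in essential
    genes, and pathogenic-annotated (PLP) missense guides in essential
    genes carry ``lof_effect`` (or their gene's archetype profile when
    archetypes are configured); all negative controls and all other guides
    are fitness-neutral.  Optionally the effect scales with the on-target
    score.
    """
    essential = set(essential_gene_names(config))
    archetype_of_gene: dict[str, str] = {}
    if config.archetypes is not None:
        names = list(config.archetypes)
        for i, gene in enumerate(sorted(essential)):
            archetype_of_gene[gene] = names[i % len(names)]

    rows = []
    for g, a in zip(guides, annotations):
        is_lof = (
            g.control_class == "istop_control"
            or (g.control_class == "targeting" and g.gene in essential
                and (a.category in ("nonsense", "splice")
                     or (a.category == "missense" and a.clinical_class == "PLP")))
        )
        if not is_lof:
            effects = tuple(0.0 for _ in config.cell_lines)
            archetype = "neutral"
        elif g.control_class == "istop_control":
            # positive controls target pan-essential function: full planted
            # depletion in every cell line, independent of gene archetype
            archetype = "lof"
            effects = tuple(config.lof_effect for _ in config.cell_lines)
        elif config.archetypes is not None and g.gene in archetype_of_gene:
            archetype = archetype_of_gene[g.gene]
            effects = tuple(config.archetypes[archetype])
        else:
            archetype = "lof"
            effects = tuple(config.lof_effect for _ in config.cell_lines)
        if config.scale_by_on_target and g.on_target_score is not None:
            effects = tuple(e * g.on_target_score for e in effects)
        rows.append(
            (g.guide_id, g.gene, g.control_class, a.category, archetype) + effects
        )
    cols = ["guide_id", "gene", "control_class", "category", "archetype"] + [
        f"effect_{cl}" for cl in config.cell_lines
    ]
    return pd.DataFrame(rows, columns=cols).set_index("guide_id")


def simulate_counts(
    truth: pd.DataFrame,
    config: SimConfig,
    cell_line: str,
    seed: int,
) -> CountMatrix:
    """Two-replicate, two-timepoint negative-binomial counts for one cell line.

    T0 means are ``depth * a_g`` with abundance a_g ~ LogNormal(0, sigma);
    endpoint means are the T0 means times 2^effect.  Counts are NB with
    variance m + dispersion * m^2; replicates are independent draws.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    a = rng.lognormal(0.0, config.abundance_sigma, size=n)
    m0 = config.depth * a
    m1 = m0 * np.power(2.0, truth[f"effect_{cell_line}"].values.astype(float))
    r = 1.0 / config.nb_dispersion

    def nb(mean: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(r, r / (r + mean))

    samples = [
        SampleMeta(f"{cell_line}_T0_R1", cell_line, "T0", 1),
        SampleMeta(f"{cell_line}_T0_R2", cell_line, "T0", 2),
        SampleMeta(f"{cell_line}_TEND_R1", cell_line, "TEND", 1),
        SampleMeta(f"{cell_line}_TEND_R2", cell_line, "TEND", 2),
    ]
    data = {
        samples[0].sample_id: nb(m0),
        samples[1].sample_id: nb(m0),
        samples[2].sample_id: nb(m1),
        samples[3].sample_id: nb(m1),
    }
    counts = pd.DataFrame(data, index=truth.index.rename("sgRNA"))
    genes = truth["gene"].fillna("NA").rename("gene")
    return CountMatrix(counts=counts, samples=samples, genes=genes)


def simulate_screen(config: SimConfig = SimConfig(), seed: Optional[int] = None) -> SimulatedScreen:
    """Generate a full screen: models, library, clinical map, truth, counts."""
    base_seed = config.seed if seed is None else seed
    seeds = _child_seeds(base_seed, 3 + len(config.cell_lines))
    models = simulate_gene_models(config, seeds[0])
    guides, annotations = simulate_library(models, config, seeds[1])
    clinical = simulate_clinical_map(guides, annotations, seeds[2])
    # re-annotate with the clinical map so clinical_class is populated
    transcripts = {m.transcript_id: m for m in models}
    annotations = [
        classify_guide(g, transcripts, config.window, clinical)
        for g in guides
    ]
    truth = simulate_truth(guides, annotations, config)
    counts = {
        cl: simulate_counts(truth, config, cl, seeds[3 + i])
        for i, cl in enumerate(config.cell_lines)
    }
    return SimulatedScreen(
        config=config,
        models=models,
        guides=guides,
        annotations=annotations,
        clinical_map=clinical,
        truth=truth,
        counts=counts,
        essential_genes=essential_gene_names(config),
    )


def null_screen_config(seed: int = 0) -> SimConfig:
    """No-effect study design (>= 2,000 guides) for p-value calibration.

    Every guide, including the iSTOP class, is fitness-neutral, so the
    empirical p-values and the category LFC distributions can be checked
    against their null expectations.
    """
    return SimConfig(
        n_genes=20, n_essential=4, guides_per_gene=100, cds_codons=400,
        n_aavs1=150, n_nontargeting=150,
        lof_effect=0.0, seed=seed,
    )


def effect_screen_config(seed: int = 0) -> SimConfig:
    """Effect-recovery study design: several hundred planted -2 LFC guides.

    Sized so that the mean recovered effect has a standard error well below
    the per-guide count noise, while loss-of-function guides stay a modest
    fraction of the library (median normalization assumes most guides are
    neutral).
    """
    return SimConfig(
        n_genes=40, n_essential=20, guides_per_gene=120, cds_codons=500,
        n_istop=240, n_empty_window=120, n_aavs1=300, n_nontargeting=300,
        seed=seed,
    )


DEFAULT_ARCHETYPES: dict[str, tuple[float, ...]] = {
    "pan_lethal": (-2.0, -2.0, -2.0),
    "line1_specific": (-2.0, 0.0, 0.0),
    "line2_specific": (0.0, -2.0, 0.0),
    "line3_specific": (0.0, 0.0, -2.0),
}


def simulate_archetype_matrix(
    n_per_archetype: int = 30,
    archetypes: Optional[Mapping[str, Sequence[float]]] = None,
    noise_sd: float = 0.3,
    cell_lines: Sequence[str] = ("CL1", "CL2", "CL3"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Guide x cell-line effect matrix with planted archetype profiles.

    Each guide's row is its archetype's effect vector plus iid Gaussian
    noise (sd ``noise_sd``); used to exercise Ward clustering and cluster
    enrichment against known labels.
    """
    rng = np.random.default_rng(seed)
    archetypes = dict(archetypes or DEFAULT_ARCHETYPES)
    rows, labels, ids = [], [], []
    for name, profile in archetypes.items():
        if len(profile) != len(cell_lines):
            raise ValidationError(f"archetype {name}: wrong profile length")
        block = np.asarray(profile, float) + rng.normal(0, noise_sd,
                                                        (n_per_archetype, len(cell_lines)))
        rows.append(block)
        labels.extend([name] * n_per_archetype)
        ids.extend(f"{name}_{i + 1}" for i in range(n_per_archetype))
    matrix = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="guide_id"),
                          columns=list(cell_lines))
    return matrix, pd.Series(labels, index=matrix.index, name="archetype")
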