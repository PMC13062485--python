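# bescreen

Analysis toolkit for pooled CRISPR **cytosine base-editing fitness screens**
of the kind used to characterize DNA-damage-response (DDR) gene variants:
a guide library tiles every NGG-PAM site of a gene set, a BE3-class editor
converts window cytosines to thymines, and deep sequencing of the guide
cassette at the start (T0) and end (T38) of growth reads out the fitness
cost of each installed variant.

The package is aimed at computational biologists analyzing such screens
(or building methods on top of them). It provides, as a library with a thin
CLI:

- **Edit annotation** — enumerate all C→T outcomes inside the editing
  window (positions 13–18 from the PAM, i.e. 5′ protospacer positions 3–8),
  project them onto explicit transcript models, call
  synonymous / missense / nonsense / splice / non-coding / empty-window
  consequences, and collapse each sgRNA to its most damaging category plus
  a ClinVar-style clinical class (B/LB < NA < VUS < P/LP).
- **Fitness scoring** — from MAGeCK-count-style tables: zero-count
  filtering, per-sample median normalization *R′ᵢ = Rᵢ / median(R)*, the
  ε-regularized log fold change

  &nbsp;&nbsp;&nbsp;&nbsp;*xᵢ = log₂((R′ᵢ + ε)/(C′ᵢ + ε))*, ε = 0.05,

  averaged over replicate pairs; empirical control bounds (5th/95th
  percentile of negative-control LFC), rank-based two-sided empirical
  p-values, low/high-priority hit tiers, ROC/AUC control contrasts and
  Fisher depletion-enrichment tests.
- **Harmonization** — control-calibrated normalized LFC,

  &nbsp;&nbsp;&nbsp;&nbsp;*nLFCᵢ = (xᵢ − μ_neg)/σ_ctrl*,

  with μ_neg from the AAVS1 + non-targeting negatives and σ_ctrl the
  pooled positive (iSTOP) + negative control s.d.; selection of guides
  with |nLFC| > 1 in ≥ 1 cell line; Ward/Euclidean hierarchical
  clustering; hypergeometric cluster enrichment by gene or clinical class.
- **Synthetic screens** — gene models with valid CDSs and GT/AG introns,
  NGG-tiled libraries with all four control classes (iSTOP positives,
  AAVS1-targeting / non-targeting / empty-window negatives), and
  negative-binomial two-replicate count tables with planted per-cell-line
  effects — full ground truth for every pipeline stage.

## Worked example

```bash
python examples/02_score_screen.py
```

```
scored 661 guides in cell line CL1
negative-control 5%/95% LFC bounds: (-1.12, 0.90)
  AUC istop_vs_aavs1: 0.958 (17 pos vs 100 neg)
  AUC istop_vs_empty_window: 0.966 (17 pos vs 28 neg)
  AUC lof_vs_neutral_essential: 0.976 (10 pos vs 46 neg)
  ...
LoF depletion Fisher p = 2.03e-08 (8/10 LoF guides below the lower bound)
tier
none             607
low_priority      46
high_priority      8
```

The bounds are the empirical 5% tails of the negative-control LFC
distribution; AUCs measure how cleanly guides installing premature stops
(iSTOP) or predicted loss-of-function edits separate from neutral
controls when ranked by depletion; the Fisher test asks whether
nonsense/splice guides in essential genes pile up below the lower bound;
tiers combine the bounds with the empirical p-value (p < 0.05 / p < 0.01).

`examples/01_annotate_guides.py` walks through consequence calling on a
hand-built transcript and `examples/03_harmonize_cell_lines.py` clusters
three simulated cell lines with planted effect archetypes. The same
stages are scriptable from a shell:

```bash
bescreen simulate --seed 1 --out sim/
bescreen annotate --library sim/library.tsv \
    --models sim/transcripts.fa,sim/transcripts.tsv \
    --clinical sim/clinical.tsv --out annot.tsv
bescreen run-all --seed 1 --out run/
```

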