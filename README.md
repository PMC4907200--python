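# aerosource

Tools for asking a concrete aerobiology question: **how much of the
microbial community in outdoor air comes from the vegetation immediately
upwind of it?** The package implements the complete computational pipeline
for paired source→sink field designs in which, at each site, three
communities are profiled by marker-gene sequencing: the epiphytes on the
dominant plant, the air upwind of the vegetated area, and the air
immediately downwind of it. Reagent (no-template) and extraction controls
round out the design.

It is aimed at microbial-ecology practitioners who have OTU count tables,
sample metadata and (optionally) qPCR plates in hand and want the full
chain of analysis — not raw-read processing, which happens upstream.

## What it computes

* **Negative-control decontamination** (`aerosource.decontam`) — the
  two-stage correction for low-biomass contamination. Each OTU detected in a
  control is either *removed* (present in the environment at similar
  library-size-scaled read numbers, i.e. ratio < 5) or *subtracted*
  per sample via
  `corrected = count_s − (lib_s / lib_control) × count_control`
  (environmental abundance ≥ 5× the scaled control abundance). NTCs are
  corrected for first, then the corrected extraction controls; rarefaction
  to a common depth follows.
* **Alpha diversity** (`aerosource.diversity`) — Shannon H (nats), inverse
  Simpson 1/D, bias-corrected Chao1, Berger-Parker dominance.
* **Community distance** (`aerosource.distance`) — Bray-Curtis
  `Σ|x−y|/Σ(x+y)`, qualitative Jaccard, weighted Canberra; nonmetric MDS
  (Kruskal stress-1) and UPGMA dendrograms (Newick output).
* **Permutation inference** (`aerosource.inference`) — ANOSIM
  (R = (r̄_B − r̄_W)/(n(n−1)/4) ∈ [−1, 1]), one-factor PERMANOVA/ADONIS
  (pseudo-F, R²), pairwise Mann-Whitney with Bonferroni correction, and the
  **enrichment regression**: per OTU and site, d_air = DW − UW (difference
  of relative abundances in downwind and upwind air) regressed on
  log(1 + plant abundance in %) for every OTU at ≥ 0.1% on the plant. A
  positive slope means the taxa most abundant on plants are the most
  enriched in the air downwind of them.
* **Bayesian source tracking** (`aerosource.sourcetrack`) — a collapsed
  Gibbs sampler attributing each air "sink" to the plant "sources" plus an
  *unknown* source learned on the fly, with posterior means and credible
  intervals of the mixing proportions.
* **qPCR quantification** (`aerosource.qpcr`) — standard-curve fits,
  amplification efficiency `E = −1 + 10^(−1/slope)`, gene copies per cubic
  meter of air, downwind:upwind fold effects.
* **Synthetic studies** (`aerosource.synth`) — a generative model of the
  whole design (per-site plant communities, shared regional background,
  downwind mixtures, contaminated controls) with recorded ground truth, so
  every stage above can be validated against known mixing proportions.
* **Orchestration** (`aerosource.pipeline`, CLI `aerosource`) — one-command
  end-to-end runs with a reproducible, fully-parameterised manifest.

## Worked example

Generate a study in which 30% of each downwind community is of plant
origin, decontaminate, and run the attribution chain:

```python
from aerosource import synth, decontam, distance, inference, sourcetrack
from aerosource.containers import meta_frame

cfg = synth.SynthConfig(n_sites=8, n_otus=300, mixing_m=0.3,
                        library_size=20000, seed=11)
counts, meta, truth = synth.generate_study(cfg)

corrected, report = decontam.apply_correction(counts, meta)
rarefied, _ = decontam.rarefy(corrected, int(corrected.library_sizes().min()),
                              seed=11)

dm = distance.distance_matrix(rarefied, "braycurtis")
habitat = meta_frame(meta).loc[rarefied.sample_ids, "habitat"]
res = inference.anosim(dm, habitat, n_permutations=999, seed=11)

model = sourcetrack.fit_source_model(rarefied, meta)
attribution = sourcetrack.attribute_all(model, rarefied, meta, seed=11)
enr = inference.enrichment_regression(rarefied, meta)
```

which prints (seed 11):

```
removed 30 contaminant OTUs, subtracted 0
ANOSIM (habitat): R = 0.777, p = 0.001
site  upwind_plant  downwind_plant
 L01         0.001           0.293
 L02         0.001           0.262
 ...
 L08         0.001           0.258
paired downwind > upwind: p = 5.5e-11
enrichment slope = 0.0081 (p = 5.5e-278, n = 1057 OTU-site points)
```

All 30 ground-truth contaminant OTUs are caught by the control correction;
the three habitats separate strongly (ANOSIM R = 0.78); the tracker
attributes ~27–29% of each downwind community to the local plant (truth:
30%) and essentially nothing upwind; and the enrichment slope is positive —
abundant epiphytes are preferentially enriched downwind.

The same run from a shell:

```bash
aerosource run --seed 11 --out results/study11
```

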