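"""End-to-end orchestration of a study: synth → decontam → rarefy →
diversity/distance → inference → source tracking → results bundle.

One master seed fans out to deterministic per-stage seeds; the JSON manifest
records every parameter and output shape but no wall-clock information, so a
fixed-seed run is byte-identical."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decontam, distance, diversity, inference, io, sourcetrack, synth
from .containers import Habitat, ValidationError, meta_frame, samples_with_habitat

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("aerosource")

#: rarefaction depths used by the original survey design
DEFAULT_DEPTHS = {"bacteria": 4714, "fungi": 1200, "corrected": 3801}


@dataclass
class PipelineConfig:
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    counts_path: str | None = None      # run from files instead of the generator
    meta_path: str | None = None
    depth: int | None = None            # None -> smallest environmental library
    run_decontam: bool = True
    decontam: decontam.DecontamConfig = field(default_factory=decontam.DecontamConfig)
    metric: str = "braycurtis"
    n_permutations: int = 999
    sourcetrack: sourcetrack.SourceTrackConfig = field(
        default_factory=sourcetrack.SourceTrackConfig
    )
    min_plant_prop: float = 0.001
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "synth" in kwargs:
            kwargs["synth"] = synth.SynthConfig(**kwargs["synth"])
        if "decontam" in kwargs:
            kwargs["decontam"] = decontam.DecontamConfig(**kwargs["decontam"])
        if "sourcetrack" in kwargs:
            kwargs["sourcetrack"] = sourcetrack.SourceTrackConfig(**kwargs["sourcetrack"])
        return cls(**kwargs)


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([int(master), 101, stage]).generate_state(1)[0]
               % (2**31 - 1))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "value"):  # enums
        return obj.value
    return obj


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every enabled stage, writing each artifact into ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(cfg), "stages": {}}

    def record(stage: str, started: float, **info) -> None:
        log.info("stage=%s elapsed=%.2fs %s", stage, time.time() - started,
                 " ".join(f"{k}={v}" for k, v in info.items()))
        manifest["stages"][stage] = info

    # -- input ------------------------------------------------------------
    t0 = time.time()
    if cfg.counts_path:
        counts = io.read_count_table(cfg.counts_path)
        meta = io.read_sample_info(cfg.meta_path)
        truth = None
    else:
        counts, meta, truth = synth.generate_study(cfg.synth)
        truth.to_json(outdir / "truth.json")
    io.write_count_table(counts, outdir / "counts.tsv")
    io.write_sample_info(meta, outdir / "meta.tsv")
    record("input", t0, n_otus=counts.n_otus, n_samples=counts.n_samples)

    # -- decontamination --------------------------------------------------
    t0 = time.time()
    has_controls = bool(
        samples_with_habitat(meta, (Habitat.NTC, Habitat.EXTRACTION_CONTROL))
    )
    if cfg.run_decontam and has_controls:
        corrected, report = decontam.apply_correction(counts, meta, cfg.decontam)
        (outdir / "decontam_report.json").write_text(
            json.dumps(report.to_dict(), sort_keys=True)
        )
    else:
        env = samples_with_habitat(
            meta, (Habitat.PLANT, Habitat.UPWIND, Habitat.DOWNWIND)
        )
        corrected = counts.select_samples([s for s in env if s in counts.sample_ids])
    io.write_count_table(corrected, outdir / "corrected.tsv")
    record("decontam", t0, n_otus=corrected.n_otus, n_samples=corrected.n_samples,
           applied=cfg.run_decontam and has_controls)

    # -- rarefaction ------------------------------------------------------
    t0 = time.time()
    depth = cfg.depth or int(corrected.library_sizes().min())
    rarefied, dropped = decontam.rarefy(corrected, depth, seed=_stage_seed(cfg.seed, 1))
    io.write_count_table(rarefied, outdir / "rarefied.tsv")
    record("rarefy", t0, depth=depth, dropped=dropped)

    # -- alpha diversity --------------------------------------------------
    t0 = time.time()
    alpha = diversity.alpha_table(rarefied)
    alpha.to_csv(outdir / "alpha.tsv", sep="\t")
    record("alpha", t0, n_samples=len(alpha))

    # -- distances / ordination / clustering ------------------------------
    t0 = time.time()
    dm = distance.distance_matrix(rarefied, cfg.metric)
    io.write_distance_matrix(dm, outdir / "distance.tsv")
    ord_ = distance.nmds(dm, seed=_stage_seed(cfg.seed, 2))
    np.savetxt(outdir / "nmds.tsv",
               np.column_stack([ord_.coordinates]), delimiter="\t",
               header="\t".join(["axis1", "axis2"]),
               comments=f"# stress={ord_.stress:.6f}\n")
    (outdir / "dendrogram.nwk").write_text(
        distance.to_newick(distance.hclust_average(dm)) + "\n"
    )
    record("distance", t0, metric=cfg.metric, stress=round(ord_.stress, 6))

    # -- permutation inference --------------------------------------------
    t0 = time.time()
    mf = meta_frame(meta).loc[rarefied.sample_ids]
    stats_out = {}
    habitat = mf["habitat"]
    a = inference.anosim(dm, habitat, cfg.n_permutations, seed=_stage_seed(cfg.seed, 3))
    stats_out["anosim_habitat"] = {"R": a.R, "p": a.p_value}
    pv = inference.permanova(dm, habitat, cfg.n_permutations, seed=_stage_seed(cfg.seed, 4))
    stats_out["permanova_habitat"] = {"pseudo_F": pv.pseudo_F, "R2": pv.R2, "p": pv.p_value}
    site = mf["site"]
    if site.nunique() >= 2 and site.value_counts().min() >= 2:
        ps = inference.permanova(dm, site, cfg.n_permutations, seed=_stage_seed(cfg.seed, 5))
        stats_out["permanova_site"] = {"pseudo_F": ps.pseudo_F, "R2": ps.R2, "p": ps.p_value}
    (outdir / "stats.json").write_text(json.dumps(stats_out, sort_keys=True))
    record("inference", t0, **{k: round(v.get("R", v.get("R2", 0)), 4)
                               for k, v in stats_out.items()})

    # -- source tracking --------------------------------------------------
    t0 = time.time()
    model = sourcetrack.fit_source_model(rarefied, meta, cfg.sourcetrack)
    attribution = sourcetrack.attribute_all(model, rarefied, meta,
                                            seed=_stage_seed(cfg.seed, 6))
    attribution.table.to_csv(outdir / "source_estimates.tsv", sep="\t")
    attribution.paired.to_csv(outdir / "source_paired.tsv", sep="\t", index=False)
    record("sourcetrack", t0, n_sinks=len(attribution.estimates),
           paired_p=round(attribution.p_value, 6))

    # -- enrichment regression --------------------------------------------
    t0 = time.time()
    enr = inference.enrichment_regression(rarefied, meta, cfg.min_plant_prop)
    enr.points.to_csv(outdir / "enrichment_points.tsv", sep="\t", index=False)
    enrichment = {"slope": enr.slope, "intercept": enr.intercept,
                  "slope_p_value": enr.slope_p_value, "r_squared": enr.r_squared,
                  "n_otus": enr.n_otus, "excluded_sites": enr.excluded_sites}
    (outdir / "enrichment.json").write_text(json.dumps(enrichment, sort_keys=True))
    record("enrichment", t0, slope=round(enr.slope, 6), p=round(enr.slope_p_value, 6))

    manifest["results"] = {
        "stats": stats_out,
        "enrichment": enrichment,
        "sourcetrack_paired_p": attribution.p_value,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
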