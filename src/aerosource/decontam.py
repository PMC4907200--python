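"""Two-stage negative-control correction of OTU count tables, plus rarefaction.

Reagent contamination shows up in no-template controls (NTCs) and extraction
blanks. The correction distinguishes, per control-detected OTU, between two
regimes by comparing environmental abundance against the control abundance
scaled to the environmental library size:

* the OTU is present in the environment at *similar* (scaled) read numbers —
  treat the whole OTU as contamination and remove its row from the table;
* the environmental abundance is at least ``similarity_threshold`` times the
  scaled control abundance — treat the control reads as a spill-over floor
  and subtract it proportionally per sample:

      corrected = count_s - (library_s / library_control) * count_control

NTC correction runs first (environmental samples and extraction controls
were amplified under the same conditions, so the NTC signal is present in
both), then the corrected extraction controls drive a second pass against
the environmental samples only. Corrected values are real-valued; they are
rounded half-to-even before the table re-enters the integer world of
rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CountTable,
    ENV_HABITATS,
    Habitat,
    SampleInfo,
    ValidationError,
    samples_with_habitat,
)

__all__ = [
    "DecontamConfig",
    "DecontamReport",
    "ControlClassification",
    "classify_control_otus",
    "relative_subtract",
    "apply_correction",
    "rarefy",
]


@dataclass
class DecontamConfig:
    similarity_threshold: float = 5.0   # "similar read numbers" boundary
    subtract_threshold: float = 5.0     # the five-times rule
    clamp_negative: bool = True
    # Default reading of the five-times rule: subtract when the environmental
    # abundance is >= threshold x the scaled control abundance. The inverse
    # reading (swap the two sets) is exposed because the prose rule is
    # grammatically ambiguous about which quantity is five times which.
    invert_rule: bool = False
    per_control_sequential: bool = False

    def __post_init__(self) -> None:
        if self.similarity_threshold <= 1 or self.subtract_threshold <= 1:
            raise ValidationError("thresholds must exceed 1")


@dataclass
class ControlClassification:
    remove: list[str]
    subtract: list[str]
    control_counts: pd.Series = field(repr=False)
    control_library: float = 0.0


@dataclass
class DecontamReport:
    removed_otus: list[dict] = field(default_factory=list)
    subtracted_otus: list[dict] = field(default_factory=list)
    reads_before: dict[str, float] = field(default_factory=dict)
    reads_after: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_otus": self.removed_otus,
            "subtracted_otus": self.subtracted_otus,
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
        }


def relative_subtract(
    count_s: float,
    lib_s: float,
    count_ntc: float,
    lib_ntc: float,
    clamp_negative: bool = True,
) -> float:
    """Library-size-scaled control subtraction for one cell.

    Returns ``count_s - (lib_s / lib_ntc) * count_ntc``, clamped at zero by
    default (counts cannot go negative).
    """
    if lib_ntc <= 0:
        raise ValidationError("control library size must be positive")
    if min(count_s, lib_s, count_ntc) < 0:
        raise ValidationError("counts and library sizes must be non-negative")
    corrected = count_s - (lib_s / lib_ntc) * count_ntc
    if clamp_negative and corrected < 0:
        return 0.0
    return corrected


def _classify(
    frame: pd.DataFrame,
    env_ids: list[str],
    env_libs: pd.Series,
    control_counts: pd.Series,
    control_lib: float,
    cfg: DecontamConfig,
) -> ControlClassification:
    remove: list[str] = []
    subtract: list[str] = []
    if control_lib <= 0:
        return ControlClassification(remove, subtract, control_counts, control_lib)
    ctrl_prop = control_counts / control_lib
    usable = [s for s in env_ids if env_libs[s] > 0]
    for otu in frame.index[control_counts > 0]:
        ratios = [
            float(frame.at[otu, s]) / (env_libs[s] * ctrl_prop[otu])
            for s in usable
        ]
        med = float(np.median(ratios)) if ratios else 0.0
        similar = med < cfg.similarity_threshold
        above = med >= cfg.subtract_threshold
        if not cfg.invert_rule:
            if similar:
                remove.append(otu)
            elif above:
                subtract.append(otu)
        else:
            if similar:
                subtract.append(otu)
            elif above:
                remove.append(otu)
    return ControlClassification(remove, subtract, control_counts, control_lib)


def classify_control_otus(
    counts: CountTable,
    meta: Sequence[SampleInfo],
    control_habitat: Habitat,
    cfg: DecontamConfig | None = None,
) -> ControlClassification:
    """Split control-detected OTUs into a remove set and a subtract set.

    For each OTU with nonzero control reads, the per-sample ratio of
    environmental abundance to library-size-scaled control abundance is
    computed and its median over environmental samples decides the fate of
    the OTU. Multiple controls of the same habitat are aggregated by summing
    counts and libraries. OTUs absent from the controls are untouched.
    """
    cfg = cfg or DecontamConfig()
    control_ids = [s for s in samples_with_habitat(meta, control_habitat)
                   if s in counts.sample_ids]
    if not control_ids:
        raise ValidationError(f"no {control_habitat.value} samples in the table")
    env_ids = [s for s in samples_with_habitat(meta, ENV_HABITATS)
               if s in counts.sample_ids]
    libs = counts.library_sizes().astype(float)
    if any(libs[c] == 0 for c in control_ids) and all(libs[c] == 0 for c in control_ids):
        # all-zero controls: nothing is classified
        return ControlClassification([], [], counts.data[control_ids].sum(axis=1), 0.0)
    ctrl_counts = counts.data[control_ids].sum(axis=1).astype(float)
    ctrl_lib = float(libs[control_ids].sum())
    return _classify(counts.data.astype(float), env_ids, libs, ctrl_counts, ctrl_lib, cfg)


def _stage(
    frame: pd.DataFrame,
    env_ids: list[str],
    target_ids: list[str],
    control_ids: list[str],
    cfg: DecontamConfig,
    stage_name: str,
    report: DecontamReport,
) -> pd.DataFrame:
    """Run one classification + correction pass in place on ``frame``.

    ``target_ids`` are the columns the subtraction is applied to; library
    sizes are the current column sums of ``frame``.
    """
    libs = frame.sum(axis=0)
    groups: list[list[str]]
    if cfg.per_control_sequential:
        groups = [[c] for c in control_ids]
    else:
        groups = [control_ids]
    for group in groups:
        ctrl_counts = frame[group].sum(axis=1)
        ctrl_lib = float(libs[group].sum())
        if ctrl_lib <= 0:
            continue
        cls = _classify(frame, env_ids, libs, ctrl_counts, ctrl_lib, cfg)
        if cls.remove:
            for otu in cls.remove:
                report.removed_otus.append(
                    {"otu_id": otu, "stage": stage_name,
                     "control_count": float(ctrl_counts[otu])}
                )
            frame = frame.drop(index=cls.remove)
            ctrl_counts = ctrl_counts.drop(index=cls.remove)
        for otu in cls.subtract:
            amounts = {}
            for s in target_ids:
                before = float(frame.at[otu, s])
                after = relative_subtract(
                    before, float(libs[s]), float(ctrl_counts[otu]), ctrl_lib,
                    clamp_negative=cfg.clamp_negative,
                )
                frame.at[otu, s] = after
                amounts[s] = before - after
            report.subtracted_otus.append(
                {"otu_id": otu, "stage": stage_name,
                 "control_count": float(ctrl_counts[otu]), "subtracted": amounts}
            )
    return frame


def apply_correction(
    counts: CountTable,
    meta: Sequence[SampleInfo],
    cfg: DecontamConfig | None = None,
) -> tuple[CountTable, DecontamReport]:
    """Full two-stage control correction.

    Stage 1 classifies against the NTCs and corrects environmental samples
    *and* extraction controls; stage 2 re-classifies against the corrected
    extraction controls and corrects environmental samples only. Control
    columns are dropped from the returned table and corrected values are
    rounded half-to-even back to integers.
    """
    cfg = cfg or DecontamConfig()
    ntc_ids = [s for s in samples_with_habitat(meta, Habitat.NTC) if s in counts.sample_ids]
    ec_ids = [s for s in samples_with_habitat(meta, Habitat.EXTRACTION_CONTROL)
              if s in counts.sample_ids]
    env_ids = [s for s in samples_with_habitat(meta, ENV_HABITATS) if s in counts.sample_ids]
    if not ntc_ids and not ec_ids:
        raise ValidationError(
            "no control samples present; skip the decontamination stage instead"
        )

    frame = counts.data.astype(float).copy()
    report = DecontamReport()
    report.reads_before = {s: float(frame[s].sum()) for s in env_ids}

    if ntc_ids:
        frame = _stage(frame, env_ids, env_ids + ec_ids, ntc_ids, cfg, "ntc", report)
    if ec_ids:
        frame = _stage(frame, env_ids, env_ids, ec_ids, cfg, "extraction_control", report)

    out = frame[env_ids]
    # np.round is round-half-to-even, the convention fixed for this stage
    out = pd.DataFrame(
        np.round(out.to_numpy()).astype(np.int64), index=out.index, columns=out.columns
    )
    report.reads_after = {s: float(out[s].sum()) for s in env_ids}
    return CountTable(out, validate=False), report


def rarefy(
    counts: CountTable, depth: int, seed: int = 0
) -> tuple[CountTable, list[str]]:
    """Subsample every library to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped and returned in the
    second element. Each retained cell is marginally hypergeometric. The
    draw is reproducible bit-for-bit for a fixed seed.
    """
    if depth < 0:
        raise ValidationError("rarefaction depth must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    libs = counts.library_sizes()
    kept: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for s in counts.sample_ids:
        col = counts.data[s].to_numpy()
        if libs[s] < depth:
            dropped.append(s)
        elif libs[s] == depth:
            kept[s] = col
        else:
            kept[s] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(kept, index=counts.data.index, dtype=np.int64)
    return CountTable(out, validate=False), dropped
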