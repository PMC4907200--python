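"""Forward simulator for complete source→sink field studies.

The generator emulates the post-clustering stage of a paired-air survey:
each site contributes a plant (epiphyte) community, every site shares one
regional background (upwind-air) community, and the downwind-air community
is a compositional mixture of background and local plant source. A single
reagent-contaminant profile leaks into every library — environmental
samples at a small rate, no-template and extraction controls at full
strength but with 10–100x smaller libraries, which is the low-biomass
control regime the decontamination stage corrects for.

Plant communities are dominated by few OTUs (heavy-tailed, log-normal
relative abundances), mirroring real epiphyte communities where a handful
of taxa carry about half the reads. Mixing happens at the composition
level followed by one multinomial draw per sample: the expected downwind
proportion of any OTU is therefore an exact convex combination
``(1-m-c)·background + m·plant + c·contaminant``, which is the relation
the enrichment regression and the source tracker are later asked to
recover. Ground truth (profiles, per-site mixing, per-sample effective
compositions) is recorded alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountTable, Habitat, Kingdom, SampleInfo, ValidationError

__all__ = ["SynthConfig", "Profiles", "StudyTruth", "draw_profiles", "simulate_sample", "generate_study"]

_HABITAT_CODE = {Habitat.PLANT: 1, Habitat.UPWIND: 2, Habitat.DOWNWIND: 3,
                 Habitat.NTC: 4, Habitat.EXTRACTION_CONTROL: 5}


@dataclass
class SynthConfig:
    """Study design knobs with defaults sized like the field campaign they
    emulate: 8 usable sites, a few hundred OTUs, 20k reads per library."""

    n_sites: int = 8
    n_otus: int = 300
    n_plant_otus: int = 60          # designated epiphyte OTUs
    n_contam_otus: int = 30         # reagent-contaminant OTUs
    mixing_m: float | Sequence[float] = 0.3   # plant-origin fraction of downwind air
    library_size: int = 20000
    control_library_size: int | None = None   # default: library_size // 50
    contam_rate: float = 0.02       # contaminant fraction of each environmental library
    overdispersion: float = 1.0     # symmetric Dirichlet concentration for profiles
    plant_dominance: float = 0.5    # profile mass on the designated epiphyte OTUs
    lognormal_sigma: float = 1.5    # heavy tail of epiphyte abundances
    overlap: float = 0.1            # fraction of plant-support OTUs shared with background
    n_ntc: int = 2
    n_extraction_controls: int = 3
    kingdom: Kingdom = Kingdom.BACTERIA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plant_otus + self.n_contam_otus >= self.n_otus:
            raise ValidationError(
                "n_plant_otus + n_contam_otus must leave room for background OTUs"
            )
        if self.library_size <= 0:
            raise ValidationError("library_size must be positive")
        m = np.atleast_1d(np.asarray(self.mixing_m, dtype=float))
        if np.any(m < 0) or np.any(m > 1):
            raise ValidationError("mixing_m must lie in [0, 1]")
        if not (0 <= self.contam_rate < 1):
            raise ValidationError("contam_rate must lie in [0, 1)")
        if np.any(m + self.contam_rate > 1):
            raise ValidationError("mixing_m + contam_rate must be ≤ 1")
        if self.overdispersion <= 0:
            raise ValidationError("overdispersion must be positive")
        if not (0 <= self.overlap <= 1):
            raise ValidationError("overlap must lie in [0, 1]")

    def mixing_per_site(self) -> np.ndarray:
        m = np.atleast_1d(np.asarray(self.mixing_m, dtype=float))
        if m.size == 1:
            return np.repeat(m, self.n_sites)
        if m.size != self.n_sites:
            raise ValidationError(
                f"mixing_m has {m.size} entries for {self.n_sites} sites"
            )
        return m

    @property
    def control_depth(self) -> int:
        return self.control_library_size or max(self.library_size // 50, 1)

    def site_names(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_sites)]


@dataclass
class Profiles:
    """Ground-truth compositions over the OTU axis."""

    plant: np.ndarray          # (n_sites, n_otus)
    background: np.ndarray     # (n_otus,)
    contaminant: np.ndarray    # (n_otus,)
    plant_otus: np.ndarray     # indices of the designated epiphyte block
    background_support: np.ndarray
    contam_otus: np.ndarray


@dataclass
class StudyTruth:
    """Everything a recovery test needs: true mixing, true profiles, and the
    effective composition each sample was actually drawn from."""

    mixing: dict[str, float]
    profiles: Profiles
    contam_rate: float
    sample_composition: dict[str, np.ndarray] = field(repr=False)
    otu_ids: list[str] = field(default_factory=list)

    def contaminant_only_otus(self) -> list[str]:
        """OTUs with zero mass in every plant profile and in the background."""
        p = self.profiles
        env_mass = p.plant.sum(axis=0) + p.background
        idx = np.flatnonzero((env_mass == 0) & (p.contaminant > 0))
        return [self.otu_ids[i] for i in idx]

    def genuine_otus(self) -> list[str]:
        p = self.profiles
        idx = np.flatnonzero(p.plant.sum(axis=0) + p.background > 0)
        return [self.otu_ids[i] for i in idx]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "mixing": self.mixing,
            "contam_rate": self.contam_rate,
            "otu_ids": self.otu_ids,
            "background": self.profiles.background.tolist(),
            "contaminant": self.profiles.contaminant.tolist(),
            "plant": self.profiles.plant.tolist(),
            "plant_otus": self.profiles.plant_otus.tolist(),
        }
        Path(path).write_text(json.dumps(obj, sort_keys=True))


def _rng(seed: int, *stream: int) -> np.random.Generator:
    # Stable per-stream generators: the master seed plus integer stream tags.
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _dirichlet_on(rng: np.random.Generator, support: np.ndarray,
                  n_otus: int, concentration: float) -> np.ndarray:
    prof = np.zeros(n_otus)
    prof[support] = rng.dirichlet(np.full(support.size, concentration))
    return prof


def draw_profiles(cfg: SynthConfig) -> Profiles:
    """Draw the per-site plant profiles and the shared background and
    contaminant profiles.

    OTU axis layout: a designated epiphyte block, a plant-tail block (the
    non-dominant half of the plant support), a background block, and a
    contaminant block at the end. The background support is the background
    block plus an ``overlap`` fraction of the plant support, so overlap=0
    makes plant and background supports disjoint while the default 0.1
    leaves them mostly — but not fully — separable.
    """
    rng = _rng(cfg.seed, 0)
    n = cfg.n_otus
    plant_block = np.arange(cfg.n_plant_otus)
    contam_block = np.arange(n - cfg.n_contam_otus, n)
    middle = np.arange(cfg.n_plant_otus, n - cfg.n_contam_otus)
    half = middle.size // 2
    plant_tail = middle[:half]
    bg_block = middle[half:]

    plant_support = np.concatenate([plant_block, plant_tail])
    n_shared = int(round(cfg.overlap * plant_support.size))
    shared = rng.choice(plant_support, size=n_shared, replace=False) if n_shared else np.empty(0, int)
    bg_support = np.sort(np.concatenate([bg_block, shared.astype(int)]))

    background = _dirichlet_on(rng, bg_support, n, cfg.overdispersion)
    contaminant = _dirichlet_on(rng, contam_block, n, cfg.overdispersion)

    plant = np.zeros((cfg.n_sites, n))
    for s in range(cfg.n_sites):
        dom = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=plant_block.size)
        dom = dom / dom.sum() * cfg.plant_dominance
        tail = rng.dirichlet(np.full(plant_tail.size, cfg.overdispersion))
        plant[s, plant_block] = dom
        plant[s, plant_tail] = tail * (1.0 - cfg.plant_dominance)
    return Profiles(plant, background, contaminant, plant_block, bg_support, contam_block)


def simulate_sample(
    profile: np.ndarray,
    m: float,
    plant_profile: np.ndarray,
    contam_rate: float,
    contam_profile: np.ndarray,
    library_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One multinomial library from the effective mixed composition
    ``(1-m-c)·profile + m·plant + c·contaminant``."""
    for name, p in (("profile", profile), ("plant_profile", plant_profile),
                    ("contam_profile", contam_profile)):
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{name} does not sum to 1 (got {p.sum():.12f})")
    if m < 0 or contam_rate < 0 or m + contam_rate > 1:
        raise ValidationError("require 0 ≤ m, contam_rate and m + contam_rate ≤ 1")
    eff = (1.0 - m - contam_rate) * profile + m * plant_profile + contam_rate * contam_profile
    if library_size == 0:
        return np.zeros(profile.size, dtype=np.int64)
    return rng.multinomial(library_size, eff / eff.sum())


def generate_study(cfg: SynthConfig) -> tuple[CountTable, list[SampleInfo], StudyTruth]:
    """Emit the full study: per-site plant/upwind/downwind samples plus NTC
    and extraction-control libraries, with aligned metadata and truth."""
    profiles = draw_profiles(cfg)
    m_site = cfg.mixing_per_site()
    otu_ids = [f"OTU{i + 1:04d}" for i in range(cfg.n_otus)]

    cols: dict[str, np.ndarray] = {}
    meta: list[SampleInfo] = []
    compositions: dict[str, np.ndarray] = {}

    def add(sample_id: str, habitat: Habitat, site: str, counts: np.ndarray,
            comp: np.ndarray) -> None:
        cols[sample_id] = counts
        meta.append(SampleInfo(sample_id, habitat, site, cfg.kingdom))
        compositions[sample_id] = comp

    c = cfg.contam_rate
    for s, site in enumerate(cfg.site_names()):
        plant_p = profiles.plant[s]
        specs = [
            (f"P-{site}", Habitat.PLANT, plant_p, 0.0),
            (f"UW-{site}", Habitat.UPWIND, profiles.background, 0.0),
            (f"DW-{site}", Habitat.DOWNWIND, profiles.background, float(m_site[s])),
        ]
        for sample_id, habitat, base, m in specs:
            rng = _rng(cfg.seed, s + 1, _HABITAT_CODE[habitat])
            counts = simulate_sample(base, m, plant_p, c, profiles.contaminant,
                                     cfg.library_size, rng)
            eff = (1 - m - c) * base + m * plant_p + c * profiles.contaminant
            add(sample_id, habitat, site, counts, eff)

    for k in range(cfg.n_ntc):
        rng = _rng(cfg.seed, 1000 + k, _HABITAT_CODE[Habitat.NTC])
        counts = rng.multinomial(cfg.control_depth, profiles.contaminant)
        add(f"NTC{k + 1}", Habitat.NTC, "control", counts, profiles.contaminant)
    for k in range(cfg.n_extraction_controls):
        rng = _rng(cfg.seed, 2000 + k, _HABITAT_CODE[Habitat.EXTRACTION_CONTROL])
        counts = rng.multinomial(cfg.control_depth, profiles.contaminant)
        add(f"EC{k + 1}", Habitat.EXTRACTION_CONTROL, "control", counts, profiles.contaminant)

    df = pd.DataFrame(cols, index=otu_ids)
    truth = StudyTruth(
        mixing={site: float(m) for site, m in zip(cfg.site_names(), m_site)},
        profiles=profiles,
        contam_rate=c,
        sample_composition=compositions,
        otu_ids=otu_ids,
    )
    return CountTable(df), meta, truth
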