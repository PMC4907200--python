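"""Bayesian microbial source tracking by collapsed Gibbs sampling.

Each air ("sink") community is modelled as a mixture of the candidate plant
("source") communities plus one *unknown* source whose composition is
learned on the fly. Every sink read carries a latent source label z; the
collapsed Gibbs conditional for read i with OTU o is

    P(z_i = v | ·) ∝ (S_vo + A_vo + α_v) / (S_v· + m_v + α_v·K) · (m_v + β_v)

where S is the (smoothed) training count of OTU o in source v (zero for the
unknown source, whose profile is carried entirely by the assigned-read
counts A), m_v is the number of sink reads currently assigned to v, K the
number of OTUs, α the per-OTU Dirichlet smoothing (looser for the unknown
source so it can absorb anything the known sources cannot explain), and β
the prior mass over source identity. Posterior mixing proportions are the
means of m_v / N over retained draws, averaged over independent restarts.

Sinks are rarefied to a common depth before attribution (default 1000
reads) since the m_v prior term is depth-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .containers import (
    CountTable,
    Habitat,
    SampleInfo,
    ValidationError,
    meta_frame,
    samples_with_habitat,
)

__all__ = [
    "SourceTrackConfig",
    "SourceModel",
    "SourceEstimate",
    "AttributionResult",
    "fit_source_model",
    "attribute_sink",
    "attribute_all",
]

UNKNOWN = "unknown"


@dataclass
class SourceTrackConfig:
    alpha_source: float = 0.001    # per-OTU smoothing for known sources
    alpha_unknown: float = 0.1     # per-OTU smoothing for the unknown source
    beta: float = 10.0             # total prior mass over source identity, spread uniformly
    n_burnin: int = 25
    n_draws: int = 25
    n_restarts: int = 10
    rarefaction_depth: int | None = 1000
    collapse_sites: bool = False   # merge same-site plant samples into one source

    def __post_init__(self) -> None:
        if self.alpha_source <= 0 or self.alpha_unknown <= 0:
            raise ValidationError("smoothing parameters must be positive")
        if self.n_draws < 1 or self.n_burnin < 0 or self.n_restarts < 1:
            raise ValidationError("need n_draws >= 1, n_burnin >= 0, n_restarts >= 1")


@dataclass
class SourceModel:
    source_ids: list[str]
    otu_ids: list[str]
    source_counts: np.ndarray          # (n_sources, n_otus) raw training counts
    cfg: SourceTrackConfig = field(default_factory=SourceTrackConfig)

    @property
    def n_sources(self) -> int:
        return len(self.source_ids)


@dataclass
class SourceEstimate:
    sink_id: str
    proportions: dict[str, float]      # source_id (incl. "unknown") -> posterior mean
    ci_low: dict[str, float]
    ci_high: dict[str, float]

    @property
    def known_total(self) -> float:
        return 1.0 - self.proportions[UNKNOWN]


def fit_source_model(
    sources: CountTable,
    meta: Sequence[SampleInfo],
    cfg: SourceTrackConfig | None = None,
) -> SourceModel:
    """One source per plant sample (or per site with ``collapse_sites``)."""
    cfg = cfg or SourceTrackConfig()
    plant_ids = [s for s in samples_with_habitat(meta, Habitat.PLANT)
                 if s in sources.sample_ids]
    if not plant_ids:
        raise ValidationError("no plant samples available as sources")
    data = sources.data[plant_ids]
    if cfg.collapse_sites:
        site_of = {m.sample_id: m.site for m in meta}
        grouped = data.T.groupby([site_of[s] for s in plant_ids]).sum().T
        source_ids = [f"site:{c}" for c in grouped.columns]
        mat = grouped.to_numpy().T.astype(float)
    else:
        source_ids = list(plant_ids)
        mat = data.to_numpy().T.astype(float)
    return SourceModel(source_ids, sources.otu_ids, mat, cfg)


@njit(cache=False)
def _gibbs_chain(read_otus, src, src_tot, alpha, beta_v, n_burnin, n_draws, seed):
    np.random.seed(seed)
    n_src, n_otus = src.shape
    n_reads = read_otus.shape[0]
    assigned = np.zeros((n_src, n_otus))
    m = np.zeros(n_src)
    z = np.empty(n_reads, np.int64)
    for i in range(n_reads):
        v = np.random.randint(0, n_src)
        z[i] = v
        assigned[v, read_otus[i]] += 1.0
        m[v] += 1.0
    p = np.empty(n_src)
    draws = np.zeros((n_draws, n_src))
    for sweep in range(n_burnin + n_draws):
        for i in range(n_reads):
            o = read_otus[i]
            v0 = z[i]
            assigned[v0, o] -= 1.0
            m[v0] -= 1.0
            total = 0.0
            for v in range(n_src):
                num = src[v, o] + assigned[v, o] + alpha[v]
                den = src_tot[v] + m[v] + alpha[v] * n_otus
                pv = num / den * (m[v] + beta_v[v])
                p[v] = pv
                total += pv
            u = np.random.random() * total
            acc = 0.0
            vnew = n_src - 1
            for v in range(n_src):
                acc += p[v]
                if u <= acc:
                    vnew = v
                    break
            z[i] = vnew
            assigned[vnew, o] += 1.0
            m[vnew] += 1.0
        if sweep >= n_burnin:
            for v in range(n_src):
                draws[sweep - n_burnin, v] = m[v] / n_reads
    return draws


def _expand_reads(sink: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(sink.size), sink.astype(np.int64))


def attribute_sink(
    model: SourceModel,
    sink,
    seed: int = 0,
    sink_id: str = "sink",
) -> SourceEstimate:
    """Posterior mixing proportions of one sink over all sources + unknown."""
    if isinstance(sink, pd.Series):
        sink = sink.reindex(model.otu_ids).fillna(0).to_numpy()
    sink = np.asarray(sink)
    if sink.size != len(model.otu_ids):
        raise ValidationError("sink vector does not match the model's OTU axis")
    if sink.sum() == 0:
        raise ValidationError("empty sink")
    cfg = model.cfg

    depth = cfg.rarefaction_depth
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    counts = sink.astype(np.int64)
    if depth is not None and counts.sum() > depth:
        counts = rng.multivariate_hypergeometric(counts, depth)
    read_otus = _expand_reads(counts)

    k = model.n_sources
    n_src = k + 1                                    # + unknown
    src = np.zeros((n_src, len(model.otu_ids)))
    src[:k] = model.source_counts
    src_tot = src.sum(axis=1)
    alpha = np.full(n_src, cfg.alpha_source)
    alpha[k] = cfg.alpha_unknown
    beta_v = np.full(n_src, cfg.beta / n_src)

    all_draws = []
    for r in range(cfg.n_restarts):
        chain_seed = int(
            np.random.SeedSequence([int(seed), 11, r]).generate_state(1)[0] % (2**31 - 1)
        )
        d = _gibbs_chain(read_otus, src, src_tot, alpha, beta_v,
                         cfg.n_burnin, cfg.n_draws, chain_seed)
        all_draws.append(d)
    draws = np.vstack(all_draws)
    mean = draws.mean(axis=0)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    names = list(model.source_ids) + [UNKNOWN]
    return SourceEstimate(
        sink_id,
        dict(zip(names, map(float, mean))),
        dict(zip(names, map(float, np.minimum(lo, mean)))),
        dict(zip(names, map(float, np.maximum(hi, mean)))),
    )


@dataclass
class AttributionResult:
    estimates: list[SourceEstimate]
    table: pd.DataFrame = field(repr=False)     # sink x source posterior means
    paired: pd.DataFrame = field(repr=False)    # per-site downwind vs upwind plant share
    p_value: float = float("nan")               # paired one-sided t: downwind > upwind


def attribute_all(
    model: SourceModel,
    sinks: CountTable,
    meta: Sequence[SampleInfo],
    seed: int = 0,
) -> AttributionResult:
    """Attribute every upwind/downwind sink and pair the plant-attributed
    shares by site for a one-sided downwind > upwind test."""
    mf = meta_frame(meta)
    sink_ids = [s for s in sinks.sample_ids
                if s in mf.index and mf.loc[s, "habitat"] in ("upwind", "downwind")]
    if not sink_ids:
        raise ValidationError("no upwind/downwind sinks in the table")
    estimates = []
    for idx, s in enumerate(sink_ids):
        sub_seed = int(np.random.SeedSequence([int(seed), 3, idx]).generate_state(1)[0]
                       % (2**31 - 1))
        estimates.append(attribute_sink(model, sinks.data[s], seed=sub_seed, sink_id=s))
    table = pd.DataFrame({e.sink_id: e.proportions for e in estimates}).T
    table.index.name = "sink_id"

    plant_share = {e.sink_id: e.known_total for e in estimates}
    rows = []
    for site in pd.unique(mf.loc[sink_ids, "site"]):
        sub = mf.loc[sink_ids][mf.loc[sink_ids, "site"] == site]
        uw = list(sub.index[sub["habitat"] == "upwind"])
        dw = list(sub.index[sub["habitat"] == "downwind"])
        if uw and dw:
            rows.append({"site": site,
                         "upwind_plant": plant_share[uw[0]],
                         "downwind_plant": plant_share[dw[0]]})
    paired = pd.DataFrame(rows)
    p = float("nan")
    if len(paired) >= 2:
        diff = paired["downwind_plant"] - paired["upwind_plant"]
        if np.allclose(diff.std(ddof=1), 0.0):
            p = 1.0 if diff.mean() <= 0 else 0.0
        else:
            p = float(stats.ttest_rel(paired["downwind_plant"], paired["upwind_plant"],
                                      alternative="greater").pvalue)
    return AttributionResult(estimates, table, paired, p)
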