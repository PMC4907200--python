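"""Permutation inference on distance matrices and the air-enrichment regression.

ANOSIM tests whether between-group dissimilarity ranks exceed within-group
ranks; R = (r̄_between - r̄_within) / (n(n-1)/4) lies in [-1, 1], with 0
meaning no separation and 1 complete separation. PERMANOVA (the one-factor
ADONIS decomposition) partitions the squared-distance variance into a
between-group and a within-group part and tests the pseudo-F by permuting
sample labels. Both tests use the +1 convention — the observed statistic is
a member of its own reference set — so p ≥ 1/(n_permutations + 1) and p = 0
is impossible.

The enrichment regression quantifies the source→sink relation directly:
for every site with all three habitats, each OTU recovered on the plant at
≥ ``min_plant_prop`` relative abundance contributes one point
(d_air, log(1 + plant abundance)), where d_air is the downwind-minus-upwind
difference in relative abundance. A positive fitted slope means the taxa
most abundant on plants are the most enriched in the air downwind of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .containers import (
    CountTable,
    Habitat,
    SampleInfo,
    ValidationError,
    meta_frame,
)

__all__ = [
    "AnosimResult",
    "PermanovaResult",
    "EnrichmentResult",
    "anosim",
    "permanova",
    "alpha_group_test",
    "enrichment_regression",
]


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    grouping: list[str]


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    factor: list[str]


def _align_labels(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, Mapping):
        labels = [groups[i] for i in dm.ids]
    elif isinstance(groups, pd.Series):
        labels = [groups[i] for i in dm.ids]
    else:
        labels = list(groups)
        if len(labels) != dm.shape[0]:
            raise ValidationError("group labels do not match distance matrix size")
    return np.asarray(labels, dtype=object)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Rank-based analysis of similarities with a seeded permutation test."""
    labels = _align_labels(dm, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValidationError("anosim needs >=2 groups each of size >=2")
    n = dm.shape[0]
    condensed = dm.condensed_form()
    ranks = stats.rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)

    obs = _anosim_r(ranks, labels[iu] == labels[ju], n)
    rng = np.random.default_rng(seed)
    # vectorized permutation null: (B, n) permuted codes -> (B, M) within masks
    codes = pd.factorize(labels)[0]
    perm = codes[np.stack([rng.permutation(n) for _ in range(n_permutations)])]
    within = perm[:, iu] == perm[:, ju]
    m_total = ranks.size
    sum_w = within @ ranks
    cnt_w = within.sum(axis=1)
    r_w = sum_w / cnt_w
    r_b = (ranks.sum() - sum_w) / (m_total - cnt_w)
    r_perm = (r_b - r_w) / (n * (n - 1) / 4.0)
    hits = int((r_perm >= obs - 1e-12).sum())
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(float(obs), float(p), n_permutations, list(uniq))


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    uniq = np.unique(labels)
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    a = uniq.size
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dm: DistanceMatrix,
    factor,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA (the ADONIS partition)."""
    labels = _align_labels(dm, factor)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("permanova needs at least 2 factor levels")
    d2 = dm.data ** 2
    n = dm.shape[0]
    obs_f, r2 = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    # vectorized permutation null: quadratic forms over group indicators
    a = uniq.size
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    perm = labels[np.stack([rng.permutation(n) for _ in range(n_permutations)])]
    ss_within = np.zeros(n_permutations)
    for g in uniq:
        x = (perm == g).astype(float)            # (B, n)
        size = int((labels == g).sum())
        if size < 2:
            continue
        quad = ((x @ d2) * x).sum(axis=1) / 2.0  # sum_{i<j in g} d2
        ss_within += quad / size
    f_perm = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    hits = int((f_perm >= obs_f - 1e-12).sum())
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(obs_f), float(r2), float(p), n_permutations, list(uniq))


def alpha_group_test(
    values,
    groups,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests of an alpha-diversity column across groups.

    Exact null enumeration is used for small tie-free groups (both n <= 8),
    the tie-corrected normal approximation otherwise. The Bonferroni factor
    is the number of pairs; corrected p-values are capped at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    uniq = [g for g in pd.unique(groups)]
    if len(uniq) < 2:
        raise ValidationError("need at least two groups")
    by_group = {g: values[groups == g] for g in uniq}
    for g, v in by_group.items():
        if v.size == 0:
            raise ValidationError(f"group {g!r} is empty")
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    rows = []
    for a, b in pairs:
        va, vb = by_group[a], by_group[b]
        no_ties = np.unique(np.concatenate([va, vb])).size == va.size + vb.size
        method = "exact" if (max(va.size, vb.size) <= 8 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
        p_adj = min(1.0, res.pvalue * len(pairs)) if correction == "bonferroni" else res.pvalue
        rows.append({"group_a": a, "group_b": b, "U": float(res.statistic),
                     "p_raw": float(res.pvalue), "p_adjusted": float(p_adj)})
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    slope: float
    intercept: float
    slope_p_value: float
    r_squared: float
    n_otus: int
    excluded_sites: list[str]
    points: pd.DataFrame = field(repr=False)


def enrichment_regression(
    counts: CountTable,
    meta: Sequence[SampleInfo],
    min_plant_prop: float = 0.001,
    percent_predictor: bool = True,
    exclude_sites: Sequence[str] = (),
    exclude_otus: Sequence[str] = (),
) -> EnrichmentResult:
    """OLS of per-OTU air enrichment (d_air = DW - UW proportion difference)
    on log(1 + plant abundance), pooled over sites.

    The plant-abundance filter (default >= 0.1%) is applied per site, so an
    OTU can enter the fit at one site and not another. Sites lacking any of
    the three habitats are excluded automatically and reported. The
    predictor is log(x + 1) of the plant abundance in percent by default
    (``percent_predictor=False`` uses the fractional scale).
    """
    mf = meta_frame(meta)
    mf = mf.loc[[s for s in mf.index if s in counts.sample_ids]]
    props = counts.proportions()

    records = []
    excluded: list[str] = list(exclude_sites)
    sites = [s for s in pd.unique(mf["site"]) if s != "control"]
    for site in sites:
        if site in exclude_sites:
            continue
        sub = mf[mf["site"] == site]
        by_hab = {h.value: list(sub.index[sub["habitat"] == h.value])
                  for h in (Habitat.PLANT, Habitat.UPWIND, Habitat.DOWNWIND)}
        if not all(by_hab.values()):
            excluded.append(site)
            continue
        p_plant = props[by_hab["plant"][0]]
        p_uw = props[by_hab["upwind"][0]]
        p_dw = props[by_hab["downwind"][0]]
        keep = (p_plant >= min_plant_prop) & (p_plant > 0)
        for otu in props.index[keep]:
            if otu in exclude_otus:
                continue
            plant_abund = p_plant[otu] * (100.0 if percent_predictor else 1.0)
            records.append(
                {"site": site, "otu_id": otu,
                 "d_air": float(p_dw[otu] - p_uw[otu]),
                 "plant_logabund": float(np.log1p(plant_abund))}
            )
    if not records:
        raise ValidationError("no OTU passes the plant-abundance filter")
    points = pd.DataFrame(records)
    y = points["d_air"].to_numpy()
    x = points["plant_logabund"].to_numpy()
    if np.allclose(y, 0.0):
        # downwind identical to upwind everywhere: no enrichment signal at all
        return EnrichmentResult(0.0, 0.0, 1.0, 0.0, len(points), excluded, points)
    if np.unique(x).size < 2:
        raise ValidationError("predictor is constant; regression undefined")
    fit = stats.linregress(x, y)
    return EnrichmentResult(
        float(fit.slope), float(fit.intercept), float(fit.pvalue),
        float(fit.rvalue ** 2), len(points), excluded, points,
    )
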