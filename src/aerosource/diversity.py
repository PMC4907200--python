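"""Per-sample alpha-diversity estimators on a rarefied count table.

Shannon entropy is reported in nats; Chao1 uses the bias-corrected form
``S_obs + F1(F1-1) / (2(F2+1))`` by default so it stays finite when there
are no doubletons (the classical ``F1^2 / (2 F2)`` form is available behind
a flag). Together with inverse Simpson and Berger-Parker dominance these
are the Hill-number family endpoints: exp(H) ≥ 1/D ≥ 1/max(p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountTable, ValidationError

__all__ = ["shannon", "inv_simpson", "chao1", "berger_parker", "alpha_table"]


def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D count vector")
    if np.any(x < 0):
        raise ValidationError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero count vector")
    return x[x > 0] / total


def shannon(counts) -> float:
    """Shannon-Wiener H = -sum p_i ln p_i (nats)."""
    p = _proportions(counts)
    return float(-(p * np.log(p)).sum())


def inv_simpson(counts) -> float:
    """Inverse Simpson 1/D = 1 / sum p_i^2 (effective number of taxa)."""
    p = _proportions(counts)
    return float(1.0 / (p ** 2).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton (F1) and doubleton (F2) frequencies."""
    x = np.asarray(counts)
    if np.any(x < 0) or np.any(x % 1 != 0):
        raise ValidationError("chao1 requires non-negative integer counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValidationError("classical Chao1 undefined with no doubletons")
    return s_obs + f1 ** 2 / (2.0 * f2)


def berger_parker(counts) -> float:
    """Berger-Parker dominance: the largest relative abundance."""
    p = _proportions(counts)
    return float(p.max())


def alpha_table(counts: CountTable) -> pd.DataFrame:
    """All estimators for every sample of a table, one row per sample."""
    records = []
    for s in counts.sample_ids:
        col = counts.data[s].to_numpy()
        records.append(
            {
                "sample_id": s,
                "richness_observed": int((col > 0).sum()),
                "shannon_H": shannon(col),
                "inv_simpson": inv_simpson(col),
                "chao1": chao1(col),
                "berger_parker": berger_parker(col),
            }
        )
    return pd.DataFrame.from_records(records).set_index("sample_id")
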