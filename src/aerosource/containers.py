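"""In-memory containers shared by every stage of the pipeline.

The universal currency is :class:`CountTable`, an OTU-by-sample matrix of
non-negative integer read counts, paired with per-sample metadata rows
(:class:`SampleInfo`) that identify the habitat (plant, upwind air, downwind
air, or one of the two control types), the sampling site, and the kingdom of
the marker gene. Pairwise dissimilarities are carried as
:class:`skbio.DistanceMatrix` objects, which enforce symmetry and a zero
diagonal at construction time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Habitat",
    "Kingdom",
    "SampleInfo",
    "CountTable",
    "TaxonomyTable",
    "ValidationError",
    "meta_frame",
    "habitat_map",
    "samples_with_habitat",
]


class ValidationError(ValueError):
    """An input artifact violates a structural invariant."""


class Habitat(enum.Enum):
    """Sample origin: three environmental habitats plus two control types."""

    PLANT = "plant"
    UPWIND = "upwind"
    DOWNWIND = "downwind"
    NTC = "ntc"
    EXTRACTION_CONTROL = "extraction_control"

    @classmethod
    def parse(cls, token: str) -> "Habitat":
        key = str(token).strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "plant": cls.PLANT,
            "plants": cls.PLANT,
            "upwind": cls.UPWIND,
            "upwind_air": cls.UPWIND,
            "downwind": cls.DOWNWIND,
            "downwind_air": cls.DOWNWIND,
            "ntc": cls.NTC,
            "no_template_control": cls.NTC,
            "extraction_control": cls.EXTRACTION_CONTROL,
            "ec": cls.EXTRACTION_CONTROL,
        }
        if key not in aliases:
            allowed = sorted({k for k in aliases})
            raise ValidationError(
                f"unknown habitat {token!r}; allowed values (case-insensitive): {allowed}"
            )
        return aliases[key]

    @property
    def is_control(self) -> bool:
        return self in (Habitat.NTC, Habitat.EXTRACTION_CONTROL)


#: Habitats of real (non-control) samples.
ENV_HABITATS = (Habitat.PLANT, Habitat.UPWIND, Habitat.DOWNWIND)


class Kingdom(enum.Enum):
    BACTERIA = "bacteria"
    FUNGI = "fungi"

    @classmethod
    def parse(cls, token: str) -> "Kingdom":
        key = str(token).strip().lower()
        for member in cls:
            if member.value == key:
                return member
        raise ValidationError(
            f"unknown kingdom {token!r}; allowed values: "
            f"{[m.value for m in cls]}"
        )


@dataclass(frozen=True)
class SampleInfo:
    """One metadata row: habitat/site/kingdom labels for a sample."""

    sample_id: str
    habitat: Habitat
    site: str
    kingdom: Kingdom = Kingdom.BACTERIA


def meta_frame(meta: Sequence[SampleInfo]) -> pd.DataFrame:
    """Metadata rows as a DataFrame indexed by sample id."""
    return pd.DataFrame(
        {
            "habitat": [m.habitat.value for m in meta],
            "site": [m.site for m in meta],
            "kingdom": [m.kingdom.value for m in meta],
        },
        index=pd.Index([m.sample_id for m in meta], name="sample_id"),
    )


def habitat_map(meta: Sequence[SampleInfo]) -> dict[str, Habitat]:
    return {m.sample_id: m.habitat for m in meta}


def samples_with_habitat(
    meta: Sequence[SampleInfo], habitats: Habitat | Iterable[Habitat]
) -> list[str]:
    if isinstance(habitats, Habitat):
        habitats = (habitats,)
    wanted = set(habitats)
    return [m.sample_id for m in meta if m.habitat in wanted]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = seen.get(i, 0) + 1
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


class CountTable:
    """Non-negative integer OTU-by-sample count matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are OTUs, columns are samples. Values must be non-negative
        integers (float input is accepted only if every value is integral).
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        if validate:
            _check_unique(list(map(str, data.index)), "otu_ids")
            _check_unique(list(map(str, data.columns)), "sample_ids")
            values = data.to_numpy()
            if values.size:
                if not np.issubdtype(values.dtype, np.number):
                    raise ValidationError("counts must be numeric")
                if np.any(values < 0):
                    r, c = np.argwhere(values < 0)[0]
                    raise ValidationError(
                        f"negative count at (row {r + 1}, col {c + 1}) "
                        f"[otu {data.index[r]!r}, sample {data.columns[c]!r}]"
                    )
                if not np.all(np.equal(np.mod(values, 1), 0)):
                    r, c = np.argwhere(np.mod(values, 1) != 0)[0]
                    raise ValidationError(
                        f"non-integer count at (row {r + 1}, col {c + 1}) "
                        f"[otu {data.index[r]!r}, sample {data.columns[c]!r}]"
                    )
            data = data.astype(np.int64)
        self.data = data

    # -- basic views ------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def proportions(self) -> pd.DataFrame:
        """Column-wise relative abundances; all-zero columns stay zero."""
        libs = self.library_sizes().astype(float)
        safe = libs.replace(0, np.nan)
        return (self.data / safe).fillna(0.0)

    # -- subsetting -------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)], validate=False)

    def drop_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        return CountTable(self.data.drop(columns=list(sample_ids)), validate=False)

    def drop_otus(self, otu_ids: Iterable[str]) -> "CountTable":
        return CountTable(self.data.drop(index=list(otu_ids)), validate=False)

    def sample(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), validate=False)

    def equals(self, other: "CountTable") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountTable({self.n_otus} OTUs x {self.n_samples} samples)"


@dataclass
class TaxonomyTable:
    """Per-OTU rank labels (domain→genus for bacteria, kingdom→species for
    fungi); unknown ranks are marked ``unclassified``. Carries labels only —
    classification itself happens upstream of this package."""

    ranks: Sequence[str]
    labels: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _check_unique(list(self.labels.index), "otu_ids")
        if list(self.labels.columns) != list(self.ranks):
            raise ValidationError(
                f"taxonomy columns {list(self.labels.columns)} do not match "
                f"declared ranks {list(self.ranks)}"
            )
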