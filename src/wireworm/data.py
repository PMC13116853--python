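"""Data model and delimited-text I/O for paired wireworm monitoring observations.

Each observation is one sampling point in a monitored field: a soil core
(direct larval count for a fixed soil volume) paired with a bait trap
located 3 m away (indirect, mobility-dependent count accumulated over ~10
days).  Either count may be missing — a trap destroyed by field work, a
core that could not be processed — and missingness is distinct from a
zero count, which is a valid observation of absence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Species",
    "PairedObservation",
    "Dataset",
    "DataError",
    "read_dataset",
    "write_dataset",
    "complete_case_pairs",
    "DEFAULT_COLUMNS",
]


class Species(str, enum.Enum):
    """The three Agriotes species with established bait-trap damage thresholds."""

    A_brevis = "A_brevis"
    A_sordidus = "A_sordidus"
    A_ustulatus = "A_ustulatus"

    @classmethod
    def coerce(cls, value: "Species | str") -> "Species":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise DataError(f"unknown species: {value!r}") from None


class DataError(ValueError):
    """Raised on malformed input data or invariant violations."""


@dataclass(frozen=True)
class PairedObservation:
    """One soil-core / bait-trap pair for one species at one sampling point.

    ``field_id`` is the permutation stratum: re-pairing under the spatial
    null shuffles trap values only among points of the same field.
    """

    site_id: str
    point_id: str
    species: Species
    soil_count: int | None
    trap_count: int | None
    field_id: str = ""

    def __post_init__(self) -> None:
        if not self.field_id:
            object.__setattr__(self, "field_id", self.site_id)
        for name in ("soil_count", "trap_count"):
            v = getattr(self, name)
            if v is None:
                continue
            if v != int(v) or v < 0:
                raise DataError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def complete(self) -> bool:
        return self.soil_count is not None and self.trap_count is not None


@dataclass
class Dataset:
    """An ordered collection of paired observations with provenance text."""

    observations: list[PairedObservation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, Species]] = set()
        for i, obs in enumerate(self.observations):
            key = (obs.site_id, obs.point_id, obs.species)
            if key in seen:
                raise DataError(
                    f"duplicate (site, point, species) at position {i}: {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def species_present(self) -> list[Species]:
        out: list[Species] = []
        for obs in self.observations:
            if obs.species not in out:
                out.append(obs.species)
        return out

    def subset(self, species: Species | str) -> list[PairedObservation]:
        sp = Species.coerce(species)
        return [o for o in self.observations if o.species == sp]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [o.site_id for o in self.observations],
                "field_id": [o.field_id for o in self.observations],
                "point_id": [o.point_id for o in self.observations],
                "species": [o.species.value for o in self.observations],
                "soil_count": [o.soil_count for o in self.observations],
                "trap_count": [o.trap_count for o in self.observations],
            }
        )


#: canonical column names; a schema maps these onto the file's own headers
DEFAULT_COLUMNS: Mapping[str, str] = {
    "site_id": "site_id",
    "field_id": "field_id",
    "point_id": "point_id",
    "species": "species",
    "soil_count": "soil_count",
    "trap_count": "trap_count",
}


def _parse_count(token: str, missing_token: str, row: int, col: str) -> int | None:
    if token == missing_token:
        return None
    try:
        value = int(token)
    except ValueError:
        raise DataError(f"row {row}: cannot parse {col}={token!r} as integer") from None
    if value < 0:
        raise DataError(f"row {row}: negative {col}={value}")
    return value


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
    missing_token: str = "",
) -> Dataset:
    """Read a delimited-text file of paired observations.

    The file must carry a header row.  ``schema`` maps canonical column
    names (see :data:`DEFAULT_COLUMNS`) onto the file's headers; the
    ``field_id`` column is optional and defaults to ``site_id``.  Cells
    equal to ``missing_token`` (default: empty) become missing values —
    zeros are data, never missing.  Comma and tab delimiters are detected
    when ``delimiter`` is not given.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    cols = dict(DEFAULT_COLUMNS)
    if schema:
        cols.update(schema)
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    required = ["site_id", "point_id", "species", "soil_count", "trap_count"]
    missing_cols = [cols[c] for c in required if cols[c] not in df.columns]
    if missing_cols:
        raise DataError(f"missing columns in {path.name}: {missing_cols}")
    has_field = cols["field_id"] in df.columns

    observations = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(df.columns, row))
        try:
            obs = PairedObservation(
                site_id=rec[cols["site_id"]],
                field_id=rec[cols["field_id"]] if has_field else "",
                point_id=rec[cols["point_id"]],
                species=Species.coerce(rec[cols["species"]]),
                soil_count=_parse_count(
                    rec[cols["soil_count"]], missing_token, i, "soil_count"
                ),
                trap_count=_parse_count(
                    rec[cols["trap_count"]], missing_token, i, "trap_count"
                ),
            )
        except DataError as exc:
            raise DataError(f"{path.name}, row {i}: {exc}") from None
        observations.append(obs)
    return Dataset(observations, provenance=f"read from {path}")


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    *,
    delimiter: str = ",",
    missing_token: str = "",
) -> None:
    """Write a dataset as delimited text; inverse of :func:`read_dataset`."""
    df = dataset.to_frame()
    for col in ("soil_count", "trap_count"):
        df[col] = df[col].map(
            lambda v: missing_token if pd.isna(v) else str(int(v))
        )
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def complete_case_pairs(
    dataset: Dataset | Iterable[PairedObservation],
    species: Species | str | None = None,
) -> list[PairedObservation]:
    """Observations with both counts present, order preserved.

    All pairwise analyses (contingency tables, correlations, count model
    fits) operate on complete cases; per-method summaries instead use each
    method's own valid values, so their N differs from the pairwise N.
    """
    if isinstance(dataset, Dataset):
        obs: Sequence[PairedObservation] = dataset.observations
    else:
        obs = list(dataset)
    if species is not None:
        sp = Species.coerce(species)
        obs = [o for o in obs if o.species == sp]
        if isinstance(dataset, Dataset) and sp not in dataset.species_present():
            raise DataError(f"species {sp.value} not present in dataset")
    return [o for o in obs if o.complete]


def relabel_fields(pairs: Sequence[PairedObservation], field_id: str) -> list[PairedObservation]:
    """Copy of ``pairs`` with every observation assigned to one field."""
    return [replace(p, field_id=field_id) for p in pairs]
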