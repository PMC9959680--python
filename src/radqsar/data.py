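"""Descriptor and activity tables: data model, validation and delimited-text I/O.

The central objects are :class:`DescriptorTable` (compounds x named molecular
descriptors), :class:`ActivityTable` (per-compound radical-scavenging
activities Y1 = hydroxyl radical, Y2 = superoxide anion, Y3 = DPPH, all on the
percent/10 scale, i.e. values in [0, 10]) and their aligned pair
:class:`DataSet`.

Descriptors are numeric molecular properties -- bond lengths in angstrom,
atomic charges and HOMO energy in atomic units, polarizability, AlogP,
Connolly surface area -- precomputed elsewhere and read here from CSV/TSV.
Ids X1..X23 denote quantum-chemically derived properties, X24..X33
cheminformatic ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

__all__ = [
    "DescriptorMeta",
    "DescriptorTable",
    "ActivityTable",
    "DataSet",
    "ScalingRecord",
    "DescriptorScaler",
    "default_descriptor_meta",
    "read_descriptor_table",
    "read_activity_table",
    "write_descriptor_table",
    "write_activity_table",
    "join_dataset",
    "autoscale",
]

#: Human-readable names for the descriptor ids whose identity is fixed by the
#: published regression equations; every other id gets a placeholder name.
KNOWN_DESCRIPTORS: dict[str, tuple[str, str]] = {
    "X16": ("bond N1-C13", "angstrom"),
    "X17": ("bond C2-R(b)", "angstrom"),
    "X19": ("bond C4-C11", "angstrom"),
    "X20": ("polarizability", "a.u."),
    "X21": ("HOMO energy", "a.u."),
    "X26": ("AlogP", "unitless"),
    "X30": ("Connolly surface area", "angstrom^2"),
}

ACTIVITY_IDS = ("Y1", "Y2", "Y3")


@dataclass(frozen=True)
class DescriptorMeta:
    """Identity of one descriptor column.

    Parameters
    ----------
    id : str
        Registry label, ``X1``..``X33``.
    name : str
        Human label, e.g. ``"bond N1-C13"``.
    units : str
        Free-text units (angstrom, a.u., unitless, ...).
    provenance : str
        ``"quantum"`` for X1..X23 (ab initio properties) or
        ``"cheminformatic"`` for X24..X33.
    """

    id: str
    name: str
    units: str = "unitless"
    provenance: str = "quantum"

    def __post_init__(self) -> None:
        if self.provenance not in ("quantum", "cheminformatic"):
            raise ValidationError(
                f"descriptor {self.id}: provenance must be 'quantum' or "
                f"'cheminformatic', got {self.provenance!r}"
            )


def default_descriptor_meta(descriptor_id: str) -> DescriptorMeta:
    """Build metadata for ``descriptor_id``, using the known names for the
    seven descriptors fixed by the published equations and placeholders
    elsewhere. Ids of the form ``X<k>`` with k <= 23 are tagged quantum,
    higher ones cheminformatic."""
    name, units = KNOWN_DESCRIPTORS.get(
        descriptor_id, (f"descriptor {descriptor_id}", "unitless")
    )
    provenance = "quantum"
    if descriptor_id.startswith("X"):
        try:
            if int(descriptor_id[1:]) >= 24:
                provenance = "cheminformatic"
        except ValueError:
            pass
    return DescriptorMeta(id=descriptor_id, name=name, units=units, provenance=provenance)


def _check_unique(labels, kind: str) -> None:
    seen: dict[str, int] = {}
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValidationError(f"duplicate {kind}: {', '.join(dupes)}")


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix with per-column metadata.

    Invariants (checked at construction): all entries finite, at least two
    compounds, unique compound ids, one :class:`DescriptorMeta` per column.
    """

    compound_ids: list[str]
    values: np.ndarray
    meta: list[DescriptorMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("descriptor values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2:
            raise DegenerateInputError(f"need at least 2 compounds, got {n}")
        if len(self.compound_ids) != n:
            raise ValidationError(
                f"{len(self.compound_ids)} compound ids for {n} rows"
            )
        _check_unique(self.compound_ids, "compound id")
        if not self.meta:
            self.meta = [default_descriptor_meta(f"X{j + 1}") for j in range(m)]
        if len(self.meta) != m:
            raise ValidationError(f"{len(self.meta)} meta entries for {m} columns")
        _check_unique([mt.id for mt in self.meta], "descriptor id")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at compound {self.compound_ids[i]!r}, "
                f"descriptor {self.meta[j].id!r}"
            )

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def descriptor_ids(self) -> list[str]:
        return [mt.id for mt in self.meta]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.compound_ids, name="compound"),
            columns=self.descriptor_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   meta: list[DescriptorMeta] | None = None) -> "DescriptorTable":
        if meta is None:
            meta = [default_descriptor_meta(str(c)) for c in frame.columns]
        return cls(compound_ids=[str(i) for i in frame.index],
                   values=frame.to_numpy(dtype=float), meta=meta)

    def columns(self, descriptor_ids: list[str]) -> np.ndarray:
        """Return the sub-matrix for ``descriptor_ids`` in the given order."""
        index = {mt.id: j for j, mt in enumerate(self.meta)}
        missing = [d for d in descriptor_ids if d not in index]
        if missing:
            raise AlignmentError(
                f"descriptor column(s) not in table: {', '.join(missing)}"
            )
        return self.values[:, [index[d] for d in descriptor_ids]]

    def reorder(self, compound_ids: list[str]) -> "DescriptorTable":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        rows = [pos[c] for c in compound_ids]
        return DescriptorTable(list(compound_ids), self.values[rows], list(self.meta))


@dataclass
class ActivityTable:
    """Per-compound scavenging activities on the percent/10 scale.

    ``y1`` = hydroxyl radical, ``y2`` = superoxide anion, ``y3`` = DPPH.
    All values must be finite and within [0, 10].
    """

    compound_ids: list[str]
    y1: np.ndarray
    y2: np.ndarray
    y3: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.compound_ids, "compound id")
        n = len(self.compound_ids)
        for name in ("y1", "y2", "y3"):
            col = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, col)
            if col.shape != (n,):
                raise ValidationError(f"{name} has shape {col.shape}, expected ({n},)")
            if not np.isfinite(col).all():
                raise ValidationError(f"non-finite value in {name}")
            if (col < 0).any() or (col > 10).any():
                raise ValidationError(
                    f"{name} outside the percent/10 scale [0, 10]; pass "
                    "percent=True to the reader if values are raw percentages"
                )

    def response(self, response_id: str) -> np.ndarray:
        if response_id not in ACTIVITY_IDS:
            raise ValidationError(f"unknown response {response_id!r}; expected Y1/Y2/Y3")
        return getattr(self, response_id.lower())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Y1": self.y1, "Y2": self.y2, "Y3": self.y3},
            index=pd.Index(self.compound_ids, name="compound"),
        )

    def reorder(self, compound_ids: list[str]) -> "ActivityTable":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        rows = [pos[c] for c in compound_ids]
        return ActivityTable(list(compound_ids), self.y1[rows], self.y2[rows],
                             self.y3[rows])


@dataclass
class DataSet:
    """An aligned descriptor/activity pair; alignment verified at construction."""

    descriptors: DescriptorTable
    activities: ActivityTable

    def __post_init__(self) -> None:
        if self.descriptors.compound_ids != self.activities.compound_ids:
            raise AlignmentError(
                "descriptor and activity tables are not in the same compound "
                "order; use join_dataset() to align them"
            )

    @property
    def compound_ids(self) -> list[str]:
        return self.descriptors.compound_ids

    @property
    def n_compounds(self) -> int:
        return self.descriptors.n_compounds

    def subset(self, compound_ids: list[str]) -> "DataSet":
        return DataSet(self.descriptors.reorder(compound_ids),
                       self.activities.reorder(compound_ids))


# ---------------------------------------------------------------------------
# delimited-text I/O

def _read_frame(path, sep: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if frame.columns.size == 0:
        raise FormatError(f"{path}: no data columns; expected a header row")
    if any(str(c).startswith("Unnamed") for c in frame.columns):
        raise FormatError(f"{path}: missing or incomplete header row")
    return frame


def _to_numeric(frame: pd.DataFrame, path) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {frame.iat[i, j]!r} at row "
            f"{frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    if out.isna().to_numpy().any():
        i, j = np.argwhere(out.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    return out


def read_descriptor_table(path, sep: str = ",",
                          meta: list[DescriptorMeta] | None = None
                          ) -> DescriptorTable:
    """Read a descriptor CSV/TSV: header of descriptor ids, first column of
    compound ids, numeric body. Column order is preserved."""
    frame = _to_numeric(_read_frame(path, sep), path)
    return DescriptorTable.from_frame(frame, meta=meta)


def read_activity_table(path, sep: str = ",", percent: bool = False
                        ) -> ActivityTable:
    """Read an activity CSV/TSV with columns Y1, Y2, Y3.

    With ``percent=True`` the file holds raw percentages and is divided by 10
    on read (the internal scale is always percent/10)."""
    frame = _to_numeric(_read_frame(path, sep), path)
    missing = [c for c in ACTIVITY_IDS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing activity column(s) {', '.join(missing)}")
    scale = 0.1 if percent else 1.0
    return ActivityTable(
        compound_ids=[str(i) for i in frame.index],
        y1=frame["Y1"].to_numpy() * scale,
        y2=frame["Y2"].to_numpy() * scale,
        y3=frame["Y3"].to_numpy() * scale,
    )


def write_descriptor_table(table: DescriptorTable, path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def write_activity_table(table: ActivityTable, path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_descriptor_meta(path, sep: str = ",") -> list[DescriptorMeta]:
    """Read an optional metadata CSV with columns id,name,units,provenance."""
    frame = pd.read_csv(path, sep=sep, dtype=str)
    required = {"id", "name", "units", "provenance"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: metadata file needs columns {sorted(required)}")
    return [DescriptorMeta(r.id, r.name, r.units, r.provenance)
            for r in frame.itertuples()]


def join_dataset(descriptors: DescriptorTable, activities: ActivityTable) -> DataSet:
    """Align two tables on their (identical) compound-id sets.

    Rows are reordered to the descriptor table's order, which becomes the
    canonical order of the returned :class:`DataSet`."""
    d_ids, a_ids = set(descriptors.compound_ids), set(activities.compound_ids)
    if d_ids != a_ids:
        only_d = sorted(d_ids - a_ids)
        only_a = sorted(a_ids - d_ids)
        parts = []
        if only_d:
            parts.append(f"only in descriptors: {', '.join(only_d)}")
        if only_a:
            parts.append(f"only in activities: {', '.join(only_a)}")
        raise AlignmentError("compound-id mismatch (" + "; ".join(parts) + ")")
    return DataSet(descriptors, activities.reorder(descriptors.compound_ids))


# ---------------------------------------------------------------------------
# autoscaling

@dataclass(frozen=True)
class ScalingRecord:
    """Per-column mean/sd used by :func:`autoscale`; supports exact inversion."""

    descriptor_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str]

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.sds + self.means


class DescriptorScaler:
    """Column-wise standardization (mean 0, sd 1) that drops constant columns.

    scikit-learn transformer API: :meth:`fit`, :meth:`transform`,
    :meth:`inverse_transform`; fitted state in ``mean_``, ``scale_``,
    ``kept_ids_``, ``dropped_ids_``. Sample (ddof=1) standard deviation, the
    chemometric autoscaling convention ([1, 2, 3] -> [-1, 0, 1]).
    """

    def __init__(self, constant_tol: float = 0.0):
        self.constant_tol = constant_tol

    def get_params(self, deep: bool = True) -> dict:
        return {"constant_tol": self.constant_tol}

    def set_params(self, **params) -> "DescriptorScaler":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: DescriptorTable) -> "DescriptorScaler":
        values = table.values
        means = values.mean(axis=0)
        sds = values.std(axis=0, ddof=1)
        keep = sds > self.constant_tol
        if not keep.any():
            raise DegenerateInputError("all descriptor columns are constant")
        dropped = [table.meta[j].id for j in np.flatnonzero(~keep)]
        if dropped:
            warnings.warn(
                f"dropping constant descriptor column(s): {', '.join(dropped)}",
                UserWarning, stacklevel=2,
            )
        self.mean_ = means[keep]
        self.scale_ = sds[keep]
        self.kept_ids_ = [table.meta[j].id for j in np.flatnonzero(keep)]
        self.dropped_ids_ = dropped
        self._kept_meta = [table.meta[j] for j in np.flatnonzero(keep)]
        return self

    def transform(self, table: DescriptorTable) -> DescriptorTable:
        values = table.columns(self.kept_ids_)
        scaled = (values - self.mean_) / self.scale_
        return DescriptorTable(list(table.compound_ids), scaled,
                               list(self._kept_meta))

    def fit_transform(self, table: DescriptorTable) -> DescriptorTable:
        return self.fit(table).transform(table)

    def inverse_transform(self, table: DescriptorTable) -> DescriptorTable:
        values = table.columns(self.kept_ids_) * self.scale_ + self.mean_
        return DescriptorTable(list(table.compound_ids), values,
                               list(self._kept_meta))

    @property
    def record_(self) -> ScalingRecord:
        return ScalingRecord(list(self.kept_ids_), self.mean_.copy(),
                             self.scale_.copy(), list(self.dropped_ids_))


def autoscale(table: DescriptorTable) -> tuple[DescriptorTable, ScalingRecord]:
    """Standardize each column to mean 0, sd 1; constant columns are dropped
    with a warning. Returns the scaled table and the scaling record."""
    scaler = DescriptorScaler()
    scaled = scaler.fit_transform(table)
    return scaled, scaler.record_
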