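"""Domain types for the four-gene genotoxicity scoring pipeline.

The pipeline moves through three tabular containers:

* :class:`ExpressionTable` — long-format per-animal intensities keyed by
  chemical, dose level, time point and replicate;
* :class:`RatioMatrix` — one row per dose point (chemical x dose x time),
  one column per panel gene, holding mean log2(exp/cont) ratios;
* score frames produced by the PCA stage (plain :class:`pandas.DataFrame`
  with ``pc1``/``pc2`` columns).

Thin dataclasses wrap :class:`pandas.DataFrame` so invariants (uniqueness,
finiteness, panel order) are checked at construction while all numerics stay
vectorized.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, IntegrityError


class Scale(str, enum.Enum):
    """Scale of stored intensities."""

    LINEAR = "linear"
    LOG2 = "log2"


class DoseLevel(str, enum.Enum):
    CONTROL = "control"
    LOW = "low"
    MIDDLE = "middle"
    HIGH = "high"

    @property
    def rank(self) -> int:
        """Ordinal dose rank: control 0, then 1/2/3 for low/middle/high."""
        return _DOSE_RANK[self]

    @property
    def letter(self) -> str:
        return _DOSE_LETTER[self]


_DOSE_RANK = {
    DoseLevel.CONTROL: 0,
    DoseLevel.LOW: 1,
    DoseLevel.MIDDLE: 2,
    DoseLevel.HIGH: 3,
}
_DOSE_LETTER = {
    DoseLevel.CONTROL: "C",
    DoseLevel.LOW: "L",
    DoseLevel.MIDDLE: "M",
    DoseLevel.HIGH: "H",
}
_LETTER_DOSE = {v: k for k, v in _DOSE_LETTER.items()}


class TimePoint(str, enum.Enum):
    """Sampling time: 24 h after a single dose, or day 29 of repeated dosing."""

    SINGLE_24H = "24h"
    REPEAT_29D = "29d"


class ChemClass(str, enum.Enum):
    """Reference classification of a chemical's hepatocarcinogenic mode."""

    GTHC = "GTHC"
    NGTHC = "NGTHC"
    NGTNHC = "NGTNHC"
    INTERMEDIATE = "INTERMEDIATE"


#: Classes counted as "non-genotoxic" when deriving the PC1 cutoff.
NON_GENOTOXIC_CLASSES = (ChemClass.NGTHC, ChemClass.NGTNHC)


class Zone(str, enum.Enum):
    """Three-zone assignment of a dose point along PC1."""

    GTHC_ZONE = "GTHC_ZONE"
    INTERMEDIATE_ZONE = "INTERMEDIATE_ZONE"
    NON_GENOTOXIC_ZONE = "NON_GENOTOXIC_ZONE"


def normalize_dose(label: object) -> DoseLevel:
    """Map a dose label to a :class:`DoseLevel`.

    Accepts the word form (``control``/``low``/``middle``/``high``, any
    case), single letters (``C``/``L``/``M``/``H``) and a few common
    synonyms.
    """
    if isinstance(label, DoseLevel):
        return label
    s = str(label).strip()
    up = s.upper()
    if up in _LETTER_DOSE:
        return _LETTER_DOSE[up]
    low = s.lower()
    aliases = {
        "control": DoseLevel.CONTROL,
        "vehicle": DoseLevel.CONTROL,
        "cont": DoseLevel.CONTROL,
        "low": DoseLevel.LOW,
        "middle": DoseLevel.MIDDLE,
        "mid": DoseLevel.MIDDLE,
        "medium": DoseLevel.MIDDLE,
        "high": DoseLevel.HIGH,
    }
    if low in aliases:
        return aliases[low]
    raise FormatError(f"unknown dose label: {label!r}")


def normalize_time(label: object) -> TimePoint:
    if isinstance(label, TimePoint):
        return label
    s = str(label).strip().lower()
    aliases = {
        "24h": TimePoint.SINGLE_24H,
        "24 h": TimePoint.SINGLE_24H,
        "single_24h": TimePoint.SINGLE_24H,
        "29d": TimePoint.REPEAT_29D,
        "29 d": TimePoint.REPEAT_29D,
        "29days": TimePoint.REPEAT_29D,
        "repeat_29d": TimePoint.REPEAT_29D,
    }
    if s in aliases:
        return aliases[s]
    raise FormatError(f"unknown time point label: {label!r}")


@dataclass(frozen=True)
class GenePanel:
    """An ordered marker-gene panel.

    Order is significant: projection coefficients are stored in panel order.
    """

    name: str
    genes: tuple[str, ...]
    gene_ids: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError(f"panel {self.name}: duplicate gene symbols")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def canonical_symbol(self, symbol: str) -> str:
        """Resolve *symbol* case-insensitively to the stored capitalization."""
        lookup = {g.lower(): g for g in self.genes}
        key = str(symbol).strip().lower()
        if key not in lookup:
            raise FormatError(f"gene {symbol!r} is not in panel {self.name}")
        return lookup[key]


@dataclass(frozen=True)
class ChemicalAnnotation:
    """Reference annotation of one chemical."""

    name: str
    abbreviation: str
    class_label: ChemClass
    cas: str | None = None
    evidence: Mapping[str, str] | None = None


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one animal's sample within a study."""

    chemical: str
    dose_level: DoseLevel
    time_point: TimePoint
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise DomainError(f"replicate must be positive, got {self.replicate}")


def dose_point_id(chemical: str, dose: DoseLevel, time: TimePoint) -> str:
    """Compact dose-point label, e.g. ``DEN24hL`` or ``AAF29dM``."""
    return f"{chemical}{time.value}{dose.letter}"


_DOSE_POINT_RE = re.compile(r"^(?P<chem>.+?)(?P<time>24h|29d)(?P<dose>[CLMH])$")
_DASH_POINT_RE = re.compile(
    r"^(?P<chem>.+?)[-_](?P<dose>control|low|middle|high)$", re.IGNORECASE
)


def parse_dose_point(label: str, default_time: TimePoint | None = None):
    """Parse a dose-point label into ``(chemical, DoseLevel, TimePoint)``.

    Two layouts are accepted: the compact suffix style used in the
    supplementary tables (``DEN24hL``) and a dash style (``DEN-low``, which
    needs *default_time*).
    """
    s = str(label).strip()
    m = _DOSE_POINT_RE.match(s)
    if m:
        return (
            m.group("chem"),
            _LETTER_DOSE[m.group("dose")],
            normalize_time(m.group("time")),
        )
    m = _DASH_POINT_RE.match(s)
    if m:
        if default_time is None:
            raise FormatError(
                f"dose-point label {label!r} has no time suffix and no "
                "default time point was given"
            )
        return m.group("chem"), normalize_dose(m.group("dose")), default_time
    raise FormatError(f"cannot parse dose-point label: {label!r}")


#: Canonical column names of the long-format expression layout.
EXPRESSION_COLUMNS = ("chemical", "dose", "time", "replicate", "gene", "value")


@dataclass
class ExpressionTable:
    """Long-format per-animal intensities.

    ``data`` columns: chemical (str), dose (:class:`DoseLevel`), time
    (:class:`TimePoint`), replicate (int), gene (str), value (float).
    """

    data: pd.DataFrame
    scale: Scale = Scale.LOG2

    def __post_init__(self) -> None:
        missing = [c for c in EXPRESSION_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"expression table missing column(s): {missing}")
        df = self.data.loc[:, list(EXPRESSION_COLUMNS)].copy()
        df["dose"] = df["dose"].map(normalize_dose)
        df["time"] = df["time"].map(normalize_time)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        key_cols = ["chemical", "dose", "time", "replicate", "gene"]
        dup = df.duplicated(subset=key_cols)
        if dup.any():
            first = df.loc[dup, key_cols].iloc[0].tolist()
            raise IntegrityError(f"duplicate (sample, gene) record: {first}")
        if self.scale is Scale.LINEAR and (df["value"] <= 0).any():
            bad = df.loc[df["value"] <= 0].iloc[0]
            raise DomainError(
                "linear-scale intensities must be strictly positive; offending "
                f"record: {bad[key_cols].tolist()} value={bad['value']}"
            )
        if not np.isfinite(df["value"]).all():
            raise DomainError("expression values must be finite")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["gene"]))

    def require_panel(self, panel: GenePanel) -> None:
        """Check every sample carries every panel gene exactly once."""
        df = self.data
        canon = {g.lower(): g for g in panel.genes}
        present = df["gene"].str.lower().isin(canon)
        sub = df.loc[present]
        counts = sub.groupby(
            ["chemical", "dose", "time", "replicate"], observed=True
        )["gene"].nunique()
        if (counts != len(panel)).any():
            bad = counts[counts != len(panel)].index[0]
            raise IntegrityError(
                f"sample {tuple(bad)} does not carry all {len(panel)} panel genes"
            )

    def equals(self, other: "ExpressionTable") -> bool:
        a = self.data.sort_values(list(EXPRESSION_COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(EXPRESSION_COLUMNS)).reset_index(drop=True)
        return self.scale is other.scale and a.equals(b)


@dataclass
class RatioMatrix:
    """Dose-point x gene matrix of mean log2(exp/cont) ratios.

    Rows are labeled by compact dose-point ids; columns follow panel order.
    """

    data: pd.DataFrame
    n_replicates: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate dose-point row labels: {dupes}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise DomainError("ratio matrix contains non-finite values")
        self.data = self.data.astype(float)
        self.data.index.name = "dose_point"
        if self.n_replicates is not None:
            self.n_replicates = self.n_replicates.reindex(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def rows(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def reorder_to_panel(self, panel: GenePanel) -> "RatioMatrix":
        """Return a copy with columns in panel order (case-insensitive match)."""
        mapping = {}
        lower = {c.lower(): c for c in self.data.columns}
        for g in panel.genes:
            if g.lower() not in lower:
                raise FormatError(f"panel gene {g} missing from ratio matrix")
            mapping[lower[g.lower()]] = g
        df = self.data.rename(columns=mapping).loc[:, list(panel.genes)]
        return RatioMatrix(df, self.n_replicates)


@dataclass(frozen=True)
class ScoreResult:
    """PC1/PC2 score of one dose point, optionally with a zone label."""

    row: str
    pc1: float
    pc2: float
    zone: Zone | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pc1) and np.isfinite(self.pc2)):
            raise DomainError(f"non-finite score for {self.row}")


@dataclass(frozen=True)
class ZoneBoundaries:
    """PC1 thresholds separating the three zones.

    ``gthc_max_pc1`` is the most positive PC1 among labeled typical GTHC
    points, ``nongtx_min_pc1`` the most negative among labeled NGTHC+NGTNHC
    points; ``cutoff`` is their midpoint.
    """

    gthc_max_pc1: float
    nongtx_min_pc1: float
    gthc_argmax: str | None = None
    nongtx_argmin: str | None = None

    @property
    def cutoff(self) -> float:
        return (self.gthc_max_pc1 + self.nongtx_min_pc1) / 2.0

    @property
    def separated(self) -> bool:
        return self.gthc_max_pc1 < self.nongtx_min_pc1


def scores_to_frame(scores: Sequence[ScoreResult]) -> pd.DataFrame:
    """Stack :class:`ScoreResult` records into a DataFrame indexed by row id."""
    return pd.DataFrame(
        {
            "pc1": [s.pc1 for s in scores],
            "pc2": [s.pc2 for s in scores],
            "zone": [s.zone.value if s.zone else "" for s in scores],
        },
        index=pd.Index([s.row for s in scores], name="dose_point"),
    )
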