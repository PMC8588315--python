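"""Shared data model for the dose x time x biostimulant factorial experiment.

The study design crossed five contaminant doses (mg of *o*-cresol per kg dry
matter of soil), three sampling days and the presence/absence of a mussel-shell
biostimulant (*Perna canaliculus*), with replicate pots per cell.  Every table
in the pipeline is keyed by a :class:`TreatmentKey` holding that triple.

Containers here are deliberately thin: validated dataclasses around plain
Python / numpy structures, convertible to pandas frames in :mod:`soiltox.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Taxonomic ranks carried by an OTU lineage, coarse to fine.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")

#: Label used when a lineage has no name at the aggregation rank.
UNCLASSIFIED = "Unclassified"

#: Number of daily colony-count observations per plate.
N_OBSERVATION_DAYS = 10

DEFAULT_DOSES: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 50.0)
DEFAULT_DAYS: tuple[int, ...] = (15, 30, 45)


@dataclass(frozen=True, order=True)
class TreatmentKey:
    """One cell of the factorial design.

    Parameters
    ----------
    dose:
        Contaminant dose in mg kg^-1 DM of soil; must be >= 0.
    time_day:
        Sampling day (soil age at measurement); must be > 0.
    biostimulant:
        Whether *Perna canaliculus* shell meal was added.
    """

    dose: float
    time_day: int
    biostimulant: bool

    def __post_init__(self) -> None:
        if not (self.dose >= 0):
            raise ValidationError(f"dose must be >= 0, got {self.dose!r}")
        if not (self.time_day > 0):
            raise ValidationError(f"time_day must be > 0, got {self.time_day!r}")

    def __str__(self) -> str:  # used in report column labels
        pc = "+Pc" if self.biostimulant else "-Pc"
        return f"{self.dose:g}mg:d{self.time_day}:{pc}"


@dataclass(frozen=True)
class ColonyEmergenceSeries:
    """Daily counts of newly appearing colonies on one plate over 10 days.

    ``counts[i]`` is the number of colonies that first became visible on
    observation day ``i + 1`` (the daily increments N1..N10, not cumulative
    counts).  ``total`` is the cumulative colony count after day 10.
    """

    group_name: str
    treatment: TreatmentKey
    replicate: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != N_OBSERVATION_DAYS:
            raise ValidationError(
                f"colony series needs exactly {N_OBSERVATION_DAYS} daily counts, "
                f"got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise ValidationError(f"negative colony count in {counts}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate}")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def proportions(self) -> np.ndarray:
        """Fraction of all colonies first appearing on each day; requires total > 0."""
        total = self.total
        if total == 0:
            raise ValidationError("proportions undefined for an empty colony series")
        return np.asarray(self.counts, dtype=float) / total


@dataclass
class ActivityTable:
    """Replicate measurements of one named response per treatment cell.

    The response is either a soil-enzyme activity or a microbial-group count;
    the container does not care which.
    """

    response_name: str
    unit: str
    records: dict[TreatmentKey, list[float]] = field(default_factory=dict)

    def add(self, key: TreatmentKey, value: float) -> None:
        value = float(value)
        if not math.isfinite(value):
            raise ValidationError(f"non-finite value {value!r} for {key}")
        if value < 0:
            raise ValidationError(f"negative value {value!r} for {key}")
        self.records.setdefault(key, []).append(value)

    def mean(self, key: TreatmentKey) -> float:
        return float(np.mean(self.records[key]))

    def aggregate(self, key: TreatmentKey, how: str = "mean") -> float:
        values = self.records[key]
        if how == "mean":
            return float(np.mean(values))
        if how == "median":
            return float(np.median(values))
        raise ValidationError(f"unknown aggregator {how!r}")

    def keys(self):
        return self.records.keys()

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.records.values())

    def validate(self, min_replicates: int = 1) -> None:
        for key, values in self.records.items():
            if len(values) < min_replicates:
                raise ValidationError(
                    f"{self.response_name}: {key} has {len(values)} replicate(s), "
                    f"needs >= {min_replicates}"
                )
            for v in values:
                if not math.isfinite(v) or v < 0:
                    raise ValidationError(f"{self.response_name}: bad value {v!r} at {key}")


@dataclass
class OtuTable:
    """OTU x sample count matrix with a 5-rank lineage per OTU.

    Lineage slots are ordered phylum -> genus; an empty string marks a rank at
    which the OTU is unclassified.
    """

    otu_ids: list[str]
    lineages: list[tuple[str, ...]]
    samples: list[str]
    counts: np.ndarray
    sample_treatments: dict[str, TreatmentKey] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dupes = sorted({x for x in self.otu_ids if self.otu_ids.count(x) > 1})
            raise ValidationError(f"duplicate OTU id(s): {dupes}")
        if self.counts.shape != (len(self.otu_ids), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("fractional OTU counts are not allowed")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("negative OTU counts are not allowed")
        fixed = []
        for otu, lin in zip(self.otu_ids, self.lineages):
            lin = tuple(lin)
            if len(lin) > len(RANKS):
                raise ValidationError(f"{otu}: lineage has {len(lin)} slots, max {len(RANKS)}")
            fixed.append(lin + ("",) * (len(RANKS) - len(lin)))
        self.lineages = fixed

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def rank_labels(self, rank: str) -> list[str]:
        """Per-OTU label at ``rank``; empty slots map to :data:`UNCLASSIFIED`."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        i = RANKS.index(rank)
        return [lin[i] if lin[i] else UNCLASSIFIED for lin in self.lineages]


@dataclass
class ResidueSeries:
    """Contaminant residue (mg kg^-1 DM) over time for one initial dose."""

    dose: float
    observations: dict[int, float]

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValidationError(f"dose must be >= 0, got {self.dose}")
        for day, residue in self.observations.items():
            if day <= 0:
                raise ValidationError(f"negative or zero observation day {day}")
            if residue < 0:
                raise ValidationError(f"negative residue {residue} at day {day}")
            if residue > self.dose + 1e-9:
                raise ValidationError(
                    f"residue {residue} at day {day} exceeds initial dose {self.dose}"
                )


def design_cells(
    doses: Sequence[float] = DEFAULT_DOSES,
    days: Sequence[int] = DEFAULT_DAYS,
    biostimulant_levels: Sequence[bool] = (False, True),
) -> list[TreatmentKey]:
    """Enumerate the full factorial design in a fixed, reproducible order."""
    return [
        TreatmentKey(dose=float(d), time_day=int(t), biostimulant=bool(b))
        for b in biostimulant_levels
        for t in days
        for d in doses
    ]


def activity_table_from_series(
    series: Sequence[ColonyEmergenceSeries], response_name: str | None = None
) -> ActivityTable:
    """Collapse colony series to an ActivityTable of cumulative counts (N10)."""
    names = {s.group_name for s in series}
    if response_name is None:
        if len(names) != 1:
            raise ValidationError(f"series span several groups {sorted(names)}; pass response_name")
        response_name = next(iter(names))
    table = ActivityTable(response_name=response_name, unit="cfu")
    for s in series:
        if s.group_name == response_name:
            table.add(s.treatment, float(s.total))
    return table
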