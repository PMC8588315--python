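"""Culture-based community indices and the biostimulation impact factor.

Three quantities drive the analysis:

* **CD, colony development index** — for a 10-day plate observation with
  daily increments N1..N10 and proportions p_i = N_i / N_total,

      CD = 100 * sum_i p_i / i.

  CD lies in [10, 100]; it rewards early colony appearance, so a high CD
  marks fast-growing (r-strategist) communities and a low CD slow-growing
  (K-strategist) ones.

* **EP, ecophysiological diversity index** — the Shannon-type entropy of the
  appearance-day distribution, EP = -sum_i p_i * log(p_i).  With base-10
  logarithms and 10 observation days EP lies in [0, 1]; 1 means colonies
  appeared evenly over the whole window.

* **IF_Pc, biostimulation impact factor** — the ratio A_Pc / A_C of a
  response (enzyme activity or microbial count) with the mussel-shell
  biostimulant to a baseline without its effect.  Values > 1 encode
  stimulation, < 1 inhibition, and exactly 1 no effect.

Both indices are undefined when a plate grew no colonies at all; such series
raise :class:`~soiltox.errors.UndefinedIndexError` rather than returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError, ValidationError
from .model import ActivityTable, ColonyEmergenceSeries, TreatmentKey

BaselineMode = Literal["paired", "control-soil"]

#: Default CD cut-off separating r- from K-strategists.  No canonical value
#: exists; 35 sits between the back-loaded (~10-30) and front-loaded (~45-100)
#: regimes so the conventional qualitative split (fast organotrophs vs slow
#: actinobacteria) is reproduced on the bundled presets.
DEFAULT_RK_THRESHOLD = 35.0

_DAY_WEIGHTS = 1.0 / np.arange(1, 11)


def compute_cd(series: ColonyEmergenceSeries) -> float:
    """Colony development index of one plate series.

    Raises :class:`UndefinedIndexError` when the series has no colonies.
    """
    if series.total == 0:
        raise UndefinedIndexError(
            f"CD undefined: no colonies in {series.group_name} {series.treatment}"
        )
    return float(100.0 * np.dot(series.proportions, _DAY_WEIGHTS))


def compute_ep(series: ColonyEmergenceSeries, log_base: float = 10.0) -> float:
    """Ecophysiological diversity index (entropy of appearance days).

    Terms with p_i = 0 contribute 0 (the usual 0*log 0 := 0 convention).
    With ``log_base`` 10 and 10 observation days the result lies in [0, 1].
    """
    if log_base <= 0 or log_base == 1:
        raise ValidationError(f"log_base must be positive and != 1, got {log_base}")
    if series.total == 0:
        raise UndefinedIndexError(
            f"EP undefined: no colonies in {series.group_name} {series.treatment}"
        )
    p = series.proportions
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)) / np.log(log_base))


def classify_strategy(cd: float, threshold: float = DEFAULT_RK_THRESHOLD) -> str:
    """Classify a community as ``"r-strategist"`` (cd >= threshold, boundary
    inclusive) or ``"K-strategist"``."""
    if not np.isfinite(cd):
        raise ValidationError(f"cd must be finite, got {cd}")
    return "r-strategist" if cd >= threshold else "K-strategist"


def percent_change(treated: Sequence[float], control: Sequence[float]) -> float:
    """Signed percent change of the treated mean relative to the control mean.

    ``100 * (mean(treated) - mean(control)) / mean(control)``; a value of
    -76.0 means a 76% reduction.  Raises :class:`UndefinedIndexError` when the
    control mean is zero.
    """
    control_mean = float(np.mean(np.asarray(control, dtype=float)))
    if control_mean == 0:
        raise UndefinedIndexError("percent change undefined: control mean is zero")
    treated_mean = float(np.mean(np.asarray(treated, dtype=float)))
    return 100.0 * (treated_mean - control_mean) / control_mean


def pool_series(series: Iterable[ColonyEmergenceSeries]) -> ColonyEmergenceSeries:
    """Sum replicate series elementwise into one pooled series."""
    series = list(series)
    if not series:
        raise ValidationError("cannot pool an empty series collection")
    first = series[0]
    for s in series[1:]:
        if s.group_name != first.group_name or s.treatment != first.treatment:
            raise ValidationError("pooled series must share group and treatment")
    counts = tuple(int(x) for x in np.sum([s.counts for s in series], axis=0))
    return ColonyEmergenceSeries(
        group_name=first.group_name, treatment=first.treatment, replicate=1, counts=counts
    )


def index_table(
    series: Iterable[ColonyEmergenceSeries],
    log_base: float = 10.0,
    per_replicate: bool = True,
) -> pd.DataFrame:
    """CD/EP summary per group x treatment cell.

    With ``per_replicate`` (default) CD and EP are computed on each replicate
    plate then averaged over replicates; otherwise replicate counts are pooled
    first and the indices computed once on the pooled series.  Cells whose
    total colony count is zero get NaN indices and ``defined = False``.

    Returns a frame with columns
    ``group,dose,day,biostimulant,cd,ep,n_total,defined``.
    """
    cells: dict[tuple[str, TreatmentKey], list[ColonyEmergenceSeries]] = {}
    for s in series:
        cells.setdefault((s.group_name, s.treatment), []).append(s)
    rows = []
    for (group, key), reps in sorted(cells.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        targets = reps if per_replicate else [pool_series(reps)]
        cds, eps = [], []
        for t in targets:
            if t.total > 0:
                cds.append(compute_cd(t))
                eps.append(compute_ep(t, log_base=log_base))
        defined = bool(cds)
        rows.append(
            {
                "group": group,
                "dose": key.dose,
                "day": key.time_day,
                "biostimulant": key.biostimulant,
                "cd": float(np.mean(cds)) if defined else np.nan,
                "ep": float(np.mean(eps)) if defined else np.nan,
                "n_total": int(sum(t.total for t in reps)),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IfMatrix:
    """IF_Pc ratios: responses as rows, (dose, day) treatment cells as columns.

    ``values`` is a DataFrame whose columns are a MultiIndex (dose, day).
    Missing or zero-denominator cells are NaN (flagged missing, never inf).
    """

    values: pd.DataFrame
    baseline_mode: BaselineMode
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        finite = self.values.to_numpy(dtype=float)
        bad = np.isfinite(finite) & (finite <= 0)
        if bad.any():
            raise ValidationError("IF values must be > 0 where defined")

    @property
    def responses(self) -> list[str]:
        return list(self.values.index)

    def flat(self) -> pd.DataFrame:
        """Long format: response, dose, day, if_pc."""
        out = self.values.stack([0, 1], future_stack=True).rename("if_pc").reset_index()
        out.columns = ["response", "dose", "day", "if_pc"]
        return out


def _cell_mean(table: ActivityTable, key: TreatmentKey, how: str) -> float | None:
    if key not in table.records or not table.records[key]:
        return None
    return table.aggregate(key, how)


def compute_if_matrix(
    with_pc: ActivityTable | Sequence[ActivityTable],
    without_pc: ActivityTable | Sequence[ActivityTable],
    baseline_mode: BaselineMode = "paired",
    aggregator: str = "mean",
) -> IfMatrix:
    """Biostimulation impact factor IF_Pc = A_Pc / A_C per (response, dose, day).

    ``with_pc`` holds observations from biostimulated soil and ``without_pc``
    the matching unamended observations, one :class:`ActivityTable` per
    response (single tables are accepted).  A values are replicate aggregates
    (mean by default).

    ``baseline_mode`` selects the denominator convention:

    * ``"paired"`` (default): A_C is the same (dose, day) cell without the
      biostimulant — IF isolates the biostimulant effect at each dose.
    * ``"control-soil"``: A_C is the uncontaminated (dose 0) biostimulated
      cell at the same day — IF compares each dose against clean amended soil.

    Cells with a zero or missing denominator become NaN, never +/-inf.
    """
    if baseline_mode not in ("paired", "control-soil"):
        raise ValidationError(f"unknown baseline_mode {baseline_mode!r}")
    with_list = [with_pc] if isinstance(with_pc, ActivityTable) else list(with_pc)
    without_list = [without_pc] if isinstance(without_pc, ActivityTable) else list(without_pc)
    without_by_name = {t.response_name: t for t in without_list}
    missing = [t.response_name for t in with_list if t.response_name not in without_by_name]
    if missing:
        raise ValidationError(f"no baseline table for response(s) {missing}")

    cells = sorted(
        {
            (k.dose, k.time_day)
            for t in with_list
            for k in t.records
            if k.biostimulant
        }
    )
    if not cells:
        raise ValidationError("with_pc tables contain no biostimulated cells")
    columns = pd.MultiIndex.from_tuples(cells, names=["dose", "day"])
    data = np.full((len(with_list), len(cells)), np.nan)
    for i, table in enumerate(with_list):
        baseline_table = without_by_name[table.response_name]
        for j, (dose, day) in enumerate(cells):
            a_pc = _cell_mean(table, TreatmentKey(dose, day, True), aggregator)
            if baseline_mode == "paired":
                a_c = _cell_mean(baseline_table, TreatmentKey(dose, day, False), aggregator)
            else:
                a_c = _cell_mean(table, TreatmentKey(0.0, day, True), aggregator)
            # zero numerator would encode IF = 0, outside the > 0 contract;
            # flagged missing along with zero/absent denominators
            if a_pc is None or a_c is None or a_pc == 0 or a_c == 0:
                continue
            data[i, j] = a_pc / a_c
    values = pd.DataFrame(data, index=[t.response_name for t in with_list], columns=columns)
    return IfMatrix(values=values, baseline_mode=baseline_mode, aggregator=aggregator)
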