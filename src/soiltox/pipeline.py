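"""End-to-end orchestration: data -> indices -> statistics -> taxa -> report.

:func:`run_pipeline` executes the full analysis sequence on either a
synthetic scenario or on-disk tables, and serializes a :class:`RunReport`
as CSV tables plus a JSON manifest.  Reports carry no wall-clock timestamps,
so a rerun with the same (inputs, config, seed) regenerates the output
directory byte-identically; provenance is the config hash, the seed and the
package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import SoiltoxError, ValidationError
from .group_stats import PcaReport, pca_if, pearson_dose_correlation, tukey_hsd
from .indices import (
    IfMatrix,
    classify_strategy,
    compute_if_matrix,
    index_table,
    percent_change,
)
from .io import (
    read_activity_table,
    read_colony_series,
    read_otu_table,
    read_residue_table,
    read_sample_map,
    write_activity_table,
    write_colony_series,
    write_otu_table,
    write_residue_table,
    write_sample_map,
)
from .model import (
    ActivityTable,
    ColonyEmergenceSeries,
    OtuTable,
    ResidueSeries,
    TreatmentKey,
    activity_table_from_series,
)
from .synthetic import (
    ScenarioConfig,
    generate_colony_counts,
    generate_enzyme_activities,
    generate_otu_table,
    generate_residue_series,
    sample_name,
    scenario_to_dict,
)
from .taxa import (
    RankProfile,
    aggregate_rank,
    dominant_by_difference,
    filter_min_proportion,
    profile_proportion_tests,
    shared_taxa,
)
from .model import RANKS

logger = logging.getLogger("soiltox")


@dataclass
class Dataset:
    """Everything the analysis consumes, however it was obtained."""

    colony_series: list[ColonyEmergenceSeries]
    enzyme_tables: list[ActivityTable]
    otu_table: OtuTable
    residue_series: list[ResidueSeries]


@dataclass
class RunReport:
    provenance: dict
    index_tables: pd.DataFrame
    strategy_table: pd.DataFrame
    percent_changes: pd.DataFrame
    if_matrices: dict[str, IfMatrix]  # "<set>/<mode>" -> matrix
    groupings: pd.DataFrame
    correlations: pd.DataFrame
    pca: dict[str, PcaReport]
    rank_profiles: dict[str, RankProfile]
    dominant: dict[str, pd.DataFrame]
    shared_genera: set[str]
    proportion_tests: pd.DataFrame
    residue_table: pd.DataFrame
    residue_summary: dict
    stage_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dataset plumbing


def generate_dataset(config: ScenarioConfig) -> Dataset:
    return Dataset(
        colony_series=generate_colony_counts(config),
        enzyme_tables=generate_enzyme_activities(config),
        otu_table=generate_otu_table(config),
        residue_series=generate_residue_series(config),
    )


def write_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_colony_series(dataset.colony_series, out / "colony_counts.csv")
    (out / "enzymes").mkdir(exist_ok=True)
    for table in dataset.enzyme_tables:
        write_activity_table(table, out / "enzymes" / f"{table.response_name}.csv")
    write_otu_table(dataset.otu_table, out / "otu_table.tsv")
    if dataset.otu_table.sample_treatments:
        write_sample_map(dataset.otu_table.sample_treatments, out / "sample_map.csv")
    write_residue_table(dataset.residue_series, out / "residue.csv")


def read_dataset(data_dir: str | Path) -> Dataset:
    data = Path(data_dir)
    otu = read_otu_table(data / "otu_table.tsv")
    sample_map_path = data / "sample_map.csv"
    if sample_map_path.exists():
        otu.sample_treatments = read_sample_map(sample_map_path)
    return Dataset(
        colony_series=read_colony_series(data / "colony_counts.csv"),
        enzyme_tables=[
            read_activity_table(p) for p in sorted((data / "enzymes").glob("*.csv"))
        ],
        otu_table=otu,
        residue_series=read_residue_table(data / "residue.csv"),
    )


def microbial_count_tables(series: Sequence[ColonyEmergenceSeries]) -> list[ActivityTable]:
    """Cumulative plate counts (N10) per group as ActivityTables."""
    groups = sorted({s.group_name for s in series})
    return [activity_table_from_series(series, g) for g in groups]


# ---------------------------------------------------------------------------
# stages


def _split_pc(tables: Sequence[ActivityTable]) -> tuple[list[ActivityTable], list[ActivityTable]]:
    """Split each table into biostimulated and unamended halves."""
    with_pc, without_pc = [], []
    for table in tables:
        a = ActivityTable(table.response_name, table.unit)
        b = ActivityTable(table.response_name, table.unit)
        for key, values in table.records.items():
            target = a if key.biostimulant else b
            for v in values:
                target.add(key, v)
        with_pc.append(a)
        without_pc.append(b)
    return with_pc, without_pc


def summarize_residue_decline(series: Sequence[ResidueSeries]) -> tuple[pd.DataFrame, dict]:
    """Percent decline per dose and day, plus mean +/- sd at the final day.

    Decline is 100 * (dose - residue) / dose; dose-0 series are reported as
    n/a (NaN) and excluded from the final-day average across contaminated
    doses.
    """
    rows = []
    final_day = max(d for s in series for d in s.observations) if series else None
    finals = []
    for s in sorted(series, key=lambda s: s.dose):
        for day in sorted(s.observations):
            residue = s.observations[day]
            decline = 100.0 * (s.dose - residue) / s.dose if s.dose > 0 else np.nan
            rows.append(
                {"dose": s.dose, "day": day, "residue": residue, "decline_pct": decline}
            )
            if s.dose > 0 and day == final_day:
                finals.append(decline)
    summary = {
        "final_day": final_day,
        "mean_final_decline_pct": float(np.mean(finals)) if finals else None,
        "sd_final_decline_pct": float(np.std(finals, ddof=1)) if len(finals) > 1 else 0.0,
        "n_doses": len(finals),
    }
    return pd.DataFrame(rows), summary


def _grouping_rows(
    tables: Sequence[ActivityTable], days: Sequence[int], alpha: float
) -> pd.DataFrame:
    rows = []
    for table in tables:
        for day in days:
            for pc in (False, True):
                grouping = tukey_hsd(
                    table, factor="dose", alpha=alpha, where={"day": day, "biostimulant": pc}
                )
                for label in grouping.labels:
                    rows.append(
                        {
                            "response": table.response_name,
                            "day": day,
                            "biostimulant": pc,
                            "dose": label,
                            "mean": grouping.means[label],
                            "letters": grouping.letters[label],
                        }
                    )
    return pd.DataFrame(rows)


def _correlation_rows(
    tables: Sequence[ActivityTable], doses: Sequence[float], days: Sequence[int], alpha: float
) -> pd.DataFrame:
    rows = []
    for table in tables:
        for day in days:
            xs, ys = [], []
            for dose in doses:
                key = TreatmentKey(dose, day, False)
                if key in table.records:
                    xs.append(dose)
                    ys.append(float(np.mean(table.records[key])))
            r, significant, p = pearson_dose_correlation(xs, ys, alpha=alpha)
            rows.append(
                {
                    "response": table.response_name,
                    "day": day,
                    "n": len(xs),
                    "r": r,
                    "p_value": p,
                    "significant": significant,
                }
            )
    return pd.DataFrame(rows)


def _percent_change_rows(
    tables: Sequence[ActivityTable], doses: Sequence[float], days: Sequence[int]
) -> pd.DataFrame:
    """Percent change of each response at each contaminated dose vs control."""
    rows = []
    for table in tables:
        for day in days:
            control_key = TreatmentKey(0.0, day, False)
            if control_key not in table.records:
                continue
            for dose in doses:
                if dose == 0:
                    continue
                key = TreatmentKey(dose, day, False)
                if key not in table.records:
                    continue
                rows.append(
                    {
                        "response": table.response_name,
                        "day": day,
                        "dose": dose,
                        "percent_change": percent_change(
                            table.records[key], table.records[control_key]
                        ),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(
    config: ScenarioConfig,
    data_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
    alpha_posthoc: float = 0.01,
    alpha_correlation: float = 0.05,
    min_proportion: float = 0.01,
    min_diff: float = 0.01,
    fisher_threshold: float = 20.0,
    rk_threshold: float = 35.0,
) -> RunReport:
    """Run the full analysis and (optionally) serialize the report.

    ``data_dir`` of ``None`` or ``"synthetic"`` generates the dataset from
    ``config``; otherwise tables are read from the directory (the formats
    written by :func:`write_dataset`).
    """
    stage_log: list[dict] = []

    def log_stage(stage: str, n_in: int, n_out: int) -> None:
        stage_log.append({"stage": stage, "records_in": n_in, "records_out": n_out})
        logger.info("stage %-12s in=%d out=%d", stage, n_in, n_out)

    # --- load / generate -------------------------------------------------
    if data_dir is None or str(data_dir) == "synthetic":
        dataset = generate_dataset(config)
    else:
        dataset = read_dataset(data_dir)
    for table in dataset.enzyme_tables:
        table.validate(min_replicates=1)
    n_in = (
        len(dataset.colony_series)
        + sum(t.n_records for t in dataset.enzyme_tables)
        + int(np.prod(dataset.otu_table.shape))
    )
    log_stage("load", n_in, n_in)

    days = sorted({s.treatment.time_day for s in dataset.colony_series})
    doses = sorted({s.treatment.dose for s in dataset.colony_series})

    # --- indices ----------------------------------------------------------
    indices_frame = index_table(dataset.colony_series)
    strategy_rows = [
        {
            "group": row.group,
            "dose": row.dose,
            "day": row.day,
            "biostimulant": row.biostimulant,
            "cd": row.cd,
            "strategy": classify_strategy(row.cd, rk_threshold) if row.defined else "undefined",
        }
        for row in indices_frame.itertuples(index=False)
    ]
    strategy_frame = pd.DataFrame(strategy_rows)
    count_tables = microbial_count_tables(dataset.colony_series)
    changes = pd.concat(
        [
            _percent_change_rows(count_tables, doses, days).assign(kind="count"),
            _percent_change_rows(dataset.enzyme_tables, doses, days).assign(kind="enzyme"),
        ],
        ignore_index=True,
    )
    log_stage("indices", len(dataset.colony_series), len(indices_frame))

    counts_pc, counts_nopc = _split_pc(count_tables)
    enzymes_pc, enzymes_nopc = _split_pc(dataset.enzyme_tables)
    if_matrices: dict[str, IfMatrix] = {}
    for label, with_pc, without_pc in (
        ("counts", counts_pc, counts_nopc),
        ("enzymes", enzymes_pc, enzymes_nopc),
    ):
        for mode in ("paired", "control-soil"):
            if_matrices[f"{label}/{mode}"] = compute_if_matrix(
                with_pc, without_pc, baseline_mode=mode
            )
    log_stage("if_matrices", len(count_tables) + len(dataset.enzyme_tables), len(if_matrices))

    # --- group statistics -------------------------------------------------
    all_tables = count_tables + dataset.enzyme_tables
    groupings = _grouping_rows(all_tables, days, alpha_posthoc)
    correlations = _correlation_rows(all_tables, doses, days, alpha_correlation)
    pca_reports = {name: pca_if(m, standardized=True) for name, m in if_matrices.items()}
    log_stage("group_stats", len(all_tables), len(groupings) + len(correlations))

    # --- taxa ---------------------------------------------------------------
    top_dose = max(doses)
    profiles: dict[str, RankProfile] = {}
    dominant: dict[str, pd.DataFrame] = {}
    test_frames = []
    for rank in RANKS:
        profile = aggregate_rank(dataset.otu_table, rank)
        filtered = filter_min_proportion(profile, threshold=min_proportion)
        profiles[rank] = filtered.retained
        for day in days:
            a = sample_name(TreatmentKey(0.0, day, False))
            b = sample_name(TreatmentKey(top_dose, day, False))
            if a not in profile.samples or b not in profile.samples:
                continue
            dominant[f"{rank}/day{day}"] = dominant_by_difference(
                filtered.retained, a, b, min_diff=min_diff
            )
            tests = profile_proportion_tests(
                filtered.retained, a, b, fisher_threshold=fisher_threshold
            )
            tests.insert(0, "rank", rank)
            tests.insert(1, "day", day)
            test_frames.append(tests)
    proportion_tests = (
        pd.concat(test_frames, ignore_index=True) if test_frames else pd.DataFrame()
    )
    genus_profile = aggregate_rank(dataset.otu_table, "genus")
    named = [t for t in genus_profile.taxa if t != "Unclassified"]
    shared = shared_taxa(genus_profile, min_proportion=min_proportion) & set(named)
    log_stage("taxa", int(np.prod(dataset.otu_table.shape)), len(proportion_tests))

    # --- residue ------------------------------------------------------------
    residue_table, residue_summary = summarize_residue_decline(dataset.residue_series)
    log_stage("residue", len(dataset.residue_series), len(residue_table))

    config_digest = hashlib.sha256(
        json.dumps(scenario_to_dict(config), sort_keys=True).encode()
    ).hexdigest()
    report = RunReport(
        provenance={
            "config_sha256": config_digest,
            "seed": config.seed,
            "version": __version__,
            "data_source": "synthetic" if data_dir in (None, "synthetic") else str(data_dir),
            "options": {
                "alpha_posthoc": alpha_posthoc,
                "alpha_correlation": alpha_correlation,
                "min_proportion": min_proportion,
                "min_diff": min_diff,
                "fisher_threshold": fisher_threshold,
                "rk_threshold": rk_threshold,
            },
        },
        index_tables=indices_frame,
        strategy_table=strategy_frame,
        percent_changes=changes,
        if_matrices=if_matrices,
        groupings=groupings,
        correlations=correlations,
        pca=pca_reports,
        rank_profiles=profiles,
        dominant=dominant,
        shared_genera=shared,
        proportion_tests=proportion_tests,
        residue_table=residue_table,
        residue_summary=residue_summary,
        stage_log=stage_log,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Serialize a report as CSV tables plus a JSON manifest (no timestamps)."""
    out = Path(out_dir)
    for sub in ("indices", "if", "stats", "pca", "taxa", "residue"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    report.index_tables.to_csv(out / "indices" / "cd_ep.csv", index=False)
    report.strategy_table.to_csv(out / "indices" / "strategy.csv", index=False)
    report.percent_changes.to_csv(out / "indices" / "percent_change.csv", index=False)

    for name, matrix in report.if_matrices.items():
        stem = name.replace("/", "_")
        flat = matrix.values.copy()
        flat.columns = [f"{dose:g}:{day}" for dose, day in flat.columns]
        flat.to_csv(out / "if" / f"{stem}.csv", index_label="response")
        with open(out / "if" / f"{stem}.json", "w") as handle:
            json.dump(
                {"baseline_mode": matrix.baseline_mode, "aggregator": matrix.aggregator},
                handle,
                sort_keys=True,
                indent=2,
            )

    report.groupings.to_csv(out / "stats" / "letters.csv", index=False)
    report.correlations.to_csv(out / "stats" / "pearson.csv", index=False)

    for name, pca in report.pca.items():
        stem = name.replace("/", "_")
        pca.loadings.to_csv(out / "pca" / f"{stem}_loadings.csv", index_label="variable")
        pca.scores.to_csv(out / "pca" / f"{stem}_scores.csv", index_label="case")
        with open(out / "pca" / f"{stem}_summary.json", "w") as handle:
            json.dump(
                {
                    "explained_pct": [float(x) for x in pca.explained_pct],
                    "standardized": pca.standardized,
                    "dropped_cases": pca.dropped_cases,
                },
                handle,
                sort_keys=True,
                indent=2,
            )

    for rank, profile in report.rank_profiles.items():
        profile.to_frame(proportions=True).to_csv(
            out / "taxa" / f"profile_{rank}.csv", index_label="taxon"
        )
    for key, frame in report.dominant.items():
        frame.to_csv(out / "taxa" / f"dominant_{key.replace('/', '_')}.csv", index=False)
    with open(out / "taxa" / "shared_genera.json", "w") as handle:
        json.dump(sorted(report.shared_genera), handle, indent=2)
    report.proportion_tests.to_csv(out / "taxa" / "proportion_tests.csv", index=False)

    report.residue_table.to_csv(out / "residue" / "decline.csv", index=False)
    with open(out / "residue" / "summary.json", "w") as handle:
        json.dump(report.residue_summary, handle, sort_keys=True, indent=2)

    with open(out / "manifest.json", "w") as handle:
        json.dump(
            {"provenance": report.provenance, "stages": report.stage_log},
            handle,
            sort_keys=True,
            indent=2,
        )
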