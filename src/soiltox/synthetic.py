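"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a pot experiment crossing five contaminant doses
(0, 0.1, 1, 10, 50 mg kg^-1 DM of soil), three sampling days (15, 30, 45) and
a mussel-shell biostimulant, with replicate pots per cell.  Four data kinds
are produced:

* colony-emergence series — plate totals drawn from a negative binomial
  around baseline x dose-effect x biostimulant multiplier, spread over the
  10 observation days by a group-specific appearance-day distribution
  (truncated geometric by default: front-loaded for fast growers, reversed
  for slow ones);
* enzyme activities — baseline x dose-effect x biostimulant multiplier with
  multiplicative lognormal noise (unit mean);
* OTU tables — per-sample composition softmax(base logits + dose-scaled
  shift), overdispersed through a Dirichlet draw, counts multinomial at the
  configured library size, lineages from a small built-in 5-rank taxonomy;
* contaminant residues — first-order decay dose * exp(-k * t), the default
  rate removing 96% of the dose within the first 15 days.

Default effect sizes encode the study conditions the pipeline is meant to
detect: a 76% drop of the fungal count at the top dose on day 15, a 65%
urease stimulation at the 0.1 mg dose on day 15, a monotone beta-glucosidase
dose response, and mild inhibition of both phosphatases at the top dose.
Everything is configuration, not truth; identical (config, seed) pairs yield
identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .model import (
    DEFAULT_DAYS,
    DEFAULT_DOSES,
    N_OBSERVATION_DAYS,
    ActivityTable,
    ColonyEmergenceSeries,
    OtuTable,
    ResidueSeries,
    TreatmentKey,
)

#: Decay rate (d^-1) for which exp(-k * 15) = 0.04, i.e. 96% removal by day 15.
DEFAULT_DECAY_RATE = math.log(25.0) / 15.0

#: Geometric appearance-day parameter giving an expected CD of 49 (front-loaded).
ORGANOTROPH_EMERGENCE_P = 0.2555128134555387

_STREAMS = {"colony": 1, "enzyme": 2, "otu": 3, "residue": 4}


def geometric_day_probs(p: float, reverse: bool = False) -> tuple[float, ...]:
    """Truncated-geometric distribution over observation days 1..10."""
    if not (0.0 < p < 1.0):
        raise ValidationError(f"geometric parameter must be in (0, 1), got {p}")
    raw = p * (1.0 - p) ** np.arange(N_OBSERVATION_DAYS)
    if reverse:
        raw = raw[::-1]
    raw = raw / raw.sum()
    return tuple(float(x) for x in raw)


DoseEffects = Mapping[float, Sequence[float]]


def _normalize_effects(effects: DoseEffects | None, n_days: int) -> dict[float, tuple[float, ...]]:
    out: dict[float, tuple[float, ...]] = {}
    for dose, per_day in (effects or {}).items():
        per_day = tuple(float(x) for x in per_day)
        if len(per_day) != n_days:
            raise ValidationError(
                f"dose {dose}: effect vector has {len(per_day)} entries, expected {n_days}"
            )
        if any(e < 0 for e in per_day):
            raise ValidationError(f"dose {dose}: negative effect multiplier")
        out[float(dose)] = per_day
    return out


@dataclass
class GroupSpec:
    """One microbial group: baseline plate count, dose response, growth tempo."""

    name: str
    baseline: float  # mean colonies per plate in clean, unamended soil
    dose_effect: dict[float, tuple[float, ...]] = field(default_factory=dict)
    emergence_p: float = 0.35  # geometric parameter; ignored if day_probs given
    day_probs: tuple[float, ...] | None = None
    dispersion: float = 25.0  # negative-binomial size; inf = deterministic totals
    pc_multiplier: float = 1.0

    def effect(self, dose: float, day_index: int) -> float:
        per_day = self.dose_effect.get(float(dose))
        return per_day[day_index] if per_day is not None else 1.0

    def emergence_distribution(self) -> np.ndarray:
        probs = (
            np.asarray(self.day_probs, dtype=float)
            if self.day_probs is not None
            else np.asarray(geometric_day_probs(self.emergence_p))
        )
        if probs.size != N_OBSERVATION_DAYS or np.any(probs < 0) or probs.sum() <= 0:
            raise ValidationError(f"{self.name}: invalid appearance-day distribution")
        return probs / probs.sum()


@dataclass
class EnzymeSpec:
    """One soil enzyme: baseline activity, dose response, noise level."""

    name: str
    baseline: float
    unit: str = "a.u."
    dose_effect: dict[float, tuple[float, ...]] = field(default_factory=dict)
    noise_cv: float = 0.08
    pc_multiplier: float = 1.15

    def effect(self, dose: float, day_index: int) -> float:
        per_day = self.dose_effect.get(float(dose))
        return per_day[day_index] if per_day is not None else 1.0


@dataclass
class OtuSpec:
    """Compositional model for OTU libraries.

    ``base_logits`` set the clean-soil composition through a softmax;
    ``dose_shift`` is added per unit of log-scaled dose, so positive entries
    enrich a taxon under contamination.  ``concentration`` is the Dirichlet
    precision (inf = no compositional overdispersion).
    """

    otu_ids: list[str]
    lineages: list[tuple[str, ...]]
    base_logits: list[float]
    dose_shift: list[float]
    library_size: int = 20000
    concentration: float = 500.0

    def __post_init__(self) -> None:
        n = len(self.otu_ids)
        if not (len(self.lineages) == len(self.base_logits) == n):
            raise ValidationError("otu_ids, lineages and base_logits must have equal length")
        if len(self.dose_shift) != n:
            raise ValidationError(
                f"dose_shift has {len(self.dose_shift)} entries for {n} taxa"
            )
        if self.library_size <= 0:
            raise ValidationError("library_size must be > 0")


@dataclass
class ResidueSpec:
    decay_rate: float = DEFAULT_DECAY_RATE  # d^-1, shared across doses
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.decay_rate < 0:
            raise ValidationError("decay_rate must be >= 0")


@dataclass
class ScenarioConfig:
    """Full description of one synthetic experiment."""

    doses: tuple[float, ...] = DEFAULT_DOSES
    days: tuple[int, ...] = DEFAULT_DAYS
    replicates: int = 3
    groups: list[GroupSpec] = field(default_factory=list)
    enzymes: list[EnzymeSpec] = field(default_factory=list)
    otu: OtuSpec | None = None
    residue: ResidueSpec = field(default_factory=ResidueSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        self.days = tuple(int(t) for t in self.days)
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        n_days = len(self.days)
        for spec in list(self.groups) + list(self.enzymes):
            spec.dose_effect = _normalize_effects(spec.dose_effect, n_days)
            if spec.baseline < 0:
                raise ValidationError(f"{spec.name}: negative baseline")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def cells(self) -> list[TreatmentKey]:
        return [
            TreatmentKey(dose, day, pc)
            for pc in (False, True)
            for day in self.days
            for dose in self.doses
        ]


# ---------------------------------------------------------------------------
# generators


def generate_colony_counts(config: ScenarioConfig) -> list[ColonyEmergenceSeries]:
    """Colony-emergence series for every group x cell x replicate."""
    rng = config.rng("colony")
    out: list[ColonyEmergenceSeries] = []
    for spec in config.groups:
        day_probs = spec.emergence_distribution()
        for key in config.cells():
            day_index = config.days.index(key.time_day)
            mu = spec.baseline * spec.effect(key.dose, day_index)
            if key.biostimulant:
                mu *= spec.pc_multiplier
            for replicate in range(1, config.replicates + 1):
                if math.isinf(spec.dispersion):
                    total = int(round(mu))
                else:
                    if spec.dispersion <= 0:
                        raise ValidationError(f"{spec.name}: dispersion must be > 0 or inf")
                    r = spec.dispersion
                    total = int(rng.negative_binomial(r, r / (r + mu))) if mu > 0 else 0
                counts = rng.multinomial(total, day_probs)
                out.append(
                    ColonyEmergenceSeries(
                        group_name=spec.name,
                        treatment=key,
                        replicate=replicate,
                        counts=tuple(int(c) for c in counts),
                    )
                )
    return out


def generate_enzyme_activities(config: ScenarioConfig) -> list[ActivityTable]:
    """One ActivityTable per enzyme over every cell x replicate."""
    rng = config.rng("enzyme")
    tables: list[ActivityTable] = []
    for spec in config.enzymes:
        if spec.noise_cv < 0:
            raise ValidationError(f"{spec.name}: negative noise_cv")
        sigma = math.sqrt(math.log1p(spec.noise_cv**2))
        table = ActivityTable(response_name=spec.name, unit=spec.unit)
        for key in config.cells():
            day_index = config.days.index(key.time_day)
            mean = spec.baseline * spec.effect(key.dose, day_index)
            if key.biostimulant:
                mean *= spec.pc_multiplier
            for _ in range(config.replicates):
                noise = (
                    math.exp(rng.normal(-sigma**2 / 2.0, sigma)) if sigma > 0 else 1.0
                )
                table.add(key, mean * noise)
        tables.append(table)
    return tables


def sample_name(key: TreatmentKey) -> str:
    return f"D{key.dose:g}_T{key.time_day}" + ("_Pc" if key.biostimulant else "")


def expected_compositions(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """Noise-free per-sample compositions (the softmax means of the Dirichlet)."""
    if config.otu is None:
        raise ValidationError("scenario has no OTU model configured")
    spec = config.otu
    logits = np.asarray(spec.base_logits, dtype=float)
    shift = np.asarray(spec.dose_shift, dtype=float)
    top = max(config.doses) if max(config.doses) > 0 else 1.0
    out: dict[str, np.ndarray] = {}
    for key in config.cells():
        scale = math.log1p(key.dose) / math.log1p(top)
        z = logits + scale * shift
        z = z - z.max()
        p = np.exp(z)
        out[sample_name(key)] = p / p.sum()
    return out


def generate_otu_table(config: ScenarioConfig) -> OtuTable:
    """Dirichlet-multinomial OTU libraries, one sample per treatment cell."""
    if config.otu is None:
        raise ValidationError("scenario has no OTU model configured")
    spec = config.otu
    rng = config.rng("otu")
    compositions = expected_compositions(config)
    cells = config.cells()
    samples = [sample_name(k) for k in cells]
    counts = np.zeros((len(spec.otu_ids), len(samples)), dtype=np.int64)
    for j, key in enumerate(cells):
        mean = compositions[samples[j]]
        if math.isinf(spec.concentration):
            p = mean
        else:
            if spec.concentration <= 0:
                raise ValidationError("concentration must be > 0 or inf")
            p = rng.dirichlet(spec.concentration * mean)
        counts[:, j] = rng.multinomial(spec.library_size, p)
    return OtuTable(
        otu_ids=list(spec.otu_ids),
        lineages=list(spec.lineages),
        samples=samples,
        counts=counts,
        sample_treatments=dict(zip(samples, cells)),
    )


def generate_residue_series(config: ScenarioConfig) -> list[ResidueSeries]:
    """First-order contaminant decay per dose, observed at the sampling days."""
    spec = config.residue
    rng = config.rng("residue")
    sigma = math.sqrt(math.log1p(spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0
    out: list[ResidueSeries] = []
    for dose in config.doses:
        observations: dict[int, float] = {}
        for day in config.days:
            residue = dose * math.exp(-spec.decay_rate * day)
            if sigma > 0:
                residue *= math.exp(rng.normal(-sigma**2 / 2.0, sigma))
            observations[day] = min(residue, dose)
        out.append(ResidueSeries(dose=dose, observations=observations))
    return out


# ---------------------------------------------------------------------------
# presets

# Mock 5-rank taxonomy spanning the dominant soil phyla; one row per OTU:
# (otu_id, lineage, base logit, dose shift).  Positive shifts enrich the OTU
# under contamination.  A few OTUs are unclassified at family/genus level.
_MOCK_TAXONOMY: list[tuple[str, tuple[str, str, str, str, str], float, float]] = [
    ("OTU001", ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Kaistobacter"), 2.9, 0.45),
    ("OTU002", ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Hyphomicrobiaceae", "Devosia"), 1.6, 0.55),
    ("OTU003", ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Hyphomicrobiaceae", "Rhodoplanes"), 1.9, -0.15),
    ("OTU004", ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"), 1.5, 0.25),
    ("OTU005", ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"), 1.2, 0.65),
    ("OTU006", ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae", ""), 0.2, 0.1),
    ("OTU007", ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"), 2.6, 0.35),
    ("OTU008", ("Firmicutes", "Bacilli", "Bacillales", "Alicyclobacillaceae", "Alicyclobacillus"), 2.0, 0.2),
    ("OTU009", ("Firmicutes", "Bacilli", "Bacillales", "Paenibacillaceae", "Paenibacillus"), 1.1, 0.15),
    ("OTU010", ("Firmicutes", "Clostridia", "Clostridiales", "", ""), -0.4, -0.2),
    ("OTU011", ("Bacteroidetes", "Sphingobacteriia", "Sphingobacteriales", "Chitinophagaceae", "Flavisolibacter"), 1.7, 0.1),
    ("OTU012", ("Bacteroidetes", "Cytophagia", "Cytophagales", "Cytophagaceae", ""), 0.1, -0.3),
    ("OTU013", ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae", "Arthrobacter"), 1.8, 0.5),
    ("OTU014", ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Streptomycetaceae", "Streptomyces"), 1.3, -0.35),
    ("OTU015", ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Nocardioidaceae", "Nocardioides"), 0.9, -0.2),
    ("OTU016", ("Acidobacteria", "Acidobacteriia", "Acidobacteriales", "Acidobacteriaceae", ""), 1.0, -0.6),
    ("OTU017", ("Chloroflexi", "Anaerolineae", "Anaerolineales", "Anaerolineaceae", ""), -0.2, -0.45),
    ("OTU018", ("Gemmatimonadetes", "Gemmatimonadetes", "Gemmatimonadales", "Gemmatimonadaceae", "Gemmatimonas"), 0.3, -0.4),
    ("OTU019", ("Planctomycetes", "Planctomycetia", "Gemmatales", "Gemmataceae", "Gemmata"), -0.9, -0.25),
    ("OTU020", ("Verrucomicrobia", "Spartobacteria", "Chthoniobacterales", "Chthoniobacteraceae", ""), -1.2, -0.1),
    ("OTU021", ("Proteobacteria", "Deltaproteobacteria", "Myxococcales", "", ""), -1.5, -0.5),
    ("OTU022", ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"), -2.3, 0.3),
]


def default_taxonomy() -> OtuSpec:
    return OtuSpec(
        otu_ids=[row[0] for row in _MOCK_TAXONOMY],
        lineages=[row[1] for row in _MOCK_TAXONOMY],
        base_logits=[row[2] for row in _MOCK_TAXONOMY],
        dose_shift=[row[3] for row in _MOCK_TAXONOMY],
    )


def default_groups() -> list[GroupSpec]:
    """The eight monitored microbial groups with effect sizes matching the
    study's headline contrasts (e.g. the fungal count falling to 0.24x at the
    top dose on day 15 — a 76% reduction)."""
    act_probs = geometric_day_probs(0.3, reverse=True)  # back-loaded, CD ~ 15
    return [
        GroupSpec("Org", 180.0, {50.0: (2.0, 1.5, 1.29), 10.0: (1.5, 1.3, 1.2), 1.0: (1.1, 1.05, 1.05)},
                  emergence_p=ORGANOTROPH_EMERGENCE_P, pc_multiplier=1.25),
        GroupSpec("Act", 90.0, {50.0: (2.0, 1.3, 0.96), 10.0: (1.4, 1.2, 1.0)},
                  day_probs=act_probs, pc_multiplier=1.15),
        GroupSpec("Fun", 120.0, {50.0: (0.24, 0.49, 0.22), 10.0: (0.6, 0.7, 0.5),
                                 1.0: (0.95, 0.9, 0.9), 0.1: (1.0, 1.0, 0.95)},
                  emergence_p=0.5, pc_multiplier=1.0),
        GroupSpec("Am", 140.0, {50.0: (2.0, 1.42, 0.81), 10.0: (1.5, 1.25, 0.95)},
                  emergence_p=0.3, pc_multiplier=1.2),
        GroupSpec("Im", 110.0, {50.0: (3.0, 1.57, 0.42), 10.0: (1.8, 1.3, 0.8)},
                  emergence_p=0.3, pc_multiplier=1.2),
        GroupSpec("Arthrobacter", 70.0, {50.0: (1.1, 1.2, 1.61), 10.0: (1.05, 1.1, 1.3)},
                  emergence_p=0.35, pc_multiplier=1.2),
        GroupSpec("Pseudomonas", 100.0, {50.0: (1.14, 1.2, 1.1), 0.1: (1.14, 1.05, 1.0)},
                  emergence_p=0.4, pc_multiplier=1.2),
        GroupSpec("Azotobacter", 40.0, {50.0: (0.9, 0.95, 0.9)},
                  emergence_p=0.3, pc_multiplier=1.25),
    ]


def default_enzymes() -> list[EnzymeSpec]:
    """Seven soil enzymes; urease stimulated 65% at the 0.1 mg dose on day 15,
    beta-glucosidase rising monotonically with dose, both phosphatases mildly
    inhibited at the top dose."""
    glu_curve = {0.1: (1.02,) * 3, 1.0: (1.15,) * 3, 10.0: (1.9,) * 3, 50.0: (4.0,) * 3}
    return [
        EnzymeSpec("Deh", 12.0, "umol TPF kg-1 h-1",
                   {50.0: (0.9, 0.92, 0.95), 1.0: (1.05, 1.1, 1.3)}),
        EnzymeSpec("Cat", 0.5, "mol O2 kg-1 h-1",
                   {50.0: (0.95, 0.9, 0.85), 1.0: (1.1, 1.4, 2.5)}),
        EnzymeSpec("Ure", 1.4, "mmol N-NH4 kg-1 h-1",
                   {0.1: (1.65, 0.87, 1.2), 1.0: (1.2, 1.1, 3.9), 50.0: (0.85, 0.9, 0.7)}),
        EnzymeSpec("Pal", 3.2, "mmol PNP kg-1 h-1",
                   {50.0: (0.90, 0.88, 0.85), 1.0: (1.05, 1.1, 1.2)}),
        EnzymeSpec("Pac", 4.1, "mmol PNP kg-1 h-1",
                   {50.0: (0.9384, 0.9, 0.85), 1.0: (1.05, 1.1, 1.15)}),
        EnzymeSpec("Glu", 0.9, "mmol PNP kg-1 h-1", glu_curve),
        EnzymeSpec("Aryl", 0.25, "mmol PNP kg-1 h-1",
                   {50.0: (0.92, 0.9, 0.8), 1.0: (1.05, 1.15, 1.4)}),
    ]


def default_scenario(seed: int = 0, replicates: int = 3) -> ScenarioConfig:
    """The full factorial study shape: 5 doses x 3 days x 2 biostimulant levels."""
    return ScenarioConfig(
        replicates=replicates,
        groups=default_groups(),
        enzymes=default_enzymes(),
        otu=default_taxonomy(),
        residue=ResidueSpec(),
        seed=seed,
    )


def null_scenario(seed: int = 0, replicates: int = 10) -> ScenarioConfig:
    """Minimal no-effect scenario for calibration checks.

    Two microbial groups and two enzymes on a single sampling day, with no
    dose effect, no biostimulant effect, no compositional shift and no
    compositional overdispersion: every treatment contrast is exactly null,
    so post-hoc letters should collapse to "a" and no taxon should pass the
    proportion-difference filter.  Kept deliberately small — a family-wise
    error rate of alpha per Tukey family means an all-clear expectation is
    only robust when few families are tested simultaneously.
    """
    return ScenarioConfig(
        days=(15,),
        replicates=replicates,
        groups=[
            GroupSpec("Org", 150.0, {}, emergence_p=ORGANOTROPH_EMERGENCE_P),
            GroupSpec("Fun", 100.0, {}, emergence_p=0.5),
        ],
        enzymes=[
            EnzymeSpec("Ure", 1.4, dose_effect={}, noise_cv=0.05, pc_multiplier=1.0),
            EnzymeSpec("Glu", 0.9, dose_effect={}, noise_cv=0.05, pc_multiplier=1.0),
        ],
        otu=OtuSpec(
            otu_ids=[row[0] for row in _MOCK_TAXONOMY],
            lineages=[row[1] for row in _MOCK_TAXONOMY],
            base_logits=[row[2] for row in _MOCK_TAXONOMY],
            dose_shift=[0.0] * len(_MOCK_TAXONOMY),
            library_size=50000,
            concentration=math.inf,
        ),
        residue=ResidueSpec(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML (de)serialization


def scenario_to_dict(config: ScenarioConfig) -> dict:
    raw = asdict(config)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, float) and math.isinf(obj):
            return ".inf"
        return obj

    return _clean(raw)


def scenario_from_dict(raw: Mapping) -> ScenarioConfig:
    def _num(x):
        return math.inf if x == ".inf" else x

    def _effects(d):
        return {float(k): tuple(v) for k, v in (d or {}).items()}

    groups = [
        GroupSpec(
            name=g["name"],
            baseline=g["baseline"],
            dose_effect=_effects(g.get("dose_effect")),
            emergence_p=g.get("emergence_p", 0.35),
            day_probs=tuple(g["day_probs"]) if g.get("day_probs") else None,
            dispersion=_num(g.get("dispersion", 25.0)),
            pc_multiplier=g.get("pc_multiplier", 1.0),
        )
        for g in raw.get("groups", [])
    ]
    enzymes = [
        EnzymeSpec(
            name=e["name"],
            baseline=e["baseline"],
            unit=e.get("unit", "a.u."),
            dose_effect=_effects(e.get("dose_effect")),
            noise_cv=e.get("noise_cv", 0.08),
            pc_multiplier=e.get("pc_multiplier", 1.15),
        )
        for e in raw.get("enzymes", [])
    ]
    otu_raw = raw.get("otu")
    otu = (
        OtuSpec(
            otu_ids=list(otu_raw["otu_ids"]),
            lineages=[tuple(lin) for lin in otu_raw["lineages"]],
            base_logits=list(otu_raw["base_logits"]),
            dose_shift=list(otu_raw["dose_shift"]),
            library_size=otu_raw.get("library_size", 20000),
            concentration=_num(otu_raw.get("concentration", 500.0)),
        )
        if otu_raw
        else None
    )
    residue_raw = raw.get("residue") or {}
    return ScenarioConfig(
        doses=tuple(raw.get("doses", DEFAULT_DOSES)),
        days=tuple(raw.get("days", DEFAULT_DAYS)),
        replicates=raw.get("replicates", 3),
        groups=groups,
        enzymes=enzymes,
        otu=otu,
        residue=ResidueSpec(
            decay_rate=residue_raw.get("decay_rate", DEFAULT_DECAY_RATE),
            noise_cv=residue_raw.get("noise_cv", 0.0),
        ),
        seed=raw.get("seed", 0),
    )


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(scenario_to_dict(config), handle, sort_keys=False)


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as handle:
        return scenario_from_dict(yaml.safe_load(handle))
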