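"""Synthetic cohort datasets with ground-truth target mappings.

Real IPD meta-analysis cohorts cannot be redistributed, so every pipeline
stage is exercised on generated ones: tabular datasets with one column per
variable, a label sidecar, a gold-mapping table and a manifest with a
construction/validation split — exactly the formats the rest of the package
reads.

Each target variable has an authored distribution template (plausible
location/spread for its unit, e.g. systolic blood pressure ~ Normal(130, 17)
so its median clears the classic >94 cutoff) and a name per dialect: verbose
("systolic_blood_pressure"), abbreviated ("systolic_bp") or coded (opaque
"v017", identifiable only through labels and value distributions). Noise
variables draw from a pool of realistic non-target names. The hard preset
additionally plants decoy columns that share a target's name token and
distribution — near-misses no metadata rule can separate — which is what
drives positive predictive value far below sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .metadata import profile_dataset
from .pipeline import GoldMapping, write_gold
from .rules import TargetRegistry, default_registry

logger = logging.getLogger("harmonizer")

__all__ = [
    "CohortSpec",
    "PlantedVariable",
    "CohortData",
    "SuiteResult",
    "TARGET_TEMPLATES",
    "generate_cohort",
    "generate_suite",
    "easy_suite",
    "hard_suite",
    "write_suite",
    "load_suite_dir",
]

DIALECTS = ("verbose", "abbreviated", "coded")

#: Decoy name suffixes for the hard preset (appended to the abbreviated name).
_DECOY_SUFFIXES = ("_v2", "_old", "_baseline", "_fu1")


@dataclass(frozen=True)
class TargetTemplate:
    """Authored generation template for one target variable."""

    token: str  # distinctive substring the default name rule tests
    verbose: str
    abbreviated: str
    label: str
    kind: str  # sampler kind
    params: tuple  # sampler parameters (kind-specific)

    def name(self, dialect: str, coded_index: int) -> str:
        if dialect == "verbose":
            return self.verbose
        if dialect == "abbreviated":
            return self.abbreviated
        return f"v{coded_index:03d}"


def _norm(mean, sd, decimals):
    return ("normal", (mean, sd, decimals))


def _intnorm(mean, sd, lo, hi):
    return ("int_normal", (mean, sd, lo, hi))


def _lognorm(mu, sigma, decimals):
    return ("lognormal", (mu, sigma, decimals))


def _bern(p):
    return ("bernoulli", (p,))


def _catint(k):
    return ("categorical_int", (k,))


def _catstr(*choices):
    return ("categorical_str", tuple(choices))


def _date(y0, y1):
    return ("date", (y0, y1))


def _zinf(p_zero, mu, sigma, decimals):
    return ("zero_inflated", (p_zero, mu, sigma, decimals))


def _template(token, verbose, abbreviated, label, spec):
    kind, params = spec
    return TargetTemplate(token, verbose, abbreviated, label, kind, params)


#: One template per packaged target. Unit-paired targets (conventional vs SI)
#: share a name token and are separable only by their value scale, mirroring
#: how real cohorts mix mg/dl with mmol/l exports.
TARGET_TEMPLATES: dict[str, TargetTemplate] = {
    "Age": _template("age", "age_at_baseline", "age", "Age at baseline (years)", _intnorm(55, 10, 20, 90)),
    "BMI": _template("bmi", "bmi_baseline", "bmi", "Body mass index (kg/m2)", _norm(27, 4, 1)),
    "Urea": _template("urea", "serum_urea_mgdl", "urea", "Serum urea (mg/dl)", _norm(35, 10, 1)),
    "Cholesterol": _template("total_chol", "total_cholesterol_mgdl", "total_chol", "Total cholesterol (mg/dl)", _norm(210, 40, 1)),
    "Cholesterol SI": _template("total_chol", "total_cholesterol_mmol", "total_chol_si", "Total cholesterol (mmol/l)", _norm(5.4, 1.0, 2)),
    "Creatinine": _template("creatinin", "serum_creatinine", "creatinin", "Serum creatinine (mg/dl)", _norm(1.0, 0.25, 2)),
    "Diabetes": _template("diabetes", "diabetes_mellitus", "diabetes", "Diabetes mellitus (yes/no)", _bern(0.12)),
    "Education": _template("education", "education_level", "education", "Education level (1-5)", _catint(5)),
    "Ethnicity": _template("ethnic", "ethnicity", "ethnic_group", "Ethnic group", _catstr("white", "black", "asian", "other")),
    "Event date": _template("event", "event_date", "event_dt", "Date of clinical event", _date(1995, 2010)),
    "Fasting glucose": _template("glucose", "fasting_glucose_mgdl", "glucose_f", "Fasting glucose (mg/dl)", _norm(95, 15, 1)),
    "Fasting glucose SI": _template("glucose", "fasting_glucose_mmol", "glucose_f_si", "Fasting glucose (mmol/l)", _norm(5.3, 0.8, 2)),
    "Fibrinogen": _template("fibrinogen", "fibrinogen_mgdl", "fibrinogen", "Plasma fibrinogen (mg/dl)", _norm(320, 60, 1)),
    "Hemoglobin": _template("hemoglobin", "hemoglobin_gdl", "hemoglobin", "Hemoglobin (g/dl)", _norm(14.2, 1.3, 1)),
    "Hemoglobin SI": _template("hemoglobin", "hemoglobin_gl", "hemoglobin_si", "Hemoglobin (g/l)", _norm(142, 13, 0)),
    "Hba1c": _template("hba1c", "hba1c_percent", "hba1c", "Glycated hemoglobin HbA1c (%)", _norm(5.8, 0.8, 1)),
    "HDL cholesterol": _template("hdl", "hdl_cholesterol_mgdl", "hdl", "HDL cholesterol (mg/dl)", _norm(52, 13, 1)),
    "HDL cholesterol SI": _template("hdl", "hdl_cholesterol_mmol", "hdl_si", "HDL cholesterol (mmol/l)", _norm(1.35, 0.35, 2)),
    "History of CVD": _template("cvd", "history_of_cvd", "cvd_hist", "History of cardiovascular disease", _bern(0.15)),
    "Hs-CRP": _template("crp", "hs_crp_mgl", "crp", "High-sensitivity CRP (mg/l)", _lognorm(0.7, 0.8, 2)),
    "Hypertension": _template("hypertension", "hypertension_diagnosed", "hypertension", "Hypertension (yes/no)", _bern(0.35)),
    "Intima Media Thickness (IMT)": _template("imt", "mean_imt_ccar", "imt_mean", "Mean common carotid IMT (0.1 mm)", _norm(7.3, 1.2, 2)),
    "Intima Media Thickness (IMT) SI": _template("imt", "mean_imt_mm", "imt_mm", "Mean common carotid IMT (mm)", _norm(0.73, 0.12, 3)),
    "Arterial diameter": _template("diameter", "carotid_diameter_mm", "diameter", "Common carotid diameter (mm)", _norm(6.2, 0.8, 2)),
    "Income": _template("income", "household_income", "income", "Household income bracket", _catint(6)),
    "LDL cholesterol": _template("ldl", "ldl_cholesterol_mgdl", "ldl", "LDL cholesterol (mg/dl)", _norm(130, 32, 1)),
    "LDL cholesterol SI": _template("ldl", "ldl_cholesterol_mmol", "ldl_si", "LDL cholesterol (mmol/l)", _norm(3.4, 0.8, 2)),
    "Leukocytes": _template("leuko", "leukocyte_count", "leukos", "Leukocyte count (1/ul)", _intnorm(6800, 1500, 2000, 20000)),
    "Dyslipidemia": _template("dyslipid", "dyslipidemia", "dyslipid", "Dyslipidemia (yes/no)", _bern(0.3)),
    "Antidiabetic medication": _template("antidiab", "antidiabetic_medication", "antidiab_med", "Antidiabetic medication (yes/no)", _bern(0.08)),
    "Antihypertensive medication": _template("antihypert", "antihypertensive_medication", "antihypert_med", "Antihypertensive medication (yes/no)", _bern(0.3)),
    "Lipid-lowering medication": _template("lipid_lower", "lipid_lowering_medication", "lipid_lower_med", "Lipid-lowering medication (yes/no)", _bern(0.2)),
    "Nicotine consumption": _template("pack", "pack_years_smoked", "packyrs", "Nicotine consumption (pack years)", _zinf(0.45, 2.7, 0.7, 1)),
    "Carotid plaque": _template("plaque", "carotid_plaque", "plaque", "Carotid plaque present (yes/no)", _bern(0.25)),
    "Diastolic blood pressure": _template("diastolic", "diastolic_blood_pressure", "diastolic_bp", "Diastolic blood pressure (mmHg)", _intnorm(80, 10, 45, 130)),
    "Systolic blood pressure": _template("systolic", "systolic_blood_pressure", "systolic_bp", "Systolic blood pressure (mmHg)", _intnorm(130, 17, 80, 230)),
    "Socioeconomic status": _template("socioecon", "socioeconomic_status", "socioecon_stat", "Socioeconomic status (1-3)", _catint(3)),
    "Sex": _template("sex", "sex", "sex_cd", "Sex (0=female, 1=male)", _bern(0.5)),
    "Smoking status": _template("smoking", "smoking_status", "smoking", "Smoking status (0/1/2)", _catint(3)),
    "Triglycerides": _template("triglyc", "triglycerides_mgdl", "triglyc", "Triglycerides (mg/dl)", _lognorm(4.7, 0.5, 1)),
    "Ultrasound date": _template("ultrasound", "ultrasound_exam_date", "ultrasound_dt", "Date of ultrasound examination", _date(1990, 2012)),
}

#: Realistic non-target column names; none contains any target's name token
#: (asserted by the test suite), so the easy preset stays noiseless.
NOISE_NAME_POOL = (
    "visit_number", "center_code", "participant_row", "height_cm", "weight_kg",
    "hip_circ", "waist_circ", "heart_rate", "qrs_duration", "albumin_gl",
    "platelet_count", "sodium_mmol", "potassium", "ferritin", "vitamin_d",
    "alcohol_units", "steps_per_day", "qc_flag", "study_site", "zip_region",
    "marital_status", "employment_cat", "followup_years", "med_count",
    "biomarker_x", "temp_c", "pulse_wave", "ecg_flag", "lab_batch", "hosp_id",
    "insurance_type", "residence_area", "grip_strength", "uric_acid",
    "bilirubin", "tsh_value", "calcium_mmol", "phosphate", "crea_clearance",
)


def _sample(kind: str, params: tuple, rng: np.random.Generator, n: int) -> list[str]:
    if kind == "normal":
        mean, sd, decimals = params
        values = rng.normal(mean, sd, size=n)
        return [f"{v:.{decimals}f}" for v in values]
    if kind == "int_normal":
        mean, sd, lo, hi = params
        values = np.clip(np.rint(rng.normal(mean, sd, size=n)), lo, hi).astype(int)
        return [str(v) for v in values]
    if kind == "lognormal":
        mu, sigma, decimals = params
        values = rng.lognormal(mu, sigma, size=n)
        return [f"{v:.{decimals}f}" for v in values]
    if kind == "bernoulli":
        (p,) = params
        return [str(v) for v in (rng.random(n) < p).astype(int)]
    if kind == "categorical_int":
        (k,) = params
        return [str(v) for v in rng.integers(1, k + 1, size=n)]
    if kind == "categorical_str":
        return [str(v) for v in rng.choice(params, size=n)]
    if kind == "date":
        y0, y1 = params
        years = rng.integers(y0, y1 + 1, size=n)
        months = rng.integers(1, 13, size=n)
        days = rng.integers(1, 29, size=n)
        return [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(years, months, days)]
    if kind == "zero_inflated":
        p_zero, mu, sigma, decimals = params
        values = rng.lognormal(mu, sigma, size=n)
        values[rng.random(n) < p_zero] = 0.0
        return [f"{v:.{decimals}f}" for v in values]
    raise ValueError(f"unknown sampler kind {kind!r}")


_NOISE_KINDS = (
    lambda rng: ("normal", (float(rng.uniform(-5, 200)), float(rng.uniform(0.5, 30)), 2)),
    lambda rng: ("int_normal", (float(rng.uniform(1, 500)), float(rng.uniform(1, 60)), 0, 10_000)),
    lambda rng: ("categorical_int", (int(rng.integers(2, 9)),)),
    lambda rng: ("bernoulli", (float(rng.uniform(0.05, 0.95)),)),
    lambda rng: ("categorical_str", ("a", "b", "c", "d")),
    lambda rng: ("date", (1985, 2015)),
)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort dataset.

    ``decoy_rate`` is the probability, per planted target, of adding one
    near-miss decoy column that shares the target's name token and
    distribution; it is 0 in the easy preset and high in the hard one.
    """

    n_participants: int = 500
    n_noise_variables: int = 100
    targets_present: tuple[str, ...] = tuple(TARGET_TEMPLATES)
    naming_dialect: str = "verbose"
    missing_rate: float = 0.0
    seed: int = 0
    decoy_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.naming_dialect not in DIALECTS:
            raise ValueError(f"naming_dialect must be one of {DIALECTS}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class PlantedVariable:
    """Ground-truth ledger entry for one planted target column."""

    target_name: str
    column_name: str
    params: dict


@dataclass
class CohortData:
    dataset_id: str
    table: pd.DataFrame
    labels: dict[str, str]
    ledger: list[PlantedVariable]


def generate_cohort(
    spec: CohortSpec,
    registry: Optional[TargetRegistry] = None,
    dataset_id: str = "SYN",
) -> CohortData:
    """Generate one cohort: planted target columns, optional decoys, noise.

    Columns are shuffled, missingness is applied uniformly at random, and
    everything is drawn from a generator seeded by ``spec.seed``, so the
    output is byte-identical across runs.
    """
    registry = registry or default_registry()
    unknown = [t for t in spec.targets_present if t not in registry.names]
    if unknown:
        raise ValueError(f"unknown targets: {unknown}")
    for t in spec.targets_present:
        if t not in TARGET_TEMPLATES:
            raise ValueError(f"no generation template for target {t!r}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    columns: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    ledger: list[PlantedVariable] = []

    coded_counter = 1
    for target_name in spec.targets_present:
        template = TARGET_TEMPLATES[target_name]
        name = template.name(spec.naming_dialect, coded_counter)
        coded_counter += 1
        columns[name] = _sample(template.kind, template.params, rng, n)
        labels[name] = template.label
        ledger.append(
            PlantedVariable(
                target_name=target_name,
                column_name=name,
                params={"kind": template.kind, "params": template.params},
            )
        )
        # near-miss decoy: same token, same distribution, not the gold variable
        if spec.decoy_rate > 0 and rng.random() < spec.decoy_rate:
            suffix = _DECOY_SUFFIXES[int(rng.integers(len(_DECOY_SUFFIXES)))]
            decoy = template.abbreviated + suffix
            if decoy not in columns:
                columns[decoy] = _sample(template.kind, template.params, rng, n)
                labels[decoy] = template.label + " (repeat measurement)"

    pool = list(NOISE_NAME_POOL)
    for i in range(spec.n_noise_variables):
        base = pool[i % len(pool)]
        name = base if i < len(pool) else f"{base}_{i // len(pool) + 1}"
        kind, params = _NOISE_KINDS[int(rng.integers(len(_NOISE_KINDS)))](rng)
        columns[name] = _sample(kind, params, rng, n)
        labels[name] = f"Study-specific variable {name}"

    order = list(columns)
    rng.shuffle(order)
    table = pd.DataFrame({name: columns[name] for name in order})

    if spec.missing_rate > 0:
        mask = rng.random(table.shape) < spec.missing_rate
        values = table.to_numpy(dtype=object)
        values[mask] = ""
        table = pd.DataFrame(values, columns=table.columns)

    return CohortData(dataset_id=dataset_id, table=table, labels=labels, ledger=ledger)


@dataclass
class SuiteResult:
    """A collection of generated cohorts plus the files the pipeline consumes."""

    cohorts: dict[str, CohortData]
    gold: list[GoldMapping]
    manifest: pd.DataFrame

    def profiles_by_dataset(self, config=None) -> dict[str, list]:
        return {
            ds_id: profile_dataset(c.table, c.labels, config)
            for ds_id, c in self.cohorts.items()
        }

    def dataset_ids(self, use: str) -> list[str]:
        mask = self.manifest["use"] == use
        return list(self.manifest.loc[mask, "acronym"])


def generate_suite(
    n_datasets: int,
    base_spec: CohortSpec,
    split_ratio: float = 0.5,
    seed: int = 0,
    registry: Optional[TargetRegistry] = None,
    dialect_cycle: Sequence[str] = ("verbose", "abbreviated"),
    target_drop_rate: float = 0.1,
) -> SuiteResult:
    """Generate a heterogeneous suite of cohorts with gold mappings and manifest.

    Per-dataset sizes are jittered around ``base_spec``, dialects cycle
    through ``dialect_cycle``, and each target is independently absent from a
    dataset with ``target_drop_rate`` (so each target has ~0-1 true match per
    dataset). Construction receives ceil(n_datasets * split_ratio) datasets.
    """
    if n_datasets < 2:
        raise ValueError("a suite needs at least 2 datasets")
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)

    cohorts: dict[str, CohortData] = {}
    gold: list[GoldMapping] = []
    rows = []
    for i in range(n_datasets):
        ds_id = f"SYN{i + 1:02d}"
        keep = tuple(
            t for t in base_spec.targets_present if rng.random() >= target_drop_rate
        )
        if not keep:  # never emit a dataset with no targets at all
            keep = (base_spec.targets_present[0],)
        spec = replace(
            base_spec,
            targets_present=keep,
            n_participants=int(base_spec.n_participants * rng.uniform(0.6, 1.4)),
            n_noise_variables=max(5, int(base_spec.n_noise_variables * rng.uniform(0.6, 1.4))),
            naming_dialect=dialect_cycle[i % len(dialect_cycle)],
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
        )
        cohort = generate_cohort(spec, registry, dataset_id=ds_id)
        cohorts[ds_id] = cohort
        for planted in cohort.ledger:
            gold.append(GoldMapping(ds_id, planted.column_name, planted.target_name))
        rows.append(
            {
                "acronym": ds_id,
                "study_name": f"Synthetic cohort {i + 1}",
                "study_type": ["general population", "risk population", "RCT"][i % 3],
                "n_variables": cohort.table.shape[1],
                "n_participants": cohort.table.shape[0],
            }
        )

    manifest = pd.DataFrame(rows)
    n_construction = int(np.ceil(n_datasets * split_ratio))
    order = rng.permutation(n_datasets)
    use = np.array(["Validation"] * n_datasets, dtype=object)
    use[order[:n_construction]] = "Construction"
    manifest["use"] = use
    return SuiteResult(cohorts=cohorts, gold=gold, manifest=manifest)


def easy_suite(
    n_datasets: int = 6,
    seed: int = 0,
    registry: Optional[TargetRegistry] = None,
    base_spec: Optional[CohortSpec] = None,
) -> SuiteResult:
    """Noiseless preset: informative names in every dataset, no decoys, no
    missingness — the end-to-end correctness gate, where the default rules
    identify every planted variable exactly."""
    base = base_spec or CohortSpec(missing_rate=0.0, decoy_rate=0.0)
    return generate_suite(
        n_datasets, base, seed=seed, registry=registry,
        dialect_cycle=("verbose", "abbreviated"), target_drop_rate=0.1,
    )


def hard_suite(
    n_datasets: int = 6,
    seed: int = 0,
    registry: Optional[TargetRegistry] = None,
    base_spec: Optional[CohortSpec] = None,
) -> SuiteResult:
    """Adversarial preset: coded names in a third of datasets, missing cells,
    and near-miss decoy columns that the metadata rules cannot separate from
    the true variable — the regime where PPV collapses while sensitivity and
    NPV stay high."""
    base = base_spec or CohortSpec(missing_rate=0.05, decoy_rate=0.9)
    return generate_suite(
        n_datasets, base, seed=seed, registry=registry,
        dialect_cycle=("verbose", "abbreviated", "coded"), target_drop_rate=0.1,
    )


def write_suite(suite: SuiteResult, out_dir: Union[str, Path]) -> None:
    """Emit the suite as CSV files: one dataset + label sidecar per cohort,
    plus gold.csv and manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds_id, cohort in suite.cohorts.items():
        cohort.table.to_csv(out / f"{ds_id}.csv", index=False)
        pd.DataFrame(
            sorted(cohort.labels.items()), columns=["name", "label"]
        ).to_csv(out / f"{ds_id}.labels.csv", index=False)
    write_gold(suite.gold, out / "gold.csv")
    suite.manifest.to_csv(out / "manifest.csv", index=False)


def load_suite_dir(directory: Union[str, Path]) -> tuple[dict[str, pd.DataFrame], dict[str, dict], pd.DataFrame, list[GoldMapping]]:
    """Read back a directory written by :func:`write_suite`.

    Returns (tables, labels, manifest, gold), keyed by dataset acronym.
    """
    from .metadata import read_dataset, read_labels
    from .pipeline import read_gold, read_manifest

    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    gold = read_gold(directory / "gold.csv")
    tables, labels = {}, {}
    for ds_id in manifest["acronym"]:
        tables[ds_id] = read_dataset(directory / f"{ds_id}.csv")
        label_path = directory / f"{ds_id}.labels.csv"
        labels[ds_id] = read_labels(label_path) if label_path.exists() else {}
    return tables, labels, manifest, gold
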