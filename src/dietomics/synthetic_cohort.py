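"""Synthetic cohort generation with planted diet-marker effects.

The generator draws food-group intakes and covariates from configurable
marginals (defaults emulate the published sample characteristics of the
cohort the analysis targets), scores the three diet indices on the generated
intakes, and then builds marker matrices as linear functions of the
*standardized* index values plus Gaussian noise:

    marker = sum_over_plan( beta * z_index ) + covariate effects + noise

so that the downstream regression scan can recover the planted coefficients.
Proteins are written on a strictly positive raw scale (exp of the linear
signal) in two assay batches; metabolites stay on the linear scale and are
unbatched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import diet_scoring
from .errors import ConfigurationError, InputError
from .omics_preprocess import MarkerMatrix

__all__ = [
    "CohortSpec",
    "EffectPlan",
    "PlannedEffect",
    "SyntheticCohort",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "load_cohort_tables",
]

#: per-sex (mean, sd) intake marginals; food-group values follow the printed
#: sample-characteristics table (units as printed), sodium is a supplementary
#: default since the source table omits it.
DEFAULT_INTAKE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "vegetables":         {"male": (2.0, 1.3),   "female": (2.4, 1.7)},
    "fruits":             {"male": (1.2, 1.0),   "female": (1.4, 1.2)},
    "low_fat_dairy":      {"male": (0.8, 0.9),   "female": (0.9, 1.0)},
    "nuts":               {"male": (0.4, 0.6),   "female": (0.2, 0.4)},
    "legumes":            {"male": (0.3, 0.3),   "female": (0.3, 0.3)},
    "whole_grains":       {"male": (1.2, 1.2),   "female": (1.2, 1.2)},
    "red_processed_meat": {"male": (0.9, 0.7),   "female": (0.6, 0.5)},
    "fish":               {"male": (0.3, 0.3),   "female": (0.3, 0.3)},
    "ssb_fruit_juice":    {"male": (1.4, 1.2),   "female": (1.1, 1.2)},
    "ssb":                {"male": (0.5, 0.8),   "female": (0.3, 0.6)},
    "fruit_juice":        {"male": (0.9, 0.9),   "female": (0.8, 0.9)},
    "alcohol_g_day":      {"male": (15.4, 20.0), "female": (6.7, 11.2)},
    "mufa_sfa_ratio":     {"male": (1.1, 0.2),   "female": (1.1, 0.2)},
    "mufa_pct":           {"male": (11.3, 2.7),  "female": (10.9, 2.6)},
    "sfa_pct":            {"male": (10.5, 3.0),  "female": (10.3, 2.8)},
    "pufa_pct":           {"male": (5.7, 1.7),   "female": (6.0, 1.7)},
    "trans_pct":          {"male": (1.6, 0.8),   "female": (1.4, 0.7)},
    "omega3_mg":          {"male": (257.8, 235.5), "female": (253.2, 217.8)},
    "sodium_mg":          {"male": (2800.0, 900.0), "female": (2400.0, 800.0)},
}

DEFAULT_COVARIATE_PARAMS: dict[str, dict] = {
    "age":               {"male": (55.7, 9.9), "female": (54.5, 9.6)},
    "physical_activity": {"male": (36.0, 7.4), "female": (33.4, 4.7)},
    "bmi":               {"male": (28.2, 4.1), "female": (26.7, 5.4)},
    "current_smoker":    {"male": 0.18, "female": 0.18},
    "lipid_med":         {"male": 0.10, "female": 0.06},
    "htn_med":           {"male": 0.23, "female": 0.17},
}

DEFAULT_ENERGY_PARAMS = {"male": (1992.0, 642.0), "female": (1742.0, 566.0)}

#: protein assay batch sizes observed in the source data; used as a ratio
DEFAULT_BATCH_RATIO = (821, 1092)


@dataclass(frozen=True)
class CohortSpec:
    """Configuration for one synthetic cohort draw."""

    n_participants: int
    seed: int = 0
    sex_fraction_female: float = 0.52
    n_proteins: int = 20
    n_metabolites: int = 20
    intake_params: Mapping = field(default_factory=lambda: DEFAULT_INTAKE_PARAMS)
    covariate_params: Mapping = field(default_factory=lambda: DEFAULT_COVARIATE_PARAMS)
    energy_params: Mapping = field(default_factory=lambda: DEFAULT_ENERGY_PARAMS)
    batch_sizes: tuple[int, int] | None = None
    unit_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_participants < 1:
            raise InputError("n_participants must be >= 1")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise InputError("sex_fraction_female must lie in [0, 1]")
        if self.n_proteins < 0 or self.n_metabolites < 0:
            raise InputError("marker counts must be nonnegative")
        for fld, per_sex in self.intake_params.items():
            for mean, sd in per_sex.values():
                if sd < 0:
                    raise InputError(f"negative SD for intake {fld!r}")
        for prm in self.covariate_params.values():
            for v in prm.values():
                if isinstance(v, tuple):
                    if v[1] < 0:
                        raise InputError("negative covariate SD")
                elif not 0.0 <= v <= 1.0:
                    raise InputError("prevalence must lie in [0, 1]")

    @property
    def marker_ids(self) -> dict[str, list[str]]:
        return {
            "protein": [f"P{i:04d}" for i in range(1, self.n_proteins + 1)],
            "metabolite": [f"M{i:04d}" for i in range(1, self.n_metabolites + 1)],
        }


@dataclass(frozen=True)
class PlannedEffect:
    index_name: str
    marker_id: str
    beta_per_sd: float

    def __post_init__(self):
        if self.index_name not in diet_scoring.INDEX_NAMES:
            raise ConfigurationError(f"unknown index {self.index_name!r}")


@dataclass(frozen=True)
class EffectPlan:
    """Ground-truth linear effects to plant into the marker matrices."""

    entries: tuple = ()
    null_markers: int | None = None
    noise_sd: float = 1.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        entries = tuple(
            e if isinstance(e, PlannedEffect) else PlannedEffect(*e)
            for e in self.entries
        )
        object.__setattr__(self, "entries", entries)
        keys = [(e.index_name, e.marker_id) for e in entries]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate (index, marker) entries in plan")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")

    @property
    def planted_marker_ids(self) -> set[str]:
        return {e.marker_id for e in self.entries}

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"index_name": e.index_name, "marker_id": e.marker_id,
                 "beta_per_sd": e.beta_per_sd}
                for e in self.entries
            ],
            "null_markers": self.null_markers,
            "noise_sd": self.noise_sd,
            "covariate_effects": dict(self.covariate_effects),
        }


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground-truth plan that produced them."""

    intakes: pd.DataFrame
    covariates: pd.DataFrame
    proteins: MarkerMatrix
    metabolites: MarkerMatrix
    truth: EffectPlan
    true_indices: pd.DataFrame  # standardized index values used for planting

    @property
    def participant_ids(self) -> pd.Index:
        return self.intakes.index


def _truncated_normal(rng, mean, sd, size):
    """Gaussian draw clipped at zero (intakes are nonnegative)."""
    return np.clip(rng.normal(mean, sd, size), 0.0, None)


def generate_cohort(spec: CohortSpec, plan: EffectPlan | None = None) -> SyntheticCohort:
    """Draw a complete synthetic cohort, deterministic given ``spec.seed``.

    Markers are built from the standardized diet indices computed on the
    generated intakes, so planted coefficients live on the same scale the
    association scan reports.
    """
    plan = plan or EffectPlan()
    namespace = {m for ids in spec.marker_ids.values() for m in ids}
    unknown = plan.planted_marker_ids - namespace
    if unknown:
        raise ConfigurationError(
            f"plan references unknown marker ids: {sorted(unknown)}"
        )
    if plan.null_markers is not None:
        actual_null = len(namespace) - len(plan.planted_marker_ids)
        if plan.null_markers != actual_null:
            raise ConfigurationError(
                f"plan declares {plan.null_markers} null markers but the "
                f"namespace leaves {actual_null}"
            )

    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    ids = pd.Index([f"S{i:05d}" for i in range(1, n + 1)], name="participant_id")

    n_female = int(round(n * spec.sex_fraction_female))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)
    female = sex == "female"

    # --- intakes ----------------------------------------------------------
    intakes = pd.DataFrame(index=ids)
    for fld in sorted(spec.intake_params):
        scale = spec.unit_overrides.get(fld, 1.0)
        col = np.empty(n)
        for s, mask in (("male", ~female), ("female", female)):
            mean, sd = spec.intake_params[fld][s]
            col[mask] = _truncated_normal(rng, mean * scale, sd * scale, mask.sum())
        intakes[fld] = col
    energy = np.empty(n)
    for s, mask in (("male", ~female), ("female", female)):
        mean, sd = spec.energy_params[s]
        energy[mask] = np.clip(rng.normal(mean, sd, mask.sum()), 1.0, None)
    intakes["energy_kcal"] = energy
    intakes["n_blank_items"] = 0

    # --- covariates -------------------------------------------------------
    covariates = pd.DataFrame(index=ids)
    covariates["sex"] = sex
    for fld in sorted(spec.covariate_params):
        prm = spec.covariate_params[fld]
        col = np.empty(n)
        for s, mask in (("male", ~female), ("female", female)):
            v = prm[s]
            if isinstance(v, tuple):
                col[mask] = rng.normal(v[0], v[1], mask.sum())
            else:
                col[mask] = rng.binomial(1, v, mask.sum())
        covariates[fld] = col
    covariates["energy_kcal"] = energy

    # --- true diet indices -------------------------------------------------
    scores = diet_scoring.score_all_indices(
        intakes, covariates["sex"], standardize=True
    )
    true_idx = scores[[f"{nm}_std" for nm in diet_scoring.INDEX_NAMES]]
    true_idx.columns = list(diet_scoring.INDEX_NAMES)

    # --- markers ----------------------------------------------------------
    cov_signal = np.zeros(n)
    for cov_name, coef in plan.covariate_effects.items():
        source = covariates if cov_name in covariates.columns else intakes
        if cov_name not in source.columns:
            raise ConfigurationError(f"unknown covariate {cov_name!r} in plan")
        cov_signal = cov_signal + coef * source[cov_name].to_numpy(dtype=float)

    beta_map: dict[str, dict[str, float]] = {}
    for e in plan.entries:
        beta_map.setdefault(e.marker_id, {})[e.index_name] = e.beta_per_sd

    def build_matrix(marker_ids: list[str]) -> np.ndarray:
        mat = np.empty((n, len(marker_ids)))
        for j, mid in enumerate(marker_ids):
            signal = cov_signal.copy()
            for idx_name, beta in beta_map.get(mid, {}).items():
                signal = signal + beta * true_idx[idx_name].to_numpy()
            mat[:, j] = signal + rng.normal(0.0, plan.noise_sd, n)
        return mat

    prot_ids = spec.marker_ids["protein"]
    met_ids = spec.marker_ids["metabolite"]
    prot_vals = np.exp(build_matrix(prot_ids))  # strictly positive raw scale
    met_vals = build_matrix(met_ids)

    batch = pd.Series(_batch_labels(n, spec.batch_sizes), index=ids, name="batch")
    proteins = MarkerMatrix(
        values=pd.DataFrame(prot_vals, index=ids, columns=prot_ids),
        platform="protein", batch=batch,
    ) if prot_ids else MarkerMatrix(
        values=pd.DataFrame(index=ids), platform="protein", batch=batch
    )
    metabolites = MarkerMatrix(
        values=pd.DataFrame(met_vals, index=ids, columns=met_ids),
        platform="metabolite",
    )

    return SyntheticCohort(
        intakes=intakes, covariates=covariates,
        proteins=proteins, metabolites=metabolites,
        truth=plan, true_indices=true_idx,
    )


def _batch_labels(n: int, batch_sizes: tuple[int, int] | None) -> np.ndarray:
    """Two-batch labels: explicit sizes, else deterministic alternation at
    the default batch-size ratio."""
    if batch_sizes is not None:
        n1, n2 = batch_sizes
        if n1 + n2 != n:
            raise ConfigurationError("batch sizes must sum to n_participants")
        return np.array([1] * n1 + [2] * n2)
    frac1 = DEFAULT_BATCH_RATIO[0] / sum(DEFAULT_BATCH_RATIO)
    # alternation: participant i goes to batch 1 iff adding them keeps the
    # running batch-1 fraction below frac1
    labels = np.empty(n, dtype=int)
    count1 = 0
    for i in range(n):
        if count1 < frac1 * (i + 1):
            labels[i] = 1
            count1 += 1
        else:
            labels[i] = 2
    return labels


def inject_missingness(cohort: SyntheticCohort, ffq_blank_rate: float,
                       covariate_missing_rate: float, seed: int
                       ) -> tuple[SyntheticCohort, dict]:
    """Blank out FFQ items and covariate cells at the given per-cell rates.

    Blanked FFQ items become NaN (distinguishable from true zero intake) and
    are tallied in ``n_blank_items``.  Returns the new cohort and a report of
    affected-participant counts.  Deterministic given ``seed``.
    """
    for rate in (ffq_blank_rate, covariate_missing_rate):
        if not 0.0 <= rate < 1.0:
            raise InputError("missingness rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    intakes = cohort.intakes.copy()
    covariates = cohort.covariates.copy()

    food_cols = [c for c in intakes.columns
                 if c not in ("energy_kcal", "n_blank_items")]
    blank_mask = rng.random((len(intakes), len(food_cols))) < ffq_blank_rate
    vals = intakes[food_cols].to_numpy(dtype=float)
    vals[blank_mask] = np.nan
    intakes[food_cols] = vals
    intakes["n_blank_items"] = (
        intakes["n_blank_items"].to_numpy() + blank_mask.sum(axis=1)
    )

    cov_cols = [c for c in covariates.columns if c != "sex"]
    cov_mask = rng.random((len(covariates), len(cov_cols))) < covariate_missing_rate
    cvals = covariates[cov_cols].to_numpy(dtype=float)
    cvals[cov_mask] = np.nan
    covariates[cov_cols] = cvals

    report = {
        "participants_with_ffq_blanks": int(blank_mask.any(axis=1).sum()),
        "participants_with_missing_covariates": int(cov_mask.any(axis=1).sum()),
        "ffq_cells_blanked": int(blank_mask.sum()),
        "covariate_cells_blanked": int(cov_mask.sum()),
    }
    new = SyntheticCohort(
        intakes=intakes, covariates=covariates,
        proteins=cohort.proteins, metabolites=cohort.metabolites,
        truth=cohort.truth, true_indices=cohort.true_indices,
    )
    return new, report


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write the cohort as TSV tables plus a JSON echo of the effect plan."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intakes": out / "intakes.tsv",
        "covariates": out / "covariates.tsv",
        "proteins": out / "proteins.tsv",
        "metabolites": out / "metabolites.tsv",
        "truth": out / "truth.json",
    }
    cohort.intakes.to_csv(paths["intakes"], sep="\t")
    cohort.covariates.to_csv(paths["covariates"], sep="\t")
    cohort.proteins.to_frame().to_csv(paths["proteins"], sep="\t")
    cohort.metabolites.to_frame().to_csv(paths["metabolites"], sep="\t")
    paths["truth"].write_text(json.dumps(cohort.truth.to_dict(), indent=2) + "\n")
    return paths


def load_cohort_tables(directory) -> dict:
    """Read back the tables written by :func:`write_cohort`."""
    d = Path(directory)
    read = lambda p: pd.read_csv(p, sep="\t", index_col="participant_id")
    return {
        "intakes": read(d / "intakes.tsv"),
        "covariates": read(d / "covariates.tsv"),
        "proteins": MarkerMatrix.from_frame(read(d / "proteins.tsv"), "protein"),
        "metabolites": MarkerMatrix.from_frame(read(d / "metabolites.tsv"), "metabolite"),
        "truth": json.loads((d / "truth.json").read_text()),
    }
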