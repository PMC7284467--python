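"""Diet-quality index construction: AHEI, DASH, and Mediterranean-style (MDS) scores.

Indices are described declaratively as :class:`DietIndexConfig` objects holding
one :class:`ComponentSpec` per scored food group or nutrient.  Three scoring
methods are supported:

``anchored_linear``
    Points interpolate linearly between a worst and a best intake anchor and
    are clamped to the component's point range.  Reverse-scored components
    simply place the worst anchor at the high intake.
``quintile_rank`` / ``quartile_rank``
    Points follow the participant's empirical quantile bin within the cohort
    (optionally sex-stratified), with ties assigned to the lower bin.
``alcohol_window``
    Full points inside a sex-specific moderate-consumption window, minimum
    points for over- or under-consumption; an optional separate score for
    non-drinkers.

The numeric anchors and alcohol windows shipped as defaults come from the
standard published definitions of each index; they are configuration, not
ground truth, and every value can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError, InputError, StratumError

__all__ = [
    "ComponentSpec",
    "DietIndexConfig",
    "INDEX_NAMES",
    "validate_ffq",
    "validate_ffq_table",
    "score_anchored_component",
    "quantile_rank_scores",
    "score_alcohol_window",
    "score_index",
    "score_all_indices",
    "standardize_index",
    "default_ahei_config",
    "default_dash_config",
    "default_mds_config",
    "default_config",
    "config_to_dict",
    "config_from_dict",
    "load_index_config",
    "save_index_config",
    "add_derived_fields",
    "extreme_profile",
]

INDEX_NAMES = ("AHEI", "DASH", "MDS")

_METHODS = ("anchored_linear", "quintile_rank", "quartile_rank", "alcohol_window")
_SEXES = ("male", "female")

#: FFQ validity thresholds (blank-item cap, caloric floor, per-sex caloric ceiling)
FFQ_MAX_BLANKS = 13
FFQ_MIN_KCAL = 600.0
FFQ_MAX_KCAL = {"female": 4000.0, "male": 4200.0}


def _per_sex(value):
    """Normalize an anchor/window that may be shared or per-sex into a dict."""
    if isinstance(value, Mapping):
        missing = [s for s in _SEXES if s not in value]
        if missing:
            raise ConfigurationError(f"per-sex value missing entries for {missing}")
        return {s: tuple(value[s]) for s in _SEXES}
    return {s: tuple(value) for s in _SEXES}


@dataclass(frozen=True)
class ComponentSpec:
    """Declarative definition of one index component.

    Parameters
    ----------
    name
        Component label used for the output column.
    intake_field
        Column of the intake table holding the consumed quantity.
    method
        One of ``anchored_linear``, ``quintile_rank``, ``quartile_rank``,
        ``alcohol_window``.
    direction
        ``direct`` (more is better) or ``reverse``.
    points_min, points_max
        Attainable point range.
    sex_specific
        For rank methods: compute quantile cut-points within each sex.
    anchors
        ``(worst, best)`` intake pair for ``anchored_linear``; either shared
        or a ``{"male": ..., "female": ...}`` mapping.
    window
        ``(low, high)`` g/day bounds for ``alcohol_window`` (shared or
        per-sex); intake inside the closed window earns ``points_max``.
    nondrinker_points
        Optional score for exactly-zero intake under ``alcohol_window``.
    """

    name: str
    intake_field: str
    method: str
    direction: str = "direct"
    points_min: float = 0
    points_max: float = 10
    sex_specific: bool = False
    anchors: object = None
    window: object = None
    nondrinker_points: float | None = None

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ConfigurationError(f"unknown scoring method {self.method!r}")
        if self.direction not in ("direct", "reverse"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.method == "anchored_linear":
            if self.anchors is None:
                raise ConfigurationError(
                    f"component {self.name!r}: anchored_linear requires anchors"
                )
            for worst, best in _per_sex(self.anchors).values():
                if not (np.isfinite(worst) and np.isfinite(best)) or worst == best:
                    raise ConfigurationError(
                        f"component {self.name!r}: anchors must be finite and distinct"
                    )
        elif self.anchors is not None:
            raise ConfigurationError(
                f"component {self.name!r}: anchors only valid for anchored_linear"
            )
        if self.method == "alcohol_window" and self.window is None:
            raise ConfigurationError(
                f"component {self.name!r}: alcohol_window requires a window"
            )
        if self.points_min >= self.points_max:
            raise ConfigurationError(
                f"component {self.name!r}: points_min must be < points_max"
            )

    @property
    def n_bins(self) -> int:
        if self.method == "quintile_rank":
            return 5
        if self.method == "quartile_rank":
            return 4
        raise ConfigurationError(f"{self.method} has no quantile bins")

    @property
    def bin_points(self) -> np.ndarray:
        """Ascending points awarded to bins 1..n for a *direct* component."""
        return np.linspace(self.points_min, self.points_max, self.n_bins)


@dataclass(frozen=True)
class DietIndexConfig:
    """An index as a named list of components with an expected maximum total."""

    index_name: str
    components: tuple
    expected_max: int

    def __post_init__(self):
        if self.index_name not in INDEX_NAMES:
            raise ConfigurationError(f"unknown index {self.index_name!r}")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate component names")
        total = sum(c.points_max for c in self.components)
        if total != self.expected_max:
            raise ConfigurationError(
                f"{self.index_name}: component maxima sum to {total}, "
                f"expected {self.expected_max}"
            )

    @property
    def minimum_total(self) -> float:
        return sum(c.points_min for c in self.components)


# ---------------------------------------------------------------------------
# FFQ validity filter
# ---------------------------------------------------------------------------

def validate_ffq(energy_kcal: float, n_blank_items: int, sex: str,
                 max_blanks: int = FFQ_MAX_BLANKS,
                 min_kcal: float = FFQ_MIN_KCAL,
                 max_kcal: Mapping[str, float] = FFQ_MAX_KCAL) -> tuple[bool, str]:
    """Apply the FFQ validity filter to one participant.

    A record is valid when it has fewer than ``max_blanks`` blank items and a
    plausible caloric intake: at least ``min_kcal`` and strictly below the
    sex-specific ceiling.  Returns ``(is_valid, reason)`` where ``reason``
    names the first failed rule (empty string when valid).
    """
    if sex not in max_kcal:
        raise InputError(f"unknown sex category {sex!r}")
    if pd.isna(energy_kcal) or pd.isna(n_blank_items):
        return False, "missing energy or blank-item count"
    if n_blank_items >= max_blanks:
        return False, f"blank items {n_blank_items} >= {max_blanks}"
    if energy_kcal < min_kcal:
        return False, f"energy {energy_kcal} kcal/d < {min_kcal}"
    if energy_kcal >= max_kcal[sex]:
        return False, f"energy {energy_kcal} kcal/d >= {max_kcal[sex]} ({sex})"
    return True, ""


def validate_ffq_table(intakes: pd.DataFrame, sex: pd.Series,
                       energy_field: str = "energy_kcal",
                       blanks_field: str = "n_blank_items",
                       **thresholds) -> pd.DataFrame:
    """Vectorized validity filter over a cohort intake table.

    Returns a frame indexed like ``intakes`` with boolean ``valid`` and text
    ``reason`` columns.
    """
    blanks = intakes[blanks_field] if blanks_field in intakes else pd.Series(0, index=intakes.index)
    out = []
    for pid in intakes.index:
        ok, why = validate_ffq(intakes.at[pid, energy_field], blanks.loc[pid],
                               sex.loc[pid], **thresholds)
        out.append((ok, why))
    return pd.DataFrame(out, columns=["valid", "reason"], index=intakes.index)


# ---------------------------------------------------------------------------
# Component scoring primitives
# ---------------------------------------------------------------------------

def score_anchored_component(intake, spec: ComponentSpec, sex: str = "female"):
    """Linear interpolation between worst and best anchors, clamped to range.

    Reverse scoring is expressed through anchor order (worst anchor at the
    high intake), so the same interpolation covers both directions.
    """
    if spec.method != "anchored_linear":
        raise ConfigurationError(f"{spec.name}: not an anchored_linear component")
    worst, best = _per_sex(spec.anchors)[sex]
    frac = (np.asarray(intake, dtype=float) - worst) / (best - worst)
    frac = np.clip(frac, 0.0, 1.0)
    return spec.points_min + frac * (spec.points_max - spec.points_min)


def quantile_rank_scores(intakes, n_bins: int, direction: str = "direct",
                         points_for_bins: Sequence[float] | None = None,
                         by_sex=None) -> np.ndarray:
    """Assign points by empirical quantile bin, optionally within sex strata.

    Cut-points sit at the ``i/n_bins`` empirical quantiles of the (stratum)
    sample; a value tied with a cut-point falls in the lower bin.  With
    ``direction="reverse"`` the points vector is flipped, so bin 1 earns the
    top score.  Duplicate cut-points (zero-inflated intakes) collapse bins:
    affected participants receive the lowest applicable bin's points, with a
    warning.
    """
    vals = np.asarray(intakes, dtype=float)
    if points_for_bins is None:
        raise ConfigurationError("points_for_bins is required")
    pts = np.asarray(points_for_bins, dtype=float)
    if pts.size != n_bins:
        raise ConfigurationError(
            f"points_for_bins has {pts.size} entries for {n_bins} bins"
        )
    if direction == "reverse":
        pts = pts[::-1]
    elif direction != "direct":
        raise ConfigurationError(f"unknown direction {direction!r}")
    if np.isnan(vals).any():
        raise InputError("quantile scoring requires complete intakes")

    out = np.empty(vals.shape, dtype=float)
    strata = (np.zeros(vals.shape, dtype=int) if by_sex is None
              else pd.factorize(np.asarray(by_sex))[0])
    for s in np.unique(strata):
        mask = strata == s
        sub = vals[mask]
        if sub.size < n_bins:
            raise StratumError(
                f"stratum has {sub.size} observations for {n_bins} bins"
            )
        cuts = np.quantile(sub, np.arange(1, n_bins) / n_bins)
        if np.unique(cuts).size < cuts.size:
            warnings.warn(
                "duplicate quantile cut-points; adjacent bins merged downward",
                stacklevel=2,
            )
        bins = np.searchsorted(cuts, sub, side="left")
        out[mask] = pts[bins]
    return out


def score_alcohol_window(alcohol_g_day, spec: ComponentSpec, sex: str):
    """Window scoring for alcohol: full points for moderate consumption.

    Intake inside the closed per-sex window earns ``points_max``; over- or
    under-consumption earns ``points_min``.  If ``nondrinker_points`` is set,
    exactly-zero intake earns that instead (AHEI-style partial credit).
    """
    if spec.window is None:
        raise ConfigurationError(f"{spec.name}: alcohol window not configured")
    low, high = _per_sex(spec.window)[sex]
    a = np.asarray(alcohol_g_day, dtype=float)
    if (a < 0).any():
        raise InputError("alcohol intake must be nonnegative")
    points = np.where((a >= low) & (a <= high), float(spec.points_max),
                      float(spec.points_min))
    if spec.nondrinker_points is not None:
        points = np.where(a == 0, float(spec.nondrinker_points), points)
    return points


# ---------------------------------------------------------------------------
# Whole-index scoring
# ---------------------------------------------------------------------------

#: derived intake columns synthesized on demand from their addends
DERIVED_FIELDS = {
    "nuts_legumes": ("nuts", "legumes"),
    "fruits_juice": ("fruits", "fruit_juice"),
}


def add_derived_fields(intakes: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the standard derived sum columns filled in."""
    out = intakes.copy()
    for name, addends in DERIVED_FIELDS.items():
        if name not in out.columns and all(a in out.columns for a in addends):
            out[name] = sum(out[a] for a in addends)
    return out


def score_index(intakes: pd.DataFrame, config: DietIndexConfig,
                sex: pd.Series | None = None) -> pd.DataFrame:
    """Score every participant on one index.

    Returns a frame indexed by participant with one column per component plus
    a ``total`` column.  Rank-based components are scored against the cohort
    in ``intakes`` (so the table must be the full analysis sample); anchored
    components are scored row-wise.
    """
    intakes = add_derived_fields(intakes)
    needs_sex = any(
        c.sex_specific or c.method == "alcohol_window"
        or (c.method == "anchored_linear" and isinstance(c.anchors, Mapping))
        for c in config.components
    )
    if needs_sex and sex is None:
        raise InputError(f"{config.index_name}: sex vector required")
    if sex is not None:
        sex = sex.reindex(intakes.index)
        bad = set(sex.dropna().unique()) - set(_SEXES)
        if bad or sex.isna().any():
            raise InputError(f"unrecognized sex categories: {sorted(bad)}")

    result = pd.DataFrame(index=intakes.index)
    for comp in config.components:
        if comp.intake_field not in intakes.columns:
            raise InputError(
                f"{config.index_name}: intake field {comp.intake_field!r} absent"
            )
        col = intakes[comp.intake_field]
        if comp.method == "anchored_linear":
            if isinstance(comp.anchors, Mapping):
                pts = np.empty(len(col))
                for s in _SEXES:
                    m = (sex == s).to_numpy()
                    pts[m] = score_anchored_component(col.to_numpy()[m], comp, s)
            else:
                pts = score_anchored_component(col.to_numpy(), comp)
        elif comp.method in ("quintile_rank", "quartile_rank"):
            pts = quantile_rank_scores(
                col.to_numpy(), comp.n_bins, comp.direction,
                comp.bin_points, by_sex=sex if comp.sex_specific else None,
            )
        else:  # alcohol_window
            pts = np.empty(len(col))
            for s in _SEXES:
                m = (sex == s).to_numpy()
                pts[m] = score_alcohol_window(col.to_numpy()[m], comp, s)
        result[comp.name] = pts
    result["total"] = result.sum(axis=1)

    lo, hi = config.minimum_total, config.expected_max
    tot = result["total"]
    if ((tot < lo - 1e-9) | (tot > hi + 1e-9)).any():
        raise ConfigurationError(
            f"{config.index_name}: totals escaped [{lo}, {hi}]"
        )
    return result


def score_all_indices(intakes: pd.DataFrame, sex: pd.Series,
                      configs: Mapping[str, DietIndexConfig] | None = None,
                      standardize: bool = True) -> pd.DataFrame:
    """Score AHEI, DASH, and MDS; return totals (and standardized totals)."""
    configs = configs or {n: default_config(n) for n in INDEX_NAMES}
    out = pd.DataFrame(index=intakes.index)
    for name, cfg in configs.items():
        totals = score_index(intakes, cfg, sex)["total"]
        out[name] = totals
        if standardize:
            out[f"{name}_std"] = standardize_index(totals.to_numpy())
    return out


def standardize_index(totals) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (ddof=1)."""
    x = np.asarray(totals, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateDataError("cannot standardize a constant score vector")
    return (x - x.mean()) / x.std(ddof=1)


# ---------------------------------------------------------------------------
# Shipped default index definitions
# ---------------------------------------------------------------------------

def default_ahei_config() -> DietIndexConfig:
    """Eleven-component AHEI, each worth 0-10 points (max 110).

    Anchors follow the published AHEI-2010 criteria, translated to the
    food-group units of the intake table; they are overridable defaults.
    Sugar-sweetened beverages and fruit juice, trans fat, and sodium are
    reverse-scored.  Alcohol uses a moderate-consumption window with partial
    credit for non-drinkers.
    """
    c = ComponentSpec
    return DietIndexConfig(
        index_name="AHEI",
        expected_max=110,
        components=(
            c("vegetables", "vegetables", "anchored_linear", anchors=(0.0, 5.0)),
            c("fruits", "fruits", "anchored_linear", anchors=(0.0, 4.0)),
            c("whole_grains", "whole_grains", "anchored_linear",
              sex_specific=True,
              anchors={"male": (0.0, 2.5), "female": (0.0, 2.0)}),
            c("nuts_legumes", "nuts_legumes", "anchored_linear", anchors=(0.0, 1.0)),
            c("omega3", "omega3_mg", "anchored_linear", anchors=(0.0, 250.0)),
            c("pufa", "pufa_pct", "anchored_linear", anchors=(2.0, 10.0)),
            c("ssb_fruit_juice", "ssb_fruit_juice", "anchored_linear",
              direction="reverse", anchors=(1.0, 0.0)),
            c("red_processed_meat", "red_processed_meat", "anchored_linear",
              direction="reverse", anchors=(1.5, 0.0)),
            c("trans_fat", "trans_pct", "anchored_linear",
              direction="reverse", anchors=(4.0, 0.5)),
            c("sodium", "sodium_mg", "anchored_linear",
              direction="reverse", anchors=(3400.0, 1100.0)),
            c("alcohol", "alcohol_g_day", "alcohol_window",
              points_min=0, points_max=10, nondrinker_points=2.5,
              window={"male": (7.0, 28.0), "female": (7.0, 21.0)}),
        ),
    )


def default_dash_config() -> DietIndexConfig:
    """Eight-component DASH score, quintile-based 1-5 points each (max 40).

    Quintiles are computed on the full analysis sample (not sex-stratified).
    Sodium, red and processed meats, and sugar-sweetened beverages are
    reverse-scored.
    """
    def c(name, fld, direction="direct"):
        return ComponentSpec(name, fld, "quintile_rank", direction=direction,
                             points_min=1, points_max=5)

    return DietIndexConfig(
        index_name="DASH",
        expected_max=40,
        components=(
            c("fruits_juice", "fruits_juice"),
            c("vegetables", "vegetables"),
            c("nuts_legumes", "nuts_legumes"),
            c("whole_grains", "whole_grains"),
            c("low_fat_dairy", "low_fat_dairy"),
            c("sodium", "sodium_mg", direction="reverse"),
            c("red_processed_meat", "red_processed_meat", direction="reverse"),
            c("ssb", "ssb", direction="reverse"),
        ),
    )


def default_mds_config() -> DietIndexConfig:
    """Mediterranean-style score: eight sex-specific quartile components
    scored 0-3 (red meat reverse-scored) plus a 0/1 moderate-alcohol
    component, for a maximum of 25.

    The moderate-alcohol window defaults (women 5-15 g/day, men 10-25 g/day)
    come from the cited Mediterranean-score literature and are configurable.
    """
    def c(name, fld, direction="direct"):
        return ComponentSpec(name, fld, "quartile_rank", direction=direction,
                             points_min=0, points_max=3, sex_specific=True)

    return DietIndexConfig(
        index_name="MDS",
        expected_max=25,
        components=(
            c("vegetables", "vegetables"),
            c("fruits", "fruits"),
            c("nuts", "nuts"),
            c("legumes", "legumes"),
            c("whole_grains", "whole_grains"),
            c("fish", "fish"),
            c("red_meat", "red_processed_meat", direction="reverse"),
            c("mufa_sfa", "mufa_sfa_ratio"),
            ComponentSpec("alcohol", "alcohol_g_day", "alcohol_window",
                          points_min=0, points_max=1,
                          window={"male": (10.0, 25.0), "female": (5.0, 15.0)}),
        ),
    )


def config_to_dict(config: DietIndexConfig) -> dict:
    """Plain-dict form of an index config, suitable for YAML/JSON dumping."""
    comps = []
    for c in config.components:
        d = {"name": c.name, "intake_field": c.intake_field,
             "method": c.method, "direction": c.direction,
             "points_min": c.points_min, "points_max": c.points_max,
             "sex_specific": c.sex_specific}
        if c.anchors is not None:
            d["anchors"] = ({s: list(v) for s, v in c.anchors.items()}
                            if isinstance(c.anchors, Mapping)
                            else list(c.anchors))
        if c.window is not None:
            d["window"] = ({s: list(v) for s, v in c.window.items()}
                           if isinstance(c.window, Mapping)
                           else list(c.window))
        if c.nondrinker_points is not None:
            d["nondrinker_points"] = c.nondrinker_points
        comps.append(d)
    return {"index_name": config.index_name,
            "expected_max": config.expected_max,
            "components": comps}


def config_from_dict(data: Mapping) -> DietIndexConfig:
    """Inverse of :func:`config_to_dict`; validates on construction."""
    try:
        comps = tuple(ComponentSpec(**c) for c in data["components"])
        return DietIndexConfig(index_name=data["index_name"],
                               components=comps,
                               expected_max=data["expected_max"])
    except (KeyError, TypeError) as err:
        raise ConfigurationError(f"bad index config: {err}") from err


def load_index_config(path) -> DietIndexConfig:
    """Read a YAML index definition from disk."""
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_index_config(config: DietIndexConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def default_config(index_name: str) -> DietIndexConfig:
    try:
        return {
            "AHEI": default_ahei_config,
            "DASH": default_dash_config,
            "MDS": default_mds_config,
        }[index_name]()
    except KeyError:
        raise ConfigurationError(f"unknown index {index_name!r}") from None


# ---------------------------------------------------------------------------
# Adversarial profile construction (testing / acceptance aid)
# ---------------------------------------------------------------------------

def extreme_profile(config: DietIndexConfig, which: str = "best",
                    sex: str = "female",
                    reference: pd.DataFrame | None = None) -> dict:
    """Build an intake row attaining the best or worst possible score.

    Anchored components take their best/worst anchor; window components take
    the window midpoint (best) or an over-consumption value (worst); rank
    components take a value beyond the favorable/unfavorable extreme of the
    ``reference`` cohort (required when the config has rank components).
    """
    if which not in ("best", "worst"):
        raise InputError("which must be 'best' or 'worst'")
    row: dict = {}
    for comp in config.components:
        if comp.method == "anchored_linear":
            worst, best = _per_sex(comp.anchors)[sex]
            row[comp.intake_field] = best if which == "best" else worst
        elif comp.method == "alcohol_window":
            low, high = _per_sex(comp.window)[sex]
            row[comp.intake_field] = (
                (low + high) / 2 if which == "best" else high + max(10.0, high)
            )
        else:
            if reference is None:
                raise InputError(
                    "rank-scored components need a reference cohort"
                )
            ref = add_derived_fields(reference)[comp.intake_field]
            favorable_high = (comp.direction == "direct") == (which == "best")
            row[comp.intake_field] = (
                float(ref.max()) + 1.0 if favorable_high else
                max(0.0, float(ref.min()) - 1.0)
            )
    # undo derived sums so the row can be appended to a raw intake table
    for name, addends in DERIVED_FIELDS.items():
        if name in row:
            val = row.pop(name)
            first, *rest = addends
            row[first] = val
            for a in rest:
                row.setdefault(a, 0.0)
    return row
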