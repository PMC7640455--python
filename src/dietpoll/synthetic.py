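"""Synthetic DHS-like household tables with known treatment and outcome models.

The generator emulates the structure of a 24-h-recall child-nutrition
survey: ten integer-coded covariates (child age band, young sibling,
mother's work and education, wealth quintile, urban/rural location, land
use, length of growing period, farming system, terrain slope), a probit
treatment-assignment model for inadequate diet diversity whose
coefficient pattern follows the gradients typically estimated on such
data (less diverse diets for younger children, uneducated mothers, poorer
and rural households), an additive-risk stunting model with optional
profile-specific planted effects ``tau_x``, and 13 recall item flags drawn
consistently with the assigned diet class so the CDDS module reproduces
it exactly on a round trip.

Because treatment assignment and every ``tau_x`` are known, each pipeline
stage can be tested against its true value without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cdds import CddsMapping, DEFAULT_ADEQUACY_THRESHOLD
from .codebook import Variable, VariableCodebook
from .data import HouseholdTable
from .polling import Profile

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20151104


@dataclass(frozen=True)
class CovariateSpec:
    labels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.probs):
            raise ValueError("labels and probs must align")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(self.probs)}")


def _default_covariates() -> dict[str, CovariateSpec]:
    return {
        "child_age_band": CovariateSpec(("6-12m", "13-25m"), (0.35, 0.65)),
        "has_young_sibling": CovariateSpec(("no", "yes"), (0.5, 0.5)),
        "mother_working": CovariateSpec(("not_working", "working"), (0.55, 0.45)),
        "mother_education": CovariateSpec(
            ("none", "primary", "secondary", "tertiary"), (0.10, 0.35, 0.45, 0.10)),
        "wealth_quintile": CovariateSpec(
            ("q1_poorest", "q2", "q3", "q4", "q5_richest"), (0.2, 0.2, 0.2, 0.2, 0.2)),
        "location": CovariateSpec(("rural", "urban"), (0.65, 0.35)),
        "land_use": CovariateSpec(
            ("cultivated", "forest_barren", "grass_wood", "built_up", "associations"),
            (0.30, 0.20, 0.25, 0.15, 0.10)),
        "growing_period": CovariateSpec(
            ("0-75d", "76-120d", "121-180d", ">180d"), (0.15, 0.35, 0.35, 0.15)),
        "farming_system": CovariateSpec(
            ("highland_temperate", "root_crop", "maize_mixed", "commercial_pastoral",
             "agropastoral"), (0.10, 0.15, 0.45, 0.15, 0.15)),
        "slope": CovariateSpec(("0-8deg", "8-30deg", ">30deg"), (0.50, 0.35, 0.15)),
    }


def _default_treatment_coefs() -> dict[str, tuple[float, ...]]:
    # probit index contributions per category (first category = 0);
    # signs follow the usual gradients: treated = inadequate diversity
    return {
        "child_age_band": (0.0, -0.30),
        "has_young_sibling": (0.0, 0.15),
        "mother_working": (0.0, -0.25),
        "mother_education": (0.0, -0.50, -0.60, -0.80),
        "wealth_quintile": (0.0, -0.10, -0.25, -0.40, -0.40),
        "location": (0.0, -0.30),
        "land_use": (0.0, -0.55, -0.45, -0.55, -0.55),
        "growing_period": (0.0, -0.05, -0.08, 0.05),
        "farming_system": (0.0, 0.25, 0.05, 0.40, 0.10),
        "slope": (0.0, -0.05, -0.15),
    }


def _default_outcome_coefs() -> dict[str, tuple[float, ...]]:
    # additive stunting-risk contributions on the probability scale
    return {
        "mother_education": (0.05, 0.02, 0.0, -0.03),
        "wealth_quintile": (0.05, 0.02, 0.0, -0.02, -0.04),
        "location": (0.02, -0.02),
        "child_age_band": (-0.02, 0.02),
    }


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the scale of the survey the method targets: roughly
    1600 children aged 6-25 months, about 70% with inadequate diet
    diversity, baseline stunting risk near 0.2, unit observation masses
    and no planted treatment effect.
    """

    n: int = 1613
    seed: int = DEFAULT_SEED
    covariates: dict[str, CovariateSpec] = field(default_factory=_default_covariates)
    treatment_intercept: float = 2.0
    treatment_coefs: dict[str, tuple[float, ...]] = field(default_factory=_default_treatment_coefs)
    day_coef: float = 0.0                  # probit-index trend per interview day
    n_days: int = 150
    baseline_stunting: float = 0.20
    outcome_coefs: dict[str, tuple[float, ...]] = field(default_factory=_default_outcome_coefs)
    effects: tuple[tuple[Profile, float], ...] = ()   # planted (profile, tau) pairs
    weight_sigma: float = 0.0              # 0 => unit weights, else lognormal(0, sigma)
    age_range: tuple[int, int] = (6, 25)
    adequacy_threshold: int = DEFAULT_ADEQUACY_THRESHOLD
    include_items: bool = True             # emit the 13 recall item flags

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, spec in self.covariates.items():
            if name in self.treatment_coefs and len(self.treatment_coefs[name]) != len(spec.labels):
                raise ValueError(f"treatment coefs for {name} mismatch category count")
            if name in self.outcome_coefs and len(self.outcome_coefs[name]) != len(spec.labels):
                raise ValueError(f"outcome coefs for {name} mismatch category count")
        for prof, _tau in self.effects:
            for var, val in zip(prof.variables, prof.values):
                if var not in self.covariates:
                    raise ValueError(f"effect profile references unknown variable {var!r}")
                if not 0 <= val < len(self.covariates[var].labels):
                    raise ValueError(f"effect profile value {val} invalid for {var!r}")

    def with_effects(self, effects: Sequence[tuple[Profile, float]]) -> "SyntheticConfig":
        return replace(self, effects=tuple(effects))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("n", "seed", "treatment_intercept", "day_coef", "n_days",
                    "baseline_stunting", "weight_sigma", "adequacy_threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        if "age_range" in raw:
            kwargs["age_range"] = tuple(raw["age_range"])
        if "covariates" in raw:
            kwargs["covariates"] = {
                name: CovariateSpec(tuple(e["labels"]), tuple(e["probs"]))
                for name, e in raw["covariates"].items()
            }
        for key in ("treatment_coefs", "outcome_coefs"):
            if key in raw:
                kwargs[key] = {k: tuple(v) for k, v in raw[key].items()}
        if "effects" in raw:
            kwargs["effects"] = tuple(
                (Profile(tuple(e["variables"]), tuple(e["values"])), float(e["tau"]))
                for e in raw["effects"]
            )
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def build_codebook(config: SyntheticConfig | None = None,
                   mapping: CddsMapping | None = None) -> VariableCodebook:
    """Codebook for a synthetic table: covariates plus binary item flags."""
    config = config or SyntheticConfig()
    mapping = mapping or CddsMapping.default()
    cb = VariableCodebook()
    for name, spec in config.covariates.items():
        cb.add(Variable(name=name, labels=spec.labels, role="covariate"))
    for item in mapping.items:
        cb.add(Variable(name=item, labels=("no", "yes"), role="item-flag"))
    return cb


def _draw_item_flags(rng: np.random.Generator, cdds: np.ndarray,
                     mapping: CddsMapping) -> pd.DataFrame:
    """Item flags whose group collapse reproduces each record's CDDS."""
    items_by_class: dict[int, list[str]] = {}
    for item, cls in mapping.item_to_class.items():
        items_by_class.setdefault(cls, []).append(item)
    classes = sorted(items_by_class)
    n = len(cdds)
    flags = {item: np.zeros(n, dtype=int) for item in mapping.items}
    for i in range(n):
        chosen = rng.choice(classes, size=int(cdds[i]), replace=False)
        for cls in chosen:
            pool = items_by_class[int(cls)]
            # at least one item of the group; extras at random
            on = rng.random(len(pool)) < 0.3
            on[rng.integers(len(pool))] = True
            for item, is_on in zip(pool, on):
                if is_on:
                    flags[item][i] = 1
    return pd.DataFrame(flags)


def generate(config: SyntheticConfig | None = None,
             seed: int | None = None) -> HouseholdTable:
    """Draw a household table from the configured data-generating process.

    Treatment is ``1{x'b + day trend + eps > 0}`` with standard-normal
    ``eps``; stunting is Bernoulli with probability ``baseline + covariate
    contributions + tau_x * treated`` inside each planted-effect profile,
    clipped to [0, 1] (an error is raised if more than 5% of records clip).
    Bit-identical output for identical ``(config, seed)``.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mapping = CddsMapping.default()
    n = config.n

    cols: dict[str, np.ndarray] = {}
    age_lo, age_hi = config.age_range
    cols["child_age_months"] = rng.integers(age_lo, age_hi + 1, size=n)
    cols["interview_day"] = rng.integers(0, config.n_days, size=n)
    for name, spec in config.covariates.items():
        if name == "child_age_band" and set(spec.labels) == {"6-12m", "13-25m"}:
            cols[name] = (cols["child_age_months"] > 12).astype(int)
        else:
            cols[name] = rng.choice(len(spec.labels), size=n, p=spec.probs)

    index = np.full(n, config.treatment_intercept, dtype=float)
    for name, coefs in config.treatment_coefs.items():
        if name in cols:
            index += np.asarray(coefs, dtype=float)[cols[name]]
    if config.day_coef:
        day = cols["interview_day"].astype(float)
        index += config.day_coef * (day - day.mean())
    treated = (index + rng.standard_normal(n) > 0).astype(int)

    p_stunt = np.full(n, config.baseline_stunting, dtype=float)
    for name, coefs in config.outcome_coefs.items():
        if name in cols:
            p_stunt += np.asarray(coefs, dtype=float)[cols[name]]
    df_cov = pd.DataFrame(cols)
    for prof, tau in config.effects:
        member = np.ones(n, dtype=bool)
        for var, val in zip(prof.variables, prof.values):
            member &= df_cov[var].to_numpy() == val
        p_stunt += tau * treated * member

    clipped = (p_stunt < 0) | (p_stunt > 1)
    if clipped.mean() > 0.05:
        raise ValueError(
            f"{100 * clipped.mean():.1f}% of stunting probabilities fall outside "
            "[0, 1]; re-specify baseline, outcome coefficients or effects"
        )
    if clipped.any():
        logger.info("clipped %d stunting probabilities into [0, 1]", int(clipped.sum()))
    p_stunt = np.clip(p_stunt, 0.0, 1.0)
    stunting = (rng.random(n) < p_stunt).astype(int)

    # CDDS consistent with the assigned class: treated <= threshold < control
    thr = config.adequacy_threshold
    cdds = np.where(
        treated == 1,
        rng.choice(np.arange(0, thr + 1), size=n, p=_cdds_probs(thr + 1)),
        rng.choice(np.arange(thr + 1, 8), size=n, p=_cdds_probs(7 - thr)),
    )
    items = _draw_item_flags(rng, cdds, mapping) if config.include_items else None

    if config.weight_sigma > 0:
        weight = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    else:
        weight = np.ones(n)

    df = pd.DataFrame({
        "id": [f"hh{i:06d}" for i in range(n)],
        "weight": weight,
        **cols,
        "diet_class": treated,
        "cdds": cdds,
        "stunting": stunting,
    })
    if items is not None:
        df = pd.concat([df, items], axis=1)
    table = HouseholdTable(df, build_codebook(config, mapping))
    table.validate()
    return table


def _cdds_probs(k: int) -> np.ndarray:
    """Mildly peaked score distribution over k adjacent CDDS values."""
    base = np.array([0.15, 0.30, 0.35, 0.20, 0.10, 0.05, 0.03, 0.02])[:k]
    return base / base.sum()


def true_treatment_probability(config: SyntheticConfig, table: HouseholdTable) -> np.ndarray:
    """Model-implied P(treated | x) for each record (the generator's truth)."""
    from scipy.stats import norm

    index = np.full(len(table), config.treatment_intercept, dtype=float)
    for name, coefs in config.treatment_coefs.items():
        if name in table.df.columns:
            index += np.asarray(coefs, dtype=float)[table.df[name].to_numpy()]
    if config.day_coef:
        day = table.df["interview_day"].to_numpy(dtype=float)
        index += config.day_coef * (day - day.mean())
    return norm.cdf(index)


# ----------------------------------------------------------------------
# deterministic toy fixture
# ----------------------------------------------------------------------
_TOY_ROWS = [
    # id, weight, region, wealth, diet_class, stunting
    ("h01", 1.0, 0, 0, 1, 1),
    ("h02", 1.0, 0, 0, 1, 0),
    ("h03", 2.0, 0, 1, 1, 1),
    ("h04", 1.0, 0, 1, 0, 0),
    ("h05", 1.0, 0, 0, 0, 1),
    ("h06", 2.0, 1, 0, 1, 0),
    ("h07", 1.0, 1, 0, 1, 1),
    ("h08", 1.0, 1, 1, 0, 0),
    ("h09", 1.0, 1, 1, 0, 0),
    ("h10", 2.0, 1, 0, 1, 0),
    ("h11", 1.0, 1, 1, 1, 0),
    ("h12", 1.0, 0, 1, 0, 1),
]


def toy_fixture() -> HouseholdTable:
    """A fixed 12-record table with hand-computable metrics.

    Two binary covariates (region: north/south, wealth: poor/rich), mixed
    unit and double masses, total mass 15 and treated mass 10.  Regenerated
    identically on every call; the expected polling and impact numbers live
    beside the unit tests.
    """
    cb = VariableCodebook.from_variables([
        Variable("region", ("north", "south"), "covariate"),
        Variable("wealth", ("poor", "rich"), "covariate"),
    ])
    df = pd.DataFrame(
        _TOY_ROWS, columns=["id", "weight", "region", "wealth", "diet_class", "stunting"]
    )
    df["child_age_months"] = 12
    df["interview_day"] = 0
    table = HouseholdTable(df, cb)
    table.validate()
    return table
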