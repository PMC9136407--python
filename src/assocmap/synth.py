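"""Seeded synthetic longitudinal cohorts with planted, optionally
confounded, effects.

The generator emulates the structure of a longitudinal infant cohort:
~160 subjects sampled at 6 visits over the first year of life, a binary
disease status, a binary probiotic-use variable whose probability depends
on disease (the confounding channel), delivery mode, a 3-level diet, and
a continuous age at visit. Feature abundances are built on the arcsine
square-root (AST) scale — baseline + planted fixed effects + a
per-subject random intercept + Gaussian noise, clamped to [0, π/2] — and
back-transformed by sin² to relative abundances. An explicit
``unassigned`` remainder feature completes each sample to a composition
summing to exactly 1, so the analysis-side TSS step is the identity and
planted AST-scale coefficients are directly comparable to fitted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .associations import ModelSpec
from .schema import CATEGORICAL, CONTINUOUS, VariableSchema
from .tables import SampleTable

HALF_PI = math.pi / 2

SUBJECT = "subject_id"
DISEASE = "disease"
PROBIOTICS = "probiotics_use"
DELIVERY = "delivery_mode"
DIET = "diet"
AGE = "visit_age_mo"

_CATEGORICAL_LEVELS = {
    DISEASE: ["case", "control"],
    PROBIOTICS: ["Pro+", "Pro-"],
    DELIVERY: ["C-section", "vaginal"],
    DIET: ["breastfed", "formula", "mixed"],
}
_EFFECT_VARIABLES = {DISEASE, PROBIOTICS, DELIVERY, DIET, AGE}

REMAINDER_FEATURE = "unassigned"


@dataclass(frozen=True)
class Effect:
    """A planted AST-scale effect of one variable on one feature.

    For a categorical variable the coefficient is added to samples whose
    value equals ``level``; for the continuous age variable ``level`` is
    None and the contribution is ``coefficient * age``.
    """

    variable: str
    level: str | None
    coefficient: float


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of one synthetic cohort."""

    n_subjects: int = 160
    visits_per_subject: int = 6
    n_features: int = 50
    disease_prevalence: float = 0.5
    probiotic_given_disease: float = 0.6
    probiotic_given_healthy: float = 0.1
    effects: Mapping[str, tuple[Effect, ...]] = field(default_factory=dict)
    subject_sd: float = 0.02
    noise_sd: float = 0.03
    baseline_range: tuple[float, float] = (0.06, 0.12)
    diet_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    age_spacing_months: float = 2.0
    age_jitter_sd: float = 0.2
    missing_probiotic_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("disease_prevalence", "probiotic_given_disease",
                     "probiotic_given_healthy", "missing_probiotic_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for feat, effs in self.effects.items():
            for eff in effs:
                if eff.variable not in _EFFECT_VARIABLES:
                    raise ValueError(
                        f"effect on {feat!r} references unknown variable {eff.variable!r}"
                    )
                if not math.isfinite(eff.coefficient):
                    raise ValueError(f"non-finite effect coefficient on {feat!r}")


def feature_name(j: int) -> str:
    return f"g__taxon_{j:02d}"


def cohort_schema() -> VariableSchema:
    """The variable schema matching generated cohorts.

    Subject ID is the single random (grouping) variable; disease uses the
    explicit reference "control" (the alphabetical default would be
    "case"), probiotics "Pro-" (alphabetically "+" sorts first).
    """
    return VariableSchema(
        sample_id_col="sample_id",
        random_vars=(SUBJECT,),
        fixed_vars={
            DISEASE: CATEGORICAL,
            PROBIOTICS: CATEGORICAL,
            DELIVERY: CATEGORICAL,
            DIET: CATEGORICAL,
            AGE: CONTINUOUS,
        },
        level_order={k: list(v) for k, v in _CATEGORICAL_LEVELS.items()},
        reference={
            DISEASE: "control",
            PROBIOTICS: "Pro-",
            DELIVERY: "C-section",
            DIET: "breastfed",
        },
    )


def case_study_models(
    ast_enabled: bool = True, random: tuple[str, ...] = (SUBJECT,)
) -> list[ModelSpec]:
    """The three nested candidate models of the cohort walkthrough:
    basic (disease + delivery + age), basic + diet, basic + diet +
    probiotics."""
    basic = ModelSpec(
        name="basic", fixed=(DISEASE, DELIVERY, AGE), random=random,
        ast_enabled=ast_enabled,
    )
    with_diet = ModelSpec(
        name="basic_diet", fixed=(DISEASE, DELIVERY, AGE, DIET), random=random,
        ast_enabled=ast_enabled,
    )
    with_pro = ModelSpec(
        name="basic_diet_pro",
        fixed=(DISEASE, DELIVERY, AGE, DIET, PROBIOTICS), random=random,
        ast_enabled=ast_enabled,
    )
    return [basic, with_diet, with_pro]


def generate_cohort(config: CohortConfig) -> tuple[SampleTable, pd.DataFrame]:
    """Generate one cohort; returns the table and the ground-truth record.

    The truth frame has one row per planted effect: feature, variable,
    level ("" for age), coefficient — directly comparable to the fitted
    coefficients of :func:`assocmap.associations.run_model` on the same
    table. Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    ns, nv = config.n_subjects, config.visits_per_subject
    n = ns * nv
    nf = config.n_features

    disease = np.where(rng.random(ns) < config.disease_prevalence, "case", "control")
    p_pro = np.where(disease == "case",
                     config.probiotic_given_disease, config.probiotic_given_healthy)
    probiotics = np.where(rng.random(ns) < p_pro, "Pro+", "Pro-").astype(object)
    probiotics[rng.random(ns) < config.missing_probiotic_rate] = np.nan
    delivery = np.where(rng.random(ns) < 0.5, "vaginal", "C-section")

    subj_idx = np.repeat(np.arange(ns), nv)
    visit = np.tile(np.arange(1, nv + 1), ns)
    age = visit * config.age_spacing_months + rng.normal(0, config.age_jitter_sd, n)
    diet = rng.choice(_CATEGORICAL_LEVELS[DIET], size=n, p=config.diet_probs)

    baseline = rng.uniform(*config.baseline_range, nf)
    intercepts = rng.normal(0, config.subject_sd, (ns, nf))
    noise = rng.normal(0, config.noise_sd, (n, nf))

    z = baseline[None, :] + intercepts[subj_idx] + noise
    sample_values = {DISEASE: disease[subj_idx], PROBIOTICS: probiotics[subj_idx],
                     DELIVERY: delivery[subj_idx], DIET: diet}
    names = [feature_name(j) for j in range(nf)]
    col_of = {name: j for j, name in enumerate(names)}
    truth_rows = []
    for feat, effs in config.effects.items():
        if feat not in col_of:
            raise ValueError(f"effect on unknown feature {feat!r}")
        for eff in effs:
            if eff.variable == AGE:
                z[:, col_of[feat]] += eff.coefficient * age
            else:
                hit = sample_values[eff.variable] == eff.level
                z[:, col_of[feat]] += eff.coefficient * hit.astype(float)
            truth_rows.append(
                {"feature": feat, "variable": eff.variable,
                 "level": eff.level or "", "coefficient": eff.coefficient}
            )

    z = np.clip(z, 0.0, HALF_PI)
    abund = np.sin(z) ** 2
    remainder = 1.0 - abund.sum(axis=1)
    over = remainder < 0
    if over.any():  # planted features alone exceed the simplex: renormalize
        abund[over] /= abund[over].sum(axis=1, keepdims=True)
        remainder[over] = 0.0

    sample_ids = [f"S{subj_idx[i]:03d}_V{visit[i]}" for i in range(n)]
    index = pd.Index(sample_ids, name="sample_id")
    metadata = pd.DataFrame(
        {
            SUBJECT: [f"subj_{i:03d}" for i in subj_idx],
            DISEASE: sample_values[DISEASE],
            PROBIOTICS: sample_values[PROBIOTICS],
            DELIVERY: sample_values[DELIVERY],
            DIET: sample_values[DIET],
            AGE: age,
        },
        index=index,
    )
    features = pd.DataFrame(abund, index=index, columns=names)
    features[REMAINDER_FEATURE] = remainder
    table = SampleTable(metadata=metadata, features=features, sample_id_col="sample_id")
    truth = pd.DataFrame(truth_rows,
                         columns=["feature", "variable", "level", "coefficient"])
    return table, truth


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """A cohort with no planted effects and no between-subject variance:
    every feature is independent of every metadata variable."""
    return CohortConfig(seed=seed, effects={}, subject_sd=0.0, **overrides)


def recovery_config(seed: int = 0, effect_size: float = 0.10) -> CohortConfig:
    """Planted effects on three features for parameter-recovery studies."""
    effects = {
        feature_name(5): (Effect(DISEASE, "case", effect_size),),
        feature_name(12): (Effect(DIET, "formula", effect_size),),
        feature_name(23): (Effect(AGE, None, effect_size / 25.0),),
    }
    return CohortConfig(seed=seed, effects=effects)


def confounder_config(seed: int = 0, effect_size: float = 0.3) -> CohortConfig:
    """A single probiotic-driven feature in a confounded cohort."""
    effects = {feature_name(0): (Effect(PROBIOTICS, "Pro+", effect_size),)}
    return CohortConfig(seed=seed, effects=effects)


def confounder_scenario(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[SampleTable, pd.DataFrame, dict]:
    """Generate the confounded cohort plus its expected qualitative outcome.

    One feature carries a true probiotic effect while probiotic use is
    correlated with disease. The expectation record states what the model
    comparison should show: in a model *without* probiotics the feature is
    significant on disease (the confounder picks up the signal); adding
    probiotics moves the significance onto probiotics and inflates the
    disease q-value.
    """
    if config is None:
        config = confounder_config(seed=seed)
    effs = [
        (f, e) for f, el in config.effects.items() for e in el
        if e.variable == PROBIOTICS
    ]
    if not effs:
        raise ValueError("confounder scenario requires a planted probiotic effect")
    feature = effs[0][0]
    table, truth = generate_cohort(config)
    expectation = {
        "feature": feature,
        "confounded_variable": DISEASE,
        "true_variable": PROBIOTICS,
        "true_level": "Pro+",
        "model_without": "basic",
        "model_with": "basic_diet_pro",
        "q_threshold": 0.2,
    }
    return table, truth, expectation
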