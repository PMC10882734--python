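"""Synthetic survey respondents from a known factor-model + logit DGP.

Each respondent carries sociodemographic covariates drawn from configurable
marginal distributions, latent preference-factor scores ``f ~ N(0, I_K)``
per illness scenario, 12 preference-item ratings ``x = Λ f + ε`` discretised
to a 1–5 Likert scale, and provider choices drawn from a baseline-category
multinomial logit on covariates and factor scores. Because Λ, the noise, and
every logit coefficient are known, downstream PCA and choice models can be
validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from carecov.geojson import Feature

#: the 12 rated preference items, in reporting order
PREFERENCE_ITEMS = [
    "distance_from_home",
    "waiting_time",
    "hospitality",
    "environment",
    "involved_in_decision_making",
    "improvement_after_first_visit",
    "cost_to_get_treatment",
    "insurance_eligibility",
    "good_medical_equipment",
    "personal_preference",
    "trusted_service_personnel",
    "family_recommendation",
]

#: choice scenarios: the habitual ("actual") choice plus three hypothetical
#: illness severities
SCENARIOS = ["actual", "mild", "chronic", "serious"]

#: per-scenario choice sets; the habitual and serious scenarios are binary
#: (pharmacy/self-medication collapse away for serious illness)
SCENARIO_CATEGORIES = {
    "actual": ["bpjs_partner", "non_bpjs_partner"],
    "mild": ["bpjs_partner", "pharmacy", "self_medication", "non_bpjs_partner"],
    "chronic": ["bpjs_partner", "self_medication", "non_bpjs_partner"],
    "serious": ["bpjs_partner", "non_bpjs_partner"],
}


@dataclass
class ChoiceDGP:
    """Baseline-category multinomial-logit data-generating process.

    Log-odds of each non-reference category against ``reference_category``
    are ``intercept + Σ covariate_effects·x + Σ factor_effects·f``.
    The reference category has all coefficients fixed at zero.
    """

    intercepts: dict[str, float]
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    factor_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    reference_category: str = "bpjs_partner"

    def __post_init__(self) -> None:
        if self.reference_category in self.intercepts:
            raise ValueError("reference category must not carry an intercept")
        for cat in list(self.covariate_effects) + list(self.factor_effects):
            if cat == self.reference_category:
                raise ValueError("reference category coefficients are fixed at 0")
            if cat not in self.intercepts:
                raise ValueError(f"category {cat!r} has effects but no intercept")

    @property
    def categories(self) -> list[str]:
        return [self.reference_category] + list(self.intercepts)


@dataclass
class PreferenceDGP:
    """Linear factor model for the 12 preference items: x = Λ f + ε."""

    loading_matrix: np.ndarray  # 12 items × K factors
    noise_sd: float | np.ndarray = 0.5
    n_factors: int = 5

    def __post_init__(self) -> None:
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        if self.loading_matrix.shape[0] != len(PREFERENCE_ITEMS):
            raise ValueError("loading_matrix must have 12 rows (one per item)")
        if self.loading_matrix.shape[1] != self.n_factors:
            raise ValueError("n_factors must equal the number of loading columns")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValueError("noise_sd must be > 0")

    def item_sds(self) -> np.ndarray:
        """Marginal sd of each latent item, sqrt(Σ_k Λ_ik² + σ_i²)."""
        sig2 = np.broadcast_to(np.square(self.noise_sd), (len(PREFERENCE_ITEMS),))
        return np.sqrt((self.loading_matrix**2).sum(axis=1) + sig2)


def default_preference_dgp(noise_sd: float = 0.5) -> PreferenceDGP:
    """Five-factor block loading structure with well-separated factor
    strengths (block sizes 3, 3, 2, 2, 2), so that correlation-matrix PCA
    retains exactly five components and each recovers one factor."""
    lam = np.zeros((12, 5))
    blocks = [(0, 3, 0.90), (3, 3, 0.37), (6, 2, 0.90), (8, 2, 0.37), (10, 2, 0.20)]
    for k, (start, size, a) in enumerate(blocks):
        lam[start : start + size, k] = a
    return PreferenceDGP(loading_matrix=lam, noise_sd=noise_sd, n_factors=5)


# ---------------------------------------------------------------------------
# covariate distributions (defaults = the study population's marginals)

#: marginal distributions of the questionnaire variables; categorical
#: variables as level → probability, age as a truncated normal
DEFAULT_COVARIATE_DISTS: dict[str, dict] = {
    "age": {"kind": "truncnorm", "mean": 44.0, "sd": 13.0, "low": 18, "high": 82},
    "gender": {"kind": "cat", "levels": {"female": 132 / 216, "male": 84 / 216}},
    "occupation": {
        "kind": "cat",
        "levels": {
            "none": 25 / 216,
            "entrepreneur": 73 / 216,
            "civil_servant": 11 / 216,
            "employee": 85 / 216,
            "freelancer": 11 / 216,
            "retiree": 11 / 216,
        },
    },
    "income": {
        "kind": "cat",
        "levels": {"low": 37 / 211, "mid": 116 / 211, "high": 58 / 211},
    },
    "education": {
        "kind": "cat",
        "levels": {"primary": 38 / 216, "secondary": 111 / 216, "higher": 67 / 216},
    },
    "mild_illness": {"kind": "bern", "p": 180 / 216},
    "chronic_illness": {"kind": "bern", "p": 67 / 216},
    "hospitalization": {"kind": "bern", "p": 29 / 216},
    "consultations": {
        "kind": "cat",
        "levels": {"none": 77 / 216, "one_to_three": 105 / 216, "over_three": 34 / 216},
    },
    "medical_cost": {
        "kind": "cat",
        "levels": {
            "under_250k": 129 / 214,
            "250k_2m": 73 / 214,
            "2m_5m": 9 / 214,
            "over_5m": 3 / 214,
        },
    },
    "cost_burden": {
        "kind": "cat",
        "levels": {"none": 159 / 214, "a_bit": 34 / 214, "cannot_undertake": 21 / 214},
    },
    "pbi": {"kind": "bern", "p": 150 / 215},
    "ever_used_benefit": {"kind": "bern", "p": 125 / 216},
    "other_insurance": {"kind": "bern", "p": 37 / 216},
}

#: small per-variable missingness mirroring the varying per-table n of a
#: real door-to-door survey
DEFAULT_MISSING_RATES = {
    "income": 5 / 216,
    "medical_cost": 2 / 216,
    "cost_burden": 2 / 216,
    "pbi": 1 / 216,
}


def default_covariate_dists() -> dict[str, dict]:
    return {k: dict(v) for k, v in DEFAULT_COVARIATE_DISTS.items()}


def default_choice_dgps() -> dict[str, ChoiceDGP]:
    """Per-scenario choice DGPs with effect magnitudes at realistic
    adjusted-odds/relative-risk levels for an insured urban population
    (e.g. other-insurance membership strongly raises the odds of bypassing
    partner providers)."""
    ln = np.log
    return {
        "actual": ChoiceDGP(
            intercepts={"non_bpjs_partner": 0.25},
            covariate_effects={
                "non_bpjs_partner": {
                    "pbi": ln(1 / 2.40),
                    "other_insurance": ln(1 / 0.18),
                    "age_c": ln(0.97),
                }
            },
        ),
        "mild": ChoiceDGP(
            intercepts={"pharmacy": -1.9, "self_medication": -0.3, "non_bpjs_partner": -1.1},
            covariate_effects={
                "pharmacy": {"other_insurance": ln(3.16), "age_c": ln(0.92)},
                "self_medication": {
                    "chronic_illness": ln(2.99),
                    "other_insurance": ln(4.27),
                    "education_higher": ln(5.11),
                },
                "non_bpjs_partner": {
                    "chronic_illness": ln(3.68),
                    "other_insurance": ln(4.34),
                },
            },
            factor_effects={
                "pharmacy": {4: ln(6.77), 1: ln(0.23)},
                "self_medication": {0: ln(2.44), 1: ln(0.36)},
                "non_bpjs_partner": {0: ln(4.70), 1: ln(0.32), 3: ln(2.12)},
            },
        ),
        "chronic": ChoiceDGP(
            intercepts={"self_medication": -0.7, "non_bpjs_partner": -0.8},
            covariate_effects={
                "self_medication": {
                    "chronic_illness": ln(3.16),
                    "education_secondary": ln(0.24),
                    "education_higher": ln(0.15),
                },
                "non_bpjs_partner": {"other_insurance": ln(4.78)},
            },
            factor_effects={
                "self_medication": {0: ln(3.26)},
                "non_bpjs_partner": {0: ln(11.97)},
            },
        ),
        "serious": ChoiceDGP(
            intercepts={"non_bpjs_partner": -0.4},
            covariate_effects={
                "non_bpjs_partner": {
                    "income_high": ln(4.90),
                    "pbi": ln(0.43),
                    "other_insurance": ln(3.48),
                }
            },
            factor_effects={"non_bpjs_partner": {0: ln(6.84)}},
        ),
    }


# ---------------------------------------------------------------------------


def _draw_covariates(n: int, dists: dict[str, dict], rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, d in dists.items():
        if d["kind"] == "truncnorm":
            v = rng.normal(d["mean"], d["sd"], size=4 * n + 16)
            v = v[(v >= d["low"]) & (v <= d["high"])]
            while len(v) < n:
                extra = rng.normal(d["mean"], d["sd"], size=2 * n)
                v = np.concatenate([v, extra[(extra >= d["low"]) & (extra <= d["high"])]])
            cols[name] = np.round(v[:n], 0)
        elif d["kind"] == "cat":
            levels = list(d["levels"])
            p = np.array([d["levels"][lv] for lv in levels], dtype=float)
            p = p / p.sum()
            cols[name] = rng.choice(levels, size=n, p=p)
        elif d["kind"] == "bern":
            cols[name] = (rng.random(n) < d["p"]).astype(int)
        else:
            raise ValueError(f"unknown distribution kind {d['kind']!r}")
    return pd.DataFrame(cols)


def _design_columns(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate columns the choice DGP may reference: binary flags
    as 0/1, centred age, and first-level-reference dummies for the ordered
    categoricals."""
    out = pd.DataFrame(index=cov.index)
    for c in cov.columns:
        if cov[c].dtype.kind in "if":
            out[c] = cov[c].astype(float)
        else:
            for lv in pd.unique(cov[c]):
                out[f"{c}_{lv}"] = (cov[c] == lv).astype(float)
    if "age" in cov:
        out["age_c"] = cov["age"].astype(float) - float(cov["age"].mean())
    return out


def _likert(latent: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Discretise standardized latent ratings to 1–5 by fixed normal
    quantile thresholds at ±1.5 and ±0.5 sd."""
    z = latent / sds
    return (np.digitize(z, [-1.5, -0.5, 0.5, 1.5]) + 1).astype(float)


def gen_respondents(
    households: list[Feature] | int,
    choice_dgps: dict[str, ChoiceDGP] | ChoiceDGP | None = None,
    pref_dgp: PreferenceDGP | None = None,
    covariate_dists: dict[str, dict] | None = None,
    seed: int = 0,
    missing_rates: dict[str, float] | None = None,
    discretize_items: bool = True,
) -> pd.DataFrame:
    """Generate one respondent per household (or ``n`` respondents).

    Returns a tidy frame with sociodemographics, four choice columns
    ``choice_<scenario>``, per-scenario item ratings
    ``pref_<scenario>_<item>`` and (for validation) the true factor scores
    ``factor_<scenario>_<k>``.
    """
    if isinstance(households, int):
        n = households
        ids = [f"R{i:06d}" for i in range(n)]
        xy = None
    else:
        n = len(households)
        ids = [str(f.properties.get("household_id", i)) for i, f in enumerate(households)]
        xy = np.array([[f.geometry.x, f.geometry.y] for f in households]) if n else None
    if choice_dgps is None:
        choice_dgps = default_choice_dgps()
    if isinstance(choice_dgps, ChoiceDGP):
        choice_dgps = {sc: choice_dgps for sc in SCENARIOS}
    if pref_dgp is None:
        pref_dgp = default_preference_dgp()
    if covariate_dists is None:
        covariate_dists = default_covariate_dists()
    if missing_rates is None:
        missing_rates = dict(DEFAULT_MISSING_RATES)

    # validate DGP covariates against what the distributions can produce
    possible: set[str] = set()
    for name, d in covariate_dists.items():
        if d["kind"] == "cat":
            possible |= {f"{name}_{lv}" for lv in d["levels"]}
        else:
            possible.add(name)
    if "age" in covariate_dists:
        possible.add("age_c")
    for sc, dgp in choice_dgps.items():
        for cat, eff in dgp.covariate_effects.items():
            unknown = set(eff) - possible
            if unknown:
                raise ValueError(
                    f"choice DGP for {sc!r}/{cat!r} references unknown covariates {sorted(unknown)}"
                )

    rng = np.random.default_rng(seed)
    cov = _draw_covariates(n, covariate_dists, rng)
    design = _design_columns(cov)

    out = cov.copy()
    out.insert(0, "respondent_id", ids)
    if xy is not None:
        out["x"] = xy[:, 0]
        out["y"] = xy[:, 1]

    K = pref_dgp.n_factors
    sds = pref_dgp.item_sds()
    for sc in SCENARIOS:
        dgp = choice_dgps.get(sc)
        if dgp is None:
            continue
        f = rng.standard_normal((n, K))
        if sc != "actual":
            eps = rng.standard_normal((n, 12)) * np.broadcast_to(
                pref_dgp.noise_sd, (12,)
            )
            latent = f @ pref_dgp.loading_matrix.T + eps
            items = _likert(latent, sds) if discretize_items else latent
            for j, item in enumerate(PREFERENCE_ITEMS):
                out[f"pref_{sc}_{item}"] = items[:, j]
        # linear predictors: reference category first, fixed at 0
        cats = dgp.categories
        eta = np.zeros((n, len(cats)))
        for ci, cat in enumerate(cats[1:], start=1):
            e = np.full(n, dgp.intercepts[cat])
            for cov_name, beta in dgp.covariate_effects.get(cat, {}).items():
                if cov_name in design:  # a level may be absent in a tiny draw
                    e += beta * design[cov_name].to_numpy()
            for k, beta in dgp.factor_effects.get(cat, {}).items():
                e += beta * f[:, k]
            eta[:, ci] = e
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        out[f"choice_{sc}"] = np.array(cats, dtype=object)[idx]
        for k in range(K):
            out[f"factor_{sc}_{k}"] = f[:, k]

    for var, rate in missing_rates.items():
        if var in out.columns and rate > 0:
            mask = rng.random(n) < rate
            out.loc[mask, var] = np.nan if out[var].dtype.kind in "if" else None
    return out
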