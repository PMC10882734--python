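"""Binary and multinomial logistic choice models with Wald inference.

The habitual provider choice is modelled by binary logistic regression
(adjusted odds ratios, AOR); the per-scenario choices by baseline-category
multinomial logit with the partner provider as the reference category
(relative risk ratios, RRR = exponentiated baseline-category coefficient).

Both are fitted by Newton–Raphson on the full multinomial likelihood with
step-halving, so the log-likelihood is non-decreasing across iterations;
convergence is declared when the score vector is numerically zero
(max |component| < 1e-6). Complete or
quasi-complete separation is detected (exploding coefficients or a failure
to converge) and flagged per equation, with the affected estimates
withheld rather than reported; an optional ridge stabiliser exists but is
off by default. Categorical covariates are dummy-coded against their first
level; rows with a missing value in any model variable are dropped
listwise and the model reports the n actually used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

Z975 = norm.ppf(0.975)  # 1.959964...

MAX_ABS_COEF = 15.0  # |beta| beyond this is treated as separation
MAX_ITER = 100
GRAD_TOL = 1e-8  # max |score| at the reported optimum


@dataclass
class ChoiceModelResult:
    """Tidy coefficient table plus fit diagnostics.

    ``table`` columns: category, term, coef, se, exp_coef (AOR or RRR),
    ci_low, ci_high, p, withheld.
    """

    outcome: str
    reference: str
    categories: list[str]          # including the reference, first
    table: pd.DataFrame
    llf: float
    n: int
    converged: bool
    n_iter: int
    effect_label: str              # "AOR" or "RRR"
    separation: list[str] = field(default_factory=list)
    dropped_categories: list[str] = field(default_factory=list)
    fitted_probabilities: np.ndarray | None = None

    def exp_effect(self, category: str, term: str) -> float:
        row = self.table[(self.table.category == category) & (self.table.term == term)]
        if row.empty:
            raise KeyError(f"no coefficient for ({category!r}, {term!r})")
        return float(row.exp_coef.iloc[0])


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    data: pd.DataFrame,
    covariates: list[str],
    reference_levels: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; categorical covariates are expanded
    into dummies with the first (or specified reference) level omitted."""
    reference_levels = reference_levels or {}
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    for c in covariates:
        s = data[c]
        if s.dtype.kind in "ifb":
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
        else:
            if isinstance(s.dtype, pd.CategoricalDtype):
                levels = [lv for lv in s.cat.categories if lv in set(s.dropna())]
            else:
                levels = sorted(pd.unique(s.dropna()))
            ref = reference_levels.get(c, levels[0])
            for lv in levels:
                if lv == ref:
                    continue
                cols.append((s == lv).to_numpy(dtype=float))
                names.append(f"{c}[{lv}]")
    X = np.column_stack(cols)
    # rank check with named offenders
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        offending = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                offending.append(names[j])
        raise ValueError(f"design matrix rank deficient; offending columns: {offending}")
    return X, names


# ---------------------------------------------------------------------------
# core Newton solver


def _fit_multinomial(
    X: np.ndarray, y_idx: np.ndarray, n_cat: int, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray, float, bool, int, np.ndarray]:
    """Maximise the baseline-category multinomial likelihood.

    Returns (beta (K-1)×p, se like beta, llf, converged, n_iter, P n×K).
    """
    n, p = X.shape
    km1 = n_cat - 1
    Y = np.zeros((n, n_cat))
    Y[np.arange(n), y_idx] = 1.0
    beta = np.zeros((km1, p))

    def probs(b: np.ndarray) -> np.ndarray:
        eta = np.zeros((n, n_cat))
        eta[:, 1:] = X @ b.T
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    def loglik(b: np.ndarray) -> float:
        P = probs(b)
        ll = float(np.sum(np.log(np.clip(P[np.arange(n), y_idx], 1e-300, None))))
        if ridge:
            ll -= 0.5 * ridge * float((b**2).sum())
        return ll

    def information(P: np.ndarray) -> np.ndarray:
        # observed information, block (j,k) = X^T diag(P_j (δ_jk − P_k)) X
        H = np.empty((km1 * p, km1 * p))
        for j in range(km1):
            for k in range(km1):
                w = P[:, j + 1] * ((1.0 if j == k else 0.0) - P[:, k + 1])
                H[j * p : (j + 1) * p, k * p : (k + 1) * p] = -(X * w[:, None]).T @ X
        if ridge:
            H -= ridge * np.eye(km1 * p)
        return H

    llf = loglik(beta)
    converged = False
    it = 0
    H = -np.eye(km1 * p)
    for it in range(1, MAX_ITER + 1):
        P = probs(beta)
        g = ((Y[:, 1:] - P[:, 1:]).T @ X).ravel()
        if ridge:
            g -= ridge * beta.ravel()
        H = information(P)
        if np.max(np.abs(g)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, g).reshape(km1, p)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        ftol = 1e-12 * (abs(llf) + 1.0)
        new_llf = loglik(beta + step)
        n_halve = 0
        while new_llf < llf - ftol and n_halve < 30:
            scale *= 0.5
            n_halve += 1
            new_llf = loglik(beta + scale * step)
        if new_llf < llf - ftol:
            break
        beta = beta + scale * step
        llf = max(new_llf, llf)
    P = probs(beta)
    llf = loglik(beta)
    # standard errors from the inverse observed information at the optimum
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(km1, p)
    except np.linalg.LinAlgError:
        se = np.full_like(beta, np.nan)
    return beta, se, llf, converged, it, P


def _result_table(
    beta: np.ndarray, se: np.ndarray, categories: list[str], names: list[str],
    withheld_cats: set[str],
) -> pd.DataFrame:
    rows = []
    for j, cat in enumerate(categories[1:]):
        withheld = cat in withheld_cats
        for a, term in enumerate(names):
            b, s = beta[j, a], se[j, a]
            if withheld or not np.isfinite(s):
                rows.append((cat, term, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, True))
            else:
                z = b / s if s > 0 else np.nan
                rows.append((
                    cat, term, b, s, float(np.exp(b)),
                    float(np.exp(b - Z975 * s)), float(np.exp(b + Z975 * s)),
                    float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                    False,
                ))
    return pd.DataFrame(
        rows,
        columns=["category", "term", "coef", "se", "exp_coef", "ci_low", "ci_high", "p", "withheld"],
    )


# ---------------------------------------------------------------------------
# public fitting functions


def fit_multinomial_choice(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    adjust: list[str] | None = None,
    reference: str = "bpjs_partner",
    reference_levels: dict[str, str] | None = None,
    ridge: float = 0.0,
) -> ChoiceModelResult:
    """Baseline-category multinomial logit of ``outcome`` on covariates
    (plus an adjustment set), reference category = partner provider.

    Categories that never occur in the data are dropped with a warning;
    RRR = exp(coefficient) per non-reference category.
    """
    adjust = list(adjust or [])
    model_vars = [outcome] + list(covariates) + adjust
    sub = data[model_vars].dropna()
    observed = list(pd.unique(sub[outcome]))
    if reference not in observed:
        raise ValueError(f"reference category {reference!r} not observed in the data")
    cats = [reference] + sorted(c for c in observed if c != reference)
    all_declared = getattr(data[outcome], "cat", None)
    dropped = []
    if all_declared is not None:
        dropped = [c for c in all_declared.categories if c not in observed]
        if dropped:
            warnings.warn(f"outcome categories absent from data dropped: {dropped}", stacklevel=2)
    if len(cats) < 2:
        raise ValueError("outcome must have at least 2 observed categories")

    X, names = build_design(sub, list(covariates) + adjust, reference_levels)
    y_idx = np.array([cats.index(v) for v in sub[outcome]])
    beta, se, llf, converged, n_iter, P = _fit_multinomial(X, y_idx, len(cats), ridge)
    sep = [cats[1:][j] for j in range(len(cats) - 1) if np.max(np.abs(beta[j])) > MAX_ABS_COEF]
    if not converged and not sep:
        sep = list(cats[1:])  # cannot localise: withhold everything
    table = _result_table(beta, se, cats, names, set(sep))
    return ChoiceModelResult(
        outcome=outcome, reference=reference, categories=cats, table=table,
        llf=llf, n=len(sub), converged=converged and not sep, n_iter=n_iter,
        effect_label="RRR" if len(cats) > 2 else "AOR",
        separation=sep, dropped_categories=dropped, fitted_probabilities=P,
    )


def fit_binary_choice(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    adjust: list[str] | None = None,
    reference: str | None = None,
    reference_levels: dict[str, str] | None = None,
    ridge: float = 0.0,
) -> ChoiceModelResult:
    """Multiple (binary) logistic regression; AOR = exp(coefficient) with
    95% Wald confidence intervals exp(β ± 1.959964·se)."""
    sub = data[[outcome]].dropna()
    levels = sorted(pd.unique(sub[outcome]))
    if len(levels) != 2:
        raise ValueError(f"binary outcome required, found {len(levels)} levels")
    if reference is None:
        reference = "bpjs_partner" if "bpjs_partner" in levels else levels[0]
    res = fit_multinomial_choice(
        data, outcome, covariates, adjust=adjust, reference=reference,
        reference_levels=reference_levels, ridge=ridge,
    )
    res.effect_label = "AOR"
    return res


def preference_choice_models(
    scores: np.ndarray | pd.DataFrame,
    data: pd.DataFrame,
    scenario: str,
    adjust: list[str] | None = None,
    reference: str = "bpjs_partner",
) -> ChoiceModelResult:
    """Choice model of the scenario's provider choice on the retained
    principal-component scores (optionally plus an adjustment set).

    ``scores`` must be row-aligned with ``data``. Two-category scenarios
    collapse to binary logistic automatically.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(data):
        raise ValueError("scores and data are not row-aligned")
    outcome = f"choice_{scenario}"
    frame = pd.DataFrame(
        scores, columns=[f"PC{k + 1}" for k in range(scores.shape[1])], index=data.index
    )
    frame[outcome] = data[outcome].to_numpy()
    for a in adjust or []:
        frame[a] = data[a].to_numpy()
    return fit_multinomial_choice(
        frame, outcome, [c for c in frame.columns if c.startswith("PC")],
        adjust=adjust, reference=reference,
    )


def render_table(result: ChoiceModelResult) -> str:
    """Text rendering with significance stars at p<0.05/0.01/0.001."""
    lines = [
        f"{result.outcome}: {result.effect_label} (95% CI), reference = {result.reference}, "
        f"n = {result.n}, llf = {result.llf:.2f}"
    ]
    for _, r in result.table.iterrows():
        if r.term == "intercept":
            continue
        if r.withheld:
            lines.append(f"  {r.category:20s} {r.term:28s} (withheld: separation)")
            continue
        stars = "***" if r.p < 0.001 else "**" if r.p < 0.01 else "*" if r.p < 0.05 else ""
        lines.append(
            f"  {r.category:20s} {r.term:28s} "
            f"{r.exp_coef:6.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}){stars}"
        )
    return "\n".join(lines)
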