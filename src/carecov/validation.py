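"""Validation experiments: recomputation of published contingency-table
statistics, parameter-recovery simulations for the choice models, PCA
recovery checks, spatial-oracle comparisons, and type-I-error calibration.

These functions are what the acceptance script and the heavier end of the
test suite run. Everything is seeded and pure: same seed, same numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from carecov.choice_models import fit_binary_choice, fit_multinomial_choice, preference_choice_models
from carecov.survey_stats import ContingencyTable, pearson_chi2
from carecov.synthetic.survey import ChoiceDGP, gen_respondents

# ---------------------------------------------------------------------------
# published cross-tabulations of the 216-resident survey (counts by
# frequent partner vs non-partner users), used to validate the chi-square
# routine against the study's reported three-decimal p-values

TABLE1_COUNTS: dict[str, list[list[int]]] = {
    "gender": [[54, 78], [29, 55]],
    "mild_illness": [[73, 107], [10, 26]],
    "chronic_illness": [[31, 36], [52, 97]],
    "hospitalization": [[13, 16], [70, 117]],
    "occupation": [[10, 15], [27, 46], [3, 8], [35, 50], [6, 5], [2, 9]],
    "education": [[22, 16], [44, 67], [17, 50]],
    "medical_cost": [[57, 72], [24, 49], [2, 7], [0, 3]],
    "cost_burden": [[64, 95], [13, 21], [6, 15]],
}

TABLE1_PUBLISHED_P: dict[str, float] = {
    "gender": 0.347,
    "mild_illness": 0.150,
    "chronic_illness": 0.112,
    "hospitalization": 0.446,
    "occupation": 0.542,
    "education": 0.004,
    "medical_cost": 0.133,
    "cost_burden": 0.585,
}

#: insurance-status marginal: 150 of 215 respondents were government-paid
#: (PBI) beneficiaries
PBI_COUNTS = (48 + 102, 215)


def table1_chi2_pvalues() -> dict[str, float]:
    """Uncorrected Pearson chi-square p-value per printed table."""
    out = {}
    for name, counts in TABLE1_COUNTS.items():
        c = np.asarray(counts)
        tab = ContingencyTable(
            row_labels=[str(i) for i in range(c.shape[0])],
            col_labels=["bpjs", "non_bpjs"], counts=c, n=int(c.sum()),
        )
        out[name] = pearson_chi2(tab).p
    return out


def pbi_share_pct() -> float:
    """PBI beneficiaries as a percentage of respondents with known status."""
    return round(100.0 * PBI_COUNTS[0] / PBI_COUNTS[1], 1)


# ---------------------------------------------------------------------------
# parameter-recovery simulations (effects at realistic AOR/RRR magnitudes)


def _summarise(estimates: list[float], covered: list[bool]) -> dict:
    return {
        "mean_exp_effect": float(np.mean(estimates)),
        "ci_coverage": float(np.mean(covered)),
        "n_replicates": len(estimates),
    }


def recovery_binary_or(true_or: float = 2.40, n: int = 50000, reps: int = 200,
                       seed: int = 0, p_flag: float = 0.7) -> dict:
    """Binary logistic recovery of an odds ratio on a PBI-like flag."""
    dgp = ChoiceDGP(intercepts={"non_bpjs_partner": -0.5},
                    covariate_effects={"non_bpjs_partner": {"pbi": np.log(true_or)}})
    est, cov = [], []
    for r in range(reps):
        df = gen_respondents(n, choice_dgps={"actual": dgp},
                             covariate_dists={"pbi": {"kind": "bern", "p": p_flag}},
                             missing_rates={}, seed=seed * 100003 + r)
        m = fit_binary_choice(df, "choice_actual", ["pbi"])
        row = m.table[m.table.term == "pbi"].iloc[0]
        est.append(row.exp_coef)
        cov.append(bool(row.ci_low <= true_or <= row.ci_high))
    return _summarise(est, cov)


def recovery_multinomial_rrr(true_rrrs: dict[str, float] | None = None,
                             n: int = 50000, reps: int = 100, seed: int = 0,
                             p_flag: float = 0.31) -> dict:
    """Three-category multinomial recovery of two relative risk ratios on
    a chronic-illness flag (defaults 2.99 and 3.68)."""
    if true_rrrs is None:
        true_rrrs = {"self_medication": 2.99, "non_bpjs_partner": 3.68}
    dgp = ChoiceDGP(
        intercepts={"self_medication": -0.6, "non_bpjs_partner": -1.0},
        covariate_effects={
            cat: {"chronic_illness": np.log(v)} for cat, v in true_rrrs.items()
        },
    )
    est = {cat: [] for cat in true_rrrs}
    cov = {cat: [] for cat in true_rrrs}
    for r in range(reps):
        df = gen_respondents(n, choice_dgps={"mild": dgp},
                             covariate_dists={"chronic_illness": {"kind": "bern", "p": p_flag}},
                             missing_rates={}, seed=seed * 200003 + r)
        m = fit_multinomial_choice(df, "choice_mild", ["chronic_illness"])
        for cat, true_v in true_rrrs.items():
            row = m.table[(m.table.category == cat) & (m.table.term == "chronic_illness")].iloc[0]
            est[cat].append(row.exp_coef)
            cov[cat].append(bool(row.ci_low <= true_v <= row.ci_high))
    return {cat: _summarise(est[cat], cov[cat]) for cat in true_rrrs}


def recovery_single_rrr(true_rrr: float = 4.78, n: int = 50000, reps: int = 100,
                        seed: int = 0, p_flag: float = 0.17) -> dict:
    """Multinomial recovery of one RRR on an other-insurance-like flag."""
    out = recovery_multinomial_rrr(
        {"non_bpjs_partner": true_rrr}, n=n, reps=reps, seed=seed, p_flag=p_flag
    )
    return out["non_bpjs_partner"]


def recovery_factor_rrr(true_rrr: float = 4.70, n: int = 50000, reps: int = 100,
                        seed: int = 0) -> dict:
    """Recovery of a preference-factor effect: factor 1 raises the
    non-partner utility; the model is fitted on the factor scores."""
    dgp = ChoiceDGP(intercepts={"self_medication": -0.4, "non_bpjs_partner": -0.8},
                    factor_effects={"non_bpjs_partner": {0: np.log(true_rrr)}})
    est, cov = [], []
    for r in range(reps):
        df = gen_respondents(n, choice_dgps={"mild": dgp}, covariate_dists={},
                             missing_rates={}, seed=seed * 300007 + r)
        scores = df[[f"factor_mild_{k}" for k in range(5)]].to_numpy()
        m = preference_choice_models(scores, df, "mild")
        row = m.table[(m.table.category == "non_bpjs_partner") & (m.table.term == "PC1")].iloc[0]
        est.append(row.exp_coef)
        cov.append(bool(row.ci_low <= true_rrr <= row.ci_high))
    return _summarise(est, cov)


# ---------------------------------------------------------------------------
# type-I-error calibration under simulated nulls


def type_i_error_chi2(reps: int = 5000, n: int = 400, seed: int = 0,
                      alpha: float = 0.05) -> float:
    """Rejection rate of the uncorrected Pearson test on independent
    2x3 multinomial tables (row margin 0.5, column margins 0.5/0.3/0.2)."""
    rng = np.random.default_rng(seed)
    p_row = np.array([0.5, 0.5])
    p_col = np.array([0.5, 0.3, 0.2])
    cell_p = np.outer(p_row, p_col).ravel()
    rejections = 0
    tables = rng.multinomial(n, cell_p, size=reps).reshape(reps, 2, 3)
    from scipy.stats import chi2_contingency

    for t in tables:
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            continue
        _, p, _, _ = chi2_contingency(t, correction=False)
        rejections += p < alpha
    return rejections / reps


def type_i_error_ttest(reps: int = 5000, n_per_group: int = 30, seed: int = 0,
                       alpha: float = 0.05) -> float:
    """Rejection rate of the pooled t-test on equal-mean normal samples."""
    from scipy.stats import ttest_ind

    rng = np.random.default_rng(seed + 1)
    a = rng.standard_normal((reps, n_per_group))
    b = rng.standard_normal((reps, n_per_group))
    p = ttest_ind(a, b, axis=1).pvalue
    return float(np.mean(p < alpha))


# ---------------------------------------------------------------------------
# spatial oracles


def dijkstra_vs_enumeration(n_graphs: int = 10, seed: int = 0) -> float:
    """Max |Dijkstra − exhaustive-path| discrepancy over random graphs of
    at most 12 nodes (minutes)."""
    import networkx as nx

    from carecov.accessibility import TravelGraph, edge_minutes

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(4, 13))
        pts = [tuple(np.round(p, 1)) for p in rng.uniform(0, 1000, size=(n, 2))]
        g = nx.Graph()
        for pt in pts:
            g.add_node(pt, xy=pt)
        order = rng.permutation(n)
        pairs = [(pts[order[i - 1]], pts[order[i]]) for i in range(1, n)]
        pairs += [
            (pts[i], pts[j])
            for i, j in rng.integers(0, n, size=(n, 2))
            if i != j and not g.has_edge(pts[i], pts[j])
        ]
        for a, b in pairs:
            length = float(np.hypot(a[0] - b[0], a[1] - b[1])) + 1.0
            g.add_edge(a, b, length=length, time=edge_minutes(length, float(rng.uniform(10, 50))))
        src = pts[0]
        times = nx.single_source_dijkstra_path_length(g, src, weight="time")
        for dst in pts[1:]:
            best = min(
                (
                    sum(g.edges[p[i], p[i + 1]]["time"] for i in range(len(p) - 1))
                    for p in nx.all_simple_paths(g, src, dst)
                ),
                default=np.inf,
            )
            worst = max(worst, abs(times.get(dst, np.inf) - best))
    return worst


def coverage_vs_brute_force(n_instances: int = 5, seed: int = 0) -> int:
    """Total |surface − brute-force point-in-polygon| over random disk
    catchments on random grids (0 means exact agreement)."""
    from shapely.geometry import Point

    from carecov.accessibility import Catchment, GridSpec, coverage_surface

    rng = np.random.default_rng(seed)
    total_diff = 0
    for _ in range(n_instances):
        grid = GridSpec(0, 0, 20, int(rng.integers(5, 50)), int(rng.integers(5, 50)))
        cats = [
            Catchment(provider_id=str(k), budget=15.0, snapped_node=(0, 0),
                      snap_distance=0.0, reached_edges=[],
                      polygon=Point(rng.uniform(0, 600), rng.uniform(0, 600)).buffer(rng.uniform(20, 200)),
                      stratum="bpjs")
            for k in range(int(rng.integers(1, 21)))
        ]
        surf = coverage_surface(cats, grid, "bpjs")
        oracle = np.zeros_like(surf.values)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                pt = Point(grid.origin_x + (c + 0.5) * grid.cell_size,
                           grid.origin_y + (r + 0.5) * grid.cell_size)
                oracle[r, c] = sum(cat.polygon.contains(pt) for cat in cats)
        total_diff += int(np.abs(surf.values - oracle).sum())
    return total_diff


# ---------------------------------------------------------------------------
# PCA checks


def pca_two_block_eigenvalues(r: float = 0.6, n: int = 40) -> tuple[float, float]:
    """Top and bottom eigenvalues of a 12-item matrix whose sample
    correlation is exactly r between two items and 0 elsewhere; the
    closed-form answer is (1+r, 1−r)."""
    from scipy.linalg import helmert

    from carecov.preference_pca import pca_preferences

    H = helmert(n)
    basis = H[:12].T * np.sqrt(n - 1)
    x = basis.copy()
    x[:, 1] = r * basis[:, 0] + np.sqrt(1 - r * r) * basis[:, 1]
    res = pca_preferences(x)
    return float(res.eigenvalues[0]), float(res.eigenvalues[-1])


def pca_factor_recovery(n: int = 5000, noise_sd: float = 0.3, seed: int = 0) -> dict:
    """Fit PCA to synthetic five-factor preference data and report the
    retained-component count and the minimum Tucker congruence."""
    from carecov.preference_pca import match_factors, pca_preferences
    from carecov.synthetic.survey import PREFERENCE_ITEMS, default_preference_dgp

    dgp = default_preference_dgp(noise_sd=noise_sd)
    df = gen_respondents(n, pref_dgp=dgp, seed=seed)
    items = df[[f"pref_mild_{i}" for i in PREFERENCE_ITEMS]]
    res = pca_preferences(items, item_labels=list(PREFERENCE_ITEMS))
    cong = match_factors(dgp.loading_matrix, res.loadings)
    return {"n_retained": res.n_retained, "min_congruence": float(min(cong)),
            "n_used": res.n_used}


def saturated_equivalence_max_diff(n_tables: int = 100, n_per_table: int = 1000,
                                   seed: int = 0) -> float:
    """Max relative |fitted RRR − cross-product ratio| over random
    saturated one-covariate multinomial designs (closed-form MLE
    identity)."""
    rng = np.random.default_rng(seed)
    cats = ["bpjs_partner", "pharmacy", "self_medication", "non_bpjs_partner"]
    worst = 0.0
    done = 0
    while done < n_tables:
        k = int(rng.integers(2, 5))
        use = cats[:k]
        x = (rng.random(n_per_table) < rng.uniform(0.3, 0.7)).astype(float)
        probs = rng.dirichlet(np.ones(k), size=2)
        y = np.array([use[rng.choice(k, p=probs[int(v)])] for v in x])
        df = pd.DataFrame({"x": x, "y": y})
        tab = pd.crosstab(df.x, df.y)
        if tab.shape != (2, k) or (tab.to_numpy() == 0).any():
            continue
        m = fit_multinomial_choice(df, "y", ["x"], reference="bpjs_partner")
        for cat in use[1:]:
            cpr = (tab.loc[1.0, cat] * tab.loc[0.0, "bpjs_partner"]) / (
                tab.loc[0.0, cat] * tab.loc[1.0, "bpjs_partner"]
            )
            worst = max(worst, abs(m.exp_effect(cat, "x") - cpr) / cpr)
        done += 1
    return worst
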