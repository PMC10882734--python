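"""Principal-component preference factors from the 12 rated items.

The items are standardized and the correlation matrix eigen-decomposed.
Components with eigenvalue strictly greater than 1 are retained
(Kaiser rule); loadings are eigenvector × √eigenvalue, so each loading is
the correlation between an item and a component, and an item is salient on
a component when |loading| ≥ 0.32. Component scores (standardized items ×
eigenvectors) feed the downstream choice models. No rotation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SALIENCE_CUTOFF = 0.32
EIGENVALUE_THRESHOLD = 1.0


@dataclass
class PCAResult:
    item_labels: list[str]
    eigenvalues: np.ndarray          # all p, descending
    eigenvectors: np.ndarray         # p × p, columns match eigenvalues
    loadings: np.ndarray             # p × n_retained (eigvec × √eigval)
    n_retained: int
    cumulative_variance_pct: float   # % variance of the retained set
    scores: np.ndarray               # n × n_retained
    salient: np.ndarray              # p × n_retained bool, |loading| ≥ cutoff
    n_used: int
    isotropic_flag: bool = False     # all eigenvalues ≈ 1: retention unstable

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.n_retained)]
        return pd.DataFrame(self.loadings, index=self.item_labels, columns=cols)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance (constant) item: PCA on the correlation matrix undefined")
    return (x - mu) / sd, mu, sd


def pca_preferences(
    items: pd.DataFrame | np.ndarray,
    item_labels: list[str] | None = None,
    eigenvalue_threshold: float = EIGENVALUE_THRESHOLD,
    salience_cutoff: float = SALIENCE_CUTOFF,
) -> PCAResult:
    """Correlation-matrix PCA of the item matrix (respondents × items).

    Rows with any missing item are dropped (listwise); at least one more
    complete row than items is required. Components are ordered by
    eigenvalue; retention is strict eigenvalue > 1 (a component at exactly
    1.00 is not retained). Sign convention: each component is oriented so
    its largest-|loading| item loads positively.
    """
    if isinstance(items, pd.DataFrame):
        if item_labels is None:
            item_labels = [str(c) for c in items.columns]
        x = items.to_numpy(dtype=float)
    else:
        x = np.asarray(items, dtype=float)
        if item_labels is None:
            item_labels = [f"item_{j + 1}" for j in range(x.shape[1])]
    x = x[~np.isnan(x).any(axis=1)]
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more complete rows ({n}) than items ({p})")
    z, _, _ = _standardize(x)
    corr = (z.T @ z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    # orient: largest-|loading| entry of each component positive
    for k in range(p):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]

    # strict "> 1": an eigenvalue at exactly the threshold (up to floating
    # point) is not retained
    retained = evals > eigenvalue_threshold + 1e-10
    n_ret = int(retained.sum())
    isotropic = bool(np.all(np.abs(evals - 1.0) < 0.1))
    if isotropic:
        warnings.warn(
            "near-isotropic correlation matrix: eigenvalue>1 retention is unstable",
            stacklevel=2,
        )
    load = evecs[:, :n_ret] * np.sqrt(evals[:n_ret])
    scores = z @ evecs[:, :n_ret]
    cum_pct = 100.0 * evals[:n_ret].sum() / p
    return PCAResult(
        item_labels=item_labels,
        eigenvalues=evals,
        eigenvectors=evecs,
        loadings=load,
        n_retained=n_ret,
        cumulative_variance_pct=float(cum_pct),
        scores=scores,
        salient=np.abs(load) >= salience_cutoff,
        n_used=n,
        isotropic_flag=isotropic,
    )


def flag_salient_loadings(result: PCAResult, cutoff: float = SALIENCE_CUTOFF) -> np.ndarray:
    """Boolean mask: item i is salient on component k iff |loading| ≥ cutoff
    (sign-blind — a loading of −0.47 is salient)."""
    return np.abs(result.loadings) >= cutoff


def component_scores(result: PCAResult, items: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Scores for (possibly new) respondents on the retained components,
    using the fit's standardization implied by its correlation structure.

    The item columns must match the fit. Scores of the fitting data have
    mean 0 and variance equal to the component's eigenvalue.
    """
    if isinstance(items, pd.DataFrame):
        if list(map(str, items.columns)) != result.item_labels:
            raise ValueError("item columns do not match the fitted PCA")
        x = items.to_numpy(dtype=float)
    else:
        x = np.asarray(items, dtype=float)
        if x.shape[1] != result.n_items:
            raise ValueError("item count does not match the fitted PCA")
    x = x[~np.isnan(x).any(axis=1)]
    z, _, _ = _standardize(x)
    return z @ result.eigenvectors[:, : result.n_retained]


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def match_factors(true_loadings: np.ndarray, est_loadings: np.ndarray) -> list[float]:
    """Congruence per true factor after optimal one-to-one column matching
    (Hungarian assignment on |congruence|) and sign alignment."""
    from scipy.optimize import linear_sum_assignment

    k_true = true_loadings.shape[1]
    k_est = est_loadings.shape[1]
    c = np.zeros((k_true, k_est))
    for i in range(k_true):
        for j in range(k_est):
            c[i, j] = abs(tucker_congruence(true_loadings[:, i], est_loadings[:, j]))
    rows, cols = linear_sum_assignment(-c)
    out = [float("nan")] * k_true
    for i, j in zip(rows, cols):
        out[i] = float(c[i, j])
    return out
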