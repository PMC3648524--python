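"""PCA expression signatures and their clinical associations.

Samples are observations, panel genes are variables. Genes are centered
(unit-variance scaling is off by default and available as a flag); loadings
carry a deterministic sign convention (the largest-magnitude entry of each
column is positive) so that signatures are comparable across datasets.
Component scores can be tested against clinical variables by multivariate
logistic regression (all components jointly, Wald p-values) and 2-D score
separation between groups by MANOVA via Wilks' lambda with the Bartlett
chi-squared approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .io import ExpressionMatrix


@dataclass
class PCAModel:
    gene_symbols: list[str]
    center: np.ndarray
    scale: np.ndarray | None
    loadings: np.ndarray           # genes x components, orthonormal columns
    explained_variance: np.ndarray  # nonincreasing, ddof=1 variances of scores
    component_labels: list[str]

    def __post_init__(self):
        g = np.asarray(self.loadings)
        gram = g.T @ g
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loading columns must be orthonormal")
        ev = np.asarray(self.explained_variance)
        if np.any(np.diff(ev) > 1e-10) or np.any(ev < -1e-12):
            raise ValueError("explained variances must be nonincreasing and nonnegative")

    def transform(self, expr: ExpressionMatrix) -> pd.DataFrame:
        """Project samples of ``expr`` onto the fitted components."""
        sub = expr.subset_genes(self.gene_symbols)
        x = sub.values.T - self.center
        if self.scale is not None:
            x = x / self.scale
        scores = x @ self.loadings
        return pd.DataFrame(scores, index=expr.sample_ids, columns=self.component_labels)


def fit_pca(
    expr_panel: ExpressionMatrix,
    scale: bool = False,
    label_suffix: str = "",
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit PCA on a panel matrix; returns the model and sample scores.

    ``label_suffix`` names the analysis the components belong to (e.g. "a"
    for all tumors, "t" for the TN-only subset), producing labels PC1a,
    PC2a, ... Scores are (centered data) @ loadings; explained variances are
    the ddof=1 variances of the scores.
    """
    if expr_panel.shape[0] < 2 or expr_panel.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    x = expr_panel.values.T.astype(float)  # samples x genes
    center = x.mean(axis=0)
    xc = x - center
    if scale:
        sd = xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [expr_panel.gene_ids[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"zero-variance gene(s) with scaling on: {zero}")
        xc = xc / sd
        scale_vec = sd
    else:
        scale_vec = None
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt.T  # genes x components
    # deterministic sign: largest-|entry| of each loading column positive
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            u[:, j] *= -1.0
    n = x.shape[0]
    explained = (s ** 2) / (n - 1)
    labels = [f"PC{j + 1}{label_suffix}" for j in range(loadings.shape[1])]
    model = PCAModel(
        gene_symbols=expr_panel.gene_ids,
        center=center,
        scale=scale_vec,
        loadings=loadings,
        explained_variance=explained,
        component_labels=labels,
    )
    scores = pd.DataFrame(xc @ loadings, index=expr_panel.sample_ids, columns=labels)
    return model, scores


def top_loading_genes(
    model: PCAModel, comp_i: int, comp_j: int, radius: float = 0.2
) -> list[str]:
    """Genes whose 2-D loading vector on components i, j (1-based) exceeds
    ``radius`` in norm, sorted by norm descending."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    k = model.loadings.shape[1]
    for c in (comp_i, comp_j):
        if not (1 <= c <= k):
            raise ValueError(f"component {c} out of range 1..{k}")
    v = model.loadings[:, [comp_i - 1, comp_j - 1]]
    norms = np.linalg.norm(v, axis=1)
    order = np.argsort(-norms, kind="stable")
    return [model.gene_symbols[i] for i in order if norms[i] > radius]


def compare_loadings(
    model_a: PCAModel, comp_a: int, model_b: PCAModel, comp_b: int
) -> tuple[float, bool]:
    """Pearson correlation of two loading vectors on their shared genes.

    Returns (r, sign_flipped) where sign_flipped is True when r < 0 — the
    same co-expression pattern recovered with reversed sign.
    """
    shared = [g for g in model_a.gene_symbols if g in set(model_b.gene_symbols)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    ia = [model_a.gene_symbols.index(g) for g in shared]
    ib = [model_b.gene_symbols.index(g) for g in shared]
    va = model_a.loadings[ia, comp_a - 1]
    vb = model_b.loadings[ib, comp_b - 1]
    r = float(np.corrcoef(va, vb)[0, 1])
    return r, r < 0


def logistic_association(
    scores: pd.DataFrame,
    outcome,
    n_components: int = 8,
    marginal: bool = False,
) -> pd.DataFrame:
    """Logistic regression of a binary outcome on component scores.

    Default fits the outcome on the first ``n_components`` scores jointly
    (plus intercept) by maximum likelihood with Wald p-values;
    ``marginal=True`` instead fits one single-score model per component.
    Perfect/quasi-separation and nonconvergence are reported in the
    ``flag`` column rather than silently returned.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    cols = list(scores.columns[:n_components])
    x = scores[cols].to_numpy(dtype=float)
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("need n > number of components + 1")

    def _fit(design, names):
        import warnings as _w

        design = sm.add_constant(design, has_constant="add")
        flag = "ok"
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            try:
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            except Exception as exc:  # separation can raise outright
                return [
                    {"component": nm, "coef": np.nan, "se": np.nan,
                     "p_value": np.nan, "flag": f"failed: {exc}"}
                    for nm in names
                ]
            if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
                flag = "separation"
        if not fit.mle_retvals.get("converged", True):
            flag = "nonconvergence"
        elif flag == "ok" and np.any(np.abs(fit.params[1:]) > 15):
            flag = "near-separation"
        return [
            {"component": nm, "coef": fit.params[k + 1], "se": fit.bse[k + 1],
             "p_value": fit.pvalues[k + 1], "flag": flag}
            for k, nm in enumerate(names)
        ]

    if marginal:
        rows = []
        for j, nm in enumerate(cols):
            rows += _fit(x[:, [j]], [nm])
    else:
        rows = _fit(x, cols)
    return pd.DataFrame(rows).set_index("component")


def manova_wilks(scores_2d, groups) -> tuple[float, float, int, float]:
    """Wilks' lambda MANOVA of 2-D scores across groups.

    Lambda = det(W)/det(T) with W and T the within-group and total
    cross-product matrices; Bartlett approximation
    chi2 = -(n - 1 - (p + g)/2) * ln(Lambda), df = p*(g-1).
    Returns (lambda, chi2, df, p).
    """
    x = np.asarray(scores_2d, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be a 2-D array (samples x dims)")
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 3):
        small = levels[counts < 3]
        raise ValueError(f"group(s) with < 3 samples: {list(small)}")
    n, p = x.shape
    g = len(levels)
    grand = x.mean(axis=0)
    t_mat = (x - grand).T @ (x - grand)
    w_mat = np.zeros_like(t_mat)
    for lev in levels:
        xi = x[groups == lev]
        ci = xi - xi.mean(axis=0)
        w_mat += ci.T @ ci
    det_t = np.linalg.det(t_mat)
    if abs(det_t) < 1e-300:
        raise ValueError("singular total cross-product matrix")
    lam = float(np.linalg.det(w_mat) / det_t)
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    chi2 = float(-(n - 1 - (p + g) / 2.0) * np.log(lam))
    df = p * (g - 1)
    pval = float(chi2_dist.sf(chi2, df))
    return lam, chi2, df, pval
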