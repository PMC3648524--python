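"""Expression-based triple-negative (TN) status calling.

Class-conditional Gaussian densities over ESR1/PGR/ERBB2 log2 expression are
fit to IHC-labeled samples (one density for IHC TN samples, one for IHC
receptor-positive samples); unlabeled samples are called by the posterior
probability of TN under the two densities with an empirical class prior.

Two density modes are available: ``joint`` (default) fits a full trivariate
Gaussian per class, capturing receptor co-expression; ``diagonal`` fits
independent per-gene Gaussians (a per-receptor-density reading of the same
procedure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .io import ExpressionMatrix, RECEPTOR_GENES

logger = logging.getLogger(__name__)

_MIN_CLASS_SIZE = 4


@dataclass
class GaussianStatusModel:
    """Trained class-conditional Gaussian model for TN vs receptor-positive."""

    genes: list[str]
    mean_tn: np.ndarray
    mean_rp: np.ndarray
    cov_tn: np.ndarray
    cov_rp: np.ndarray
    prior_tn: float
    mode: str = "joint"

    def __post_init__(self):
        if not (0.0 < self.prior_tn < 1.0):
            raise ValueError(f"prior_tn must lie in (0,1), got {self.prior_tn}")


def _mle_gaussian(x: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood mean and covariance with eps*I regularization.

    eps = 1e-6 x mean diagonal of the MLE covariance; a floor of 1e-6 keeps
    fully degenerate classes (identical samples) usable.
    """
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / x.shape[0]
    if mode == "diagonal":
        cov = np.diag(np.diag(cov))
    eps = 1e-6 * float(np.mean(np.diag(cov)))
    if eps <= 0.0:
        eps = 1e-6
    # regularize only when near-singular
    if np.linalg.matrix_rank(cov, tol=1e-10) < cov.shape[0] or np.min(
        np.linalg.eigvalsh(cov)
    ) < eps:
        cov = cov + eps * np.eye(cov.shape[0])
    return mean, cov


def fit_status_model(
    expr3: ExpressionMatrix | pd.DataFrame | np.ndarray,
    tn_labels,
    genes: tuple[str, ...] = RECEPTOR_GENES,
    mode: str = "joint",
) -> GaussianStatusModel:
    """Fit class-conditional Gaussians on IHC-labeled samples.

    Parameters
    ----------
    expr3 : receptor-gene expression, genes x samples (3 x n) or raw array.
    tn_labels : boolean array-like, True for IHC triple-negative samples.
    mode : "joint" (full covariance) or "diagonal".

    The prior for TN is the labeled TN fraction. Each class needs at least
    4 labeled samples.
    """
    if mode not in ("joint", "diagonal"):
        raise ValueError(f"unknown mode {mode!r}")
    x, genes = _as_samples_by_genes(expr3, genes)
    labels = np.asarray(tn_labels, dtype=bool)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("label length does not match the number of samples")
    n_tn, n_rp = int(labels.sum()), int((~labels).sum())
    if n_tn < _MIN_CLASS_SIZE or n_rp < _MIN_CLASS_SIZE:
        raise ValueError(
            f"each class needs >= {_MIN_CLASS_SIZE} labeled samples "
            f"(TN={n_tn}, RP={n_rp})"
        )
    mean_tn, cov_tn = _mle_gaussian(x[labels], mode)
    mean_rp, cov_rp = _mle_gaussian(x[~labels], mode)
    prior = n_tn / (n_tn + n_rp)
    logger.info("status model: %d TN / %d RP labeled samples, prior_tn=%.3f", n_tn, n_rp, prior)
    return GaussianStatusModel(
        genes=list(genes), mean_tn=mean_tn, mean_rp=mean_rp,
        cov_tn=cov_tn, cov_rp=cov_rp, prior_tn=prior, mode=mode,
    )


def _as_samples_by_genes(expr3, genes):
    if isinstance(expr3, ExpressionMatrix):
        sub = expr3.subset_genes(list(genes))
        return sub.values.T, list(genes)
    if isinstance(expr3, pd.DataFrame):
        sub = expr3.loc[list(genes)]
        return sub.to_numpy(dtype=float).T, list(genes)
    x = np.asarray(expr3, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D array (genes x samples)")
    return x.T, list(genes)[: x.shape[0]]


def assign_tn_status(
    model: GaussianStatusModel,
    expr3: ExpressionMatrix | pd.DataFrame | np.ndarray,
    sample_ids=None,
) -> pd.DataFrame:
    """Posterior TN probability and call per sample.

    posterior_tn = prior * phi_tn(x) / (prior * phi_tn(x) + (1-prior) * phi_rp(x)),
    evaluated in log space; call = "TN" iff posterior_tn > 0.5 (a posterior of
    exactly 0.5 is called receptor-positive, the conservative tie-break).
    """
    x, _ = _as_samples_by_genes(expr3, model.genes)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite expression values")
    log_tn = multivariate_normal.logpdf(x, mean=model.mean_tn, cov=model.cov_tn)
    log_rp = multivariate_normal.logpdf(x, mean=model.mean_rp, cov=model.cov_rp)
    a = np.log(model.prior_tn) + np.atleast_1d(log_tn)
    b = np.log1p(-model.prior_tn) + np.atleast_1d(log_rp)
    # stable posterior: 1 / (1 + exp(b - a))
    post = 1.0 / (1.0 + np.exp(np.clip(b - a, -700, 700)))
    call = np.where(post > 0.5, "TN", "RP")
    if sample_ids is None:
        if isinstance(expr3, ExpressionMatrix):
            sample_ids = expr3.sample_ids
        elif isinstance(expr3, pd.DataFrame):
            sample_ids = list(expr3.columns)
        else:
            sample_ids = list(range(len(post)))
    return pd.DataFrame({"posterior_tn": post, "call": call}, index=sample_ids)


def assign_tn_with_ihc(
    model: GaussianStatusModel,
    expr3,
    ihc: pd.DataFrame,
) -> pd.DataFrame:
    """Combine IHC with the expression model.

    Any IHC-positive receptor forces an RP call (IHC TN requires all three
    receptors negative); all-negative IHC forces TN; samples with partial or
    fully unknown IHC and no positive receptor fall back to the model call.
    Adds a ``source`` column ("ihc" or "model").
    """
    calls = assign_tn_status(model, expr3)
    cols = [c for c in ihc.columns if c in ("ihc_er", "ihc_pr", "ihc_her2")] or list(ihc.columns)
    ihc = ihc.reindex(calls.index)
    any_pos = (ihc[cols] == "pos").any(axis=1)
    all_neg = (ihc[cols] == "neg").all(axis=1)
    out = calls.copy()
    out["source"] = "model"
    out.loc[any_pos, ["call", "source"]] = ["RP", "ihc"]
    out.loc[all_neg, ["call", "source"]] = ["TN", "ihc"]
    return out


def status_error_rate(calls, truth) -> tuple[float, pd.DataFrame]:
    """Misclassification fraction with a 2x2 count breakdown.

    ``calls`` and ``truth`` are same-length label vectors (any labels that
    compare equal count as correct).
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {truth.shape}")
    mismatch = calls != truth
    breakdown = (
        pd.crosstab(pd.Series(truth, name="truth"), pd.Series(calls, name="call"))
        if len(calls)
        else pd.DataFrame()
    )
    return float(np.mean(mismatch)), breakdown
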