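"""Nearest-centroid subtype classification with Spearman correlation.

The same machinery serves PAM50-style intrinsic subtyping and TNBC
subtyping: class centroids are per-gene summaries (mean by default) of the
training samples, and a new sample is assigned to the class whose centroid
has the highest Spearman correlation with the sample's expression over the
classifier genes — unless every correlation falls below the unclassified
threshold (0.1 by default), in which case the sample is left unclassified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class CentroidModel:
    gene_symbols: list[str]
    class_names: list[str]
    centroids: np.ndarray  # classes x genes
    correlation_threshold: float = 0.1

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (len(self.class_names), len(self.gene_symbols)):
            raise ValueError("centroid matrix shape inconsistent with class/gene lists")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate classifier genes")
        if not (-1.0 <= self.correlation_threshold <= 1.0):
            raise ValueError("correlation_threshold must be in [-1,1]")

    def to_files(self, tsv_path, json_path) -> None:
        pd.DataFrame(
            self.centroids.T, index=self.gene_symbols, columns=self.class_names
        ).to_csv(tsv_path, sep="\t", float_format="%.17g")
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "class_names": self.class_names,
                    "correlation_threshold": self.correlation_threshold,
                },
                fh,
            )

    @classmethod
    def from_files(cls, tsv_path, json_path) -> "CentroidModel":
        frame = pd.read_csv(tsv_path, sep="\t", index_col=0)
        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(
            gene_symbols=list(frame.index),
            class_names=meta["class_names"],
            centroids=frame[meta["class_names"]].to_numpy().T,
            correlation_threshold=meta["correlation_threshold"],
        )


def fit_centroids(
    expr: ExpressionMatrix,
    labels,
    statistic: str = "mean",
    correlation_threshold: float = 0.1,
) -> CentroidModel:
    """Per-gene mean (or median) of each class's samples; classes sorted.

    Each class needs at least 2 samples.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown centroid statistic {statistic!r}")
    labels = pd.Series(np.asarray(labels), index=expr.sample_ids)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"class(es) with < 2 samples: {list(small.index)}")
    class_names = sorted(map(str, counts.index))
    frame = expr.to_frame()
    rows = []
    for cname in class_names:
        cols = labels.index[labels.astype(str) == cname]
        block = frame[list(cols)]
        rows.append(block.mean(axis=1) if statistic == "mean" else block.median(axis=1))
    centroids = np.vstack([r.to_numpy() for r in rows])
    return CentroidModel(
        gene_symbols=expr.gene_ids,
        class_names=class_names,
        centroids=centroids,
        correlation_threshold=correlation_threshold,
    )


def _spearman(sample: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Spearman correlation of one sample against each centroid row.

    Average ranks for ties, then Pearson on the ranks.
    """
    rs = rankdata(sample)
    rc = np.apply_along_axis(rankdata, 1, centroids)
    rs = rs - rs.mean()
    rc = rc - rc.mean(axis=1, keepdims=True)
    denom = np.sqrt((rs @ rs) * np.sum(rc * rc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ rs) / denom
    return np.where(np.isfinite(rho), rho, 0.0)


def classify(model: CentroidModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Assign each sample to the best-correlated centroid.

    Model genes missing from the matrix are dropped pairwise (logged); fewer
    than 3 overlapping genes is an error. Returns a DataFrame with one
    correlation column per class plus ``label`` (or "unclassified" when the
    maximum correlation is below the threshold). Exact correlation ties are
    broken by class order and logged.
    """
    present = [g for g in model.gene_symbols if g in set(expr.gene_ids)]
    dropped = [g for g in model.gene_symbols if g not in set(expr.gene_ids)]
    if dropped:
        logger.info("classify: dropping %d model genes absent from matrix: %s",
                    len(dropped), dropped)
    if len(present) < 3:
        raise ValueError(f"only {len(present)} model genes present; need >= 3")
    gidx = [model.gene_symbols.index(g) for g in present]
    cent = model.centroids[:, gidx]
    sub = expr.subset_genes(present)
    x = sub.values.T  # samples x genes
    labels, rows = [], []
    for i in range(x.shape[0]):
        rho = _spearman(x[i], cent)
        rows.append(rho)
        best = int(np.argmax(rho))  # argmax takes the first max: class-order tie-break
        if np.sum(rho == rho[best]) > 1:
            tied = [model.class_names[j] for j in np.where(rho == rho[best])[0]]
            logger.info("classify: correlation tie for sample %s among %s; keeping %s",
                        expr.sample_ids[i], tied, model.class_names[best])
        if rho[best] < model.correlation_threshold:
            labels.append(UNCLASSIFIED)
        else:
            labels.append(model.class_names[best])
    out = pd.DataFrame(rows, index=expr.sample_ids,
                       columns=[f"rho_{c}" for c in model.class_names])
    out["label"] = labels
    return out


def loocv(
    expr: ExpressionMatrix,
    labels,
    statistic: str = "mean",
    correlation_threshold: float = 0.1,
    refit: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated accuracy of the centroid classifier.

    Each sample is classified by centroids refit without it (``refit=False``
    reuses full-data centroids, the optimistic resubstitution-style variant).
    Unclassified counts as incorrect. Returns (accuracy, confusion table with
    true labels on rows).
    """
    labels = pd.Series(np.asarray(labels).astype(str), index=expr.sample_ids)
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError(
            f"LOOCV needs >= 3 samples per class, got {counts.to_dict()}"
        )
    full_model = fit_centroids(expr, labels, statistic, correlation_threshold)
    predicted = []
    for sid in expr.sample_ids:
        rest = [s for s in expr.sample_ids if s != sid]
        model = (
            fit_centroids(expr.subset_samples(rest), labels.loc[rest],
                          statistic, correlation_threshold)
            if refit
            else full_model
        )
        pred = classify(model, expr.subset_samples([sid]))["label"].iloc[0]
        predicted.append(pred)
    predicted = pd.Series(predicted, index=expr.sample_ids, name="predicted")
    accuracy = float((predicted == labels).mean())
    confusion = pd.crosstab(labels.rename("true"), predicted)
    return accuracy, confusion
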