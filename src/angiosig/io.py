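"""Expression-matrix data model, TSV readers/writers, probe collapsing and gene panels.

The matrix convention throughout the package is genes x samples, values on the
log2 scale (expression is assumed already normalized upstream; this layer never
renormalizes). Annotation tables are keyed by sample id and carry IHC receptor
status, derived triple-negative (TN) calls, subtype labels, survival and
clinical covariates. Missing annotation values stay explicit ("unknown"/NA);
nothing is imputed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IHC_LEVELS = ("pos", "neg", "unknown")
TN_LEVELS = ("TN", "RP", "unknown")


class ExpressionMatrix:
    """A validated genes x samples matrix of log2 expression values.

    Parameters
    ----------
    values : array-like, shape (n_genes, n_samples)
    gene_ids, sample_ids : sequences of unique strings

    Invariants enforced at construction: unique ids, finite values, and
    dimensions consistent with the id lists.
    """

    def __init__(self, values, gene_ids: Sequence[str], sample_ids: Sequence[str]):
        values = np.asarray(values, dtype=float)
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(gene_ids)} gene ids "
                f"and {len(sample_ids)} sample ids"
            )
        _check_unique(gene_ids, "gene id")
        _check_unique(sample_ids, "sample id")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {gene_ids[bad[0]]!r}, sample {sample_ids[bad[1]]!r}"
            )
        self._frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def gene_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def to_frame(self) -> pd.DataFrame:
        """Return a copy as a genes x samples DataFrame."""
        return self._frame.copy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self._frame.index]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        return ExpressionMatrix.from_frame(self._frame.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self._frame.columns]
        if missing:
            raise KeyError(f"samples not present: {missing}")
        return ExpressionMatrix.from_frame(self._frame[list(samples)])

    def gene_vector(self, gene: str) -> np.ndarray:
        return self._frame.loc[gene].to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}(s): {sorted(set(dups))}")


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered set of gene symbols."""

    name: str
    gene_symbols: tuple[str, ...]

    def __post_init__(self):
        if not self.gene_symbols:
            raise ValueError("panel must be nonempty")
        _check_unique(self.gene_symbols, "panel gene")

    def __len__(self) -> int:
        return len(self.gene_symbols)


def load_panel(name: str = "vegf_sema") -> GenePanel:
    """Load a bundled gene panel by name.

    The default ``vegf_sema`` panel is the 31 VEGF- and semaphorin-related
    genes (VEGF ligands and receptors, neuropilins, semaphorin classes 3-7
    and plexins) analysed throughout the package.
    """
    ref = resources.files("angiosig").joinpath(f"panels/{name}.txt")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise KeyError(f"no bundled panel named {name!r}") from None
    symbols = tuple(line.strip() for line in text.splitlines() if line.strip())
    return GenePanel(name=name, gene_symbols=symbols)


VEGF_SEMA_PANEL = load_panel("vegf_sema")

#: Receptor genes used for expression-based ER/PR/HER2 status calling.
RECEPTOR_GENES = ("ESR1", "PGR", "ERBB2")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Read a tab-separated expression table (first column = row ids).

    ``orientation`` is ``"genes_by_samples"`` (default) or
    ``"samples_by_genes"`` (the table is transposed after reading).
    Malformed cells, duplicate ids and non-numeric values raise with
    row/column context.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValueError(f"duplicate row id(s) in {path}: {dups}")
    if raw.columns.has_duplicates:
        dups = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise ValueError(f"duplicate column id(s) in {path}: {dups}")
    try:
        values = raw.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError):
        for col in raw.columns:
            for row, cell in raw[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {row!r}, column {col!r}: {cell!r}"
                    ) from None
        raise
    mat = ExpressionMatrix(values, list(raw.index), list(raw.columns))
    if orientation == "samples_by_genes":
        mat = ExpressionMatrix.from_frame(mat.to_frame().T)
    logger.info("read expression matrix %s: %d genes x %d samples", path, *mat.shape)
    return mat


def write_expression(expr: ExpressionMatrix, path, index_label: str = "gene") -> None:
    """Write a genes x samples TSV (full float precision, round-trip safe)."""
    frame = expr.to_frame()
    frame.index.name = index_label
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation TSV keyed by sample_id."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    ann.index = ann.index.astype(str)
    if ann.index.has_duplicates:
        dups = sorted(set(ann.index[ann.index.duplicated()]))
        raise ValueError(f"duplicate sample id(s) in {path}: {dups}")
    for col in ("ihc_er", "ihc_pr", "ihc_her2"):
        if col in ann.columns:
            bad = set(ann[col].dropna().unique()) - set(IHC_LEVELS)
            if bad:
                raise ValueError(f"invalid {col} level(s): {sorted(bad)}")
    if "event" in ann.columns:
        ev = ann["event"].dropna()
        if not set(np.unique(ev)).issubset({0, 1, 0.0, 1.0}):
            raise ValueError("event column must be 0/1")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_probe_map(path) -> dict[str, str]:
    """Read a two-column probe_id -> gene_symbol TSV (no header required)."""
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] < 2:
        raise ValueError("probe map must have two columns: probe_id, gene_symbol")
    probes = raw.iloc[:, 0].tolist()
    _check_unique(probes, "probe id")
    return dict(zip(probes, raw.iloc[:, 1].tolist()))


# ---------------------------------------------------------------------------
# Probe collapsing and panel subsetting
# ---------------------------------------------------------------------------

def collapse_probes(
    expr: ExpressionMatrix, probe_map: Mapping[str, str]
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Collapse probe-level rows to one row per gene by maximum variance.

    For each gene with several probe sets, the probe whose values have the
    highest sample variance (n-1 denominator, across all samples jointly) is
    retained unchanged; exact variance ties keep the first probe in input
    order. Returns the collapsed matrix and a gene -> chosen-probe provenance
    map.
    """
    unmapped = [p for p in expr.gene_ids if p not in probe_map]
    if unmapped:
        raise KeyError(f"probes without a gene mapping: {unmapped}")
    frame = expr.to_frame()
    variances = frame.var(axis=1, ddof=1)
    chosen: dict[str, str] = {}
    gene_order: list[str] = []
    best_var: dict[str, float] = {}
    for probe in expr.gene_ids:
        gene = probe_map[probe]
        v = float(variances[probe])
        if gene not in chosen:
            chosen[gene] = probe
            best_var[gene] = v
            gene_order.append(gene)
        elif v > best_var[gene]:  # strict: ties keep first-in-order probe
            chosen[gene] = probe
            best_var[gene] = v
    for gene, probe in chosen.items():
        logger.debug("collapse: gene %s <- probe %s (var %.4g)", gene, probe, best_var[gene])
    rows = frame.loc[[chosen[g] for g in gene_order]].to_numpy()
    return ExpressionMatrix(rows, gene_order, expr.sample_ids), chosen


def subset_panel(expr: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Restrict rows to panel genes present in ``expr``, in panel order.

    Panel genes absent from the matrix are dropped with a warning listing
    them; an empty intersection is an error.
    """
    present = [g for g in panel.gene_symbols if g in set(expr.gene_ids)]
    missing = [g for g in panel.gene_symbols if g not in set(expr.gene_ids)]
    if not present:
        raise ValueError(f"no genes of panel {panel.name!r} present in the matrix")
    if missing:
        warnings.warn(f"panel {panel.name!r}: genes absent from matrix: {missing}")
    return expr.subset_genes(present)
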