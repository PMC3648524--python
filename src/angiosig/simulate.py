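"""Synthetic breast-tumor cohort generator.

Emulates the statistical structure the downstream analyses assume:

* a 31-gene VEGF/semaphorin panel with planted cluster mean-shifts on top of
  iid Gaussian log2 noise (7 default tumor clusters qualitatively mimicking
  the high-VEGFA, high-VEGFC, high-FLT1/FLT4 and high-SEMA3 tumor groups),
* bimodal two-component Gaussian mixtures for the receptor genes ESR1, PGR
  and ERBB2, with triple-negative (TN) truth defined as all three receptors
  drawn from their negative component,
* IHC labels derived from the true mixture component with configurable error
  and missingness,
* survival times from an exponential proportional-hazards model whose
  log-hazard depends on the planted signature score, TN status, stage and
  nodal status, with independent uniform administrative censoring calibrated
  to a target censoring fraction,
* iid Gaussian background genes so probe collapsing / gene ordering run at
  realistic sizes.

Everything is driven by a single integer seed and is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel, RECEPTOR_GENES, VEGF_SEMA_PANEL


@dataclass(frozen=True)
class ReceptorMixture:
    """Two-component Gaussian mixture for one receptor gene (log2 scale)."""

    mu_neg: float
    mu_pos: float
    sigma_neg: float
    sigma_pos: float
    p_pos: float

    def validate(self) -> None:
        if not (0.0 <= self.p_pos <= 1.0):
            raise ValueError(f"p_pos must be in [0,1], got {self.p_pos}")
        if self.sigma_neg <= 0 or self.sigma_pos <= 0:
            raise ValueError("mixture sds must be > 0")


@dataclass(frozen=True)
class ClusterSpec:
    """One planted tumor cluster: name, mixing proportion, panel mean shifts."""

    name: str
    proportion: float
    shift: Mapping[str, float]


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential proportional-hazards generator for tumor survival.

    ``baseline_rate`` is the event rate (per month) at log-hazard 0;
    coefficients are log hazard ratios. Censoring is independent uniform
    administrative censoring on [0, tau] with tau calibrated so the realized
    censoring fraction matches ``censoring_rate``.
    """

    baseline_rate: float = 0.012
    coef_signature: float = -0.7
    coef_tn: float = 0.5
    coef_stage: float = 0.4
    coef_node: float = 0.6
    censoring_rate: float = 0.6

    def validate(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0,1)")


def default_receptor_spec() -> dict[str, ReceptorMixture]:
    # >=4 sd separation per gene: clearly bimodal marginals.
    return {
        "ESR1": ReceptorMixture(6.0, 10.5, 0.8, 0.8, 0.50),
        "PGR": ReceptorMixture(5.5, 9.0, 0.8, 0.8, 0.45),
        "ERBB2": ReceptorMixture(9.0, 12.5, 0.8, 0.8, 0.15),
    }


def default_cluster_spec() -> list[ClusterSpec]:
    """Seven tumor clusters (A-G) with qualitative VEGF/semaphorin shift patterns.

    A/B: high VEGFA, low secreted class-3 semaphorins (A additionally high
    FLT1/FLT4/SEMA3A, B high VEGFC/KDR/NRP1); C: high FLT1/FLT4/SEMA3A with
    low VEGFA/VEGFC; D: high VEGFC/KDR/NRP1/SEMA5A with low VEGFA; E: mild
    class-4/plexin-B pattern; F/G: high class-3 semaphorins, low VEGFA.
    """
    return [
        ClusterSpec("A", 0.16, {
            "VEGFA": 2.0, "SEMA3B": -1.8, "SEMA3C": -1.5, "SEMA3F": -1.8,
            "FLT1": 1.5, "FLT4": 1.5, "SEMA3A": 1.2,
            "VEGFC": -1.2, "KDR": -1.2, "NRP1": -1.0,
        }),
        ClusterSpec("B", 0.15, {
            "VEGFA": 2.0, "SEMA3B": -1.8, "SEMA3C": -1.5, "SEMA3F": -1.8,
            "VEGFC": 1.2, "KDR": 1.2, "NRP1": 1.0, "FLT1": -1.2,
        }),
        ClusterSpec("C", 0.12, {
            "FLT1": 1.8, "FLT4": 1.8, "SEMA3A": 1.8, "SEMA6B": 1.0, "SEMA7A": 1.0,
            "VEGFA": -1.5, "VEGFC": -1.2, "KDR": -1.2, "NRP1": -1.0,
            "SEMA3C": -1.0, "PLXNA1": -1.0, "PLXND1": -1.0,
        }),
        ClusterSpec("D", 0.18, {
            "VEGFC": 2.0, "KDR": 1.8, "NRP1": 1.5, "SEMA5A": 1.5, "SEMA3G": 1.2,
            "VEGFA": -1.5,
        }),
        ClusterSpec("E", 0.12, {
            "SEMA4D": 1.2, "PLXNB1": 1.2, "PLXNB2": 1.0, "VEGFB": 1.0,
        }),
        ClusterSpec("F", 0.14, {
            "SEMA3B": 1.8, "SEMA3E": 1.5, "SEMA3F": 1.8, "SEMA3G": 1.0,
            "VEGFA": -1.8,
        }),
        ClusterSpec("G", 0.13, {
            "SEMA3B": 1.5, "SEMA3C": 1.5, "SEMA3F": 1.2, "PLXNB1": 1.0,
            "PLXNB2": 1.0, "VEGFA": -1.5, "SEMA4D": -1.0,
        }),
    ]


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort draw."""

    n_tumor: int = 800
    n_normal: int = 40
    n_background_genes: int = 500
    panel: GenePanel = field(default_factory=lambda: VEGF_SEMA_PANEL)
    cluster_spec: list[ClusterSpec] = field(default_factory=default_cluster_spec)
    receptor_spec: dict[str, ReceptorMixture] = field(default_factory=default_receptor_spec)
    baseline_mean: float = 7.5
    noise_sd: float = 0.6
    ihc_missing_rate: float = 0.10
    ihc_error_rate: float = 0.02
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumor < 1:
            raise ValueError("n_tumor must be >= 1")
        if self.n_normal < 0 or self.n_background_genes < 0:
            raise ValueError("counts must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        props = [c.proportion for c in self.cluster_spec]
        if not props or any(p < 0 or p > 1 for p in props):
            raise ValueError("cluster proportions must lie in [0,1]")
        if abs(sum(props) - 1.0) > 1e-8:
            raise ValueError(f"cluster proportions must sum to 1, got {sum(props)}")
        names = [c.name for c in self.cluster_spec]
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")
        for gene, mix in self.receptor_spec.items():
            mix.validate()
        for rate in (self.ihc_missing_rate, self.ihc_error_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("ihc rates must be in [0,1]")
        self.survival.validate()
        unknown = [
            g for c in self.cluster_spec for g in c.shift if g not in self.panel.gene_symbols
        ]
        if unknown:
            raise ValueError(f"cluster shifts reference non-panel genes: {sorted(set(unknown))}")


@dataclass
class CohortTruth:
    """Ground truth of one generated cohort (tumor samples only)."""

    cluster: pd.Series                    # planted cluster name per tumor
    receptor_positive: pd.DataFrame       # bool, tumors x receptor genes
    tn: pd.Series                         # bool triple-negative truth
    signature_score: pd.Series            # projection on the planted direction
    signature_direction: pd.Series        # unit vector over panel genes
    survival_coefficients: dict[str, float]
    censoring_tau: float
    true_event_times: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "cluster": self.cluster.to_dict(),
            "receptor_positive": {
                c: self.receptor_positive[c].astype(bool).to_dict()
                for c in self.receptor_positive.columns
            },
            "tn": self.tn.astype(bool).to_dict(),
            "signature_score": self.signature_score.to_dict(),
            "signature_direction": self.signature_direction.to_dict(),
            "survival_coefficients": self.survival_coefficients,
            "censoring_tau": self.censoring_tau,
            "true_event_times": self.true_event_times.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def cluster_mean_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Planted cluster mean-shift vectors (clusters x panel genes)."""
    genes = list(config.panel.gene_symbols)
    rows = []
    for c in config.cluster_spec:
        rows.append([float(c.shift.get(g, 0.0)) for g in genes])
    return pd.DataFrame(rows, index=[c.name for c in config.cluster_spec], columns=genes)


def planted_signature_directions(config: SimulationConfig) -> pd.DataFrame:
    """Normalized between-cluster contrast directions over the panel genes.

    Row ``c`` is the unit vector along (mean shift of cluster c) minus the
    proportion-weighted overall mean shift. With exactly two clusters this
    reduces (up to sign) to the normalized difference of the two cluster
    means. Raises if only one cluster is configured (no contrast exists).
    """
    if len(config.cluster_spec) < 2:
        raise ValueError("at least two clusters are required for a contrast direction")
    shifts = cluster_mean_matrix(config)
    w = np.array([c.proportion for c in config.cluster_spec])
    overall = w @ shifts.to_numpy() / w.sum()
    centered = shifts.to_numpy() - overall
    norms = np.linalg.norm(centered, axis=1)
    if np.any(norms == 0):
        flat = [shifts.index[i] for i in np.where(norms == 0)[0]]
        raise ValueError(f"cluster(s) with no contrast against the overall mean: {flat}")
    return pd.DataFrame(centered / norms[:, None], index=shifts.index, columns=shifts.columns)


def primary_contrast_direction(config: SimulationConfig) -> pd.Series:
    """Leading planted contrast: first right-singular vector of the
    proportion-weighted, centered cluster-shift matrix (unit norm, sign fixed
    so its largest-magnitude entry is positive)."""
    shifts = cluster_mean_matrix(config)
    w = np.array([c.proportion for c in config.cluster_spec])
    overall = w @ shifts.to_numpy() / w.sum()
    centered = (shifts.to_numpy() - overall) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return pd.Series(v, index=shifts.columns)


def _calibrate_censoring_tau(true_times: np.ndarray, target: float) -> float:
    """Find tau such that uniform-[0, tau] censoring yields the target
    expected censoring fraction on the realized event times.

    With C ~ U(0, tau), P(censored | T) = min(T, tau)/tau, so the expected
    fraction mean(min(T, tau))/tau decreases monotonically in tau; bisection.
    """
    if target <= 0:
        return float("inf")

    def frac(tau: float) -> float:
        return float(np.mean(np.minimum(true_times, tau)) / tau)

    lo = float(np.min(true_times)) * 1e-3 + 1e-12
    hi = float(np.max(true_times)) * 2 + 1e-9
    while frac(hi) > target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Draw one cohort: (expression, annotation, truth).

    Expression rows are panel genes, then ESR1/PGR/ERBB2, then background
    genes; columns are tumors (T0001...) followed by normals (N0001...).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes_panel = list(config.panel.gene_symbols)
    n_t, n_n = config.n_tumor, config.n_normal
    tumor_ids = [f"T{i + 1:04d}" for i in range(n_t)]
    normal_ids = [f"N{i + 1:04d}" for i in range(n_n)]

    # --- planted clusters and panel expression ---------------------------
    props = np.array([c.proportion for c in config.cluster_spec])
    cluster_idx = rng.choice(len(props), size=n_t, p=props / props.sum())
    cluster_names = np.array([c.name for c in config.cluster_spec])[cluster_idx]
    shifts = cluster_mean_matrix(config).to_numpy()
    panel_tumor = (
        config.baseline_mean
        + shifts[cluster_idx]
        + rng.normal(0.0, config.noise_sd, size=(n_t, len(genes_panel)))
    )
    panel_normal = config.baseline_mean + rng.normal(
        0.0, config.noise_sd, size=(n_n, len(genes_panel))
    )

    # --- receptor genes (bimodal mixtures, tumors only) -------------------
    receptor_genes = [g for g in RECEPTOR_GENES if g in config.receptor_spec]
    comp_pos = np.zeros((n_t, len(receptor_genes)), dtype=bool)
    rec_tumor = np.zeros((n_t, len(receptor_genes)))
    rec_normal = np.zeros((n_n, len(receptor_genes)))
    for j, g in enumerate(receptor_genes):
        mix = config.receptor_spec[g]
        comp_pos[:, j] = rng.random(n_t) < mix.p_pos
        mu = np.where(comp_pos[:, j], mix.mu_pos, mix.mu_neg)
        sd = np.where(comp_pos[:, j], mix.sigma_pos, mix.sigma_neg)
        rec_tumor[:, j] = rng.normal(mu, sd)
        # normal tissue: mid-level expression between the two components
        rec_normal[:, j] = rng.normal(
            0.5 * (mix.mu_neg + mix.mu_pos), 0.5 * (mix.sigma_neg + mix.sigma_pos), size=n_n
        )
    tn_truth = ~comp_pos.any(axis=1)

    # --- background genes --------------------------------------------------
    n_bg = config.n_background_genes
    bg_means = rng.uniform(4.0, 12.0, size=n_bg)
    bg_tumor = bg_means + rng.normal(0.0, config.noise_sd, size=(n_t, n_bg))
    bg_normal = bg_means + rng.normal(0.0, config.noise_sd, size=(n_n, n_bg))
    bg_names = [f"BG{i + 1:04d}" for i in range(n_bg)]

    gene_ids = genes_panel + receptor_genes + bg_names
    tumor_block = np.hstack([panel_tumor, rec_tumor, bg_tumor])
    normal_block = np.hstack([panel_normal, rec_normal, bg_normal])
    values = np.vstack([tumor_block, normal_block]).T  # genes x samples
    expr = ExpressionMatrix(values, gene_ids, tumor_ids + normal_ids)

    # --- IHC labels ---------------------------------------------------------
    ihc = {}
    for j, g in enumerate(receptor_genes):
        true_lab = np.where(comp_pos[:, j], "pos", "neg")
        flip = rng.random(n_t) < config.ihc_error_rate
        lab = np.where(
            flip, np.where(true_lab == "pos", "neg", "pos"), true_lab
        )
        missing = rng.random(n_t) < config.ihc_missing_rate
        lab = np.where(missing, "unknown", lab)
        ihc[g] = lab
    ihc_df = pd.DataFrame(ihc, index=tumor_ids)

    def tn_call(row) -> str:
        labs = [row[g] for g in receptor_genes]
        if "pos" in labs:
            return "RP"
        if all(l == "neg" for l in labs):
            return "TN"
        return "unknown"

    tn_ihc = ihc_df.apply(tn_call, axis=1)

    # --- clinical covariates -----------------------------------------------
    stage = rng.choice(["I", "II", "III"], size=n_t, p=[0.30, 0.45, 0.25])
    node = rng.random(n_t) < 0.4
    grade = rng.choice([1, 2, 3], size=n_t, p=[0.20, 0.45, 0.35])
    age = np.clip(rng.normal(58.0, 12.0, size=n_t), 25.0, 90.0)

    # --- survival -----------------------------------------------------------
    direction = primary_contrast_direction(config)
    centered_panel = panel_tumor - panel_tumor.mean(axis=0)
    sig_score = centered_panel @ direction.to_numpy()
    sp = config.survival
    eta = (
        sp.coef_signature * sig_score
        + sp.coef_tn * tn_truth.astype(float)
        + sp.coef_stage * (stage == "III").astype(float)
        + sp.coef_node * node.astype(float)
    )
    rate = sp.baseline_rate * np.exp(eta)
    true_times = rng.exponential(1.0 / rate)
    tau = _calibrate_censoring_tau(true_times, sp.censoring_rate)
    if np.isfinite(tau):
        cens = rng.uniform(0.0, tau, size=n_t)
        time = np.minimum(true_times, cens)
        event = (true_times <= cens).astype(int)
    else:
        time = true_times
        event = np.ones(n_t, dtype=int)

    # --- assemble annotation ------------------------------------------------
    ann_t = pd.DataFrame(
        {
            "tissue": "tumor",
            "ihc_er": ihc_df["ESR1"] if "ESR1" in ihc_df else "unknown",
            "ihc_pr": ihc_df["PGR"] if "PGR" in ihc_df else "unknown",
            "ihc_her2": ihc_df["ERBB2"] if "ERBB2" in ihc_df else "unknown",
            "tn_status": tn_ihc,
            "subtype_label": "unassigned",
            "time": time,
            "event": event,
            "stage": stage,
            "grade": grade,
            "node": node.astype(int),
            "age": age,
        },
        index=tumor_ids,
    )
    ann_n = pd.DataFrame(
        {
            "tissue": "normal",
            "ihc_er": "unknown",
            "ihc_pr": "unknown",
            "ihc_her2": "unknown",
            "tn_status": "unknown",
            "subtype_label": "unassigned",
            "time": np.nan,
            "event": np.nan,
            "stage": pd.NA,
            "grade": pd.NA,
            "node": pd.NA,
            "age": np.nan,
        },
        index=normal_ids,
    )
    annotation = pd.concat([ann_t, ann_n])
    annotation.index.name = "sample_id"

    truth = CohortTruth(
        cluster=pd.Series(cluster_names, index=tumor_ids, name="cluster"),
        receptor_positive=pd.DataFrame(comp_pos, index=tumor_ids, columns=receptor_genes),
        tn=pd.Series(tn_truth, index=tumor_ids, name="tn"),
        signature_score=pd.Series(sig_score, index=tumor_ids, name="signature_score"),
        signature_direction=direction,
        survival_coefficients={
            "signature": sp.coef_signature,
            "tn": sp.coef_tn,
            "stage": sp.coef_stage,
            "node": sp.coef_node,
            "baseline_rate": sp.baseline_rate,
        },
        censoring_tau=float(tau),
        true_event_times=pd.Series(true_times, index=tumor_ids, name="true_event_time"),
    )
    return expr, annotation, truth
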