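"""End-to-end orchestration of the VEGF/semaphorin analysis.

``run_pipeline`` sequences the stages in dependency order — simulate (or
load) -> receptor status -> subtype classification -> differential
expression -> PCA + clinical association -> consensus clustering ->
survival — writing every table as TSV and metadata as JSON, and recording a
manifest with a parameter hash and the seed so identical configs reproduce
identical outputs. A single global seed fans out to per-stage seeds through
numpy SeedSequence(seed, stage_index), so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import io as aio
from . import pca as apca
from . import receptor, centroid, diffexp, survival
from .simulate import (
    ClusterSpec, ReceptorMixture, SimulationConfig, SurvivalSpec, generate_cohort,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "status", "subtype", "diffexp", "pca", "cluster", "survival")


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    outdir: str = "angiosig_out"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    expression_path: str | None = None
    annotation_path: str | None = None
    panel: str = "vegf_sema"
    stages: tuple[str, ...] = STAGES
    # stage parameters
    correlation_threshold: float = 0.1
    loocv_max_samples: int = 150
    conf_level: float = 0.99
    k_min: int = 2
    k_max: int = 7
    consensus_iterations: int = 100
    subsample_fraction: float = 0.8
    consensus_restarts: int = 10
    kmeans_restarts: int = 50

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        if self.k_max < self.k_min:
            raise ValueError(f"k_max={self.k_max} < k_min={self.k_min}")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0,1]")
        if not (0.0 < self.conf_level < 1.0):
            raise ValueError("conf_level must be in (0,1)")
        if self.consensus_iterations < 1 or self.kmeans_restarts < 1:
            raise ValueError("iteration/restart counts must be >= 1")
        if self.simulate:
            self.sim.validate()
        elif not (self.expression_path and self.annotation_path):
            raise ValueError("need expression_path and annotation_path when simulate=False")

    # -- config (de)serialization ------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["panel"] = self.sim.panel.name
        d["sim"]["cluster_spec"] = [
            {"name": c.name, "proportion": c.proportion, "shift": dict(c.shift)}
            for c in self.sim.cluster_spec
        ]
        d["sim"]["receptor_spec"] = {
            g: dataclasses.asdict(m) for g, m in self.sim.receptor_spec.items()
        }
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        if sim_d:
            if "panel" in sim_d:
                sim_d["panel"] = aio.load_panel(sim_d["panel"])
            if "cluster_spec" in sim_d:
                sim_d["cluster_spec"] = [ClusterSpec(**c) for c in sim_d["cluster_spec"]]
            if "receptor_spec" in sim_d:
                sim_d["receptor_spec"] = {
                    g: ReceptorMixture(**m) for g, m in sim_d["receptor_spec"].items()
                }
            if "survival" in sim_d:
                sim_d["survival"] = SurvivalSpec(**sim_d["survival"])
            d["sim"] = SimulationConfig(**sim_d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def params_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence((int(seed), idx)).generate_state(1)[0] % (2**31))


def crosstab(labels_a, labels_b) -> dict[str, pd.DataFrame]:
    """Contingency table of two label vectors over the same samples.

    Returns counts plus both conditional percentage tables:
    ``row_pct[i,j]`` = percent of row-class i found in column-class j, and
    ``col_pct[i,j]`` = percent of column-class j coming from row-class i.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b) or not a.index.equals(b.index):
        raise ValueError("label vectors must cover the same sample set")
    counts = pd.crosstab(a, b)
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    col_pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return {"counts": counts, "row_pct": row_pct, "col_pct": col_pct}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest (also written to disk).

    Any stage failure aborts with the stage name; the partial manifest is
    persisted before the exception propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "stages": {},
        "stats": {},
    }
    config.to_yaml(outdir / "config.yaml")

    def record(stage: str, outputs: list[str], **stats):
        manifest["stages"][stage] = {"outputs": outputs, "seed": stage_seed(config.seed, stage)}
        manifest["stats"].update(stats)
        logger.info("stage %s done: %s", stage, outputs)

    def persist():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)

    current_stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        current_stage = "simulate"
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
            expr, ann, truth = generate_cohort(sim)
            aio.write_expression(expr, outdir / "expression.tsv")
            aio.write_annotation(ann, outdir / "annotation.tsv")
            truth.to_json(outdir / "truth.json")
            if "simulate" in config.stages:
                record("simulate",
                       ["expression.tsv", "annotation.tsv", "truth.json"],
                       n_tumor=int((ann["tissue"] == "tumor").sum()),
                       n_normal=int((ann["tissue"] == "normal").sum()))
        else:
            expr = aio.read_expression(config.expression_path)
            ann = aio.read_annotation(config.annotation_path)
            truth = None
        panel = aio.load_panel(config.panel)
        tumors = list(ann.index[ann["tissue"] == "tumor"]) if "tissue" in ann else list(ann.index)
        normals = [s for s in ann.index if s not in set(tumors)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expr_panel = aio.subset_panel(expr, panel)
        panel_tumor = expr_panel.subset_samples(tumors)

        # ---- receptor status -------------------------------------------
        if "status" in config.stages:
            current_stage = "status"
            rec = expr.subset_genes(list(aio.RECEPTOR_GENES)).subset_samples(tumors)
            ihc = ann.loc[tumors, ["ihc_er", "ihc_pr", "ihc_her2"]]
            labeled = ann.loc[tumors, "tn_status"].isin(["TN", "RP"])
            model = receptor.fit_status_model(
                rec.subset_samples(list(np.array(tumors)[labeled])),
                (ann.loc[tumors, "tn_status"][labeled] == "TN").to_numpy(),
            )
            calls = receptor.assign_tn_with_ihc(model, rec, ihc)
            calls.to_csv(outdir / "tn_calls.tsv", sep="\t")
            stats = {}
            if truth is not None:
                truth_lab = np.where(truth.tn.loc[tumors], "TN", "RP")
                err, _ = receptor.status_error_rate(calls["call"].to_numpy(), truth_lab)
                stats["tn_misclassification_rate"] = err
            record("status", ["tn_calls.tsv"], **stats)

        # ---- subtype classification ------------------------------------
        if "subtype" in config.stages:
            current_stage = "subtype"
            if truth is None:
                raise ValueError("subtype stage of the demo requires simulated truth labels")
            labels = truth.cluster.loc[tumors]
            sub_model = centroid.fit_centroids(
                panel_tumor, labels, correlation_threshold=config.correlation_threshold
            )
            assigned = centroid.classify(sub_model, panel_tumor)
            assigned.to_csv(outdir / "subtype_calls.tsv", sep="\t")
            # LOOCV on a stratified subsample for tractability
            rng = np.random.default_rng(stage_seed(config.seed, "subtype"))
            per_class = max(3, config.loocv_max_samples // labels.nunique())
            keep: list[str] = []
            for name, grp in labels.groupby(labels):
                take = min(len(grp), per_class)
                keep += list(rng.choice(grp.index, size=take, replace=False))
            acc, confusion = centroid.loocv(
                panel_tumor.subset_samples(keep), labels.loc[keep],
                correlation_threshold=config.correlation_threshold,
            )
            confusion.to_csv(outdir / "subtype_loocv_confusion.tsv", sep="\t")
            record("subtype", ["subtype_calls.tsv", "subtype_loocv_confusion.tsv"],
                   loocv_accuracy=acc, loocv_n=len(keep))

        # ---- differential expression ------------------------------------
        if "diffexp" in config.stages:
            current_stage = "diffexp"
            if not normals:
                raise ValueError("diffexp stage needs normal samples")
            de = diffexp.diff_expression_table(
                expr_panel, tumors, normals, conf=config.conf_level
            )
            de.to_csv(outdir / "diffexp.tsv", sep="\t")
            ligands = [g for g in de.index if g.startswith(("VEGF", "PGF", "SEMA"))]
            receptors = [g for g in de.index if g.startswith(("FLT", "KDR", "NRP", "PLXN"))]
            record("diffexp", ["diffexp.tsv"],
                   mean_abs_log2_ratio_ligands=diffexp.mean_abs_difference(
                       de.loc[ligands, "log2_ratio"]),
                   mean_abs_log2_ratio_receptors=diffexp.mean_abs_difference(
                       de.loc[receptors, "log2_ratio"]),
                   n_significant=int((de["p_value"] < 0.001).sum()))

        # ---- PCA and clinical association -------------------------------
        pca_scores = None
        if "pca" in config.stages:
            current_stage = "pca"
            pca_model, pca_scores = apca.fit_pca(panel_tumor, label_suffix="a")
            pd.DataFrame(
                pca_model.loadings, index=pca_model.gene_symbols,
                columns=pca_model.component_labels,
            ).to_csv(outdir / "pca_loadings.tsv", sep="\t", float_format="%.17g")
            pca_scores.to_csv(outdir / "pca_scores.tsv", sep="\t", float_format="%.17g")
            stats = {
                "pc1_explained_fraction": float(
                    pca_model.explained_variance[0] / pca_model.explained_variance.sum()
                )
            }
            tn_known = ann.loc[tumors, "tn_status"].isin(["TN", "RP"])
            if truth is not None:
                outcome = truth.tn.loc[tumors].astype(int).to_numpy()
            else:
                outcome = (ann.loc[tumors, "tn_status"] == "TN").astype(int).to_numpy()
            assoc = apca.logistic_association(pca_scores, outcome)
            assoc.to_csv(outdir / "pca_tn_association.tsv", sep="\t")
            lam, c2, df_, pval = apca.manova_wilks(
                pca_scores.iloc[:, 2:4].to_numpy(), outcome
            )
            stats["manova_wilks_lambda"] = lam
            stats["manova_p"] = pval
            if truth is not None:
                planted = truth.signature_direction.reindex(pca_model.gene_symbols).to_numpy()
                cosines = np.abs(pca_model.loadings.T @ planted)
                stats["planted_direction_best_cosine"] = float(np.max(cosines[:4]))
            with open(outdir / "pca_meta.json", "w") as fh:
                json.dump(
                    {
                        "explained_variance": pca_model.explained_variance.tolist(),
                        "center": pca_model.center.tolist(),
                    },
                    fh,
                )
            record("pca", ["pca_loadings.tsv", "pca_scores.tsv",
                           "pca_tn_association.tsv", "pca_meta.json"], **stats)

        # ---- consensus clustering ---------------------------------------
        cluster_labels = None
        if "cluster" in config.stages:
            current_stage = "cluster"
            seed = stage_seed(config.seed, "cluster")
            results = {}
            for k in range(config.k_min, config.k_max + 1):
                results[k] = cl.consensus_cluster(
                    panel_tumor.values.T, k,
                    iterations=config.consensus_iterations,
                    subsample_fraction=config.subsample_fraction,
                    seed=seed + k,
                    restarts=config.consensus_restarts,
                    full_restarts=config.kmeans_restarts,
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = cl.select_k(results)
            area_table = pd.DataFrame(
                {"k": sel.k_range, "cdf_area": sel.cdf_areas,
                 "relative_change": sel.relative_area_changes}
            )
            area_table.to_csv(outdir / "consensus_areas.tsv", sep="\t", index=False)
            chosen = results[sel.chosen_k]
            cluster_labels = pd.Series(chosen.labels, index=tumors, name="cluster")
            cluster_labels.to_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t")
            np.savetxt(outdir / f"consensus_k{sel.chosen_k}.tsv",
                       chosen.consensus, delimiter="\t", fmt="%.6g")
            stats = {"chosen_k": sel.chosen_k}
            if truth is not None:
                from sklearn.metrics import adjusted_rand_score

                planted = truth.cluster.loc[tumors]
                stats["cluster_ari_vs_planted"] = float(
                    adjusted_rand_score(planted, cluster_labels)
                )
                true_k = planted.nunique()
                if true_k in results:
                    stats["cluster_ari_at_planted_k"] = float(
                        adjusted_rand_score(planted, results[true_k].labels)
                    )
                tabs = crosstab(planted, cluster_labels)
                tabs["counts"].to_csv(outdir / "cluster_crosstab.tsv", sep="\t")
                stats["min_modal_capture_pct"] = float(tabs["row_pct"].max(axis=1).min())
            record("cluster",
                   ["consensus_areas.tsv", "cluster_labels.tsv",
                    f"consensus_k{sel.chosen_k}.tsv", "cluster_crosstab.tsv"],
                   **stats)

        # ---- survival ----------------------------------------------------
        if "survival" in config.stages:
            current_stage = "survival"
            surv_ann = ann.loc[tumors].dropna(subset=["time", "event"])
            ids = list(surv_ann.index)
            times = surv_ann["time"].to_numpy(dtype=float)
            events = surv_ann["event"].to_numpy(dtype=int)
            factors = pd.DataFrame(index=ids)
            tn_col = (surv_ann["tn_status"] == "TN").astype(int)
            factors["TN"] = tn_col
            factors["stage_III"] = (surv_ann["stage"] == "III").astype(int)
            factors["grade_3"] = (surv_ann["grade"].astype(float) == 3).astype(int)
            factors["node_positive"] = surv_ann["node"].astype(float).astype(int)
            factors["age_gt_50"] = (surv_ann["age"].astype(float) > 50).astype(int)
            if pca_scores is not None:
                for comp in pca_scores.columns[:6]:
                    factors[f"{comp}_gt_median"] = survival.median_dichotomize(
                        pca_scores.loc[ids, comp].to_numpy()
                    )
            table = survival.survival_table(times, events, factors)
            table.to_csv(outdir / "survival_table.tsv", sep="\t")
            chi2, df_, p_tn = survival.logrank_test(times, events, tn_col.to_numpy())
            km_tn = survival.km_estimate(times[tn_col == 1], events[tn_col == 1])
            km_rp = survival.km_estimate(times[tn_col == 0], events[tn_col == 0])
            record("survival", ["survival_table.tsv"],
                   logrank_tn_chi2=chi2, logrank_tn_p=p_tn,
                   km_5yr_tn=km_tn.survival_at(60.0),
                   km_5yr_rp=km_rp.survival_at(60.0),
                   censoring_fraction=float(1.0 - events.mean()))
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        persist()
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    started = manifest.setdefault("completed_at", time.strftime("%Y-%m-%dT%H:%M:%S"))
    persist()
    return manifest
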