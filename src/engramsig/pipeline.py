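"""End-to-end orchestration: simulate/load → QC → cluster → DE → signatures →
reactivity → GO network, with plain-file stage outputs and a run manifest.

Stage outputs are tab-separated tables under numbered subdirectories of the
run directory, so any stage can be inspected or re-consumed on its own.
The manifest records every parameter, package versions and stage timings;
all randomness derives from the single configured seed, so re-running an
identical configuration reproduces every stage output byte for byte (only
the manifest carries timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import iterative_cluster, name_clusters, refine_clusters_rf
from .diffexp import ROTSParams, rots_test
from .gonet import enrichment_test, export_network, go_gene_distance
from .io import read_matrix, read_metadata
from .qc import exclude_arc_discordant, qc_filter_nuclei
from .reactivity import (
    batch_association,
    evaluate_roc,
    predict_primed,
    reactivity_component,
    select_predictive_genes,
    train_models,
)
from .signatures import (
    assign_temporal_groups,
    classify_activity_state,
    late_signature_score,
    reactivation_labels,
)
from .simulate import SimulationConfig, save_simulation, simulate_experiment, simulate_go_annotation

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("engramsig")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All stage parameters with study defaults.

    Depth/Arc QC cutoffs, the t-SNE settings, the bootstrap count and seed
    of the differential-expression test, the predictive-gene fractions and
    the forest sizes default to the published analysis values; they are
    calibrated to real SmartSeq2-scale data.  ``PipelineConfig.for_simulation``
    returns a configuration whose QC gene cutoff is rescaled to the
    simulated transcriptome size (a simulated cohort has far fewer genes
    than a real one, so the absolute detected-gene cutoff must scale).
    """

    seed: int = 1234
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    matrix_path: str | None = None
    metadata_path: str | None = None
    marker_table_path: str | None = None
    # QC
    qc_min_reads: int = 100_000
    qc_min_genes: int = 4000
    arc_threshold: float = 2.5
    # clustering (cell typing runs on home-cage and 1-h nuclei, the strata
    # the cell-type identification was designed for)
    cluster_enabled: bool = True
    cluster_conditions: tuple[str, ...] = ("HC", "NE1h")
    de_alpha: float = 0.05
    min_de_genes: int = 10
    min_leaf: int = 10
    perplexity: float = 17.0
    initial_dims: int = 20
    theta: float = 0.0
    split_B: int = 100
    refine_trees: int = 1000
    refine_gini_cutoff: float = 1.0
    refine_min_total_expression: float = 10.0
    # differential expression
    de_B: int = 500
    de_seed: int = 1234
    alpha: float = 0.05
    # signatures
    threshold_policy: str = "two_means"
    fixed_threshold: float = 10.0
    # reactivity
    frac_up: float = 0.8
    frac_down: float = 0.4
    expr_cutoff: float = 1.0
    n_train_per_class: int = 15
    reactivity_trees: int = 10_000
    gini_pool_cutoff: float = 0.4
    # GO network
    go_n_terms: int = 300
    go_max_parents: int = 8
    go_edge_threshold: float = 0.3

    def validate(self) -> None:
        for frac in (self.frac_up, self.frac_down):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction out of [0, 1]: {frac}")
        if not 0.0 <= self.go_edge_threshold <= 1.0:
            raise ValueError("go_edge_threshold must be in [0, 1]")
        if self.simulate:
            self.sim.validate()
        elif not (self.matrix_path and self.metadata_path):
            raise ValueError("matrix_path and metadata_path required unless simulating")

    #: transcriptome size the absolute QC thresholds were calibrated on
    REFERENCE_TRANSCRIPTOME = 20_000

    @classmethod
    def for_simulation(cls, sim: SimulationConfig | None = None, **kwargs) -> "PipelineConfig":
        sim = sim or SimulationConfig()
        kwargs.setdefault("qc_min_genes", max(sim.n_genes // 4, 1))
        # TPM concentrates on fewer genes in a reduced transcriptome, so the
        # absolute Arc threshold shifts by the log2 inflation factor
        inflation = math.log2(max(cls.REFERENCE_TRANSCRIPTOME / sim.n_genes, 1.0))
        kwargs.setdefault("arc_threshold", 2.5 + inflation)
        return cls(simulate=True, sim=sim, **kwargs)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_yaml() if self.simulate else None
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        sim_text = d.pop("sim", None)
        if "cluster_conditions" in d:
            d["cluster_conditions"] = tuple(d["cluster_conditions"])
        cfg = cls(**{k: v for k, v in d.items() if k != "sim"})
        if sim_text:
            cfg.sim = SimulationConfig.from_yaml(sim_text)
        return cfg

    def param_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)


def _marker_table(matrix: pd.DataFrame, metadata: pd.DataFrame,
                  config: "PipelineConfig") -> dict[str, list[str]]:
    """Cell-type marker genes for prior-knowledge cluster naming.

    For simulated cohorts the generator's marker naming convention
    (``mk_<type>_<i>``) is used; for real data a two-column TSV
    (cell_type, gene) can be supplied via ``marker_table_path``.
    """
    if config.marker_table_path:
        tab = pd.read_csv(config.marker_table_path, sep="\t")
        table: dict[str, list[str]] = {}
        for ct, g in zip(tab.iloc[:, 0], tab.iloc[:, 1]):
            table.setdefault(str(ct), []).append(str(g))
        return table
    if config.simulate:
        types = sorted(metadata["population"].unique())
        return {
            ct: [g for g in matrix.index if str(g).startswith(f"mk_{ct}_")]
            for ct in types
        }
    return {}


def _sub(meta: pd.DataFrame, matrix: pd.DataFrame, **conditions) -> pd.DataFrame:
    mask = pd.Series(True, index=meta.index)
    for col, val in conditions.items():
        vals = val if isinstance(val, (list, tuple, set)) else [val]
        mask &= meta[col].isin(vals)
    return matrix[meta.index[mask & meta.index.isin(matrix.columns)]]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages, writing outputs under ``out_dir``.

    Returns a result dictionary of the key in-memory objects.  A stage
    failure raises with the stage name; outputs of completed stages remain
    on disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "parameters": yaml.safe_load(config.to_yaml()),
        "param_hash": config.param_hash(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    results: dict = {}
    rng_pool = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["simulate", "cluster", "de", "signatures", "reactivity", "gonet"],
            rng_pool.spawn(6),
        )
    }

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)

        def done():
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
            log.info("stage %s finished in %.1fs", name, time.time() - t0)

        return done

    try:
        # ---- input ----------------------------------------------------
        done = stage("input")
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=stage_seeds["simulate"])
            matrix, metadata, truth = simulate_experiment(sim)
            save_simulation(out / "00_input", matrix, metadata, truth, sim)
            results["truth"] = truth
        else:
            matrix = read_matrix(config.matrix_path)
            metadata = read_metadata(config.metadata_path, matrix)
        results["matrix_raw"], results["metadata"] = matrix, metadata
        done()

        # ---- qc --------------------------------------------------------
        done = stage("qc")
        report = qc_filter_nuclei(matrix, metadata,
                                  min_reads=config.qc_min_reads,
                                  min_genes=config.qc_min_genes)
        matrix = matrix[report.retained_ids]
        # the Arc-concordance rule targets putative *inactive* FOS- nuclei;
        # nuclei sorted through an ARC+ gate are known recently active and
        # exempt (their FOS-/Arc-high pattern is the collection criterion)
        candidates = [n for n in matrix.columns
                      if metadata.loc[n, "arc_protein"] != "pos"]
        arc_report = exclude_arc_discordant(matrix[candidates], metadata,
                                            arc_threshold=config.arc_threshold)
        dropped = set(candidates) - set(arc_report.retained_ids)
        matrix = matrix[[n for n in matrix.columns if n not in dropped]]
        metadata = metadata.loc[matrix.columns]
        qc_summary = {**report.summary(),
                      "n_fail_arc_rule": arc_report.n_fail_arc_rule,
                      "n_retained": matrix.shape[1]}
        (out / "01_qc").mkdir(parents=True, exist_ok=True)
        (out / "01_qc" / "qc_summary.json").write_text(
            json.dumps(qc_summary, indent=1))
        _write(pd.DataFrame({"nucleus_id": list(matrix.columns)}),
               out / "01_qc" / "retained_nuclei.tsv", index=False)
        results["matrix"], results["qc"] = matrix, qc_summary
        done()

        # ---- clustering ------------------------------------------------
        if config.cluster_enabled:
            done = stage("cluster")
            cluster_matrix = _sub(metadata.loc[matrix.columns], matrix,
                                  condition=list(config.cluster_conditions))
            tree = iterative_cluster(
                cluster_matrix, de_alpha=config.de_alpha, min_de_genes=config.min_de_genes,
                min_leaf=config.min_leaf, seed=stage_seeds["cluster"],
                de_params=ROTSParams(B=config.split_B, n_perm=500,
                                     seed=stage_seeds["cluster"]),
                perplexity=config.perplexity, initial_dims=config.initial_dims,
                theta=config.theta,
            )
            (out / "02_cluster").mkdir(parents=True, exist_ok=True)
            tree.to_json(out / "02_cluster" / "tree.json")
            _write(tree.labels.rename("cluster").to_frame(),
                   out / "02_cluster" / "labels.tsv")
            # prior-knowledge labelling: leaves matching the same marker set
            # (e.g. activity sub-states of one population) merge into one
            # cell type before refinement
            marker_table = _marker_table(matrix, metadata, config)
            if marker_table:
                names = name_clusters(tree.labels, cluster_matrix, marker_table)
                typed_labels = tree.labels.map(names)
                _write(typed_labels.rename("cell_type").to_frame(),
                       out / "02_cluster" / "cell_type_labels.tsv")
            else:
                typed_labels = tree.labels
            if typed_labels.nunique() >= 2:
                refined, precision = refine_clusters_rf(
                    cluster_matrix, typed_labels,
                    min_total_expression=config.refine_min_total_expression,
                    gini_cutoff=config.refine_gini_cutoff,
                    n_trees=config.refine_trees, seed=stage_seeds["cluster"],
                )
                _write(refined.to_frame(), out / "02_cluster" / "refined_labels.tsv")
                _write(pd.DataFrame({"precision": precision.precision}).rename_axis("cluster"),
                       out / "02_cluster" / "precision.tsv")
                results["cluster_precision"] = precision
            results["cluster_tree"] = tree
            results["cluster_labels"] = typed_labels
            done()

        # ---- differential expression ----------------------------------
        done = stage("de")
        dg = metadata["population"] == "DG"
        meta_dg = metadata[dg]

        def de_pair(a, b, tag, seed_off):
            res = rots_test(a, b, ROTSParams(
                B=config.de_B, seed=(config.de_seed + seed_off) % (2**31)))
            _write(res, out / "03_de" / f"{tag}.tsv")
            return res

        hc = _sub(meta_dg, matrix, condition="HC", fos_protein="neg")
        de_1h = de_pair(_sub(meta_dg, matrix, condition="NE1h", fos_protein="pos"),
                        hc, "de_1h_vs_hc", 1)
        de_4h = de_pair(_sub(meta_dg, matrix, condition="NE4h",
                             fos_protein="neg", arc_protein="pos"),
                        hc, "de_4h_vs_hc", 2)
        de_5h = de_pair(_sub(meta_dg, matrix, condition="NE5h",
                             fos_protein="neg", arc_protein="pos"),
                        hc, "de_5h_vs_hc", 3)
        results.update({"de_1h": de_1h, "de_4h": de_4h, "de_5h": de_5h})
        done()

        # ---- signatures ------------------------------------------------
        done = stage("signatures")
        assignment = assign_temporal_groups(de_1h, de_4h, de_5h, alpha=config.alpha)
        _write(assignment.groups.rename("temporal_group").to_frame(),
               out / "04_signatures" / "temporal_groups.tsv")
        dg_matrix = matrix[meta_dg.index[meta_dg.index.isin(matrix.columns)]]
        scores = late_signature_score(dg_matrix, assignment.late_genes)
        labels, warn = classify_activity_state(
            scores, threshold_policy=config.threshold_policy,
            threshold=config.fixed_threshold)
        react = reactivation_labels(labels, metadata)
        sig_table = pd.DataFrame({"pc_score": scores, "signature_label": labels,
                                  "reactivity_label": react})
        _write(sig_table, out / "04_signatures" / "signature_scores.tsv")
        results.update({"temporal_groups": assignment, "signature_scores": scores,
                        "signature_labels": labels, "reactivity_labels": react,
                        "signature_warning": warn})
        done()

        # ---- reactivity ------------------------------------------------
        done = stage("reactivity")
        r_ids = list(react.index[react == "Reactivated"])
        nr_ids = list(react.index[react == "NotReactivated"])
        de_r_nr = rots_test(matrix[r_ids], matrix[nr_ids],
                            ROTSParams(B=config.de_B,
                                       seed=(config.de_seed + 4) % (2**31)))
        _write(de_r_nr, out / "05_reactivity" / "de_r_vs_nr.tsv")
        batch_genes = batch_association(matrix, metadata["batch_id"],
                                        alpha=config.alpha)
        genes = select_predictive_genes(
            de_r_nr, matrix, r_ids, de_1h_vs_hc=de_1h,
            batch_assoc_genes=batch_genes, frac_up=config.frac_up,
            frac_down=config.frac_down, expr_cutoff=config.expr_cutoff,
            alpha=config.alpha,
        )
        _write(genes.table, out / "05_reactivity" / "predictive_genes.tsv")
        models = train_models(
            matrix, react, genes,
            n_train_per_class=config.n_train_per_class,
            n_trees=config.reactivity_trees,
            gini_pool_cutoff=config.gini_pool_cutoff,
            seed=stage_seeds["reactivity"],
        )
        test_labels = react.loc[models.test_ids]
        roc_i = evaluate_roc(models.model_i, matrix,
                             test_labels[test_labels.isin(["Reactivated", "NewlyActivated"])],
                             models.features_pairwise)
        roc_ii = evaluate_roc(models.model_ii, matrix,
                              test_labels[test_labels.isin(["Reactivated", "NotReactivated"])],
                              models.features_pairwise)
        _write(pd.DataFrame({"fpr": roc_i.fpr, "tpr": roc_i.tpr}),
               out / "05_reactivity" / "roc_model_i.tsv", index=False)
        _write(pd.DataFrame({"fpr": roc_ii.fpr, "tpr": roc_ii.tpr}),
               out / "05_reactivity" / "roc_model_ii.tsv", index=False)
        (out / "05_reactivity" / "model_spec.json").write_text(
            json.dumps({**models.spec(), "auc_i": roc_i.auc, "auc_ii": roc_ii.auc},
                       indent=1))

        late_single = metadata.index[
            metadata["condition"].isin(["NE4h", "NE5h"])
            & (metadata["population"] == "DG")
            & metadata.index.isin(matrix.columns)
        ]
        primed = predict_primed(models.model_three_way, matrix,
                                models.features_pooled, list(late_single))
        _write(primed, out / "05_reactivity" / "predicted_primed.tsv")

        late_nuclei = labels.index[labels == "late"]
        fos_groups = metadata.loc[late_nuclei, "fos_protein"].map(
            {"pos": "FOS+", "neg": "FOS-"})
        proba_all = predict_primed(models.model_three_way, matrix,
                                   models.features_pooled, list(late_nuclei))
        component = reactivity_component(
            matrix[list(late_nuclei)], fos_groups,
            probabilities=proba_all["probability_reactivated"],
            positive_group="FOS+")
        _write(component.scores.to_frame(),
               out / "05_reactivity" / "reactivity_component.tsv")
        results.update({"reactivity_models": models, "roc_i": roc_i,
                        "roc_ii": roc_ii, "primed": primed,
                        "reactivity_component": component,
                        "predictive_genes": genes})
        done()

        # ---- GO network ------------------------------------------------
        done = stage("gonet")
        annotation = simulate_go_annotation(
            n_genes=matrix.shape[0], n_terms=config.go_n_terms,
            max_parents=config.go_max_parents, seed=stage_seeds["gonet"],
            genes=list(matrix.index), min_parents=1,
        )
        universe = list(matrix.index)
        late_genes = [g for g in assignment.late_genes if g in matrix.index]
        if late_genes:
            enr = enrichment_test(late_genes, annotation, universe)
            _write(enr, out / "06_gonet" / "late_signature_enrichment.tsv",
                   index=False)
            results["enrichment"] = enr
        dist = go_gene_distance(models.features_pooled, annotation)
        _write(dist, out / "06_gonet" / "predictive_gene_distance.tsv")
        edges = export_network(dist, config.go_edge_threshold,
                               out / "06_gonet" / "network_edges.tsv")
        results.update({"go_distance": dist, "go_edges": edges})
        done()
    except Exception as exc:  # noqa: BLE001 - annotate stage, keep partial output
        pending = [s for s in ("input", "qc", "cluster", "de", "signatures",
                               "reactivity", "gonet") if s not in manifest["stages"]]
        failed = pending[0] if pending else "unknown"
        manifest["error"] = f"stage {failed}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
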