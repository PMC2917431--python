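"""Pipeline configuration and the end-to-end run.

A :class:`RunConfig` ties the stages together: (optional) synthetic-data
simulation -> network assembly -> resolution sweep -> edge similarities ->
homogeneity calls -> community topology -> ROC/AUC evaluation.  Every stage
writes a plain-text artifact into the output directory, and a manifest records
the seed, the configuration and its hash so a rerun with the same config is
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from commscale import homogeneity as hmg
from commscale import network_io, potts, similarity, synthetic_data, topology
from commscale import classifier as clf

log = logging.getLogger("commscale")


@dataclass
class SimulateConfig:
    n_coarse: int = 2
    fine_per_coarse: int = 2
    fine_size: int = 12
    p_fine: float = 0.6
    p_coarse: float = 0.15
    p_between: float = 0.01
    terms_per_module: int = 3
    n_background_terms: int = 20
    fidelity: float = 0.9
    n_conditions: int = 418
    effect_size: float = 1.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.0


@dataclass
class RunConfig:
    outdir: str = "commscale_out"
    seed: int = 0
    # inputs; ignored when simulate is set
    edges: str | None = None
    annotations: str | None = None
    ontology: str | None = None
    growth: str | None = None
    itype: str = "A"
    simulate: SimulateConfig | None = None
    # sweep
    log_lambda_min: float = -1.0
    log_lambda_max: float = 3.0
    step: float = 0.25
    warm_start: bool = True
    # analysis
    measures: list[str] = field(default_factory=lambda: ["G", "C"])
    threshold: float = hmg.DEFAULT_THRESHOLD
    min_size: int = hmg.DEFAULT_MIN_SIZE
    metrics: list[str] = field(default_factory=lambda: list(topology.ALL_METRICS))
    eval_log_lambda_min: float = 0.0
    eval_log_lambda_max: float = 3.0

    def validate(self) -> None:
        if self.simulate is None:
            if self.edges is None:
                raise ValueError("either 'simulate' or an 'edges' path is required")
            if "G" in self.measures and (self.annotations is None or self.ontology is None):
                raise ValueError("measure G requires 'annotations' and 'ontology' paths")
            if "M" in self.measures and self.annotations is None:
                raise ValueError("measure M requires an 'annotations' path")
            if "C" in self.measures and self.growth is None:
                raise ValueError("measure C requires a 'growth' path")
        bad = [m for m in self.measures if m not in ("G", "M", "C")]
        if bad:
            raise ValueError(f"unknown measures: {bad}")
        if self.log_lambda_min >= self.log_lambda_max or self.step <= 0:
            raise ValueError("invalid sweep grid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulateConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_inputs(cfg: RunConfig, outdir: Path):
    """Return (net, annotation set or None, growth matrix or None)."""
    if cfg.simulate is not None:
        s = cfg.simulate
        net, structure = synthetic_data.generate_planted_network(
            s.n_coarse, s.fine_per_coarse, s.fine_size,
            s.p_fine, s.p_coarse, s.p_between, seed=cfg.seed,
        )
        ann = synthetic_data.generate_annotations(
            structure, s.terms_per_module, s.n_background_terms, s.fidelity,
            seed=cfg.seed + 1,
        )
        gm = synthetic_data.generate_growth_profiles(
            structure, s.n_conditions, s.effect_size, s.noise_sd,
            s.missing_fraction, seed=cfg.seed + 2,
        )
        synthetic_data.write_edge_tsv(net, outdir / "edges.tsv", itype=cfg.itype)
        synthetic_data.write_annotation_tsv(ann, outdir / "annotations.tsv")
        synthetic_data.write_obo(ann, outdir / "ontology.obo")
        synthetic_data.write_growth_csv(gm, outdir / "growth.csv")
        synthetic_data.write_labels_csv(structure, outdir / "true_labels.csv")
        log.info("simulated network: %d nodes, %d edges", net.n_nodes, net.W)
        return net, ann, gm

    records, unmapped = network_io.read_interactions([cfg.edges], on_unmapped="skip")
    if unmapped:
        log.warning("%d lines skipped with unmapped evidence codes", len(unmapped))
    net = network_io.build_network(records, cfg.itype, keep_lcc=True)
    log.info("network (%s, LCC): %d nodes, %d edges", cfg.itype, net.n_nodes, net.W)
    ann = None
    if cfg.annotations is not None:
        if cfg.ontology is not None:
            dag, root = similarity.read_obo(cfg.ontology)
        else:  # flat vocabulary
            dag, root = {}, ""
        ann = similarity.read_annotation_tsv(cfg.annotations, dag, root)
    gm = similarity.read_growth_csv(cfg.growth) if cfg.growth is not None else None
    return net, ann, gm


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every configured stage; returns the output directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    stage = "inputs"
    try:
        net, ann, gm = _load_inputs(cfg, outdir)

        stage = "summary"
        stats = network_io.network_summary(net)
        network_io.write_summary(stats, outdir / "network_summary.json")

        stage = "sweep"
        sw = potts.sweep(
            net, cfg.log_lambda_min, cfg.log_lambda_max, cfg.step,
            seed=cfg.seed, warm_start=cfg.warm_start,
        )
        sw.to_csv(outdir / "partitions.csv")
        sw.energies_to_csv(outdir / "energies.csv")
        log.info(
            "sweep: %d resolutions, %d..%d communities",
            len(sw), sw.partitions[sw.log_grid[0]].n_communities,
            sw.partitions[sw.log_grid[-1]].n_communities,
        )

        stage = "similarity"
        ez_by_measure = {}
        for measure in cfg.measures:
            data = {"G": ann, "M": ann.annotations if ann else None, "C": gm}[measure]
            es = similarity.edge_similarity(net, measure, data, seed=cfg.seed)
            es.to_csv(outdir / f"edge_similarity_{measure}.csv")
            ez_by_measure[measure] = hmg.zscore_edges(es)
            log.info(
                "measure %s: %d scored edges, interacting mean %.4f, all-pairs mean %.4f",
                measure, len(es.values), es.interacting_mean, es.all_pairs_mean,
            )

        stage = "homogeneity"
        calls = hmg.call_communities(
            sw, ez_by_measure, net, threshold=cfg.threshold, min_size=1
        )
        hmg.calls_to_frame(calls).to_csv(outdir / "community_calls.csv", index=False)
        summary = hmg.sweep_summary(calls, sw, min_size=cfg.min_size)
        summary.to_csv(outdir / "sweep_summary.csv", index=False)
        for _, row in summary.iterrows():
            log.info(
                "log lambda %.3g: %d communities (size >= %d), %d proteins",
                row["log10_lambda"], row["n_communities"], cfg.min_size, row["n_proteins"],
            )

        stage = "topology"
        metric_table = topology.sweep_metrics(net, sw, cfg.metrics, min_size=cfg.min_size)
        metric_table.to_csv(outdir / "community_metrics.csv", index=False)

        stage = "evaluate"
        tables = []
        for measure in cfg.measures:
            table = clf.evaluate_metrics(
                metric_table,
                [c for c in calls if c.size >= cfg.min_size],
                measure=measure,
                min_size=cfg.min_size,
                log_lambda_range=(cfg.eval_log_lambda_min, cfg.eval_log_lambda_max),
            )
            if not table.empty:
                tables.append(table)
        import pandas as pd

        if tables:
            ranking = clf.metric_ranking(pd.concat(tables, ignore_index=True))
        else:
            # single-class labels at every resolution leave the AUC undefined
            ranking = pd.DataFrame(columns=["metric", "measure", "mean_auc", "n_lambdas"])
            log.warning("no resolution had both homogeneous and non-homogeneous "
                        "communities; metric AUC table is empty")
        ranking.to_csv(outdir / "metric_auc.csv", index=False)

        stage = "manifest"
        import networkx
        import numpy
        import commscale

        manifest = {
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "versions": {
                "commscale": commscale.__version__,
                "numpy": numpy.__version__,
                "networkx": networkx.__version__,
            },
            "n_nodes": net.n_nodes,
            "n_edges": net.W,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
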