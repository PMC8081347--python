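"""End-to-end orchestration of the prediction strategy.

Stages, in order: network validation -> absorbing-chain construction and
absorption probabilities -> architecture search -> descriptor reduction
(PCA and k-means) -> randomized evaluation over the algorithm x reduction
grid -> selection of the best cell (lowest misclassification, ties to the
highest consistency) -> final training and binomial prediction for the
query compounds.  Every stochastic stage derives its stream from the single
pipeline seed, so a (config, seed) pair fully determines the JSON report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import ann, architecture, features, markov, network
from .synthetic import GeneratorConfig, generate_descriptor_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    #: SIF network file; None -> packaged PI3K/AKT reference
    network_path: str | None = None
    #: descriptor + label CSVs; None -> generate the default synthetic set
    descriptors_path: str | None = None
    labels_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    output_dir: str | None = None
    # architecture search
    arch_iterations: int = 100_000
    walks_per_iter: int = 500
    tau: float = 0.05
    # reductions
    pca_k: int = 3
    kmeans_k: int = 2
    # evaluation protocol
    algorithms: tuple[str, ...] = ann.ALGORITHMS
    n_iter: int = 1000
    test_size: int = 4
    max_steps: int = 100_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**obj.pop("generator", {}))
        if "algorithms" in obj:
            obj["algorithms"] = tuple(obj["algorithms"])
        return cls(generator=gen, **obj)

    def to_yaml(self, path: str | Path) -> Path:
        obj = asdict(self)
        obj["algorithms"] = list(self.algorithms)
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
        return Path(path)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("network")
def _load_and_validate(cfg: PipelineConfig) -> network.PathwayNetwork:
    net = (network.load_network(cfg.network_path) if cfg.network_path
           else network.reference_network())
    report = network.validate_network(net)
    if not report.valid:
        raise ValueError(f"network invalid: {report.violations}")
    return net


@_stage("markov")
def _markov_stage(net) -> tuple[markov.TransitionMatrix, dict]:
    tm = markov.build_transition_matrix(net)
    return tm, markov.absorption_probabilities(tm)


@_stage("architecture")
def _arch_stage(net, cfg: PipelineConfig, seed: int):
    return architecture.search_topology(
        net, iterations=cfg.arch_iterations, seed=seed,
        walks_per_iter=cfg.walks_per_iter, tau=cfg.tau, input_dim=cfg.pca_k)


@_stage("reduction")
def _reduction_stage(cfg: PipelineConfig, seed: int):
    if cfg.descriptors_path:
        if not Path(cfg.descriptors_path).exists():
            raise FileNotFoundError(f"descriptor file not found: {cfg.descriptors_path}")
        dm = features.load_descriptors(cfg.descriptors_path, cfg.labels_path)
        true_query = None
    else:
        dm, true_query = generate_descriptor_dataset(cfg.generator)
    clean = features.clean_descriptors(dm)
    reduced = {
        "pca": features.pca_reduce(clean, k=cfg.pca_k),
        "kmeans": features.kmeans_reduce(clean, k=cfg.kmeans_k, seed=seed),
    }
    return clean, reduced, true_query


@_stage("evaluation")
def _evaluation_stage(reduced, topology, cfg: PipelineConfig, seed: int):
    base = ann.TrainingConfig(max_steps=cfg.max_steps)
    return ann.evaluate_protocol(reduced, topology, config=base,
                                 algorithms=cfg.algorithms, n_iter=cfg.n_iter,
                                 test_size=cfg.test_size, seed=seed)


@_stage("prediction")
def _prediction_stage(reduced, topology, report, cfg: PipelineConfig, seed: int):
    alg, red_name = report.best_cell()
    red = reduced[red_name]
    labels = np.array(red.labels)
    labeled = labels != "query"
    Xl = red.coordinates[labeled]
    yl = (labels[labeled] == "agonist").astype(float)
    topo = dataclasses.replace(topology, input_dim=Xl.shape[1])
    cfg_train = ann.TrainingConfig(algorithm=alg, seed=seed, max_steps=cfg.max_steps)
    mlp, trace = ann.train(topo, Xl, yl, cfg_train)
    preds = ann.predict_labels(mlp, red.coordinates[~labeled],
                               [c for c, l in zip(red.compound_ids, red.labels)
                                if l == "query"])
    return alg, red_name, mlp, trace, preds


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full strategy; returns (and optionally writes) the report."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(4)]

    net = _load_and_validate(cfg)
    tm, absorption = _markov_stage(net)
    arch = _arch_stage(net, cfg, seeds[0])
    clean, reduced, true_query = _reduction_stage(cfg, seeds[1])
    report = _evaluation_stage(reduced, arch.topology, cfg, seeds[2])
    alg, red_name, mlp, trace, preds = _prediction_stage(
        reduced, arch.topology, report, cfg, seeds[3])

    out = {
        "seed": cfg.seed,
        "network": {
            "n_nodes": len(net.nodes),
            "n_edges": len(net.edges),
            "terminals": sorted(t.id for t in net.terminals),
            "absorption": absorption,
        },
        "architecture": arch.to_json(),
        "reductions": {
            name: {"k": red.k, "explained_variance": red.explained_variance}
            for name, red in reduced.items()
        },
        "evaluation": report.to_json(),
        "best": {"algorithm": alg, "reduction": red_name},
        "final_training": {"steps": trace.steps, "converged": trace.converged,
                           "final_error": trace.errors[-1]},
        "predictions": preds,
    }
    if true_query is not None:
        out["generator_truth"] = true_query
    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(render_report(out))
    return out


def render_report(report: dict) -> str:
    """Canonical JSON rendering (sorted keys); byte-identical per seed."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
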