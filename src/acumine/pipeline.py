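"""End-to-end orchestration: load, analyse, and write a full report.

A single :func:`run_pipeline` call reproduces the whole analysis on one
input — frequency tables, association rules at the study thresholds
(15% support, 80% confidence), co-occurrence matrices, co-usage network
statistics and node/edge exports — plus a manifest with the configuration
echo, package version and input checksum, so identical inputs and
configuration give byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .arm import mine_rules, rules_to_frame
from .cooccurrence import cooccurrence_matrix, top_pairs
from .frequency import acupoint_frequency, meridian_frequency
from .network import build_network, export_graph, fr_layout, graph_stats
from .registry import Registry, builtin_registry, load_registry, load_transactions

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and input."""


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    The defaults reproduce the study settings: minimum support 15%,
    minimum confidence 80%, rules up to 3 items under the
    antecedent-support convention, and a network over every co-occurring
    pair (``min_weight`` 1).
    """

    input_path: str
    out_dir: str
    input_format: str = "long"
    registry_path: str | None = None
    strict: bool = True
    min_support_pct: float = 15.0
    min_confidence_pct: float = 80.0
    max_rule_size: int = 3
    support_convention: str = "antecedent"
    min_weight: int = 1
    layout_seed: int = 42
    layout_iterations: int = 50
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("min_support_pct", "min_confidence_pct"):
            value = getattr(self, name)
            if not 0 < value <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {value}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` configuration file."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, _, raw = line.partition("=")
        values[key.strip()] = raw.strip()
    kwargs: dict = {}
    for f in PipelineConfig.__dataclass_fields__.values():
        if f.name not in values:
            continue
        raw = values[f.name]
        if f.type in ("int", int):
            kwargs[f.name] = int(raw)
        elif f.type in ("float", float):
            kwargs[f.name] = float(raw)
        elif f.type in ("bool", bool):
            kwargs[f.name] = raw.lower() in ("1", "true", "yes")
        else:
            kwargs[f.name] = raw
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a mapping from artifact name to written path.  Stage errors
    propagate as :class:`PipelineError` naming the failed stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as err:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage {name!r} failed on "
                                f"{config.input_path}: {err}") from err
        logger.info("stage %s done", name)
        return result

    if config.registry_path:
        registry: Registry = stage(
            "registry", lambda: load_registry(config.registry_path,
                                              strict=config.strict)
        )
    else:
        registry = stage("registry", lambda: builtin_registry(strict=config.strict))

    dataset = stage(
        "load",
        lambda: load_transactions(config.input_path,
                                  format=config.input_format,
                                  registry=registry),
    )
    logger.info("loaded %d prescriptions, %d acupoints, %d usages",
                dataset.N, len(dataset.universe), dataset.total_usages)

    def write(name: str, fn) -> Path:
        path = out_dir / name
        stage(name, lambda: fn(path))
        outputs[name] = path
        return path

    freq = stage("acupoint_frequency", lambda: acupoint_frequency(dataset))
    write("acupoint_frequency.csv", freq.write)
    mfreq = stage("meridian_frequency",
                  lambda: meridian_frequency(dataset, registry))
    write("meridian_frequency.csv", mfreq.write)

    rules = stage(
        "rules",
        lambda: mine_rules(
            dataset,
            min_support_pct=config.min_support_pct,
            min_confidence_pct=config.min_confidence_pct,
            support_convention=config.support_convention,
            max_rule_size=config.max_rule_size,
        ),
    )
    write("rules.csv",
          lambda p: rules_to_frame(rules).to_csv(p, index=False))

    matrix = stage("cooccurrence", lambda: cooccurrence_matrix(dataset))
    write("cooccurrence_counts.csv", lambda p: matrix.counts.to_csv(p))
    write("cooccurrence_normalized.csv", lambda p: matrix.normalized.to_csv(p))

    graph = stage("network",
                  lambda: build_network(dataset, min_weight=config.min_weight))
    stats = stage("graph_stats", lambda: graph_stats(graph))
    write("graph_stats.json",
          lambda p: p.write_text(json.dumps(asdict(stats), indent=2,
                                            sort_keys=True) + "\n"))
    layout = stage(
        "layout",
        lambda: fr_layout(graph, iterations=config.layout_iterations,
                          seed=config.layout_seed),
    )
    nodes_path = out_dir / "nodes.csv"
    edges_path = out_dir / "edges.csv"
    stage("export", lambda: export_graph(graph, layout, nodes_path, edges_path))
    outputs["nodes.csv"] = nodes_path
    outputs["edges.csv"] = edges_path

    manifest = {
        "package": "acumine",
        "version": __version__,
        "config": asdict(config),
        "input_sha256": _sha256(Path(config.input_path)),
        "n_prescriptions": dataset.N,
        "n_acupoints": len(dataset.universe),
        "total_usages": dataset.total_usages,
        "n_rules": len(rules),
        "top_pair": list(top_pairs(matrix, k=1)[0]) if dataset.N else None,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest.json"] = manifest_path
    return outputs
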