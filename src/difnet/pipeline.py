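"""End-to-end orchestration: simulate/ingest -> DE -> enrichment -> candidate
selection -> condition networks -> degree-difference hub nomination.

Every stage writes a plain-text table into the output directory; a JSON run
report aggregates the counts and parameters and a manifest records SHA-256
digests of every emitted file.  Identical configuration (including the seed)
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from . import io as dio
from .de import compute_de, de_frame, significant_genes
from .enrich import fisher_enrichment, select_focus_candidates
from .errors import ConfigurationError, DifnetError, PipelineError
from .expression import ExpressionMatrix
from .network import build_network, dif_degree, select_hubs
from .simulate import SimulationConfig, generate_annotations, generate_paired

logger = logging.getLogger("difnet.pipeline")

__all__ = ["AnnotationParams", "PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class AnnotationParams:
    n_terms: int = 30
    term_size_min: int = 10
    term_size_max: int = 40
    n_enriched_terms: int = 6


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run (simulation or file ingestion)."""

    outdir: str
    seed: int = 0
    control_label: str = "control"
    perturbation_labels: tuple[str, ...] = ("pert1", "pert2")
    # simulation mode
    simulation: SimulationConfig | None = None
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    # ingestion mode (one matrix per condition label, shared condition map)
    expression_paths: Mapping[str, str] | None = None
    conditions_path: str | None = None
    gmt_path: str | None = None
    # thresholds
    de_alpha: float = 0.05
    de_fold: float = 2.0
    pseudocount: float | None = None
    term_alpha: float = 0.01
    edge_fdr: float = 0.05
    dif_threshold: int = 8
    focus_terms: tuple[str, ...] | None = None  # None -> auto (shared enriched terms)

    def validate(self) -> None:
        if not self.perturbation_labels:
            raise ConfigurationError("at least one perturbation label is required")
        if not 0 < self.de_alpha <= 1:
            raise ConfigurationError(f"de_alpha out of range: {self.de_alpha}")
        if self.de_fold <= 0:
            raise ConfigurationError(f"de_fold must be positive: {self.de_fold}")
        if not 0 < self.term_alpha <= 1:
            raise ConfigurationError(f"term_alpha out of range: {self.term_alpha}")
        if not 0 < self.edge_fdr <= 1:
            raise ConfigurationError(f"edge_fdr out of range: {self.edge_fdr}")
        if self.dif_threshold < 0:
            raise ConfigurationError(f"dif_threshold must be >= 0: {self.dif_threshold}")
        if self.simulation is None and self.expression_paths is None:
            raise ConfigurationError(
                "either a simulation block or expression_paths must be given"
            )
        if self.simulation is not None and self.expression_paths is not None:
            raise ConfigurationError("simulation and expression_paths are exclusive")
        if self.expression_paths is not None and self.gmt_path is None:
            raise ConfigurationError("ingestion mode requires gmt_path")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        ann = data.pop("annotation", None)
        ann = AnnotationParams(**ann) if ann is not None else AnnotationParams()
        for key in ("perturbation_labels", "focus_terms"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(simulation=sim, annotation=ann, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)


@dataclass
class RunReport:
    version: str
    seed: int
    parameters: dict
    counts: dict
    core_regulators: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context manager that prefixes stage names onto failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            if isinstance(exc, DifnetError):
                raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
            return False
        logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all intermediates under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = list(config.perturbation_labels)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    # ---------------------------------------------------------------- input
    with _Stage("input"):
        if config.simulation is not None:
            control, perturbed, truth = generate_paired(
                config.simulation, labels, config.control_label
            )
            ann = config.annotation
            annotations = generate_annotations(
                truth,
                n_terms=ann.n_terms,
                term_size_range=(ann.term_size_min, ann.term_size_max),
                n_enriched_terms=ann.n_enriched_terms,
                seed=config.simulation.seed,
            )
            emit("truth_manifest.txt", lambda p: dio.write_truth_manifest(truth, p))
            emit(
                f"expression_{config.control_label}.tsv",
                lambda p: dio.write_expression(control, p),
            )
            for lab in labels:
                emit(
                    f"expression_{lab}.tsv",
                    lambda p, lab=lab: dio.write_expression(perturbed[lab], p),
                )
            all_conditions = dict(control.conditions)
            for lab in labels:
                all_conditions.update(perturbed[lab].conditions)
            emit(
                "conditions.tsv",
                lambda p: dio.write_condition_map(all_conditions, p),
            )
            emit("annotations.gmt", lambda p: dio.write_gmt(annotations, p))
        else:
            paths = dict(config.expression_paths)
            missing = [
                lab
                for lab in [config.control_label, *labels]
                if lab not in paths
            ]
            if missing:
                raise ConfigurationError(f"expression_paths lacks conditions: {missing}")
            control = dio.read_expression(
                paths[config.control_label], config.conditions_path
            )
            perturbed = {
                lab: dio.read_expression(paths[lab], config.conditions_path)
                for lab in labels
            }
            annotations = dio.read_gmt(config.gmt_path)

    merged = {lab: control.merge(perturbed[lab]) for lab in labels}

    # ------------------------------------------------------------------- DE
    de_sets: dict[str, set[str]] = {}
    de_counts: dict[str, dict[str, int]] = {}
    with _Stage("differential_expression"):
        for lab in labels:
            results = compute_de(
                merged[lab],
                control_label=config.control_label,
                perturbed_label=lab,
                pseudocount=config.pseudocount,
                alpha=config.de_alpha,
                fold=config.de_fold,
            )
            frame = de_frame(results)
            emit(
                f"de_{lab}.tsv",
                lambda p, f=frame: p.write_text(f.to_csv(sep="\t", index=False)),
            )
            de_sets[lab] = significant_genes(results)
            de_counts[lab] = {
                "up": int((frame["status"] == "up").sum()),
                "down": int((frame["status"] == "down").sum()),
            }
            logger.info(
                "DE %s: %d up / %d down (alpha=%g fold=%g)",
                lab,
                de_counts[lab]["up"],
                de_counts[lab]["down"],
                config.de_alpha,
                config.de_fold,
            )

    # ----------------------------------------------------------- enrichment
    enrichments = {}
    enriched_ids: dict[str, list[str]] = {}
    with _Stage("enrichment"):
        for lab in labels:
            testable = de_sets[lab] & annotations.universe
            res = fisher_enrichment(testable, annotations)
            enrichments[lab] = res
            enriched_ids[lab] = [r.term_id for r in res if r.p_value < config.term_alpha]
            rows = ["term_id\tterm_name\tk\tK\tn\tN\tp_value\tq_value"]
            rows += [
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                f"\t{r.p_value!r}\t{r.q_value!r}"
                for r in res
            ]
            emit(
                f"enrichment_{lab}.tsv",
                lambda p, text="\n".join(rows) + "\n": p.write_text(text),
            )

    # ------------------------------------------------------------ candidates
    with _Stage("candidate_selection"):
        if config.focus_terms is not None:
            focus = list(config.focus_terms)
        else:
            shared = set(enriched_ids[labels[0]])
            for lab in labels[1:]:
                shared &= set(enriched_ids[lab])
            focus = sorted(shared)
        selection = select_focus_candidates(enrichments, de_sets, focus, annotations)
        for lab in labels:
            emit(
                f"candidates_{lab}.txt",
                lambda p, lab=lab: dio.write_gene_list(selection.candidates[lab], p),
            )
        emit("overlap.txt", lambda p: dio.write_gene_list(selection.overlap, p))
        logger.info(
            "focus terms: %s; overlap size %d", focus, len(selection.overlap)
        )

    # --------------------------------------------------------------- network
    network_genes = list(selection.overlap)
    nets = {}
    edge_counts: dict[str, int] = {}
    tables = {}
    with _Stage("network"):
        if len(network_genes) >= 2:
            control_net = build_network(
                control, network_genes, config.control_label, config.edge_fdr
            )
            nets[config.control_label] = control_net
            for lab in labels:
                nets[lab] = build_network(
                    perturbed[lab], network_genes, lab, config.edge_fdr
                )
            for lab, net in nets.items():
                emit(f"network_{lab}.tsv", lambda p, n=net: dio.write_network(n, p))
                edge_counts[lab] = len(net.edges)
            for lab in labels:
                tables[lab] = dif_degree(nets[config.control_label], nets[lab])
                emit(
                    f"degrees_{lab}.tsv",
                    lambda p, t=tables[lab]: dio.write_degree_table(t, p),
                )
        else:
            logger.warning(
                "overlap has %d genes; skipping network stage", len(network_genes)
            )

    # ------------------------------------------------------------------ hubs
    with _Stage("hub_selection"):
        if tables:
            hubs = select_hubs(tables, threshold=config.dif_threshold)
            selected = {lab: list(v) for lab, v in hubs.selected.items()}
            core = list(hubs.core_regulators)
        else:
            selected = {lab: [] for lab in labels}
            core = []
        emit("core_regulators.txt", lambda p: dio.write_gene_list(core, p))

    report = RunReport(
        version=__version__,
        seed=config.seed,
        parameters={
            "control_label": config.control_label,
            "perturbation_labels": labels,
            "de_alpha": config.de_alpha,
            "de_fold": config.de_fold,
            "term_alpha": config.term_alpha,
            "edge_fdr": config.edge_fdr,
            "dif_threshold": config.dif_threshold,
            "focus_terms": focus,
            "simulated": config.simulation is not None,
        },
        counts={
            "de": de_counts,
            "enriched_terms": {lab: len(v) for lab, v in enriched_ids.items()},
            "candidates": {lab: len(selection.candidates[lab]) for lab in labels},
            "overlap_size": len(selection.overlap),
            "edges": edge_counts,
            "hubs": selected,
        },
        core_regulators=core,
    )
    (outdir / "report.json").write_text(report.to_json())
    written.append(outdir / "report.json")
    manifest = "".join(
        f"{_sha256(p)}  {p.name}\n" for p in sorted(set(written), key=lambda p: p.name)
    )
    (outdir / "manifest.txt").write_text(manifest)
    return report
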