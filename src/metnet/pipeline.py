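"""End-to-end pipeline: map -> similarity -> cosine network -> fuse -> rank/evaluate.

Every artifact is written with a provenance header (tool version, config
hash, input-file hashes) so identical inputs and config produce identical
outputs and each output records how it was made.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cf import build_dmn, build_profiles, write_profiles
from .disease_sim import all_pairs_similarity, write_similarity_matrix
from .evaluation import build_validation_cases, evaluate_network, write_report
from .fusion import build_fldmn
from .io import (
    DataFormatError,
    read_association_table,
    read_gene_annotations,
    read_gene_network,
    read_ontology,
    read_textmining_scores,
    write_association_table,
    write_metabolite_network,
)
from .rwr import RwrConfig, rwr_scores, write_ranking
from .vocab import (
    build_vocabulary,
    map_associations,
    read_medic,
    read_raw_associations,
    write_unmapped_report,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ontology: str
    gene_annotations: str
    gene_network: str
    out_dir: str
    associations_earlier: str | None = None
    associations_later: str | None = None
    raw_associations: str | None = None
    medic: str | None = None
    textmining: str | None = None
    threshold: float = 0.01
    restart_probability: float = 0.7
    tolerance: float = 1e-10
    max_iterations: int = 10_000
    normalization_mode: str = "max"
    ambiguity_policy: str = "drop"
    st_scale: float = 1.0
    no_fusion: bool = False
    query_disease: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise DataFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _meta(cfg: PipelineConfig, **inputs: str) -> dict[str, str]:
    meta = {
        "tool_version": __version__,
        "config_hash": cfg.config_hash(),
        "config": json.dumps(asdict(cfg), sort_keys=True),
    }
    for name, path in inputs.items():
        meta[f"input_{name}"] = f"{path} sha256:{_file_hash(path)}"
    return meta


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute every configured stage; returns the artifact paths.

    Any stage failure propagates with the stage name prefixed, leaving the
    artifacts written so far on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    rwr_cfg = RwrConfig(
        restart_probability=cfg.restart_probability,
        tolerance=cfg.tolerance,
        max_iterations=cfg.max_iterations,
    )

    def stage(name):
        logger.info("stage: %s", name)

    stage("load ontology")
    dag = read_ontology(cfg.ontology)

    stage("load associations")
    if cfg.associations_earlier:
        earlier = read_association_table(cfg.associations_earlier, "earlier")
    elif cfg.raw_associations:
        medic = read_medic(cfg.medic) if cfg.medic else []
        vocab = build_vocabulary(dag, medic)
        raw = read_raw_associations(cfg.raw_associations)
        earlier, report = map_associations(
            raw, vocab, policy=cfg.ambiguity_policy, version_tag="earlier"
        )
        artifacts["unmapped_report"] = out / "unmapped_report.tsv"
        write_unmapped_report(artifacts["unmapped_report"], report)
        artifacts["associations_mapped"] = out / "associations_mapped.tsv"
        write_association_table(artifacts["associations_mapped"], earlier)
    else:
        raise DataFormatError(
            "config must provide associations_earlier or raw_associations"
        )
    unknown_terms = sorted(earlier.diseases() - dag.terms)
    if unknown_terms:
        raise DataFormatError(
            f"association diseases missing from ontology: {unknown_terms[:5]}"
        )

    stage("disease similarity")
    ann = read_gene_annotations(cfg.gene_annotations)
    gnet = read_gene_network(cfg.gene_network)
    diseases = sorted(earlier.diseases())
    dsim = all_pairs_similarity(
        diseases, dag, ann, gnet, normalization=cfg.normalization_mode
    )
    artifacts["dsim"] = out / "disease_similarity.tsv"
    write_similarity_matrix(
        artifacts["dsim"],
        dsim,
        meta=_meta(cfg, ontology=cfg.ontology, gene_network=cfg.gene_network),
    )

    stage("metabolite profiles + cosine network")
    profiles = build_profiles(earlier, dsim)
    artifacts["profiles"] = out / "profiles.tsv"
    write_profiles(artifacts["profiles"], profiles)
    dmn = build_dmn(profiles, threshold=cfg.threshold)
    artifacts["dmn"] = out / "dmn.tsv"
    write_metabolite_network(artifacts["dmn"], dmn, meta=_meta(cfg))

    network = dmn
    if cfg.textmining and not cfg.no_fusion:
        stage("fusion")
        st = read_textmining_scores(cfg.textmining, scale=cfg.st_scale)
        network = build_fldmn(dmn, st)
        artifacts["fldmn"] = out / "fldmn.tsv"
        write_metabolite_network(
            artifacts["fldmn"], network, meta=_meta(cfg, textmining=cfg.textmining)
        )

    if cfg.associations_later:
        stage("evaluation")
        later = read_association_table(cfg.associations_later, "later")
        cases = build_validation_cases(earlier, later, network)
        if cases:
            report = evaluate_network(network, cases, rwr_cfg)
            artifacts["evaluation"] = out / "evaluation.tsv"
            write_report(artifacts["evaluation"], report, meta=_meta(cfg))
        else:
            logger.warning("no valid evaluation cases; evaluation skipped")

    if cfg.query_disease:
        stage("ranking")
        seeds = earlier.by_disease().get(cfg.query_disease, set()) & network.nodes
        if not seeds:
            raise DataFormatError(
                f"query disease {cfg.query_disease!r} has no in-network seeds"
            )
        result = rwr_scores(network, seeds, rwr_cfg)
        artifacts["ranking"] = out / "ranking.tsv"
        write_ranking(artifacts["ranking"], result, meta=_meta(cfg))

    logger.info("pipeline complete; %d artifacts in %s", len(artifacts), out)
    return artifacts
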