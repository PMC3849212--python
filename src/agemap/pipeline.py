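"""End-to-end orchestration: simulate/mine -> store -> matrices -> map/cluster.

A run is described by a :class:`RunConfig` (typically loaded from YAML),
executed stage by stage with per-stage artifacts written to the run
directory and a ``manifest.json`` recording the counts at every stage:
abstracts in, age-related abstracts, instances stored, diseases per
matrix, diseases compared and accepted by the mapper.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clustering, mapper, matrix, mining, store, synthetic
from .lexicon import build_lexicon, read_term_list

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # input corpus: a MEDLINE file, or None to simulate from specs
    corpus: str | None = None
    specs: str | list | None = None  # YAML path or in-memory DiseaseSpec list
    n_distractors: int = 30
    noise_cv: float = 0.0
    # lexicon inputs (generated from specs when omitted)
    obo: str | None = None
    terms: str | None = None
    strains: str | None = None
    blocklist: str | None = None
    # analysis options
    min_instances: int = 5
    range_policy: str = "midpoint"
    max_shift: int = 1028
    r2_threshold: float = 0.5
    min_overlap: int = 10
    linkage: str = "average"
    human_matrix: str | None = None  # path; synthetic pair's human side when None
    log_level: str = "INFO"

    def validate(self) -> None:
        missing = [
            f"{name}={p!r}"
            for name, p in (
                ("corpus", self.corpus), ("obo", self.obo), ("terms", self.terms),
                ("strains", self.strains), ("blocklist", self.blocklist),
                ("human_matrix", self.human_matrix),
            )
            if p is not None and not Path(p).exists()
        ]
        if isinstance(self.specs, str) and not Path(self.specs).exists():
            missing.append(f"specs={self.specs!r}")
        if self.corpus is None and self.specs is None:
            missing.append("one of corpus/specs is required")
        if missing:
            raise ValueError("invalid config: " + "; ".join(missing))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_specs(config: RunConfig):
    if config.specs is None:
        return None
    if isinstance(config.specs, str):
        return synthetic.load_specs(config.specs)
    return list(config.specs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    specs = _load_specs(config)

    # -- corpus -------------------------------------------------------------
    if config.corpus is not None:
        stage("read_corpus")
        corpus = mining.read_medline(config.corpus)
    else:
        stage("simulate_corpus")
        medline_text, gold = synthetic.generate_corpus(
            specs, n_distractors=config.n_distractors, seed=config.seed
        )
        (out / "corpus.medline").write_text(medline_text)
        corpus = mining.read_medline(out / "corpus.medline")
        manifest["gold_age_related"] = sum(g.is_age_related for g in gold)
        manifest["gold_with_phenotype"] = sum(bool(g.concept_ids) for g in gold)

    # -- lexicon ------------------------------------------------------------
    stage("build_lexicon")
    if config.obo is not None:
        obo_text = Path(config.obo).read_text(encoding="utf-8")
    else:
        obo_text = synthetic.generate_ontology(specs)
        (out / "ontology.obo").write_text(obo_text)
    extra = read_term_list(config.terms) if config.terms else None
    lex = build_lexicon(obo_text, extra)
    strains = mining.read_lines(config.strains) if config.strains else synthetic.DEFAULT_STRAINS
    blocklist = (
        mining.read_lines(config.blocklist)
        if config.blocklist
        else list(mining.DEFAULT_ORGANISM_BLOCKLIST)
    )
    manifest["lexicon_surface_forms"] = len(lex)

    # -- mine & store -------------------------------------------------------
    stage("mine_corpus")
    stats: dict = {}
    instances = mining.mine_corpus(corpus, lex, strains, blocklist, stats=stats)
    manifest.update(stats)
    stage("write_store")
    store.write_store(instances, out / "store")
    ev_store = store.read_store(out / "store")

    # -- matrices -----------------------------------------------------------
    stage("build_matrices")
    opts = matrix.MatrixBuildOptions(
        range_policy=config.range_policy, min_instances=config.min_instances
    )
    mouse_counts = matrix.build_matrix(ev_store, "mouse", opts)
    manifest["diseases_mouse_matrix"] = len(mouse_counts.diseases)
    mouse_norm = (
        matrix.normalize(mouse_counts) if len(mouse_counts.diseases) else mouse_counts
    )
    matrix.write_matrix(mouse_norm, out / "mouse_matrix.tsv")

    if config.human_matrix is not None:
        human_norm = matrix.read_matrix(config.human_matrix)
    elif specs is not None:
        human_norm, _, truth = synthetic.generate_matrix_pair(
            specs, noise_cv=config.noise_cv, seed=config.seed
        )
        truth.to_csv(out / "planted_shifts.tsv", sep="\t", index=False)
    else:
        human_norm = None
    manifest["diseases_human_matrix"] = (
        len(human_norm.diseases) if human_norm is not None else 0
    )

    # -- age map ------------------------------------------------------------
    if human_norm is not None and len(mouse_norm.diseases) and mouse_norm.normalized:
        stage("map_diseases")
        mopts = mapper.MapperOptions(
            max_shift=config.max_shift,
            r2_threshold=config.r2_threshold,
            min_overlap=config.min_overlap,
        )
        matrix.write_matrix(human_norm, out / "human_matrix.tsv")
        amap = mapper.map_diseases(human_norm, mouse_norm, mopts)
        mapper.write_age_map(amap, out / "agemap.json", lex.concept_names)
        manifest["diseases_compared"] = amap.n_compared
        manifest["diseases_accepted"] = amap.n_accepted

    # -- clustering ---------------------------------------------------------
    if len(mouse_norm.diseases) >= 2:
        stage("cluster_diseases")
        try:
            dend = clustering.cluster_diseases(mouse_norm, linkage=config.linkage)
            (out / "tree.nwk").write_text(clustering.to_newick(dend))
            manifest["diseases_clustered"] = dend.n_leaves
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
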