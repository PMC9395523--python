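"""End-to-end pipeline: simulate -> similarity -> exclusive -> sites ->
cluster -> de -> anc, with a run manifest of checksums and parameters.

Each stage reads its inputs from the output directory of the previous
one, so any stage can be re-run standalone from files; a failing stage
halts the run with a stage-scoped diagnostic while earlier outputs are
preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import SearchParams
from .ancestral import AncestralTraitModel
from .de import GroupContrastNB
from .gene_content import ThresholdConfig, find_group_exclusive
from .homology import build_similarity_matrix
from .orthologs import build_homology_graph, cluster_orthologs
from .sites import scan_core_proteome
from .synthetic import (
    CladeConfig,
    DECountsConfig,
    generate_clade,
    generate_counts,
    write_fixtures,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "similarity", "exclusive", "sites", "cluster", "de", "anc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """One structured configuration for the whole pipeline."""

    out_dir: Path
    clade: CladeConfig = field(default_factory=CladeConfig)
    counts: DECountsConfig = field(default_factory=DECountsConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    search: SearchParams = field(default_factory=SearchParams)
    seed: int = 0
    #: load a previously written fixture directory instead of simulating
    input_fixtures: Path | None = None

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            out_dir=Path(out_dir or raw.get("out_dir", "pipeline_out")),
            clade=CladeConfig(**raw.get("clade", {})),
            counts=DECountsConfig(**raw.get("counts", {})),
            thresholds=ThresholdConfig(**raw.get("thresholds", {})),
            search=SearchParams(**raw.get("search", {})),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class RunManifest:
    """Record of one pipeline run: stage outputs, checksums, parameters."""

    version: str
    parameters: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "outputs": {
                str(p.name): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in outputs
            },
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "parameters": self.parameters,
            "stages": self.stages,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in dependency order on a synthetic clade."""
    if config.input_fixtures is not None:
        fixtures = Path(config.input_fixtures)
        required = [fixtures / "truth.json", fixtures / "tree.nwk",
                    fixtures / "traits.csv"]
        missing = [str(p) for p in required if not p.exists()]
        if missing:
            raise PipelineError(
                f"missing input files before any stage ran: {missing}"
            )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        parameters={
            "clade": config.clade.__dict__,
            "counts": config.counts.__dict__,
            "thresholds": config.thresholds.__dict__,
            "search": {
                k: v for k, v in config.search.__dict__.items()
            },
            "seed": config.seed,
        },
    )
    state: dict = {}
    for stage in STAGES:
        logger.info("pipeline stage: %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            manifest.write(out / "manifest.run.json")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, outputs)
    manifest.write(out / "manifest.run.json")
    return manifest


def _stage_simulate(config, out, state):
    if config.input_fixtures is not None:
        from .synthetic import read_counts, read_fixtures

        clade = read_fixtures(config.input_fixtures)
        counts = read_counts(config.input_fixtures)
    else:
        clade = generate_clade(config.clade)
        counts = generate_counts(clade, config.counts)
    write_fixtures(clade, out / "fixtures", counts=counts, overwrite=True)
    state["clade"] = clade
    state["counts"] = counts
    return sorted((out / "fixtures").rglob("*.*"))


def _stage_similarity(config, out, state):
    clade = state["clade"]
    reference_a = clade.genome_ids[0]
    reference_b = next(
        gid for gid in clade.genome_ids if clade.groups[gid] == "B"
    )
    outputs = []
    for label, ref in (("A", reference_a), ("B", reference_b)):
        matrix = build_similarity_matrix(
            clade.proteomes[ref], clade.genomes, config.search
        )
        path = out / f"similarity_ref{label}.tsv"
        matrix.to_tsv(path)
        outputs.append(path)
        state[f"matrix_{label}"] = matrix
        state[f"reference_{label}"] = ref
    return outputs


def _stage_exclusive(config, out, state):
    clade = state["clade"]
    outputs = []
    for label in ("A", "B"):
        report = find_group_exclusive(
            state[f"matrix_{label}"], clade.groups, config.thresholds, "A"
        )
        path = out / f"exclusive_ref{label}.json"
        path.write_text(
            json.dumps(
                {
                    "reference": state[f"reference_{label}"],
                    "exclusive_present": report.exclusive_present,
                    "exclusive_absent": report.exclusive_absent,
                },
                indent=1,
            )
        )
        outputs.append(path)
        state[f"exclusive_{label}"] = report
    return outputs


def _stage_sites(config, out, state):
    clade = state["clade"]
    core_ids, sites = scan_core_proteome(
        state["matrix_A"], clade.proteomes, clade.groups,
        config.thresholds, config.search,
        reference_genome=state["reference_A"],
    )
    rows = [
        {
            "family": s.family_id,
            "column": s.column,
            "ref_position": s.reference_position,
            "residue_a": s.residue_a,
            "residue_b": s.residue_b,
        }
        for fam_sites in sites.values()
        for s in fam_sites
    ]
    path = out / "diagnostic_sites.tsv"
    pd.DataFrame(rows, columns=["family", "column", "ref_position",
                                "residue_a", "residue_b"]).to_csv(
        path, sep="\t", index=False
    )
    state["core_ids"] = core_ids
    state["sites"] = sites
    return [path]


def _stage_cluster(config, out, state):
    clade = state["clade"]
    graph = build_homology_graph(
        clade.proteomes, config.thresholds.graph_cutoff, config.search
    )
    clusters = cluster_orthologs(graph)
    path = out / "clusters.tsv"
    with open(path, "w") as fh:
        fh.write("cluster\tgenome\tlocus_tag\n")
        for cid, members in clusters.clusters.items():
            for member in members:
                gid, tag = member.split(":", 1)
                fh.write(f"{cid}\t{gid}\t{tag}\n")
    state["clusters"] = clusters
    return [path]


def _stage_de(config, out, state):
    counts = state["counts"]
    results = GroupContrastNB(counts).fit()
    path = out / "de_results.tsv"
    results.to_tsv(path)
    state["de"] = results
    return [path]


def _stage_anc(config, out, state):
    clade = state["clade"]
    model = AncestralTraitModel(clade.truth.tree_newick, clade.truth.trait_map)
    results = model.fit(frequencies="ml")
    path = out / "ancestral_states.tsv"
    results.to_tsv(path)
    state["anc"] = results
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "similarity": _stage_similarity,
    "exclusive": _stage_exclusive,
    "sites": _stage_sites,
    "cluster": _stage_cluster,
    "de": _stage_de,
    "anc": _stage_anc,
}
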