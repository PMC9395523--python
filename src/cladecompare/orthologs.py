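"""Ortholog unification through an all-vs-all protein homology graph.

Proteins from a panel of genomes are nodes; an edge joins two proteins
whenever their best local alignment exceeds a percent-similarity cutoff
(default 60) at the e-value cutoff.  Connected components of this graph
are the ortholog clusters; each receives a unified name ("NEISS_0001",
...) that replaces the per-genome locus tags in the annotations, making
read counts comparable across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .align import SearchParams, align_protein_pair, make_aligner
from .records import CdsFeature, ProteinRecord

logger = logging.getLogger(__name__)

CLUSTER_PREFIX = "NEISS"


class OrthologError(ValueError):
    """Invalid ortholog-graph input."""


@dataclass
class HomologyGraph:
    """Protein homology graph; node ids are genome-qualified."""

    graph: nx.Graph
    cutoff: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class OrthologClusterSet:
    """Named ortholog clusters partitioning the protein set."""

    clusters: dict[str, list[str]]  # cluster id -> genome-qualified member ids
    membership: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.membership:
            self.membership = {
                m: cid for cid, members in self.clusters.items() for m in members
            }
        n_members = sum(len(m) for m in self.clusters.values())
        if n_members != len(self.membership):
            raise OrthologError("clusters do not partition the protein set")

    def cluster_of(self, genome_id: str, locus_tag: str) -> str:
        return self.membership[f"{genome_id}:{locus_tag}"]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_homology_graph(
    proteomes: dict[str, list[ProteinRecord]],
    cutoff: float = 60.0,
    params: SearchParams | None = None,
    prescreen_k: int | None = 4,
) -> HomologyGraph:
    """All-vs-all homology graph over a panel of proteomes.

    Every protein (including within-proteome pairs, so paralogs connect)
    is aligned against every other; an edge is stored when the percent
    similarity of the optimal local alignment exceeds ``cutoff`` and the
    e-value passes the cutoff.  Local alignment is symmetric under a
    symmetric scoring table, so one alignment per unordered pair decides
    both directions.
    """
    params = params or SearchParams()
    if not proteomes:
        raise OrthologError("no proteomes supplied")
    records: list[ProteinRecord] = []
    for gid, prots in proteomes.items():
        for p in prots:
            if p.genome_id != gid:
                raise OrthologError(
                    f"protein {p.id} carries genome id {p.genome_id} but was "
                    f"supplied under {gid}"
                )
            records.append(p)
    ids = [p.qualified_id for p in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise OrthologError(f"duplicate qualified protein ids: {dupes[:5]}")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    aligner = make_aligner(params)
    kmers = (
        [_kmer_set(p.residues, prescreen_k) for p in records]
        if prescreen_k
        else None
    )
    n_aligned = 0
    for i, j in combinations(range(len(records)), 2):
        if kmers is not None and not (kmers[i] & kmers[j]):
            continue
        n_aligned += 1
        hit = align_protein_pair(records[i], records[j], params)
        if hit.percent_similarity > cutoff and hit.e_value <= params.evalue_cutoff:
            graph.add_edge(ids[i], ids[j], weight=hit.percent_similarity)
    logger.info(
        "homology graph: %d proteins, %d alignments, %d edges at cutoff %g",
        len(records), n_aligned, graph.number_of_edges(), cutoff,
    )
    return HomologyGraph(graph=graph, cutoff=cutoff)


def cluster_orthologs(graph: HomologyGraph) -> OrthologClusterSet:
    """Connected components of the homology graph, deterministically named.

    Components are sorted by their smallest member id (genome id, then
    locus tag) and numbered from 1 as ``NEISS_0001``; singletons stay as
    their own clusters.
    """
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph.graph)),
        key=lambda c: c[0],
    )
    width = max(4, len(str(len(components))))
    clusters = {
        f"{CLUSTER_PREFIX}_{i + 1:0{width}d}": members
        for i, members in enumerate(components)
    }
    return OrthologClusterSet(clusters=clusters)


def core_clusters(
    clusters: OrthologClusterSet, genome_ids: list[str]
) -> set[str]:
    """Clusters with at least one member in every listed genome."""
    seen_genomes = {m.split(":", 1)[0] for m in clusters.membership}
    unknown = [g for g in genome_ids if g not in seen_genomes]
    if unknown:
        raise OrthologError(f"genome ids absent from the cluster set: {unknown}")
    wanted = set(genome_ids)
    core = set()
    for cid, members in clusters.clusters.items():
        genomes = {m.split(":", 1)[0] for m in members}
        if wanted <= genomes:
            core.add(cid)
    return core


def rename_annotations(
    clusters: OrthologClusterSet,
    annotations: dict[str, list[CdsFeature]],
) -> dict[str, list[CdsFeature]]:
    """Rewrite per-genome CDS annotations with unified cluster names.

    Each CDS's locus tag becomes ``<cluster>|<original locus tag>``, so
    the unified id is shared across genomes while the original tag stays
    recoverable (round-trippable via :func:`original_locus_tag`).
    """
    renamed: dict[str, list[CdsFeature]] = {}
    for gid, feats in annotations.items():
        missing = [
            f.locus_tag
            for f in feats
            if f"{gid}:{f.locus_tag}" not in clusters.membership
        ]
        if missing:
            raise OrthologError(
                f"genome {gid}: CDS without a clustered protein: {missing[:5]}"
            )
        renamed[gid] = [
            CdsFeature(
                f.contig_id, f.start, f.end, f.strand,
                f"{clusters.cluster_of(gid, f.locus_tag)}|{f.locus_tag}",
            )
            for f in feats
        ]
    return renamed


def original_locus_tag(renamed_tag: str) -> str:
    """Invert :func:`rename_annotations` for one locus tag."""
    if "|" not in renamed_tag:
        raise OrthologError(f"{renamed_tag!r} is not a renamed locus tag")
    return renamed_tag.split("|", 1)[1]


def cluster_of_renamed(renamed_tag: str) -> str:
    """Cluster id encoded in a renamed locus tag."""
    if "|" not in renamed_tag:
        raise OrthologError(f"{renamed_tag!r} is not a renamed locus tag")
    return renamed_tag.split("|", 1)[0]
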