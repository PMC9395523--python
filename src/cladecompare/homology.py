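"""Proteome-versus-genome best-hit search and similarity matrices.

Each reference protein is searched against the translated CDS set of each
genome (both strands honoured through the annotated strand) and scored by
the percent similarity of its best local alignment; queries whose best hit
fails the e-value cutoff are recorded as 0, encoding "no hit".  Stacking
the per-genome vectors over a genome panel yields the genes x genomes
similarity matrix that downstream presence/absence analysis consumes.

A shared-k-mer prescreen skips subject CDS that cannot plausibly reach the
similarity cutoff; it is exact for the e-value filter's purposes on
related sequences and can be disabled (``prescreen_k=None``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import (
    SearchParams,
    align_protein_pair,
    e_value,
    make_aligner,
)
from .records import GenomeRecord, ProteinRecord

logger = logging.getLogger(__name__)


class SearchError(ValueError):
    """Invalid homology-search input."""


@dataclass
class SimilarityMatrix:
    """Best-hit percent similarity of reference proteins across genomes.

    ``values.loc[q, g]`` is the percent similarity (0-100) of query ``q``
    against genome ``g``; 0 encodes "no hit at the e-value cutoff".
    ``best_subjects``, when available, records the locus tag of the
    best-hit CDS behind each cell (empty string for no hit).
    """

    values: pd.DataFrame
    best_subjects: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 100):
            raise SearchError("similarity values must lie in [0, 100]")

    @property
    def query_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="query")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="query"))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search_proteome_vs_genome(
    queries: list[ProteinRecord],
    genome: GenomeRecord,
    params: SearchParams | None = None,
    prescreen_k: int | None = 4,
    return_subjects: bool = False,
):
    """Best-hit percent similarity of each query against one genome.

    All annotated CDS are translated (minus-strand CDS reverse-complemented
    first) and each query is aligned locally against each translation.  The
    best hit is the highest raw score; ties break toward higher identity,
    then lexicographically smaller locus tag.  A query whose best hit has
    e-value above the cutoff scores 0.

    Returns the vector of similarities, plus the best-hit locus tags when
    ``return_subjects`` is set.
    """
    params = params or SearchParams()
    if not genome.cds:
        raise SearchError(f"genome {genome.id} has no annotated CDS")
    subjects = genome.proteome()
    aligner = make_aligner(params)
    kmers = (
        [_kmer_set(s.residues, prescreen_k) for s in subjects]
        if prescreen_k
        else None
    )
    sims = np.zeros(len(queries))
    best_tags = [""] * len(queries)
    for qi, query in enumerate(queries):
        qk = _kmer_set(query.residues, prescreen_k) if prescreen_k else None
        best_score = -np.inf
        candidates: list[int] = []
        for si, subject in enumerate(subjects):
            if kmers is not None and not (qk & kmers[si]):
                continue
            score = aligner.score(query.residues, subject.residues)
            if score > best_score:
                best_score = score
                candidates = [si]
            elif score == best_score:
                candidates.append(si)
        if not candidates:
            continue
        if e_value(best_score, len(query), len(subjects[candidates[0]]), params) > params.evalue_cutoff:
            continue
        hits = [align_protein_pair(query, subjects[si], params) for si in candidates]
        hits.sort(key=lambda h: (-h.percent_identity, h.subject_id))
        best = hits[0]
        if best.e_value <= params.evalue_cutoff:
            sims[qi] = best.percent_similarity
            best_tags[qi] = best.subject_id
    if return_subjects:
        return sims, best_tags
    return sims


def build_similarity_matrix(
    reference: list[ProteinRecord],
    genomes: list[GenomeRecord],
    params: SearchParams | None = None,
    prescreen_k: int | None = 4,
) -> SimilarityMatrix:
    """Genes x genomes matrix of best-hit percent similarities.

    Row order follows the reference proteome, column order the genome
    list.  The matrix has ``len(reference) * len(genomes)`` cells.
    """
    params = params or SearchParams()
    if not reference:
        raise SearchError("empty reference proteome")
    if not genomes:
        raise SearchError("empty genome list")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise SearchError("duplicate genome ids in panel")
    logger.info(
        "building similarity matrix: %d queries x %d genomes (%d cells)",
        len(reference), len(genomes), len(reference) * len(genomes),
    )
    cols = {}
    tag_cols = {}
    for genome in genomes:
        sims, tags = search_proteome_vs_genome(
            reference, genome, params, prescreen_k, return_subjects=True
        )
        cols[genome.id] = sims
        tag_cols[genome.id] = tags
    index = [q.id for q in reference]
    return SimilarityMatrix(
        values=pd.DataFrame(cols, index=index),
        best_subjects=pd.DataFrame(tag_cols, index=index),
    )


BLAST_TAB_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def similarity_matrix_from_blast_tab(
    path,
    subject_to_genome: dict[str, str],
    query_ids: list[str] | None = None,
    evalue_cutoff: float = 1e-10,
) -> SimilarityMatrix:
    """Ingest precomputed tabular homology-search output (12-column TSV).

    The standard 12 columns are expected, with an optional 13th
    "percent positives" column; when absent, percent identity stands in
    for similarity (logged).  Rows failing the e-value cutoff are dropped;
    per (query, genome) the best row by bitscore wins.
    """
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] == 13:
        table.columns = BLAST_TAB_COLUMNS + ["ppos"]
    elif table.shape[1] == 12:
        table.columns = BLAST_TAB_COLUMNS
        table["ppos"] = table["pident"]
        logger.warning(
            "%s: no percent-positives column; using percent identity as "
            "similarity", path,
        )
    else:
        raise SearchError(
            f"{path}: expected 12 or 13 tab-separated columns, got {table.shape[1]}"
        )
    unknown = set(table["subject"]) - set(subject_to_genome)
    if unknown:
        raise SearchError(f"subjects with no genome mapping: {sorted(unknown)[:5]}")
    table["genome"] = table["subject"].map(subject_to_genome)
    table = table[table["evalue"] <= evalue_cutoff]
    best = (
        table.sort_values("bitscore", ascending=False)
        .groupby(["query", "genome"], sort=False)
        .first()
        .reset_index()
    )
    matrix = best.pivot(index="query", columns="genome", values="ppos").fillna(0.0)
    if query_ids is not None:
        matrix = matrix.reindex(index=query_ids, fill_value=0.0)
    matrix = matrix.reindex(
        columns=sorted(set(subject_to_genome.values())), fill_value=0.0
    )
    return SimilarityMatrix(values=matrix)
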