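"""Average nucleotide identity (ANI) and ANI-based species grouping.

ANIb-style conventions: the query genome is chopped into consecutive
1020-base fragments, each fragment is aligned locally against the subject
genome on both strands, and ANI is the mean percent identity over
fragments passing the identity (>= 30%) and coverage (>= 70% of fragment
aligned) filters.  The symmetric ANI of a pair is the mean of the two
directional values, and species groups are single-linkage components of
the graph with edges where symmetric ANI exceeds the threshold
(default > 96%).
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .records import GenomeRecord


class AniError(ValueError):
    """Invalid ANI input."""


def _nucleotide_aligner() -> PairwiseAligner:
    # blastn-style scoring: reward 2, penalty -3, gap open 5, extend 2
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _fragment_identity(aligner, fragment: str, subject: str):
    """(percent identity, percent fragment coverage) of the best local hit."""
    best = None
    for frag in (fragment, str(Seq(fragment).reverse_complement())):
        alignment = next(iter(aligner.align(subject, frag)))
        if best is None or alignment.score > best.score:
            best = alignment
    identities = 0
    columns = 0
    covered = 0
    target, query = best.sequences
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(best.aligned[0], best.aligned[1]):
        if prev_t is not None:
            columns += (t0 - prev_t) + (q0 - prev_q)
        covered += q1 - q0
        for i in range(t1 - t0):
            columns += 1
            if target[t0 + i] == query[q0 + i]:
                identities += 1
        prev_t, prev_q = t1, q1
    if columns == 0:
        return 0.0, 0.0
    return 100.0 * identities / columns, 100.0 * covered / len(fragment)


def ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_length: int = 1020,
    min_fragment_identity: float = 30.0,
    min_fragment_coverage: float = 70.0,
) -> float:
    """Directional ANI of genome ``a`` against genome ``b`` (percent).

    Raises when either genome is shorter than one fragment, and returns
    0 when no fragment passes the filters.
    """
    for genome in (a, b):
        if genome.length < fragment_length:
            raise AniError(
                f"genome {genome.id} ({genome.length} bp) shorter than one "
                f"fragment ({fragment_length} bp)"
            )
    subject = "".join(b.contigs[c] for c in sorted(b.contigs))
    aligner = _nucleotide_aligner()
    identities = []
    for contig_id in sorted(a.contigs):
        contig = a.contigs[contig_id]
        for off in range(0, len(contig) - fragment_length + 1, fragment_length):
            fragment = contig[off : off + fragment_length]
            pid, cov = _fragment_identity(aligner, fragment, subject)
            if pid >= min_fragment_identity and cov >= min_fragment_coverage:
                identities.append(pid)
    if not identities:
        return 0.0
    return sum(identities) / len(identities)


def symmetric_ani(a: GenomeRecord, b: GenomeRecord, **kwargs) -> float:
    """Mean of the two directional ANI values."""
    return 0.5 * (ani(a, b, **kwargs) + ani(b, a, **kwargs))


def group_species_by_ani(
    genomes: list[GenomeRecord], threshold: float = 96.0, **kwargs
) -> list[set[str]]:
    """Partition genomes into species groups by symmetric ANI > threshold.

    Single-linkage: connected components of the ANI graph.  Returns the
    blocks sorted by their smallest member id.
    """
    if not genomes:
        raise AniError("no genomes to group")
    graph = nx.Graph()
    graph.add_nodes_from(g.id for g in genomes)
    for a, b in combinations(genomes, 2):
        if symmetric_ani(a, b, **kwargs) > threshold:
            graph.add_edge(a.id, b.id)
    blocks = [set(c) for c in nx.connected_components(graph)]
    return sorted(blocks, key=min)
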