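"""Group-diagnostic amino-acid sites in core protein families.

A diagnostic site (amino-acid "permutation") is an alignment column whose
residue is invariant within each phenotype group but differs between the
groups — the signature of a substitution fixed alongside a phenotype
transition.  Columns containing a gap in any row are excluded entirely:
indels and truncated proteins are not scored as residue changes.

The built-in aligner is a deterministic star-progressive aligner (every
sequence aligned globally to a centre chosen by mean similarity, gaps
merged with "once a gap, always a gap") intended for desk-scale families;
externally produced alignments can be supplied as pre-aligned rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import SearchParams, global_align, make_aligner
from .gene_content import ThresholdConfig
from .homology import SimilarityMatrix
from .records import ProteinRecord


class SiteError(ValueError):
    """Invalid alignment or labelling input."""


@dataclass
class FamilyAlignment:
    """A multiple alignment of one protein family (gap = '-')."""

    family_id: str
    rows: dict[str, str]  # species id -> aligned residues, insertion order kept
    reference_species: str | None = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SiteError(f"family {self.family_id}: need >= 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1 or 0 in lengths:
            raise SiteError(f"family {self.family_id}: rows of unequal length")
        if self.reference_species is not None and self.reference_species not in self.rows:
            raise SiteError(
                f"family {self.family_id}: reference species "
                f"{self.reference_species!r} not among rows"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass(frozen=True)
class DiagnosticSite:
    """One group-diagnostic alignment column."""

    family_id: str
    column: int  # 1-based alignment column
    residue_a: str
    residue_b: str
    reference_position: int | None = None  # 1-based ungapped; None if ref gapped

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise SiteError("diagnostic residues must differ")
        if "-" in (self.residue_a, self.residue_b):
            raise SiteError("diagnostic residues cannot be gaps")


def _merge_star(center: str, pairwise: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise (center, other) alignments into one multiple alignment.

    Classic star merge: the union of gap positions inserted into the
    centre defines the master coordinate system.
    """
    # map each alignment's centre-gaps into centre coordinates
    gap_counts: dict[int, int] = {}  # gaps to insert *before* centre position i
    per_aln_gaps = []
    for c_aln, _ in pairwise:
        gaps: dict[int, int] = {}
        pos = 0
        run = 0
        for ch in c_aln:
            if ch == "-":
                run += 1
            else:
                if run:
                    gaps[pos] = run
                run = 0
                pos += 1
        if run:
            gaps[pos] = run
        per_aln_gaps.append(gaps)
        for p, n in gaps.items():
            gap_counts[p] = max(gap_counts.get(p, 0), n)
    n = len(center)
    master_center = []
    for p in range(n + 1):
        master_center.append("-" * gap_counts.get(p, 0))
        if p < n:
            master_center.append(center[p])
    master = ["".join(master_center)]
    for (c_aln, o_aln), gaps in zip(pairwise, per_aln_gaps):
        out = []
        pos = 0  # centre position
        i = 0  # index into this pairwise alignment
        for p in range(n + 1):
            want = gap_counts.get(p, 0)
            have = gaps.get(p, 0)
            # this alignment's own gap block at p carries other-row residues
            block = []
            while i < len(c_aln) and c_aln[i] == "-":
                block.append(o_aln[i])
                i += 1
            block = "".join(block)
            out.append("-" * (want - have) + block)
            if p < n:
                out.append(o_aln[i])
                i += 1
        master.append("".join(out))
    return master


def build_family_alignment(
    members: list[ProteinRecord],
    family_id: str | None = None,
    params: SearchParams | None = None,
    reference_species: str | None = None,
) -> FamilyAlignment:
    """Star-progressive multiple alignment of a protein family.

    The centre sequence is the member with the highest mean pairwise
    alignment score against the others (ties toward the smaller genome
    id); every other member is aligned to it globally and the pairwise
    alignments are merged.  For two sequences this reduces exactly to the
    pairwise global alignment.  Deterministic for a fixed input order.
    """
    params = params or SearchParams()
    if len(members) < 2:
        raise SiteError("need at least two sequences to align")
    ids = [m.genome_id for m in members]
    if len(set(ids)) != len(ids):
        raise SiteError("one member per species required (duplicate genome ids)")
    aligner = make_aligner(params, mode="global")
    n = len(members)
    mean_scores = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(members[i].residues, members[j].residues)
            mean_scores[i] += s
            mean_scores[j] += s
    order = sorted(range(n), key=lambda i: (-mean_scores[i], members[i].genome_id))
    center = members[order[0]]
    others = [members[i] for i in order[1:]]
    pairwise = [
        global_align(center.residues, o.residues, params)[:2] for o in others
    ]
    merged = _merge_star(center.residues, pairwise)
    rows = {center.genome_id: merged[0]}
    for o, row in zip(others, merged[1:]):
        rows[o.genome_id] = row
    # restore input row order
    rows = {m.genome_id: rows[m.genome_id] for m in members}
    return FamilyAlignment(
        family_id=family_id or "family",
        rows=rows,
        reference_species=reference_species,
    )


def find_diagnostic_columns(
    alignment: FamilyAlignment, groups: dict[str, str]
) -> list[DiagnosticSite]:
    """Columns conserved within each group but different between groups.

    A column qualifies iff all group-A residues are identical, all group-B
    residues are identical, neither consensus is a gap, and the two
    consensi differ; any gap anywhere in the column disqualifies it.
    """
    missing = [s for s in alignment.rows if s not in groups]
    if missing:
        raise SiteError(f"species without a group label: {missing}")
    a_rows = [r for s, r in alignment.rows.items() if groups[s] == "A"]
    b_rows = [r for s, r in alignment.rows.items() if groups[s] == "B"]
    if not a_rows or not b_rows:
        raise SiteError("both groups need at least one species")
    sites = []
    for col in range(alignment.n_columns):
        column = [r[col] for r in a_rows] + [r[col] for r in b_rows]
        if "-" in column:
            continue
        res_a = a_rows[0][col]
        res_b = b_rows[0][col]
        if any(r[col] != res_a for r in a_rows):
            continue
        if any(r[col] != res_b for r in b_rows):
            continue
        if res_a == res_b:
            continue
        site = DiagnosticSite(
            family_id=alignment.family_id,
            column=col + 1,
            residue_a=res_a,
            residue_b=res_b,
        )
        if alignment.reference_species is not None:
            ref_pos = map_to_reference(site, alignment)
            site = DiagnosticSite(
                site.family_id, site.column, site.residue_a, site.residue_b,
                reference_position=ref_pos,
            )
        sites.append(site)
    return sites


def map_to_reference(site: DiagnosticSite, alignment: FamilyAlignment) -> int | None:
    """1-based ungapped reference position of an alignment column.

    Counts non-gap reference characters up to and including the column;
    returns None when the reference row is gapped at the column.
    """
    if alignment.reference_species is None:
        raise SiteError("alignment has no reference species")
    if not (1 <= site.column <= alignment.n_columns):
        raise SiteError(
            f"column {site.column} out of range 1..{alignment.n_columns}"
        )
    ref_row = alignment.rows[alignment.reference_species]
    if ref_row[site.column - 1] == "-":
        return None
    return sum(1 for ch in ref_row[: site.column] if ch != "-")


def scan_core_proteome(
    matrix: SimilarityMatrix,
    proteomes: dict[str, list[ProteinRecord]],
    groups: dict[str, str],
    thresholds: ThresholdConfig | None = None,
    params: SearchParams | None = None,
    reference_genome: str | None = None,
):
    """Scan the strictly conserved core proteome for diagnostic sites.

    Core families are reference proteins whose best-hit similarity is at
    least ``core_similarity`` in every genome.  For each, the best-hit
    member per genome (recorded in the matrix during its construction) is
    collected, the members aligned, and the alignment scanned for
    diagnostic columns.

    Returns ``(core_family_ids, {family_id: [DiagnosticSite, ...]})`` with
    an entry for every core family (possibly an empty site list).
    """
    thresholds = thresholds or ThresholdConfig()
    params = params or SearchParams()
    if matrix.best_subjects is None:
        raise SiteError(
            "similarity matrix carries no best-hit subjects; rebuild it "
            "with build_similarity_matrix or supply pre-aligned families"
        )
    missing = [g for g in matrix.genome_ids if g not in proteomes]
    if missing:
        raise SiteError(f"no proteome supplied for genomes: {missing}")
    core_mask = (matrix.values >= thresholds.core_similarity).all(axis=1)
    core_ids = list(matrix.values.index[core_mask])
    by_tag = {
        gid: {p.id: p for p in prots} for gid, prots in proteomes.items()
    }
    sites_by_family: dict[str, list[DiagnosticSite]] = {}
    for family in core_ids:
        members = []
        for gid in matrix.genome_ids:
            tag = matrix.best_subjects.loc[family, gid]
            if not tag:
                raise SiteError(
                    f"core family {family}: no best hit recorded in {gid}"
                )
            members.append(by_tag[gid][tag])
        alignment = build_family_alignment(
            members, family_id=family, params=params,
            reference_species=reference_genome,
        )
        sites_by_family[family] = find_diagnostic_columns(alignment, groups)
    return core_ids, sites_by_family
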