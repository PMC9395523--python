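"""Presence/absence calls and group-exclusive gene detection.

Best-hit similarity values are categorised with two one-sided thresholds:
below 50% is "absent", above 55% is "present", and the band between is
"ambiguous".  A gene is exclusively present in a phenotype group when it
is called present in every genome of the group and absent in every genome
outside it; ambiguous calls disqualify the gene in either direction —
the conservative reading of the two thresholds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .homology import SimilarityMatrix


class ContentError(ValueError):
    """Invalid presence/absence input."""


class PresenceCall(enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis thresholds, with the study defaults.

    absent_below / present_above bound the ambiguous similarity band;
    graph_cutoff is the ortholog-graph edge threshold; core_similarity the
    core-proteome membership threshold; ani_species the species-grouping
    ANI threshold.
    """

    absent_below: float = 50.0
    present_above: float = 55.0
    evalue_cutoff: float = 1e-10
    graph_cutoff: float = 60.0
    core_similarity: float = 60.0
    ani_species: float = 96.0

    def __post_init__(self) -> None:
        if not (0 <= self.absent_below <= self.present_above <= 100):
            raise ContentError(
                "need 0 <= absent_below <= present_above <= 100, got "
                f"{self.absent_below} / {self.present_above}"
            )


@dataclass
class ExclusiveGeneReport:
    """Genes exclusively present in / absent from one phenotype group."""

    group_label: str
    exclusive_present: list[str]
    exclusive_absent: list[str]
    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        overlap = set(self.exclusive_present) & set(self.exclusive_absent)
        if overlap:
            raise ContentError(f"genes in both lists: {sorted(overlap)}")


def categorize_similarity(
    value: float, thresholds: ThresholdConfig | None = None
) -> PresenceCall:
    """Categorise one similarity value into present/absent/ambiguous."""
    thresholds = thresholds or ThresholdConfig()
    if not (0 <= value <= 100):
        raise ContentError(f"similarity {value} outside [0, 100]")
    if value < thresholds.absent_below:
        return PresenceCall.ABSENT
    if value > thresholds.present_above:
        return PresenceCall.PRESENT
    return PresenceCall.AMBIGUOUS


def call_matrix(
    matrix: SimilarityMatrix, thresholds: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Apply categorize_similarity to every cell."""
    thresholds = thresholds or ThresholdConfig()
    return matrix.values.map(lambda v: categorize_similarity(v, thresholds).value)


def find_group_exclusive(
    matrix: SimilarityMatrix,
    groups: dict[str, str],
    thresholds: ThresholdConfig | None = None,
    group_label: str = "A",
) -> ExclusiveGeneReport:
    """Genes present in every group genome and absent outside, or vice versa.

    ``groups`` maps each genome (matrix column) to "A" or "B"; the report
    is phrased for ``group_label`` (default group A).  Ambiguous calls
    block a gene from both lists.
    """
    thresholds = thresholds or ThresholdConfig()
    unlabeled = [g for g in matrix.genome_ids if g not in groups]
    if unlabeled:
        raise ContentError(f"genomes without a group label: {unlabeled}")
    bad = {g: l for g, l in groups.items() if l not in ("A", "B")}
    if bad:
        raise ContentError(f"group labels must be 'A' or 'B': {bad}")
    in_group = [g for g in matrix.genome_ids if groups[g] == group_label]
    out_group = [g for g in matrix.genome_ids if groups[g] != group_label]
    if not in_group or not out_group:
        raise ContentError("both groups need at least one genome")
    calls = call_matrix(matrix, thresholds)
    present = calls == PresenceCall.PRESENT.value
    absent = calls == PresenceCall.ABSENT.value
    exclusive_present = calls.index[
        present[in_group].all(axis=1) & absent[out_group].all(axis=1)
    ]
    exclusive_absent = calls.index[
        absent[in_group].all(axis=1) & present[out_group].all(axis=1)
    ]
    return ExclusiveGeneReport(
        group_label=group_label,
        exclusive_present=list(exclusive_present),
        exclusive_absent=list(exclusive_absent),
        calls=calls,
    )
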