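"""Muropeptide quantification from HPLC peak areas.

Peak areas (UV absorbance at 204 nm) are converted to molar abundances by
dividing by the oligomer unit count — a dimer carries two muropeptide
subunits' worth of signal — then normalised to molar percentages.  The
crosslink percentage is the Glauner-style fraction of peptide stems
engaged in a crosslink: an n-mer has n stems, n - 1 of them crosslinked,
so crosslink% = sum over classes of molar% * (n - 1) / n.  The simpler
"crosslinked muropeptide fraction" (total oligomer molar%) is also
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

OLIGOMER_NAMES = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer"}


class MuropeptideError(ValueError):
    """Invalid peak table."""


@dataclass(frozen=True)
class PeakRecord:
    """One muropeptide HPLC peak."""

    name: str
    oligomer_units: int
    area: float

    def __post_init__(self) -> None:
        if self.oligomer_units not in OLIGOMER_NAMES:
            raise MuropeptideError(
                f"peak {self.name}: oligomer_units must be 1..4, got "
                f"{self.oligomer_units}"
            )
        if self.area < 0:
            raise MuropeptideError(f"peak {self.name}: negative area")


@dataclass
class MuropeptideProfile:
    """Molar composition and crosslink statistics of one sacculus prep."""

    molar_percent: dict[str, float]
    oligomer_class_percent: dict[str, float]
    crosslink_percent: float  # stem fraction (default statistic)
    crosslinked_muropeptide_percent: float  # oligomer molar fraction

    def __post_init__(self) -> None:
        total = sum(self.molar_percent.values())
        if abs(total - 100.0) > 1e-6:
            raise MuropeptideError(f"molar percentages sum to {total}, not 100")
        if not (0.0 <= self.crosslink_percent <= 100.0):
            raise MuropeptideError("crosslink percent outside [0, 100]")


def molar_percentages(
    peaks: list[PeakRecord], per_unit_normalization: bool = True
) -> MuropeptideProfile:
    """Molar percentages and crosslink statistics from peak areas.

    ``per_unit_normalization`` divides each area by its oligomer unit
    count before normalising (UV signal scales with subunit content);
    disabling it treats relative areas as already molar.
    """
    if not peaks:
        raise MuropeptideError("no peaks supplied")
    names = [p.name for p in peaks]
    if len(set(names)) != len(names):
        raise MuropeptideError("duplicate peak names")
    abundances = {
        p.name: p.area / (p.oligomer_units if per_unit_normalization else 1)
        for p in peaks
    }
    total = sum(abundances.values())
    if total <= 0:
        raise MuropeptideError("total peak area is zero")
    molar = {name: 100.0 * a / total for name, a in abundances.items()}
    class_percent = {name: 0.0 for name in OLIGOMER_NAMES.values()}
    stem_crosslink = 0.0
    oligomer_molar = 0.0
    for p in peaks:
        cls = OLIGOMER_NAMES[p.oligomer_units]
        class_percent[cls] += molar[p.name]
        stem_crosslink += molar[p.name] * (p.oligomer_units - 1) / p.oligomer_units
        if p.oligomer_units > 1:
            oligomer_molar += molar[p.name]
    return MuropeptideProfile(
        molar_percent=molar,
        oligomer_class_percent=class_percent,
        crosslink_percent=stem_crosslink,
        crosslinked_muropeptide_percent=oligomer_molar,
    )


def crosslink_percent(profile: MuropeptideProfile) -> float:
    """Percent of peptide stems engaged in crosslinks."""
    return profile.crosslink_percent


def oligomer_ratios(profile: MuropeptideProfile) -> dict[str, float]:
    """Molar abundance of each oligomer class relative to monomers."""
    mono = profile.oligomer_class_percent.get("monomer", 0.0)
    if mono <= 0:
        raise MuropeptideError("monomer molar abundance is zero")
    return {
        cls: pct / mono
        for cls, pct in profile.oligomer_class_percent.items()
        if cls != "monomer"
    }


def read_peaks_csv(path) -> list[PeakRecord]:
    """Read a ``name,units,area`` CSV of peaks."""
    import pandas as pd

    table = pd.read_csv(path)
    required = {"name", "units", "area"}
    if not required <= set(table.columns):
        raise MuropeptideError(f"peak CSV needs columns {sorted(required)}")
    return [
        PeakRecord(str(r["name"]), int(r["units"]), float(r["area"]))
        for _, r in table.iterrows()
    ]
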