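"""Synthetic clades with planted, recoverable truth.

Generates a two-phenotype-group clade of annotated genomes — core protein
families present everywhere, families gained only in group A, families
lost only from group A, and core families carrying planted
group-diagnostic residues — plus the generating tree, a trait table and
(optionally) NB-distributed per-cluster read counts with planted group
effects.  The planted truth travels with the clade so downstream analyses
can be tested for exact recovery.

Sequence evolution is deliberately simple: i.i.d. residue substitutions
along a random ultrametric tree whose root-to-leaf height is half the
target pairwise divergence, no indels.  Genomes are concatenations of CDS
(reverse-translated with randomly chosen synonymous codons, stop codon
included) separated by short random spacers, alternating strands so that
minus-strand handling is exercised.

The default configuration mirrors the comparison design the package
targets: 5 genomes in the focal (MuLDi-like) group versus 32 in the
rod-like group, 7 planted exclusive gains, 4 planted losses and 3
diagnostic families at 5% background divergence.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .de import CountsTable
from .records import AMINO_ACIDS, CdsFeature, GenomeRecord, ProteinRecord

NUCLEOTIDES = "ACGT"

# codon choices per amino acid under the bacterial code (table 11),
# avoiding codons that translate differently in edge contexts
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOP = "TAA"


class SyntheticError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class CladeConfig:
    """Study-design parameters of a synthetic clade."""

    n_group_a: int = 5
    n_group_b: int = 32
    n_core_families: int = 30
    n_exclusive_gains: int = 7
    n_exclusive_losses: int = 4
    n_diagnostic_families: int = 3
    mean_protein_length: int = 120
    background_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_group_a, self.n_group_b, self.n_core_families,
            self.n_exclusive_gains, self.n_exclusive_losses,
            self.n_diagnostic_families,
        )
        if any(c < 0 for c in counts):
            raise SyntheticError("all counts must be >= 0")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise SyntheticError("need at least one genome per group")
        if not (0 <= self.background_divergence < 0.5):
            raise SyntheticError(
                "background_divergence must lie in [0, 0.5); beyond that "
                "families are not recognisable as orthologs"
            )
        if self.mean_protein_length < 30:
            raise SyntheticError("mean_protein_length must be >= 30")
        if self.n_diagnostic_families > self.n_core_families:
            raise SyntheticError(
                "diagnostic families are a subset of core families"
            )


@dataclass(frozen=True)
class DECountsConfig:
    """Parameters of the planted-effect NB count generator."""

    n_de: int = 20
    log2fc_magnitude: float = 1.0
    dispersion: float = 0.1
    mean_expression: float = 500.0
    size_factor_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de < 0:
            raise SyntheticError("n_de must be >= 0")
        if self.dispersion < 0:
            raise SyntheticError("dispersion must be >= 0")
        if self.mean_expression <= 0:
            raise SyntheticError("mean_expression must be > 0")


@dataclass
class CladeTruth:
    """Planted ground truth of a synthetic clade."""

    planted_gain_ids: tuple[str, ...]
    planted_loss_ids: tuple[str, ...]
    # (family id, 1-based position, group-A residue, group-B residue)
    planted_sites: tuple[tuple[str, int, str, str], ...]
    planted_de: tuple[tuple[str, float], ...]
    tree_newick: str
    trait_map: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.planted_gain_ids) & set(self.planted_loss_ids):
            raise SyntheticError("gain and loss family ids must be disjoint")
        for fam, pos, res_a, res_b in self.planted_sites:
            if res_a == res_b:
                raise SyntheticError(
                    f"planted site {fam}:{pos} has identical residues"
                )


@dataclass
class SyntheticClade:
    """A generated clade: genomes, proteomes and the planted truth."""

    config: CladeConfig
    genomes: list[GenomeRecord]
    proteomes: dict[str, list[ProteinRecord]]
    truth: CladeTruth

    @property
    def genome_ids(self) -> list[str]:
        return [g.id for g in self.genomes]

    @property
    def groups(self) -> dict[str, str]:
        return {
            gid: ("A" if self.truth.trait_map[gid] == "muldi" else "B")
            for gid in self.genome_ids
        }

    def genome(self, gid: str) -> GenomeRecord:
        return next(g for g in self.genomes if g.id == gid)


class _Node:
    __slots__ = ("children", "name", "length")

    def __init__(self, name=None, length=0.0):
        self.children: list[_Node] = []
        self.name = name
        self.length = length

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_inner() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6f}"


def _random_ultrametric(names: list[str], height: float, rng) -> _Node:
    """Random ultrametric subtree: leaves exactly ``height`` below the node."""
    node = _Node()
    k = int(rng.integers(1, len(names)))
    for part in (names[:k], names[k:]):
        if len(part) == 1:
            node.children.append(_Node(part[0], length=height))
        else:
            child_height = height * float(rng.uniform(0.3, 0.8))
            child = _random_ultrametric(part, child_height, rng)
            child.length = height - child_height
            node.children.append(child)
    return node


def _group_subtree(names: list[str], height: float, rng) -> _Node:
    """Subtree for one phenotype group, hung off the root by a short stem."""
    if len(names) == 1:
        return _Node(names[0], length=height)
    sub = _random_ultrametric(names, height * 0.9, rng)
    sub.length = height * 0.1
    return sub


def _evolve(node: _Node, seq: np.ndarray, rng, frozen: set[int], out) -> None:
    """Evolve an integer-coded sequence down the tree (i.i.d. sites)."""
    for child in node.children or []:
        p = 1.0 - np.exp(-child.length)
        child_seq = seq.copy()
        if p > 0:
            hit = rng.random(len(seq)) < p
            for pos in np.nonzero(hit)[0]:
                if int(pos) in frozen:
                    continue
                # substitute to a uniformly chosen different residue
                child_seq[pos] = (seq[pos] + int(rng.integers(1, 20))) % 20
        if child.children:
            _evolve(child, child_seq, rng, frozen, out)
        else:
            out[child.name] = child_seq
    if not node.children:
        out[node.name] = seq.copy()


def _decode(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def generate_clade(config: CladeConfig | None = None) -> SyntheticClade:
    """Generate a synthetic clade with planted truth.

    Deterministic for a fixed configuration (including seed): the same
    config yields byte-identical emitted files.
    """
    config = config or CladeConfig()
    rng = np.random.default_rng(config.seed)
    a_ids = [f"A{i + 1:02d}" for i in range(config.n_group_a)]
    b_ids = [f"B{i + 1:02d}" for i in range(config.n_group_b)]
    height = config.background_divergence / 2.0
    root = _Node(length=0.0)
    subtree_a = _group_subtree(a_ids, height, rng)
    subtree_b = _group_subtree(b_ids, height, rng)
    root.children = [subtree_a, subtree_b]
    trait_map = {g: "muldi" for g in a_ids} | {g: "rod" for g in b_ids}

    core_ids = [f"fam{i + 1:04d}" for i in range(config.n_core_families)]
    gain_ids = [f"gain{i + 1:04d}" for i in range(config.n_exclusive_gains)]
    loss_ids = [f"loss{i + 1:04d}" for i in range(config.n_exclusive_losses)]
    diagnostic_ids = core_ids[: config.n_diagnostic_families]

    # family id -> genome id -> residue string
    members: dict[str, dict[str, str]] = {}
    planted_sites = []
    for family in core_ids + gain_ids + loss_ids:
        length = max(30, int(round(rng.normal(config.mean_protein_length,
                                              0.1 * config.mean_protein_length))))
        ancestor = rng.integers(0, 20, size=length)
        frozen: set[int] = set()
        site = None
        if family in diagnostic_ids:
            pos = int(rng.integers(6, length - 4))  # 1-based interior position
            res_a = int(rng.integers(0, 20))
            res_b = (res_a + 1 + int(rng.integers(0, 19))) % 20
            site = (family, pos, AMINO_ACIDS[res_a], AMINO_ACIDS[res_b])
            frozen = {pos - 1}
        if family in gain_ids:
            tree, carriers = subtree_a, set(a_ids)
        elif family in loss_ids:
            tree, carriers = subtree_b, set(b_ids)
        else:
            tree, carriers = root, set(a_ids) | set(b_ids)
        out: dict[str, np.ndarray] = {}
        _evolve(tree, ancestor, rng, frozen, out)
        if site is not None:
            fam, pos, res_a, res_b = site
            for gid in carriers:
                out[gid][pos - 1] = AMINO_ACIDS.index(
                    res_a if gid in a_ids else res_b
                )
            planted_sites.append(site)
        members[family] = {gid: _decode(out[gid]) for gid in sorted(carriers)}

    genomes = []
    proteomes: dict[str, list[ProteinRecord]] = {}
    for gid in a_ids + b_ids:
        families = [f for f in core_ids + gain_ids + loss_ids if gid in members[f]]
        parts = []
        feats = []
        cursor = 0
        contig_id = f"{gid}_c1"
        for idx, family in enumerate(families):
            spacer = "".join(
                NUCLEOTIDES[i] for i in rng.integers(0, 4, size=int(rng.integers(20, 51)))
            )
            parts.append(spacer)
            cursor += len(spacer)
            protein = members[family][gid]
            # 24 is divisible by every codon-family size (1, 2, 3, 4, 6),
            # so draw % len is uniform over each family's codons
            draws = rng.integers(0, 24, size=len(protein))
            codons = "".join(
                _CODONS[aa][d % len(_CODONS[aa])]
                for aa, d in zip(protein, draws)
            ) + _STOP
            strand = "+" if idx % 2 == 0 else "-"
            nt = codons if strand == "+" else str(Seq(codons).reverse_complement())
            start = cursor + 1
            end = cursor + len(nt)
            parts.append(nt)
            cursor = end
            feats.append(
                CdsFeature(contig_id, start, end, strand, f"{gid}_{family}")
            )
        tail = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=30))
        parts.append(tail)
        phenotype = "muldi" if gid in a_ids else "rod"
        genome = GenomeRecord(
            id=gid,
            contigs={contig_id: "".join(parts)},
            cds=feats,
            phenotype=phenotype,
        )
        genomes.append(genome)
        proteomes[gid] = genome.proteome()

    truth = CladeTruth(
        planted_gain_ids=tuple(gain_ids),
        planted_loss_ids=tuple(loss_ids),
        planted_sites=tuple(planted_sites),
        planted_de=(),
        tree_newick=root.newick(),
        trait_map=trait_map,
    )
    return SyntheticClade(
        config=config, genomes=genomes, proteomes=proteomes, truth=truth
    )


def generate_counts(
    clade: SyntheticClade, de_config: DECountsConfig | None = None
) -> CountsTable:
    """NB2 read counts per core family per genome, with planted effects.

    Counts follow the NB2 law (variance mu + alpha mu^2; alpha = 0 is
    Poisson).  The first ``n_de`` core families receive a group effect of
    alternating sign and magnitude ``log2fc_magnitude`` (group B mean
    multiplied by 2**lfc).  The clade's truth is updated with the planted
    (cluster, lfc) pairs.
    """
    de_config = de_config or DECountsConfig()
    groups = clade.groups
    if "A" not in groups.values() or "B" not in groups.values():
        raise SyntheticError("clade needs at least one genome per group")
    core_ids = [
        f for f in (f"fam{i + 1:04d}" for i in range(clade.config.n_core_families))
    ]
    if de_config.n_de > len(core_ids):
        raise SyntheticError(
            f"n_de={de_config.n_de} exceeds the {len(core_ids)} core families"
        )
    rng = np.random.default_rng(de_config.seed)
    planted = []
    lfc_by_family = {}
    for i, family in enumerate(core_ids[: de_config.n_de]):
        lfc = de_config.log2fc_magnitude * (1 if i % 2 == 0 else -1)
        planted.append((family, float(lfc)))
        lfc_by_family[family] = lfc
    sample_ids = clade.genome_ids
    lib = (
        np.exp(rng.normal(0.0, de_config.size_factor_sigma, size=len(sample_ids)))
        if de_config.size_factor_sigma > 0
        else np.ones(len(sample_ids))
    )
    alpha = de_config.dispersion
    data = np.zeros((len(core_ids), len(sample_ids)), dtype=np.int64)
    for fi, family in enumerate(core_ids):
        lfc = lfc_by_family.get(family, 0.0)
        for si, sid in enumerate(sample_ids):
            mu = de_config.mean_expression * lib[si]
            if groups[sid] == "B":
                mu *= 2.0 ** lfc
            if alpha == 0:
                data[fi, si] = rng.poisson(mu)
            else:
                n = 1.0 / alpha
                p = n / (n + mu)
                data[fi, si] = rng.negative_binomial(n, p)
    clade.truth.planted_de = tuple(planted)
    counts = pd.DataFrame(data, index=core_ids, columns=sample_ids)
    return CountsTable(counts, {s: groups[s] for s in sample_ids})


# ---------------------------------------------------------------------------
# fixtures on disk

MANIFEST_NAME = "manifest.json"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    clade: SyntheticClade,
    directory,
    counts: CountsTable | None = None,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write the clade as standard-format files; returns {file: sha256}.

    Emits per-genome nucleotide FASTA, protein FASTA and GFF3, plus the
    Newick tree, trait CSV, truth JSON and, when given, the counts TSV.
    Refuses to overwrite an existing manifest unless ``overwrite``.
    """
    if not clade.genomes:
        raise SyntheticError("refusing to write an empty clade (0 genomes)")
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise SyntheticError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )
    for sub in ("genomes", "proteomes", "gff"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for genome in clade.genomes:
        fna = directory / "genomes" / f"{genome.id}.fna"
        with open(fna, "w") as fh:
            for contig_id in genome.contigs:
                fh.write(f">{contig_id}\n")
                seq = genome.contigs[contig_id]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        files.append(fna)
        faa = directory / "proteomes" / f"{genome.id}.faa"
        with open(faa, "w") as fh:
            for prot in clade.proteomes[genome.id]:
                fh.write(f">{prot.id}\n")
                for i in range(0, len(prot.residues), 70):
                    fh.write(prot.residues[i : i + 70] + "\n")
        files.append(faa)
        gff = directory / "gff" / f"{genome.id}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig_id, seq in genome.contigs.items():
                fh.write(f"##sequence-region {contig_id} 1 {len(seq)}\n")
            for feat in genome.cds:
                attrs = f"ID={feat.locus_tag};locus_tag={feat.locus_tag}"
                fh.write(
                    f"{feat.contig_id}\tcladecompare\tCDS\t{feat.start}\t"
                    f"{feat.end}\t.\t{feat.strand}\t0\t{attrs}\n"
                )
        files.append(gff)
    tree_path = directory / "tree.nwk"
    tree_path.write_text(clade.truth.tree_newick + "\n")
    files.append(tree_path)
    traits_path = directory / "traits.csv"
    with open(traits_path, "w") as fh:
        fh.write("leaf,state\n")
        for leaf in clade.genome_ids:
            fh.write(f"{leaf},{clade.truth.trait_map[leaf]}\n")
    files.append(traits_path)
    if counts is not None:
        counts_path = directory / "counts.tsv"
        counts.to_tsv(counts_path)
        files.append(counts_path)
        groups_path = directory / "groups.csv"
        with open(groups_path, "w") as fh:
            fh.write("sample,group\n")
            for sid in counts.sample_ids:
                fh.write(f"{sid},{counts.sample_group[sid]}\n")
        files.append(groups_path)
    truth_path = directory / "truth.json"
    truth_payload = {
        "config": clade.config.__dict__,
        "planted_gain_ids": list(clade.truth.planted_gain_ids),
        "planted_loss_ids": list(clade.truth.planted_loss_ids),
        "planted_sites": [list(s) for s in clade.truth.planted_sites],
        "planted_de": [list(d) for d in clade.truth.planted_de],
        "tree_newick": clade.truth.tree_newick,
        "trait_map": clade.truth.trait_map,
        "phenotypes": {g.id: g.phenotype for g in clade.genomes},
    }
    truth_path.write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    files.append(truth_path)
    manifest = {str(p.relative_to(directory)): _sha256(p) for p in files}
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_fixtures(directory) -> SyntheticClade:
    """Reconstruct a SyntheticClade from files written by write_fixtures."""
    from Bio import SeqIO

    directory = Path(directory)
    truth_payload = json.loads((directory / "truth.json").read_text())
    config = CladeConfig(**truth_payload["config"])
    phenotypes = truth_payload["phenotypes"]
    genomes = []
    proteomes: dict[str, list[ProteinRecord]] = {}
    for fna in sorted((directory / "genomes").glob("*.fna")):
        gid = fna.stem
        contigs = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fna), "fasta")
        }
        feats = []
        with open(directory / "gff" / f"{gid}.gff3") as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) != 9 or cols[2] != "CDS":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                feats.append(
                    CdsFeature(
                        cols[0], int(cols[3]), int(cols[4]), cols[6],
                        attrs.get("locus_tag", attrs.get("ID", "")),
                    )
                )
        genome = GenomeRecord(
            id=gid, contigs=contigs, cds=feats,
            phenotype=phenotypes.get(gid, "unknown"),
        )
        genomes.append(genome)
        proteomes[gid] = [
            ProteinRecord(rec.id, gid, str(rec.seq))
            for rec in SeqIO.parse(
                str(directory / "proteomes" / f"{gid}.faa"), "fasta"
            )
        ]
    truth = CladeTruth(
        planted_gain_ids=tuple(truth_payload["planted_gain_ids"]),
        planted_loss_ids=tuple(truth_payload["planted_loss_ids"]),
        planted_sites=tuple(
            (f, int(p), a, b) for f, p, a, b in truth_payload["planted_sites"]
        ),
        planted_de=tuple(
            (c, float(l)) for c, l in truth_payload["planted_de"]
        ),
        tree_newick=truth_payload["tree_newick"],
        trait_map=dict(truth_payload["trait_map"]),
    )
    return SyntheticClade(
        config=config, genomes=genomes, proteomes=proteomes, truth=truth
    )


def read_counts(directory) -> CountsTable:
    """Read the counts table and group labels written by write_fixtures."""
    directory = Path(directory)
    counts = pd.read_csv(directory / "counts.tsv", sep="\t", index_col="cluster")
    groups = pd.read_csv(directory / "groups.csv")
    mapping = dict(zip(groups["sample"], groups["group"]))
    return CountsTable(counts, mapping)
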