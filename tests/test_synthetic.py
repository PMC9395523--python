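"""The synthetic-clade generator: determinism, planted structure,
count statistics and file round-trips."""

import numpy as np
import pytest

from cladecompare import (
    CladeConfig,
    DECountsConfig,
    generate_clade,
    generate_counts,
    read_fixtures,
    write_fixtures,
)
from cladecompare.synthetic import SyntheticError, read_counts


def test_same_seed_reproduces_identical_files(tmp_path):
    cfg = CladeConfig(n_group_a=2, n_group_b=2, n_core_families=4,
                      n_exclusive_gains=1, n_exclusive_losses=1,
                      n_diagnostic_families=1, seed=5)
    m1 = write_fixtures(generate_clade(cfg), tmp_path / "run1")
    m2 = write_fixtures(generate_clade(cfg), tmp_path / "run2")
    assert m1 == m2  # same relative paths, same sha256 digests


def test_different_seeds_differ():
    a = generate_clade(CladeConfig(n_group_a=2, n_group_b=2,
                                   n_core_families=4, n_diagnostic_families=1,
                                   n_exclusive_gains=1, n_exclusive_losses=1,
                                   seed=1))
    b = generate_clade(CladeConfig(n_group_a=2, n_group_b=2,
                                   n_core_families=4, n_diagnostic_families=1,
                                   n_exclusive_gains=1, n_exclusive_losses=1,
                                   seed=2))
    assert a.genomes[0].contigs != b.genomes[0].contigs


def test_planted_gains_present_only_in_group_a():
    clade = generate_clade(
        CladeConfig(n_group_a=5, n_group_b=32, n_core_families=6,
                    n_exclusive_gains=7, n_exclusive_losses=2,
                    n_diagnostic_families=0, seed=3)
    )
    assert len(clade.truth.planted_gain_ids) == 7
    for family in clade.truth.planted_gain_ids:
        for gid in clade.genome_ids:
            tags = [p.id for p in clade.proteomes[gid]]
            carried = f"{gid}_{family}" in tags
            assert carried == (clade.groups[gid] == "A")


def test_core_families_have_one_member_everywhere(small_clade):
    for i in range(small_clade.config.n_core_families):
        family = f"fam{i + 1:04d}"
        for gid in small_clade.genome_ids:
            matches = [p for p in small_clade.proteomes[gid]
                       if p.id == f"{gid}_{family}"]
            assert len(matches) == 1


def test_zero_divergence_gives_identical_core_sequences():
    clade = generate_clade(
        CladeConfig(n_group_a=2, n_group_b=3, n_core_families=3,
                    n_exclusive_gains=0, n_exclusive_losses=0,
                    n_diagnostic_families=0, background_divergence=0.0, seed=4)
    )
    for i in range(3):
        family = f"fam{i + 1:04d}"
        seqs = {
            next(p.residues for p in clade.proteomes[gid]
                 if p.id == f"{gid}_{family}")
            for gid in clade.genome_ids
        }
        assert len(seqs) == 1


def test_diagnostic_residues_split_by_group(small_clade):
    for family, pos, res_a, res_b in small_clade.truth.planted_sites:
        for gid in small_clade.genome_ids:
            seq = next(p.residues for p in small_clade.proteomes[gid]
                       if p.id == f"{gid}_{family}")
            expected = res_a if small_clade.groups[gid] == "A" else res_b
            assert seq[pos - 1] == expected


def test_cds_translations_equal_emitted_proteins(small_clade):
    genome = small_clade.genome("B03")
    translated = {f.locus_tag: genome.translate_cds(f) for f in genome.cds}
    for prot in small_clade.proteomes["B03"]:
        assert translated[prot.id] == prot.residues


def test_divergence_out_of_range_rejected():
    with pytest.raises(SyntheticError, match="divergence"):
        CladeConfig(background_divergence=0.5)


def test_counts_poisson_limit_variance_matches_mean():
    clade = generate_clade(CladeConfig(n_group_a=2, n_group_b=2,
                                       n_core_families=1, n_exclusive_gains=0,
                                       n_exclusive_losses=0,
                                       n_diagnostic_families=0, seed=6))
    rng_draws = []
    # 10,000 effective draws: 2500 repetitions of a 1-cluster, 4-sample table
    for seed in range(2500):
        counts = generate_counts(
            clade, DECountsConfig(n_de=0, dispersion=0.0,
                                  mean_expression=1000.0, seed=seed)
        )
        rng_draws.extend(counts.counts.to_numpy().ravel())
    draws = np.asarray(rng_draws, dtype=float)
    ratio = draws.var(ddof=1) / draws.mean()
    assert 0.9 <= ratio <= 1.1  # Poisson: variance == mean


def test_counts_no_de_leaves_truth_empty():
    clade = generate_clade(CladeConfig(n_group_a=2, n_group_b=2,
                                       n_core_families=3, n_exclusive_gains=0,
                                       n_exclusive_losses=0,
                                       n_diagnostic_families=0, seed=7))
    generate_counts(clade, DECountsConfig(n_de=0, seed=1))
    assert clade.truth.planted_de == ()


def test_planted_fold_change_reflected_in_group_means():
    clade = generate_clade(CladeConfig(n_group_a=10, n_group_b=10,
                                       n_core_families=40, n_exclusive_gains=0,
                                       n_exclusive_losses=0,
                                       n_diagnostic_families=0, seed=8))
    counts = generate_counts(
        clade, DECountsConfig(n_de=1, log2fc_magnitude=1.0, dispersion=0.05,
                              mean_expression=500.0, seed=9)
    )
    family, lfc = clade.truth.planted_de[0]
    assert lfc == 1.0
    a_cols = counts.group_samples("A")
    b_cols = counts.group_samples("B")
    row = counts.counts.loc[family]
    ratio = row[b_cols].mean() / row[a_cols].mean()
    assert 1.7 <= ratio <= 2.3


def test_negative_dispersion_rejected():
    with pytest.raises(SyntheticError):
        DECountsConfig(dispersion=-0.1)


def test_fixture_round_trip(tmp_path, small_clade):
    counts = generate_counts(small_clade, DECountsConfig(n_de=2, seed=13))
    write_fixtures(small_clade, tmp_path, counts=counts)
    restored = read_fixtures(tmp_path)
    assert restored == small_clade
    restored_counts = read_counts(tmp_path)
    assert restored_counts.counts.equals(counts.counts)
    assert restored_counts.sample_group == counts.sample_group


def test_overwrite_requires_flag(tmp_path, small_clade):
    write_fixtures(small_clade, tmp_path)
    with pytest.raises(SyntheticError, match="overwrite"):
        write_fixtures(small_clade, tmp_path)
    write_fixtures(small_clade, tmp_path, overwrite=True)


def test_emitted_files_parse_with_standard_validators(tmp_path, small_clade):
    from Bio import SeqIO
    import dendropy

    write_fixtures(small_clade, tmp_path)
    fna = list((tmp_path / "genomes").glob("*.fna"))
    assert fna and all(list(SeqIO.parse(str(p), "fasta")) for p in fna)
    tree = dendropy.Tree.get(path=str(tmp_path / "tree.nwk"), schema="newick")
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    assert labels == set(small_clade.genome_ids)


def test_gff_interval_translation_matches_protein(tmp_path, small_clade):
    """Translate a planted family's GFF interval straight off the genome
    FASTA and compare with the emitted protein."""
    from Bio import SeqIO
    from Bio.Seq import Seq

    write_fixtures(small_clade, tmp_path)
    gid = "A01"
    contigs = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(tmp_path / "genomes" / f"{gid}.fna"), "fasta")
    }
    gain = small_clade.truth.planted_gain_ids[0]
    target = f"{gid}_{gain}"
    with open(tmp_path / "gff" / f"{gid}.gff3") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip().split("\t")
            if target in cols[8]:
                nt = contigs[cols[0]][int(cols[3]) - 1 : int(cols[4])]
                if cols[6] == "-":
                    nt = str(Seq(nt).reverse_complement())
                aa = str(Seq(nt).translate(table=11)).rstrip("*")
                expected = next(
                    p.residues for p in small_clade.proteomes[gid]
                    if p.id == target
                )
                assert aa == expected
                break
        else:
            pytest.fail(f"CDS {target} not found in GFF")


def test_empty_clade_write_rejected(tmp_path, small_clade):
    empty = type(small_clade)(
        config=small_clade.config, genomes=[], proteomes={},
        truth=small_clade.truth,
    )
    with pytest.raises(SyntheticError, match="empty"):
        write_fixtures(empty, tmp_path / "none")
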