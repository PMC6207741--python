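"""Feature statistics, maturase inventory/association, coding identity,
collinear blocks."""

import numpy as np
import pytest

from plastocompare.intron_stats import (coding_identity, collinear_blocks,
                                        compute_stats_row, derived_ratios,
                                        gc_percent,
                                        maturase_intron_association,
                                        maturase_inventory, round_half_away)
from plastocompare.model import (ArchitectureCall, ArchitectureClass, Feature,
                                 FeatureKind, Plastome)
from plastocompare.synthetic_data import SynthSpec, _mutate, generate_plastome

from oracles import brute_force_collinear_blocks

SC = ArchitectureCall(ArchitectureClass.SINGLE_COPY)


def test_rounding_is_half_away_from_zero():
    assert round_half_away(0.485, 2) == 0.49
    assert round_half_away(26.65, 1) == 26.7
    assert round_half_away(0.125, 2) == 0.13  # not banker's 0.12


def test_derived_ratio_arithmetic():
    ipp, pct = derived_ratios(29, 60, 16)
    assert (ipp, pct) == (0.48, 26.7)
    assert derived_ratios(0, 0, 0) == (None, None)


def test_stats_row_matches_generator_truth(small_genome):
    p, truth = small_genome
    row = compute_stats_row(p)
    assert row == truth.stats


def test_stats_row_invariants_hold(small_genome):
    p, _ = small_genome
    row = compute_stats_row(p)
    assert row.introns_per_pcg == round_half_away(row.n_introns / row.n_pcg, 2)
    assert row.pct_pcg_with_introns == round_half_away(
        100 * row.n_pcg_with_introns / row.n_pcg, 1)
    assert row.n_pcg_with_introns <= row.n_pcg


def test_intronless_genome_has_zero_ratios():
    spec = SynthSpec(seed=9, genome_id="flat", n_pcg=6, intron_rate=0.0,
                     ir_copies=1, maturases=())
    p, truth = generate_plastome(spec)
    row = compute_stats_row(p)
    assert row.n_introns == 0
    assert row.introns_per_pcg == 0.0
    assert row.pct_pcg_with_introns == 0.0
    assert row == truth.stats


def test_gc_percent_counts_unambiguous_bases_only():
    assert gc_percent("GGCC") == 100.0
    assert gc_percent("ATGCNN") == 50.0


def test_maturase_inventory_from_gene_names():
    feats = [Feature(FeatureKind.CDS, g, 1, [(i * 1000, i * 1000 + 300)])
             for i, g in enumerate(["mat1", "mat2", "mat5", "psbA"])]
    p = Plastome(id="x", seq="A" * 5000, features=feats)
    assert maturase_inventory(p).present == {"mat1", "mat2", "mat5"}


def test_ycf13_synonym_resolves_to_mat1():
    p = Plastome(id="x", seq="A" * 1000, features=[
        Feature(FeatureKind.CDS, "ycf13", 1, [(0, 300)])])
    inv = maturase_inventory(p)
    assert inv.present == {"mat1"}
    assert inv.count == 1


def test_maturase_inventory_matches_generator_truth(small_genome):
    p, truth = small_genome
    assert maturase_inventory(p).present == truth.maturases.present


def test_monotone_association_is_perfect():
    rho, p = maturase_intron_association([(1, 10), (2, 20), (3, 30)])
    assert rho == pytest.approx(1.0)


def test_all_equal_maturase_counts_are_degenerate():
    with pytest.raises(ValueError, match="equal"):
        maturase_intron_association([(2, 10), (2, 20), (2, 30)])


def test_association_matches_hand_rank_formula():
    """Eight genomes, six tied at 2 maturases: rho equals the tie-aware rank
    formula computed by hand (cov of average ranks / rank sd product)."""
    rows = [(3, 104), (1, 29), (2, 59), (2, 50), (2, 79), (2, 81), (2, 94),
            (2, 95)]
    rho, pval = maturase_intron_association(rows)
    # x average ranks: 1, 8 and six ties at 4.5; y ranks are 1..8.
    # cov = 24.5, var_x = 24.5, var_y = 42 -> rho = 24.5/sqrt(24.5*42)
    assert rho == pytest.approx(24.5 / np.sqrt(24.5 * 42), abs=1e-12)
    assert rho > 0
    assert 0 < pval <= 1


def test_exact_permutation_pvalue_on_tiny_input():
    """n=3 monotone data: 6 permutations, two (identity and full reversal)
    reach |rho| = 1, so the two-sided exact p-value is 1/3."""
    _, p = maturase_intron_association([(1, 5), (2, 7), (3, 9)])
    assert p == pytest.approx(2 / 6)


def test_coding_identity_of_identical_genomes(small_genome):
    p, _ = small_genome
    assert coding_identity(p, p) == 100.0


def test_coding_identity_forced_arithmetic():
    """Single shared 100-nt gene differing at 5 positions, no indels -> 95.0."""
    seq = ("ACGT" * 25)
    mutated = list(seq)
    for i in (3, 17, 31, 59, 83):
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    a = Plastome(id="a", seq=seq,
                 features=[Feature(FeatureKind.CDS, "g", 1, [(0, 100)])])
    b = Plastome(id="b", seq="".join(mutated),
                 features=[Feature(FeatureKind.CDS, "g", 1, [(0, 100)])])
    assert coding_identity(a, b) == 95.0
    assert coding_identity(b, a) == coding_identity(a, b)  # symmetry


def test_coding_identity_near_binomial_expectation():
    """Substitution-only mutation at rate 5% over 20 genes -> ~95%."""
    spec = SynthSpec(seed=21, genome_id="idA", n_pcg=20, intron_rate=0.0,
                     ir_copies=1, maturases=())
    p, _ = generate_plastome(spec)
    rng = np.random.default_rng(77)
    q = Plastome(id="idB", seq=_mutate(p.seq, 0.05, rng), is_circular=True,
                 features=p.features)
    assert coding_identity(p, q) == pytest.approx(95.0, abs=1.0)


def test_no_shared_genes_is_an_error():
    a = Plastome(id="a", seq="A" * 100,
                 features=[Feature(FeatureKind.CDS, "x", 1, [(0, 90)])])
    b = Plastome(id="b", seq="A" * 100,
                 features=[Feature(FeatureKind.CDS, "y", 1, [(0, 90)])])
    with pytest.raises(ValueError, match="share"):
        coding_identity(a, b)


def _signed(names):
    return [(n.lstrip("-"), -1 if n.startswith("-") else 1) for n in names]


def test_identical_orders_are_one_direct_block():
    order = _signed(["a", "b", "c", "d"])
    (block,) = collinear_blocks(order, order)
    assert block.genes == order
    assert block.orientation == 1


def test_full_reversal_is_one_inverted_block():
    order = _signed(["a", "b", "c", "d"])
    rev = [(g, -s) for g, s in reversed(order)]
    (block,) = collinear_blocks(order, rev)
    assert block.genes == order
    assert block.orientation == -1


def test_duplicate_gene_names_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        collinear_blocks(_signed(["a", "a"]), _signed(["a", "b"]))


@pytest.mark.parametrize("seed", range(10))
def test_blocks_match_brute_force_on_random_permutations(seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(20)]
    a = [(g, int(rng.choice([-1, 1]))) for g in genes]
    perm = rng.permutation(20)
    b = [(genes[i], int(rng.choice([-1, 1]))) for i in perm]
    got = [(tuple(blk.genes), blk.orientation) for blk in collinear_blocks(a, b)]
    assert got == brute_force_collinear_blocks(a, b)


def test_blocks_partition_shared_genes_and_reversal_flips_orientation():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(15)]
    a = [(g, 1) for g in genes]
    perm = rng.permutation(15)
    b = [(genes[i], int(rng.choice([-1, 1]))) for i in perm]
    blocks = collinear_blocks(a, b)
    covered = [g for blk in blocks for g, _ in blk.genes]
    assert sorted(covered) == sorted(genes)  # partition, no repeats
    b_rev = [(g, -s) for g, s in reversed(b)]
    flipped = collinear_blocks(a, b_rev)
    assert [(tuple(x.genes), -x.orientation) for x in flipped] == \
        [(tuple(x.genes), x.orientation) for x in blocks]
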