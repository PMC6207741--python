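"""Motif scanning, reference-intron homology and twintron calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastocompare.model import (MotifPattern, ReferenceIntron, TwintronCall,
                                 TwintronCode)
from plastocompare.synthetic_data import _mutate
from plastocompare.twintron import (NH, TwintronConfig, call_twintron,
                                    count_motifs, match_reference_intron,
                                    scan_motif, serialize_call,
                                    table_to_glyphs, build_twintron_table)

from oracles import brute_force_motif_scan


def test_exact_literal_match_at_origin():
    assert scan_motif("ACGTT", MotifPattern("ACGTT", 0)) == [0]


def test_disjoint_base_sets_never_match():
    assert scan_motif("CCCCCC", MotifPattern("AAAA", 0)) == []


def test_pattern_longer_than_sequence_matches_nowhere():
    assert scan_motif("ACG", MotifPattern("ACGTACGT", 0)) == []


def test_iupac_sets_intersect():
    # R={A,G} intersects N and D but not Y={C,T}
    assert scan_motif("AG", MotifPattern("RR", 0)) == [0]
    assert scan_motif("CT", MotifPattern("RR", 0)) == []
    # degenerate symbols in the *sequence* match by intersection too
    assert scan_motif("NN", MotifPattern("AC", 0)) == [0]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(0, 1))
def test_scan_matches_brute_force_sliding_window(seed, mism):
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
    pattern = "YRNAAG"
    got = scan_motif(seq, MotifPattern(pattern, mism))
    assert got == brute_force_motif_scan(seq, pattern, mism)


def test_mismatch_budget_is_monotone():
    """Tightening the mismatch budget can only drop matches."""
    rng = np.random.default_rng(8)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
    hits = [set(scan_motif(seq, MotifPattern("YRNAAG", m))) for m in range(3)]
    assert hits[0] <= hits[1] <= hits[2]


def _ref(seq, id="ref.psbC.i1", gene="psbC", ordinal=1):
    return ReferenceIntron(id=id, gene=gene, ordinal=ordinal, seq=seq)


def test_identical_query_matches_reference():
    rng = np.random.default_rng(1)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    ref = _ref(seq)
    assert match_reference_intron(seq, [ref]) is ref


def test_empty_reference_set_is_nh():
    assert match_reference_intron("ACGT" * 50, []) is NH


def test_divergence_threshold_separates_homologs():
    """20% substitution stays homologous at the default identity threshold;
    50% and 80% substitution do not (their alignment identities fall to
    ~53% and to the ~40% unrelated-sequence floor)."""
    rng = np.random.default_rng(2)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    ref = _ref(seq)
    near = _mutate(seq, 0.20, rng)
    mid = _mutate(seq, 0.50, rng)
    far = _mutate(seq, 0.80, rng)
    assert match_reference_intron(near, [ref]) is ref
    assert match_reference_intron(mid, [ref]) is NH
    assert match_reference_intron(far, [ref]) is NH


def _cfg(**kw):
    base = dict(motif5=MotifPattern("ATGGCGTT", 0),
                motif3=MotifPattern("TTCGACGA", 0),
                min_internal=73, putative_below=88, terminal_exclusion=20)
    base.update(kw)
    return TwintronConfig(**base)


def _construct_external(rng, length, pos5, pos3, cfg):
    """Background free of both motifs, with motifs planted at pos5/pos3."""
    m5, m3 = cfg.motif5.iupac, cfg.motif3.iupac
    while True:
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        if not scan_motif(s, cfg.motif5) and not scan_motif(s, cfg.motif3):
            break
    s = list(s)
    for p in pos5:
        s[p:p + len(m5)] = m5
    for p in pos3:
        s[p:p + len(m3)] = m3
    return "".join(s)


def test_planted_motif_pair_yields_potential_twintron():
    rng = np.random.default_rng(3)
    cfg = _cfg()
    ext = _construct_external(rng, 200, [10], [100], cfg)
    assert count_motifs(ext, cfg) == (1, 1)
    call = call_twintron("tax", ("psbC", 1), ext, [_ref(ext)], cfg)
    assert call.code is TwintronCode.Y
    assert (call.n5, call.n3) == (1, 1)


def test_short_external_intron_downgrades_to_putative():
    rng = np.random.default_rng(4)
    cfg = _cfg(min_internal=40)  # fits inside an 87-nt external intron
    ext = _construct_external(rng, 87, [5], [50], cfg)
    call = call_twintron("tax", ("psbK", 2), ext, [_ref(ext, gene="psbK")], cfg)
    assert call.code is TwintronCode.Y_PUTATIVE


def test_three_prime_motif_in_terminal_window_not_counted():
    """A 3' motif overlapping the final terminal_exclusion nt is the
    external intron's own motif, never internal evidence."""
    rng = np.random.default_rng(5)
    cfg = _cfg()
    ext = _construct_external(rng, 200, [10], [185], cfg)  # 185+8 > 180
    assert count_motifs(ext, cfg) == (0, 0)
    call = call_twintron("tax", ("petB", 1), ext, [_ref(ext, gene="petB")], cfg)
    assert call.code is TwintronCode.N


def test_five_prime_motif_needs_room_for_internal_intron():
    """motif5 too close to the only counted motif3 (implied length <
    min_internal) does not count."""
    rng = np.random.default_rng(6)
    cfg = _cfg()
    ext = _construct_external(rng, 200, [60], [100], cfg)  # implied 48 < 73
    assert count_motifs(ext, cfg) == (0, 1)


def test_no_intron_at_site_is_dash():
    cfg = _cfg()
    call = call_twintron("tax", ("atpE", 1), None, [], cfg)
    assert call.code is TwintronCode.NO_INTRON
    assert serialize_call(call) == "—"


def test_nonhomologous_intron_is_nh():
    rng = np.random.default_rng(7)
    cfg = _cfg()
    ext = _construct_external(rng, 200, [10], [100], cfg)
    other = "".join(np.array(list("ACGT"))[np.random.default_rng(99).integers(0, 4, 200)])
    call = call_twintron("tax", ("psbC", 1), ext, [_ref(other)], cfg,
                         min_identity=95.0)
    assert call.code is TwintronCode.NH
    assert call.matched_reference is None


@pytest.mark.parametrize("call,glyph", [
    (TwintronCall("t", ("petB", 1), TwintronCode.Y, n5=26, n3=4), "Y[26,4]"),
    (TwintronCall("t", ("psbK", 2), TwintronCode.Y_PUTATIVE, n5=1, n3=2), "Y*[1,2]"),
    (TwintronCall("t", ("psbT", 1), TwintronCode.N), "N"),
    (TwintronCall("t", ("psbD", 1), TwintronCode.NH), "NH"),
    (TwintronCall("t", ("atpE", 1), TwintronCode.NO_INTRON), "—"),
])
def test_call_serialization_glyphs(call, glyph):
    assert serialize_call(call) == glyph


def test_call_invariants_enforced():
    with pytest.raises(ValueError):
        TwintronCall("t", ("g", 1), TwintronCode.Y, n5=0, n3=1)
    with pytest.raises(ValueError):
        TwintronCall("t", ("g", 1), TwintronCode.NH, n5=1, n3=1)


def test_table_on_synthetic_cohort_matches_truth(small_spec, small_genome,
                                                 small_refs):
    p, truth = small_genome
    cfg = small_spec.twintron_config()
    sites = [c.site for c in truth.twintron_calls] + [("atpE", 9)]
    table = build_twintron_table([(truth.genome_id, p)], sites, small_refs, cfg)
    for c in truth.twintron_calls:
        got = table.loc[truth.genome_id, f"{c.site[0]}.i{c.site[1]}"]
        assert (got.code, got.n5, got.n3) == (c.code, c.n5, c.n3)
        assert got.matched_reference == c.matched_reference
    assert table.loc[truth.genome_id, "atpE.i9"].code is TwintronCode.NO_INTRON
    glyphs = table_to_glyphs(table)
    assert glyphs.loc[truth.genome_id, "psbC.i1"] == "Y[1,1]"


def test_missing_motif_config_errors(tmp_path):
    bad = tmp_path / "m.yaml"
    bad.write_text("motif5:\n  iupac: ACGT\n")
    with pytest.raises(ValueError, match="motif"):
        TwintronConfig.from_yaml(bad)


def test_config_round_trip_from_yaml(tmp_path):
    f = tmp_path / "m.yaml"
    f.write_text("motif5: {iupac: GTGYG, max_mismatches: 1}\n"
                 "motif3: {iupac: YRNYAG}\n"
                 "min_internal: 70\nputative_below: 90\nterminal_exclusion: 15\n")
    cfg = TwintronConfig.from_yaml(f)
    assert cfg.motif5 == MotifPattern("GTGYG", 1)
    assert cfg.motif3 == MotifPattern("YRNYAG", 0)
    assert (cfg.min_internal, cfg.putative_below, cfg.terminal_exclusion) == \
        (70, 90, 15)
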