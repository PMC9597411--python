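"""Repeat ingest, region merging, local alignment, densities, randomization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trifrac as tf
from trifrac.repeats import REHit, SAIRInterval, merge_regions
from trifrac.sairs import SAIRGroup, SAIRMember

from conftest import sw_oracle


def _hit(sair, a, b, elem="RE01", genome="tom", ev=1e-20):
    return REHit(elem, sair, genome, a, b, 4.0 * (b - a), ev)


# ------------------------------------------------------------------ ingest
BLAST6_ROWS = "\n".join(
    [
        "s1\tRE01\t98.0\t100\t2\t0\t11\t110\t1\t100\t1e-20\t180",
        "s1\tRE02\t90.0\t50\t5\t0\t210\t161\t50\t1\t1e-05\t60",  # minus strand
        "s2\tRE01\t85.0\t40\t6\t1\t5\t44\t1\t40\t1e-04\t35",  # fails cutoff
    ]
)


def test_blast6_cutoff_and_normalisation(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(BLAST6_ROWS + "\n")
    hits = tf.load_hits(p, "blast6", e_cutoff=1e-5, genome="tom")
    assert [h.sair_id for h in hits] == ["s1", "s1"]
    assert (hits[0].start, hits[0].end) == (10, 110)
    # reversed (minus-strand) coordinates are normalised, E = cutoff is kept
    assert (hits[1].start, hits[1].end) == (160, 210)
    assert hits[1].evalue == 1e-5


def test_nhmmer_tblout_dialect(tmp_path):
    lines = [
        "# comment line",
        "s1 - RE03 - 1 80 21 100 15 105 2000 + 1e-09 55.0 2.1 desc",
        "s1 - RE04 - 1 60 300 241 295 235 2000 - 2e-04 20.0 1.0 bad evalue",
    ]
    p = tmp_path / "hits.tbl"
    p.write_text("\n".join(lines) + "\n")
    hits = tf.load_hits(p, "nhmmer", e_cutoff=1e-5, genome="tom")
    assert len(hits) == 1
    assert (hits[0].element_id, hits[0].start, hits[0].end) == ("RE03", 20, 100)


def test_unknown_dialect_rejected(tmp_path):
    p = tmp_path / "x.tsv"
    p.write_text("")
    with pytest.raises(ValueError, match="dialect"):
        tf.load_hits(p, "psl")


# ----------------------------------------------------------------- regions
def test_merge_overlap_rules():
    merged = merge_regions([_hit("s1", 10, 50), _hit("s1", 49, 90, "RE02")])
    assert [(r.start, r.end) for r in merged] == [(10, 90)]
    assert merged[0].elements == ("RE01", "RE02")
    abutting = merge_regions([_hit("s1", 10, 50), _hit("s1", 50, 90)])
    assert [(r.start, r.end) for r in abutting] == [(10, 50), (50, 90)]
    nested = merge_regions([_hit("s1", 10, 90), _hit("s1", 20, 30)])
    assert [(r.start, r.end) for r in nested] == [(10, 90)]


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 300), st.integers(1, 60)), min_size=1, max_size=12
    )
)
def test_merge_idempotent_order_invariant_disjoint(intervals):
    hits = [_hit("s1", a, a + ln) for a, ln in intervals]
    merged = merge_regions(hits)
    # disjoint and sorted
    for r1, r2 in zip(merged, merged[1:]):
        assert r1.end <= r2.start
    # order-invariant
    assert merge_regions(hits[::-1]) == merged
    # idempotent: merging the regions again changes nothing
    again = merge_regions(
        [_hit(r.sair_id, r.start, r.end) for r in merged]
    )
    assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in merged]


# --------------------------------------------------------------- alignment
def test_identical_sequences_score_four_per_base():
    rng = np.random.default_rng(0)
    s = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
    score, length = tf.local_align(s, s)
    assert (score, length) == (320.0, 80)
    s50 = s[:50]
    assert tf.local_align(s50, s50) == (200.0, 50)


def test_alignment_symmetry_and_errors():
    a, b = "ACGTACGTGG", "ACGTTCGTGG"
    assert tf.local_align(a, b)[0] == tf.local_align(b, a)[0]
    with pytest.raises(ValueError, match="empty"):
        tf.local_align("", "ACGT")
    with pytest.raises(ValueError, match="non-ACGTN"):
        tf.local_align("ACGU", "ACGT")


def test_n_scores_as_mismatch():
    score_n, _ = tf.local_align("ACGTNACGT", "ACGTAACGT")
    score_mm, _ = tf.local_align("ACGTCACGT", "ACGTAACGT")
    assert score_n == score_mm


@pytest.mark.parametrize("seed", range(6))
def test_scores_match_dp_oracle_on_100mers(seed):
    rng = np.random.default_rng(seed)
    q = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    t = list(q)
    # mutate and delete to force gapped local alignments
    for pos in rng.integers(0, 90, 8):
        t[pos] = "ACGT"[rng.integers(0, 4)]
    del t[40:43]
    t = "".join(t)
    score, _ = tf.local_align(q, t)
    assert score == pytest.approx(sw_oracle(q, t))


# ------------------------------------------------------------- ancestral calls
def _group(sair_id, genomes, seqs=None, subgenome="LF"):
    members = {
        g: SAIRMember(f"{sair_id}|{g}", 0, 1000, "L", "R",
                      None if seqs is None else seqs[g])
        for g in genomes
    }
    return SAIRGroup(sair_id, subgenome, 0, 1, 0.99, members)


def test_parsimony_requires_all_genomes():
    genomes = ["a", "b", "c", "d"]
    groups = [_group("s1", genomes), _group("s2", genomes)]
    hits = [_hit("s1", 0, 100, "RE01", g) for g in genomes]
    hits += [_hit("s2", 0, 100, "RE02", g) for g in genomes[:3]]  # 3/4 only
    calls = tf.call_ancestral_parsimony(hits, groups)
    assert calls == [("s1", "RE01")]


def test_parsimony_respects_e_cutoff_filtering():
    genomes = ["a", "b", "c", "d"]
    groups = [_group("s1", genomes)]
    hits = [_hit("s1", 0, 100, "RE01", g) for g in genomes[:3]]
    hits.append(_hit("s1", 0, 100, "RE01", "d", ev=1e-3))
    kept = [h for h in hits if h.evalue <= 1e-5]  # load-time rule
    assert tf.call_ancestral_parsimony(kept, groups) == []


def test_ancestral_regions_boundary_conditions():
    rng = np.random.default_rng(3)
    core = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
    pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    seqs = {g: pad + core + pad[::-1] for g in ["a", "b", "c", "d"]}
    groups = [_group("s1", list(seqs), seqs)]
    region = tf.RERegion("s1", 200, 320, ("RE01",))
    assert tf.call_ancestral_regions([region], groups, "a") == [region]
    # one genome divergent beyond recognition -> not ancestral
    seqs2 = dict(seqs)
    seqs2["d"] = "".join("ACGT"[i] for i in rng.integers(0, 4, 520))
    groups2 = [_group("s1", list(seqs2), seqs2)]
    assert tf.call_ancestral_regions([region], groups2, "a") == []
    # 79-base identity fails the >= 80 rule even though the score passes
    short_core = core[:79]
    seqs3 = {g: (pad if g != "d" else pad[::-1]) + core + pad for g in ["a", "b", "c"]}
    seqs3["d"] = "GG" + short_core + "TT"
    groups3 = [_group("s1", list(seqs3), seqs3)]
    region3 = tf.RERegion("s1", 200, 279, ("RE01",))
    assert tf.call_ancestral_regions([region3], groups3, "a", min_score=200) == []


# ----------------------------------------------------------------- density
def _sairs(spec):
    return [SAIRInterval(f"{sub}{i}", sub, ln) for sub, lens in spec.items()
            for i, ln in enumerate(lens)]


def test_density_arithmetic():
    sairs = _sairs({"LF": [600, 400], "IF": [500]})
    hits = [_hit("LF0", 0, 50), _hit("LF1", 0, 50)]
    rep = tf.re_density(hits, sairs)
    assert rep.loc["LF", "density_per_kb"] == pytest.approx(2.0)
    assert rep.loc["IF", "density_per_kb"] == 0.0
    assert rep.loc["LF", "length_bp"] == 1000


def test_density_pooling_is_length_weighted_mean():
    sairs = _sairs({"LF": [800], "IF": [200]})
    hits = [_hit("LF0", 0, 50), _hit("IF0", 0, 20), _hit("IF0", 30, 60)]
    rep = tf.re_density(hits, sairs)
    pooled = [SAIRInterval(s.sair_id, "ALL", s.length) for s in sairs]
    rep_all = tf.re_density(hits, pooled)
    expected = (
        rep.loc["LF", "density_per_kb"] * 0.8 + rep.loc["IF", "density_per_kb"] * 0.2
    )
    assert rep_all.loc["ALL", "density_per_kb"] == pytest.approx(expected)


def test_zero_length_density_is_an_error():
    with pytest.raises(ValueError, match="zero total"):
        tf.re_density([], [SAIRInterval("x", "LF", 0)])


# ----------------------------------------------------------- randomization
def test_symmetric_null_gives_large_p():
    sairs = _sairs({"LF": [1000] * 10, "IF": [1000] * 10})
    hits = [_hit(f"LF{i}", 0, 100) for i in range(3)]
    hits += [_hit(f"IF{i}", 0, 100) for i in range(3)]
    r = tf.randomization_test(hits, sairs, ("LF", "IF"), replicates=500, seed=1)
    assert r.observed_diff == pytest.approx(0.0)
    assert r.p_value > 0.5


def test_two_sair_exact_enumeration():
    """One hit, two equal SAIRs: the null difference is +/-d with
    probability 1/2 each, so the two-sided p is ~1."""
    sairs = [SAIRInterval("a", "LF", 1000), SAIRInterval("b", "IF", 1000)]
    hits = [_hit("a", 0, 100)]
    r = tf.randomization_test(hits, sairs, ("LF", "IF"), replicates=10_000, seed=3)
    assert abs(r.observed_diff) == pytest.approx(1.0)  # 1 hit per kB vs 0
    # exceedances ~ Binomial(10^4, 1.0 since |null|=|obs| always)
    assert r.p_value == 1.0
    one_sided = tf.randomization_test(
        hits, sairs, ("LF", "IF"), replicates=10_000, seed=3, alternative="greater"
    )
    # null >= obs happens when the hit lands in LF: p ~ 1/2 within 3 sigma
    se = 3 * 0.5 / np.sqrt(10_000)
    assert abs(one_sided.p_value - 0.5) < se + 1e-3


def test_determinism_and_error_paths():
    sairs = _sairs({"LF": [1000] * 5, "IF": [800] * 5})
    hits = [_hit("LF0", 0, 100), _hit("IF1", 0, 50)]
    r1 = tf.randomization_test(hits, sairs, ("LF", "IF"), replicates=300, seed=9)
    r2 = tf.randomization_test(hits, sairs, ("LF", "IF"), replicates=300, seed=9)
    assert r1.p_value == r2.p_value and r1.exceedances == r2.exceedances
    many = [_hit(f"LF{i % 5}", 0, 10, f"E{i}") for i in range(11)]
    with pytest.raises(ValueError, match="without reuse"):
        tf.randomization_test(many, sairs, ("LF", "IF"), replicates=10, seed=0)
    with pytest.raises(ValueError, match="alternative"):
        tf.randomization_test(hits, sairs, ("LF", "IF"), replicates=10, seed=0,
                              alternative="both")
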