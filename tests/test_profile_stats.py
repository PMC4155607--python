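import numpy as np
import pytest

from helpers import (
    enumerate_threads,
    random_grouped_alignment,
    rescan_joint,
    rescan_motif,
    rescan_profile,
)
from seqbundles import (
    Alignment,
    AlignmentError,
    GroupSummary,
    assign_groups,
    bridge_counts,
    consensus,
    detect_threads,
    motif_match_count,
    position_profile,
    select_by_residue,
    single_group,
    summarize_groups,
)


# ------------------------------------------------------------- profiles --

def test_profile_counts_with_gap():
    ga = single_group(Alignment(("a", "b", "c"), ("AC", "AC", "A-")))
    prof = position_profile(ga, None, 2)
    assert prof.counts == {"C": 2, "-": 1}
    assert prof.depth == 3


def test_profile_single_row():
    ga = single_group(Alignment(("a",), ("AK",)))
    assert position_profile(ga, None, 1).counts == {"A": 1}


def test_profile_bad_column():
    ga = single_group(Alignment(("a",), ("AK",)))
    with pytest.raises(AlignmentError, match="column"):
        position_profile(ga, None, 3)


def test_profile_respects_groups(two_group_alignment):
    assert position_profile(two_group_alignment, "pos", 1).counts == {"A": 3}
    assert position_profile(two_group_alignment, "neg", 1).counts == {"G": 2}
    assert position_profile(two_group_alignment, None, 1).depth == 5


# ------------------------------------------------------------ consensus --

def test_consensus_beats_gaps():
    ga = single_group(Alignment(("a", "b", "c"), ("PPKK", "PPK-", "PP-K")))
    assert consensus(ga) == "PPKK"


def test_consensus_identity():
    ga = single_group(Alignment(("a", "b"), ("ACDK", "ACDK")))
    assert consensus(ga) == "ACDK"


def test_consensus_alphabetical_tie_break():
    ga = single_group(Alignment(("a", "b"), ("A", "C")))
    assert consensus(ga) == "A"


def test_consensus_gap_loses_ties_without_scale():
    ga = single_group(Alignment(("a", "b"), ("A", "-")))
    assert consensus(ga) == "A"


def test_consensus_gap_can_win_majority():
    ga = single_group(Alignment(("a", "b", "c"), ("A-", "C-", "C-")))
    assert consensus(ga) == "C-"


# -------------------------------------------------------------- summary --

@pytest.mark.parametrize(
    "sizes,total,per100",
    [
        ((923, 886), 1809, (100, 96)),
        ((10, 10), 20, (100, 100)),
        ((200, 50, 100), 350, (100, 25, 50)),
    ],
)
def test_summarize_groups_arithmetic(sizes, total, per100):
    s = GroupSummary(tuple(f"g{i}" for i in range(len(sizes))), sizes)
    assert s.total == total
    assert s.per_100_of_largest == per100


def test_ratio_string_largest_first():
    s = GroupSummary(("neg", "pos"), (923, 886))
    assert s.ratio_string == "100:96"


def test_summarize_groups_from_alignment(two_group_alignment):
    s = summarize_groups(two_group_alignment)
    assert s.sizes == (3, 2)
    assert s.total == 5
    assert s.per_100_of_largest == (100, 67)


# ------------------------------------------------------------ selection --

def test_select_identical_members():
    rows = ("ANKK", "ANKK", "ANKK", "AGKK", "ACKK")
    ga = single_group(Alignment(tuple("abcde"), rows))
    rep = select_by_residue(ga, None, 2, "N")
    assert rep.size == 3
    assert rep.identical_count == 3
    assert rep.variable_positions == ()
    assert rep.modal_sequence == "ANKK"


def test_select_reports_variable_positions():
    rows = ("ANKK", "ANKA", "ANKK", "CNKK")
    ga = single_group(Alignment(tuple("abcd"), rows))
    rep = select_by_residue(ga, None, 2, "N")
    assert rep.size == 4
    assert rep.modal_sequence == "ANKK"  # ties go to earliest in MSA order
    assert rep.identical_count == 2
    assert rep.variable_positions == (1, 4)


def test_select_absent_residue_gives_empty_report():
    ga = single_group(Alignment(("a", "b"), ("AK", "AK")))
    rep = select_by_residue(ga, None, 1, "W")
    assert rep.size == 0
    assert rep.identical_count == 0
    assert rep.variable_positions == ()


def test_select_size_matches_profile_count():
    rng = np.random.default_rng(7)
    for _ in range(20):
        ga = random_grouped_alignment(rng)
        for label in (*ga.labels, None):
            p = int(rng.integers(1, ga.alignment.n_cols + 1))
            prof = position_profile(ga, label, p)
            for sym, n in prof.counts.items():
                assert select_by_residue(ga, label, p, sym).size == n


# ---------------------------------------------------------------- motif --

def test_motif_exact_window_match():
    ga = single_group(Alignment(tuple("abc"), ("PPKK", "PPKA", "PPAK")))
    assert motif_match_count(ga, None, 1, "PPKK") == 1
    assert motif_match_count(ga, None, 1, "PP") == 3


def test_motif_full_length_counts_duplicates():
    ga = single_group(Alignment(tuple("abc"), ("PPKK", "PPKK", "PAKK")))
    assert motif_match_count(ga, None, 1, "PPKK") == 2


def test_motif_gap_literal():
    ga = single_group(Alignment(("a", "b"), ("P-K", "PKK")))
    assert motif_match_count(ga, None, 1, "P-K") == 1


def test_motif_bad_symbol():
    ga = single_group(Alignment(("a",), ("PK",)))
    with pytest.raises(AlignmentError, match="outside alphabet"):
        motif_match_count(ga, None, 1, "P1")


def test_motif_length_one_equals_profile_count():
    rng = np.random.default_rng(11)
    for _ in range(20):
        ga = random_grouped_alignment(rng)
        p = int(rng.integers(1, ga.alignment.n_cols + 1))
        prof = position_profile(ga, None, p)
        for sym, n in prof.counts.items():
            assert motif_match_count(ga, None, p, sym) == n


# -------------------------------------------------------------- bridges --

def test_bridge_xor_miniature():
    """The Feature-3 structure in miniature: both residues common in
    their own columns, the (K, K) bridge absent."""
    ga = single_group(Alignment(tuple("abc"), ("KA", "AK", "KA")))
    t = bridge_counts(ga, None, 1)
    assert t.joint == {("K", "A"): 2, ("A", "K"): 1}
    assert t.count("K", "K") == 0


def test_bridge_conserved_pair_single_cell():
    ga = single_group(Alignment(tuple("abc"), ("PP", "PP", "PP")))
    t = bridge_counts(ga, None, 1)
    assert t.joint == {("P", "P"): 3}


def test_bridge_marginals_reconcile_with_profiles():
    rng = np.random.default_rng(23)
    for _ in range(30):
        ga = random_grouped_alignment(rng)
        for label in (*ga.labels, None):
            for p in range(1, ga.alignment.n_cols):
                t = bridge_counts(ga, label, p)
                assert t.marginal_left() == position_profile(ga, label, p).counts
                assert t.marginal_right() == position_profile(ga, label, p + 1).counts
                assert sum(t.joint.values()) == t.depth


# -------------------------------------------------------------- threads --

def _conserved_ga(n_rows=8):
    return single_group(
        Alignment(tuple(f"s{i}" for i in range(n_rows)),
                  ("ACDKA",) * n_rows)
    )


def test_threads_fully_conserved_single_thread():
    ts = detect_threads(_conserved_ga(), None, (1, 5), k=2, min_support=0.5)
    assert len(ts.threads) == 1
    assert ts.threads[0].residues == "ACDKA"
    assert ts.threads[0].support == (8, 8, 8, 8)
    assert not ts.bifurcation


def test_threads_k1_is_argmax_path():
    rng = np.random.default_rng(3)
    for _ in range(15):
        ga = random_grouped_alignment(rng)
        n = ga.alignment.n_cols
        ts = detect_threads(ga, None, (1, n), k=1, min_support=0.01)
        assert len(ts.threads) <= 1
        if ts.threads:
            argmax = "".join(
                min(
                    position_profile(ga, None, p).counts.items(),
                    key=lambda kv: (-kv[1], kv[0]),
                )[0]
                for p in range(1, n + 1)
            )
            assert ts.threads[0].residues == argmax


def test_threads_match_exhaustive_enumeration():
    """The three-phase DP extraction equals brute-force path enumeration
    (bottleneck, then total weight, then lexicographic) on small trellises."""
    rng = np.random.default_rng(42)
    for _ in range(40):
        ga = random_grouped_alignment(rng, max_rows=15, max_cols=6)
        n = ga.alignment.n_cols
        k = int(rng.integers(1, 4))
        ms = float(rng.uniform(0.1, 0.6))
        ts = detect_threads(ga, None, (1, n), k=k, min_support=ms)
        expected = enumerate_threads(ga, None, (1, n), k, ms)
        got = [(t.residues, t.support) for t in ts.threads]
        assert got == expected


def test_threads_single_column_interval():
    ga = single_group(Alignment(tuple("abcd"), ("A", "A", "C", "G")))
    ts = detect_threads(ga, None, (1, 1), k=2, min_support=0.25)
    assert [(t.residues, t.support) for t in ts.threads] == [
        ("A", (2,)), ("C", (1,)),
    ]
    assert not ts.bifurcation


def test_threads_bad_interval():
    ga = _conserved_ga()
    with pytest.raises(AlignmentError):
        detect_threads(ga, None, (1, 9))
    with pytest.raises(AlignmentError):
        detect_threads(ga, None, (1, 3), k=0)
    with pytest.raises(AlignmentError):
        detect_threads(ga, None, (1, 3), min_support=0.0)


def test_planted_bifurcation_small():
    """40/40/20 split between two motifs and an alternating pattern: both
    motifs come back as threads, the chimeric consensus has strictly lower
    minimum bridge support, and the bifurcation is flagged."""
    from seqbundles import Bifurcation, FixtureSpec, GroupFixture, generate

    spec = FixtureSpec(
        groups=(
            GroupFixture(
                "g", "#000000", 50,
                (Bifurcation((2, 6), "KVEGI", "AKADV", 0.4, 0.4),),
            ),
        ),
        n_cols=8,
        seed=5,
    )
    ga, manifest = generate(spec)
    feat = manifest["groups"]["g"]["features"][0]
    ts = detect_threads(ga, "g", (2, 6), k=2, min_support=0.25)
    names = {t.residues for t in ts.threads}
    assert names == {"KVEGI", "AKADV"}
    assert ts.consensus == feat["expected_consensus"]
    assert ts.bifurcation
    for t in ts.threads:
        assert t.bottleneck > min(ts.consensus_support)
        assert t.bottleneck in (feat["n_a"], feat["n_b"])


def test_oracle_profile_rescans():
    rng = np.random.default_rng(99)
    for _ in range(25):
        ga = random_grouped_alignment(rng)
        p = int(rng.integers(1, ga.alignment.n_cols + 1))
        assert position_profile(ga, None, p).counts == rescan_profile(ga, None, p)
        if p < ga.alignment.n_cols:
            assert bridge_counts(ga, None, p).joint == rescan_joint(ga, None, p)
        motif = ga.alignment.rows[0][p - 1 :]
        assert motif_match_count(ga, None, p, motif) == rescan_motif(
            ga, None, p, motif
        )
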