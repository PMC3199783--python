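"""Chromosome assignment, block segmentation, colinearity, correspondence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cucsyn.synteny import (AMBIGUOUS, ASSIGNED, COLINEAR, DIRECT, INVERTED,
                            REARRANGED, TRANSITIVE, UNANCHORED, UNDETERMINED,
                            AnchoredMarker, ReferenceMap, assign_chromosome,
                            block_views, colinearity, correspondence_table,
                            detect_blocks, partner_sets)
from cucsyn.vpcr import ScaffoldHit


def refmap(rows):
    return ReferenceMap(pd.DataFrame(
        rows, columns=["marker_id", "chromosome", "position_cM", "scaffold"]))


def hit(scaffold="s1"):
    return [ScaffoldHit("m", "draft", scaffold, 100, 300, "+", 201)]


REF = refmap([
    ("q1", "5", 31.2, "s9"),
    ("r1", "5", 30.0, "s1"), ("r2", "5", 31.0, "s1"), ("r3", "5", 40.0, "s1"),
    ("r4", "2", 10.0, "s2"), ("r5", "6", 50.0, "s2"),
])


def test_direct_assignment_takes_reference_position():
    a = assign_chromosome("q1", "I", 12.0, "unique", hit("s7"), REF)
    assert (a.status, a.evidence) == (ASSIGNED, DIRECT)
    assert (a.target_chromosome, a.target_cM) == ("5", 31.2)


def test_transitive_assignment_uses_majority_and_median():
    a = assign_chromosome("q2", "I", 12.0, "unique", hit("s1"), REF)
    assert (a.status, a.evidence) == (ASSIGNED, TRANSITIVE)
    assert a.target_chromosome == "5"
    assert a.target_cM == 31.0  # median of {30.0, 31.0, 40.0}


def test_split_scaffold_is_ambiguous():
    a = assign_chromosome("q2", "I", 12.0, "unique", hit("s2"), REF)
    assert a.status == AMBIGUOUS


def test_empty_scaffold_and_bad_classes_are_unanchored():
    a = assign_chromosome("q2", "I", 12.0, "unique", hit("s99"), REF)
    assert (a.status, a.reason) == (UNANCHORED, "scaffold without mapped markers")
    for cls in ("no_hit", "multi_copy", "repeat_region"):
        a = assign_chromosome("q2", "I", 12.0, cls, [], REF)
        assert (a.status, a.reason) == (UNANCHORED, cls)


def test_two_thirds_majority_assigns():
    rm = refmap([("r1", "5", 10.0, "sx"), ("r2", "5", 20.0, "sx"),
                 ("r3", "2", 30.0, "sx")])
    a = assign_chromosome("q", "I", 1.0, "unique", hit("sx"), rm)
    assert a.status == ASSIGNED and a.target_chromosome == "5"


# ---------------------------------------------------------------------------
# block segmentation
# ---------------------------------------------------------------------------

def anchored_from_targets(targets, source="I"):
    out = []
    for i, t in enumerate(targets):
        if t is None:
            out.append(AnchoredMarker(f"m{i:02d}", source, float(i), UNANCHORED))
        else:
            out.append(AnchoredMarker(f"m{i:02d}", source, float(i), ASSIGNED,
                                      str(t), float(i), TRANSITIVE))
    return out


def segmentation(targets, min_block=2, max_gap=1):
    blocks, singles = detect_blocks(anchored_from_targets(targets),
                                    min_block, max_gap)
    runs = []
    for b in blocks:
        runs.append((b.target_chromosome, b.n_markers, len(b.discordant)))
    return runs, [s.target_chromosome for s in singles]


@pytest.mark.parametrize(
    "targets, max_gap, expected_runs",
    [
        ([5, 5, 5, 5], 1, [("5", 4, 0)]),
        ([2, 2, 2, 6, 6, 2, 2], 0, [("2", 3, 0), ("6", 2, 0), ("2", 2, 0)]),
        ([2, 2, 6, 2, 2], 1, [("2", 4, 1)]),  # one absorbed discordant
    ],
)
def test_block_segmentation_examples(targets, max_gap, expected_runs):
    runs, _ = segmentation(targets, max_gap=max_gap)
    assert runs == expected_runs


def test_unanchored_loci_are_transparent():
    runs, singles = segmentation([5, None, 5, None, None, 5], max_gap=0)
    assert runs == [("5", 3, 0)]
    assert singles == []


def test_short_runs_become_singletons():
    runs, singles = segmentation([5, 2, 2, 2], max_gap=0)
    assert runs == [("2", 3, 0)]
    assert singles == ["5"]


def oracle_segmentation(targets, max_gap):
    """Exhaustive enumeration of every partition into valid runs.

    A valid run starts and ends on its own target and holds at most max_gap
    interior discordant loci.  Among partitions with the minimal number of
    runs, the lexicographically longest-first one wins.
    """
    n = len(targets)

    def valid(i, j):
        t = targets[i]
        if targets[j] != t:
            return False
        return sum(1 for k in range(i, j + 1) if targets[k] != t) <= max_gap

    best_key, best_segs = None, None
    for bits in range(2 ** max(n - 1, 0)):
        cuts = [0] + [k + 1 for k in range(n - 1) if bits >> k & 1] + [n]
        spans = list(zip(cuts, cuts[1:]))
        if all(valid(i, j - 1) for i, j in spans):
            segs = [(targets[i], j - i) for i, j in spans]
            key = (len(segs), tuple(-(j - i) for i, j in spans))
            if best_key is None or key < best_key:
                best_key, best_segs = key, segs
    return best_segs


@pytest.mark.parametrize("max_gap", [0, 1])
def test_segmentation_matches_dp_oracle_exhaustively(max_gap):
    """Every target string of length <= 8 over two targets, both gap settings."""
    for n in range(1, 9):
        for targets in itertools.product([2, 6], repeat=n):
            blocks, singles = detect_blocks(anchored_from_targets(list(targets)),
                                            min_block_markers=1,
                                            max_gap_markers=max_gap)
            got = [(int(b.target_chromosome), b.n_markers + len(b.discordant))
                   for b in blocks]
            exp = oracle_segmentation(list(targets), max_gap)
            assert got == exp, (targets, max_gap)


def test_segmentation_oracle_three_targets():
    for n in range(1, 7):
        for targets in itertools.product([1, 2, 3], repeat=n):
            blocks, _ = detect_blocks(anchored_from_targets(list(targets)),
                                      min_block_markers=1, max_gap_markers=1)
            got = [(int(b.target_chromosome), b.n_markers + len(b.discordant))
                   for b in blocks]
            assert got == oracle_segmentation(list(targets), 1), targets


def test_discordants_never_exceed_gap_budget(rng):
    for _ in range(50):
        targets = rng.integers(1, 4, size=int(rng.integers(1, 30))).tolist()
        gap = int(rng.integers(0, 3))
        blocks, _ = detect_blocks(anchored_from_targets(targets),
                                  min_block_markers=1, max_gap_markers=gap)
        for b in blocks:
            assert len(b.discordant) <= gap
            assert all(m.target_chromosome == b.target_chromosome
                       for m in b.members)


# ---------------------------------------------------------------------------
# colinearity
# ---------------------------------------------------------------------------

def test_monotone_pairs_are_colinear_or_inverted():
    up = [(float(i), float(10 + i)) for i in range(6)]
    tau, cls = colinearity(up)
    assert tau == pytest.approx(1.0) and cls == COLINEAR
    down = [(float(i), float(10 - i)) for i in range(6)]
    tau, cls = colinearity(down)
    assert tau == pytest.approx(-1.0) and cls == INVERTED


def test_tau_matches_pair_counting_oracle(rng):
    for _ in range(20):
        src = rng.uniform(0, 100, 6)
        tgt = rng.uniform(0, 100, 6)
        tau, _ = colinearity(list(zip(src, tgt)))
        conc = disc = 0
        for i in range(6):
            for j in range(i + 1, 6):
                s = np.sign((src[i] - src[j]) * (tgt[i] - tgt[j]))
                conc += s > 0
                disc += s < 0
        assert tau == pytest.approx((conc - disc) / 15, abs=1e-12)


def test_too_few_members_is_undetermined():
    tau, cls = colinearity([(0.0, 1.0), (1.0, 2.0)])
    assert tau is None and cls == UNDETERMINED


def test_shuffled_pairs_are_rearranged():
    pairs = [(0, 5.0), (1, 1.0), (2, 4.0), (3, 0.0), (4, 3.0), (5, 2.0)]
    tau, cls = colinearity(pairs)
    assert cls == REARRANGED


# ---------------------------------------------------------------------------
# correspondence and views
# ---------------------------------------------------------------------------

def make_block(source, target, start, end, n):
    from cucsyn.synteny import SyntenicBlock
    members = [AnchoredMarker(f"{source}{target}{i}", source,
                              start + i * (end - start) / max(n - 1, 1),
                              ASSIGNED, target,
                              start + i * (end - start) / max(n - 1, 1),
                              TRANSITIVE)
               for i in range(n)]
    return SyntenicBlock(source, target, start, end, members)


def test_correspondence_from_planted_pattern():
    blocks = [
        make_block("I", "7", 0, 100, 10),
        make_block("V", "2", 0, 50, 5),
        make_block("XI", "2", 0, 40, 4), make_block("XI", "6", 45, 80, 4),
        make_block("III", "2", 0, 40, 4), make_block("III", "6", 45, 80, 4),
    ]
    sets = partner_sets(blocks, "source->target")
    assert sets["I"] == {"7"}
    rev = partner_sets(blocks, "target->source")
    assert rev["2"] == {"III", "V", "XI"}
    table = correspondence_table(blocks)
    row = table[(table["direction"] == "target->source")
                & (table["chromosome"] == "2")].iloc[0]
    assert row["partners"] == "III,V,XI"


def test_correspondence_is_symmetric():
    blocks = [make_block("I", "7", 0, 100, 5), make_block("II", "1", 0, 50, 5),
              make_block("XII", "1", 0, 60, 3)]
    fwd = partner_sets(blocks, "source->target")
    rev = partner_sets(blocks, "target->source")
    for s, ts in fwd.items():
        for t in ts:
            assert s in rev[t]


def test_empty_blocks_give_empty_table():
    assert len(correspondence_table([])) == 0


def test_block_views_segment_patterns():
    # intact chromosome: one segment; alternating: 4 segments of 2 colors;
    # nested: target view shows VII, VIII, VII
    blocks = [
        make_block("I", "7", 0, 100, 10),
        make_block("II", "1", 0, 25, 4), make_block("XII", "1", 30, 50, 4),
        make_block("II", "1", 55, 75, 4), make_block("XII", "1", 80, 100, 4),
        make_block("VII", "4", 0, 40, 5), make_block("VIII", "4", 45, 60, 3),
        make_block("VII", "4", 65, 100, 5),
    ]
    # target positions must interleave for the target-view ordering
    for i, b in enumerate(blocks[1:5]):
        for m in b.members:
            m.target_cM = i * 25 + (m.source_cM % 25)
    for i, b in enumerate(blocks[5:]):
        for m in b.members:
            m.target_cM = i * 35 + (m.source_cM % 35)
    views = block_views(blocks)
    src_i = views[(views["view"] == "source") & (views["chromosome"] == "I")]
    assert len(src_i) == 1
    tgt_1 = views[(views["view"] == "target") & (views["chromosome"] == "1")]
    assert len(tgt_1) >= 3
    assert set(tgt_1["partner"]) == {"II", "XII"}
    tgt_4 = views[(views["view"] == "target") & (views["chromosome"] == "4")]
    assert list(tgt_4["partner"]) == ["VII", "VIII", "VII"]
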