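"""Palindromicity, category calls, and the antirepeat array assignment."""

from types import SimpleNamespace

import numpy as np
import pytest

from rnascout import classify as C
from rnascout.homology import ScoringParams
from rnascout.io_formats import CrisprArray, GeneAnnotation, Interval, revcomp
from rnascout.region_prep import Region

BASES = "ACGT"


def rand_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# Palindromicity
# ---------------------------------------------------------------------------


def test_perfect_palindrome_scores_one():
    assert C.palindromicity("GGGGCCCC") == pytest.approx(1.0)


def test_homopolymer_scores_zero():
    assert C.palindromicity("AAAAAAAA") == pytest.approx(0.0)


def test_palindromicity_undefined_below_eight():
    with pytest.raises(ValueError):
        C.palindromicity("GGGCCC")


def _oracle_semiglobal(a, b, params):
    """Independent recursion maximizing (score, matches) lexicographically.

    Overlap-alignment semantics: the alignment starts on a boundary of the
    dynamic-programming table (free leading gaps on one sequence) and ends
    when either sequence is exhausted (free trailing gaps).
    """
    from functools import lru_cache

    go_, ge = params.gap_open, params.gap_extend

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        # state: 1 = aligned, 2 = gap-in-a open, 3 = gap-in-b open
        if i == len(a) or j == len(b):
            return (0, 0)
        m = a[i] == b[j]
        s = params.match if m else params.mismatch
        nxt = rec(i + 1, j + 1, 1)
        opts = [(s + nxt[0], (1 if m else 0) + nxt[1])]
        cost = ge if state == 2 else go_ + ge
        nxt = rec(i, j + 1, 2)
        opts.append((cost + nxt[0], nxt[1]))
        cost = ge if state == 3 else go_ + ge
        nxt = rec(i + 1, j, 3)
        opts.append((cost + nxt[0], nxt[1]))
        return max(opts)

    starts = [rec(i0, 0, 1) for i0 in range(len(a) + 1)]
    starts += [rec(0, j0, 1) for j0 in range(len(b) + 1)]
    return max(starts)


def test_palindromicity_matches_exhaustive_oracle(rng):
    params = ScoringParams()
    for _ in range(8):
        seq = rand_seq(rng, int(rng.integers(10, 26)))
        _, matches = _oracle_semiglobal(seq, revcomp(seq), params)
        assert C.palindromicity(seq, params) == pytest.approx(matches / len(seq))


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------


def _cand(cid, intervals):
    instances = [
        SimpleNamespace(genome=iv, region_id=f"r_{iv.contig_id}") for iv in intervals
    ]
    return SimpleNamespace(
        candidate_id=cid,
        instances=instances,
        palindromicity=0.2,
        model=SimpleNamespace(consensus="ACGTACGTACGT"),
    )


@pytest.fixture
def annotation():
    genes = [
        GeneAnnotation(Interval("c1", 2000, 3400, "+", "cas9"), "cas9", "op0", "II-C"),
        GeneAnnotation(Interval("c1", 3500, 4400, "+", "cas1"), "cas1", "op0", "II-C"),
    ]
    arrays = [
        CrisprArray(
            "arr0",
            (Interval("c1", 5000, 5035), Interval("c1", 5070, 5105)),
            (Interval("c1", 5035, 5070),),
            "G" * 35,
            "II-C",
            0.9,
        )
    ]
    return genes, arrays


def test_repeat_overlap_dominates(annotation):
    genes, arrays = annotation
    cand = _cand("x", [Interval("c1", 5000, 5035), Interval("c1", 5070, 5105)])
    call = C.categorize(cand, genes, arrays, tracr_candidate_ids={"x"})
    assert call.category == "direct_repeat"
    assert call.frac_repeat == 1.0


def test_upstream_of_cas9_with_antirepeat_is_tracr_like(annotation):
    genes, arrays = annotation
    cand = _cand("x", [Interval("c1", 1910, 1990), Interval("c1", 1905, 1985)])
    call = C.categorize(cand, genes, arrays, tracr_candidate_ids={"x"})
    assert call.category == "tracrRNA_like"
    # without the antirepeat link the same positions are intergenic
    call2 = C.categorize(cand, genes, arrays, tracr_candidate_ids=set())
    assert call2.category == "intergenic"


def test_gene_overlap_and_intergenic_fallthrough(annotation):
    genes, arrays = annotation
    inside = _cand("x", [Interval("c1", 2500, 2560), Interval("c1", 3600, 3660)])
    call = C.categorize(inside, genes, arrays, tracr_candidate_ids=set())
    assert call.category == "coding_overlap"
    assert call.frac_gene == 1.0
    assert call.mean_relative_position is not None
    nowhere = _cand("x", [Interval("c1", 9000, 9060)])
    assert (
        C.categorize(nowhere, genes, arrays, tracr_candidate_ids=set()).category
        == "intergenic"
    )


def test_relative_position_strand_aware():
    gene_fwd = [GeneAnnotation(Interval("c1", 1000, 2000, "+", "cas3"), "cas3", "op0", "I-E")]
    gene_rev = [GeneAnnotation(Interval("c1", 1000, 2000, "-", "cas3"), "cas3", "op0", "I-E")]
    cand = _cand("x", [Interval("c1", 1800, 1860)])
    fwd = C.categorize(cand, gene_fwd, [], set())
    rev = C.categorize(cand, gene_rev, [], set())
    assert fwd.mean_relative_position == pytest.approx(0.83)
    assert rev.mean_relative_position == pytest.approx(1 - 0.83)


# ---------------------------------------------------------------------------
# Antirepeat assignment
# ---------------------------------------------------------------------------


def test_no_candidates_no_assignments(annotation, rng):
    genes, arrays = annotation
    regions = [Region("r0", Interval("c1", 0, 2000, "+", "r0"), rand_seq(rng, 2000))]
    assignments, summary = C.antirepeat_assign(arrays, [], regions, {})
    assert assignments == []
    assert summary["n_arrays_assigned"] == 0


def test_self_matches_excluded(rng):
    """A repeat hit landing inside its own array never yields an assignment."""
    repeat = rand_seq(rng, 35)
    spacer = rand_seq(rng, 35)
    bg = rand_seq(rng, 3000)
    array_start = 1000
    seq = bg[:array_start] + repeat + spacer + repeat + bg[array_start + 105 :]
    arrays = [
        CrisprArray(
            "arr0",
            (
                Interval("c1", array_start, array_start + 35),
                Interval("c1", array_start + 70, array_start + 105),
            ),
            (Interval("c1", array_start + 35, array_start + 70),),
            repeat,
            "II-C",
            0.9,
        )
    ]
    regions = [Region("r0", Interval("c1", 0, len(seq), "+", "r0"), seq)]
    # a candidate covering the array itself: any hit there is a self match
    cand = SimpleNamespace(
        candidate_id="x",
        instances=[
            SimpleNamespace(
                genome=Interval("c1", array_start, array_start + 35), region_id="r0"
            )
        ],
    )
    assignments, _ = C.antirepeat_assign(arrays, [cand], regions, {})
    assert assignments == []


def test_assignment_requires_significant_nonself_hit(rng):
    """A planted antirepeat outside the array links the array to the candidate."""
    repeat = rand_seq(rng, 35)
    bg = rand_seq(rng, 4000)
    anti = revcomp(repeat)
    seq = bg[:500] + anti + bg[535:1000] + repeat + rand_seq(rng, 35) + repeat + bg[1070 + 35 :]
    arrays = [
        CrisprArray(
            "arr0",
            (Interval("c1", 1000, 1035), Interval("c1", 1070, 1105)),
            (Interval("c1", 1035, 1070),),
            repeat,
            "II-C",
            0.9,
        )
    ]
    regions = [Region("r0", Interval("c1", 0, len(seq), "+", "r0"), seq)]
    region_for = {"op0": "II-C"}
    cand = SimpleNamespace(
        candidate_id="tracr_like",
        instances=[SimpleNamespace(genome=Interval("c1", 495, 545), region_id="r0")],
    )
    regions[0] = Region(
        "r0", Interval("c1", 0, len(seq), "+", "r0"), seq, member_loci=("op0",)
    )
    assignments, summary = C.antirepeat_assign(arrays, [cand], regions, region_for)
    assert len(assignments) == 1
    a = assignments[0]
    assert a.candidate_id == "tracr_like"
    assert a.e_value < 0.05
    assert a.assigned_subtype == "II-C"
    assert a.agreement is True
    assert summary["agreement_fraction"] == 1.0
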