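"""Model building, scanning, E-value calibration, retention and dedup."""

import numpy as np
import pytest

from rnascout import search as S
from rnascout.io_formats import Interval, StockholmAlignment, revcomp
from rnascout.motif import MotifAlignment, fold_consensus
from rnascout.region_prep import Region
from rnascout.synthetic_data import mutate_sequence

BASES = "ACGT"


def rand_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def make_region(rid, seq):
    return Region(rid, Interval(f"c_{rid}", 0, len(seq), "+", rid), seq)


@pytest.fixture
def family_model(rng):
    """A model built from diverged copies of one 50-nt motif."""
    consensus = rand_seq(rng, 50)
    instances = [mutate_sequence(consensus, 0.15, rng)[0] for _ in range(8)]
    aln = StockholmAlignment(names=[f"s{i}" for i in range(8)], rows=instances)
    aln.ss_cons = fold_consensus(aln)
    bg = np.full(4, 0.25)
    model = S.build_model(MotifAlignment("m0", aln, 0.0), bg)
    return consensus, instances, model


def test_scan_score_matches_independent_recomputation(family_model, rng):
    consensus, instances, model = family_model
    window = model.consensus
    scores = S.scan_sequence(model, window)
    assert len(scores) == 1
    # independent per-column/per-pair recomputation
    assert scores[0] == pytest.approx(S.score_window(model, window))
    manual = sum(
        model.column_lo[c, "ACGTN".index(window[c])] for c in range(model.width)
    )
    for (i, j), tab in zip(model.pairs, model.pair_lo):
        manual += tab["ACGTN".index(window[i]), "ACGTN".index(window[j])]
    assert scores[0] == pytest.approx(manual)


def test_scan_finds_planted_instance_at_offset(family_model, rng):
    consensus, instances, model = family_model
    offset = 700
    region_seq = rand_seq(rng, offset) + consensus + rand_seq(rng, 600)
    scores = S.scan_sequence(model, region_seq)
    best = int(np.argmax(scores))
    assert abs(best - offset) <= 2


def test_scan_strand_symmetry(family_model, rng):
    consensus, instances, model = family_model
    region_seq = rand_seq(rng, 300) + consensus + rand_seq(rng, 300)
    region = make_region("r0", region_seq)
    flipped = make_region("r1", revcomp(region_seq))
    scans = S.scan(model, [region, flipped])
    plus_best = scans[("r0", "+")].max()
    minus_best = scans[("r1", "-")].max()
    assert plus_best == pytest.approx(minus_best)
    assert int(np.argmax(scans[("r0", "+")])) == 300


def test_dinucleotide_shuffle_preserves_dinucleotide_counts(rng):
    from collections import Counter

    for trial in range(10):
        seq = rand_seq(rng, int(rng.integers(50, 400)))
        sh = S.dinucleotide_shuffle(seq, rng)
        assert len(sh) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(sh, sh[1:]))
        assert sh[0] == seq[0] and sh[-1] == seq[-1]


def test_calibration_monotone_and_median(family_model, rng):
    consensus, instances, model = family_model
    regions = [make_region(f"r{i}", rand_seq(rng, 2500)) for i in range(4)]
    efunc = S.calibrate(model, regions, n_shuffles=3, seed=5)
    scores = np.linspace(efunc.sorted_null[0], efunc.sorted_null[-1] + 30, 60)
    evals = [efunc(float(s)) for s in scores]
    assert all(a >= b - 1e-9 for a, b in zip(evals, evals[1:]))
    # E at the median null score is M/2 within a factor of 2
    med = float(np.median(efunc.sorted_null))
    assert efunc.m_total / 4 <= efunc(med) <= efunc.m_total


def test_calibration_rejects_degenerate_null():
    with pytest.raises(ValueError):
        S.EValueCalibration(np.zeros(100), 1000)


def test_true_instances_significant_decoy_regions_not(family_model, rng):
    consensus, instances, model = family_model
    regions = []
    for i, inst in enumerate(instances[:5]):
        bg = rand_seq(rng, 2000)
        regions.append(make_region(f"r{i}", bg[:900] + inst + bg[950:]))
    for i in range(5, 10):
        regions.append(make_region(f"r{i}", rand_seq(rng, 2000)))
    efunc = S.calibrate(model, regions, n_shuffles=3, seed=6)
    scans = S.scan(model, regions)
    insts = S.find_instances(model, scans, efunc, regions, e_threshold=1e-6)
    hit_regions = {i.region_id for i in insts}
    assert {"r0", "r1", "r2", "r3", "r4"} <= hit_regions
    assert not any(f"r{i}" in hit_regions for i in range(5, 10))


# ---------------------------------------------------------------------------
# Retention, dedup, subtraction (constructed candidates)
# ---------------------------------------------------------------------------


def _instance(region_id, start, end, e=1e-9):
    return S.Instance(
        region_id=region_id,
        start=start,
        end=end,
        strand="+",
        score=50.0,
        e_value=e,
        genome=Interval(f"c_{region_id}", start, end, "+"),
    )


def _candidate(cid, width, instances):
    model = S.MotifModel(
        model_id=cid, width=width, column_lo=np.zeros((width, 5)), bg=np.full(4, 0.25)
    )
    return S.Candidate(candidate_id=cid, model=model, motif=None, instances=instances)


def test_retain_searchable_region_counting():
    m = S.MotifModel("m", 40, np.zeros((40, 5)), bg=np.full(4, 0.25))
    two = [(None, m, [_instance("rA", 0, 40, 1e-9), _instance("rB", 0, 40, 1e-9)])]
    assert S.retain_searchable(two) == []
    three = [
        (
            None,
            m,
            [
                _instance("rA", 0, 40, 1e-7),
                _instance("rB", 0, 40, 1e-7),
                _instance("rC", 0, 40, 1e-7),
            ],
        )
    ]
    assert len(S.retain_searchable(three)) == 1
    one_region = [(None, m, [_instance("rA", k * 100, k * 100 + 40) for k in range(5)])]
    assert S.retain_searchable(one_region) == []


def test_dedup_keeps_longest_of_overlapping():
    a = _candidate("a", 80, [_instance("r0", 100, 180, 1e-9)])
    b = _candidate("b", 60, [_instance("r0", 150, 210, 1e-9)])
    kept = S.dedup([a, b])
    assert [c.candidate_id for c in kept] == ["a"]


def test_dedup_keeps_disjoint():
    a = _candidate("a", 80, [_instance("r0", 100, 180)])
    b = _candidate("b", 60, [_instance("r0", 500, 560)])
    assert len(S.dedup([a, b])) == 2


def test_dedup_overlap_chain_keeps_ends():
    a = _candidate("a", 80, [_instance("r0", 100, 180)])
    b = _candidate("b", 70, [_instance("r0", 160, 230)])
    c = _candidate("c", 60, [_instance("r0", 220, 280)])
    kept = S.dedup([a, b, c])
    assert sorted(x.candidate_id for x in kept) == ["a", "c"]


def test_subtract_known():
    cand = _candidate(
        "a", 60, [_instance("r0", 100 * k, 100 * k + 60) for k in range(5)]
    )
    assert S.subtract_known([cand], []) == [cand]
    overlapping = [Interval("c_r0", 130, 150)]
    assert S.subtract_known([cand], overlapping) == []
    touching = [Interval("c_r0", 60, 100)]  # half-open adjacency
    assert S.subtract_known([cand], touching) == [cand]
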