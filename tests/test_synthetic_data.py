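"""The generator's statistical contracts: these define what the pipeline is
asked to recover, so they are tested independently of the pipeline."""

import numpy as np
import pytest
from scipy import stats as sps

from rnascout.io_formats import revcomp
from rnascout.synthetic_data import (
    DatasetSpec,
    FamilySpec,
    Helix,
    build_crispr_array,
    generate_dataset,
    pairwise_identity,
    random_family_spec,
    sample_family,
)


def _spec(theta=0.2, rho=0.9, n=10, structured=True, L=60):
    helices = (Helix(2, 21, 5),) if structured else ()
    return FamilySpec("fam", L, n, helices, theta, rho, structured)


def test_theta_zero_instances_equal_consensus():
    fam = sample_family(_spec(theta=0.0), seed=5)
    assert all(inst == fam.consensus for inst in fam.instances)
    assert all(log == [] for log in fam.mutation_logs)


def test_rho_one_keeps_every_helix_pair_canonical():
    canonical = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    spec = _spec(theta=0.4, rho=1.0)
    fam = sample_family(spec, seed=6)
    for inst in fam.instances:
        for i, j in spec.helices[0].pairs():
            assert (inst[i], inst[j]) in canonical


def test_mean_identity_matches_mutation_log_prediction():
    spec = _spec(theta=0.2, n=12, L=80)
    fam = sample_family(spec, seed=7)
    observed, predicted = [], []
    for a in range(12):
        for b in range(a + 1, 12):
            observed.append(pairwise_identity(fam.instances[a], fam.instances[b]))
            da = {p: new for p, _, new in fam.mutation_logs[a]}
            db = {p: new for p, _, new in fam.mutation_logs[b]}
            diff = set(da) | set(db)
            same_change = sum(
                1 for p in set(da) & set(db) if da[p] == db[p]
            )
            predicted.append((80 - len(diff) + same_change) / 80)
    assert abs(np.mean(observed) - np.mean(predicted)) <= 0.02


def test_helix_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        FamilySpec("bad", 60, 5, (Helix(2, 21, 5), Helix(4, 30, 4)), 0.1, 0.9, True)


def test_decoy_with_helices_rejected():
    with pytest.raises(ValueError):
        FamilySpec("bad", 60, 5, (Helix(2, 21, 5),), 0.1, 0.9, False)


# ---------------------------------------------------------------------------
# CRISPR arrays
# ---------------------------------------------------------------------------


def test_array_counts_and_length_arithmetic():
    repeat = "ACGTACGTACGTACGTACGTACGTACGTAC"
    seq, reps, spcs = build_crispr_array(repeat, 4, (30, 40), seed=3)
    assert len(reps) == 4 and len(spcs) == 3
    assert len(seq) == 4 * len(repeat) + sum(len(s) for s in spcs)
    for r in reps:
        assert seq[r.start : r.end] == repeat


def test_array_determinism_and_precondition():
    repeat = "A" * 30
    s1 = build_crispr_array(repeat, 5, (30, 40), seed=11)[0]
    s2 = build_crispr_array(repeat, 5, (30, 40), seed=11)[0]
    assert s1 == s2
    with pytest.raises(ValueError):
        build_crispr_array(repeat, 1, (30, 40), seed=0)


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------


def test_dataset_determinism(small_dataset):
    spec = small_dataset.spec
    again = generate_dataset(spec)
    assert [c.sequence for c in again.contigs] == [
        c.sequence for c in small_dataset.contigs
    ]
    assert again.truth.records == small_dataset.truth.records


def test_manifest_intervals_within_contig_bounds(small_dataset):
    length_of = {c.id: len(c) for c in small_dataset.contigs}
    for rec in small_dataset.truth.records:
        iv = rec.interval
        assert 0 <= iv.start < iv.end <= length_of[iv.contig_id]


def test_contigs_exceed_filter_threshold(small_dataset):
    assert all(len(c) > 3000 for c in small_dataset.contigs)


def test_antirepeat_near_reverse_complement_of_repeat():
    ds = generate_dataset(DatasetSpec(seed=9))
    mu = ds.spec.antirepeat_divergence
    contig = {c.id: c.sequence for c in ds.contigs}
    arrays = {a.array_id: a for a in ds.arrays}
    idents = []
    for rec in ds.truth.by_type("antirepeat"):
        anti = contig[rec.interval.contig_id][rec.interval.start : rec.interval.end]
        rep = arrays[rec.array_id].consensus_repeat
        idents.append(pairwise_identity(anti, revcomp(rep)))
    assert idents
    # per-site divergence mu, so identity recomputed from the emitted
    # sequences averages 1-mu; the slack absorbs binomial noise at ~35 nt
    assert np.mean(idents) >= 1 - mu - 0.05
    assert min(idents) >= 1 - mu - 0.15


def test_structured_families_show_covariation_precondition(rng):
    """With rho >= 0.8 and moderate theta, some pair shows >= 2 distinct
    canonical pair types across instances."""
    canonical = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    for trial in range(10):
        spec = random_family_spec(f"f{trial}", rng, structured=True, theta=0.2, rho=0.9)
        fam = sample_family(spec, rng)
        found = False
        for h in spec.helices:
            for i, j in h.pairs():
                types = {
                    (inst[i], inst[j])
                    for inst in fam.instances
                    if (inst[i], inst[j]) in canonical
                }
                if len(types) >= 2:
                    found = True
        assert found, f"family {trial} lacks covariation signal"


def test_decoy_identity_distribution_matches_structured(rng):
    """Decoys are conserved like structured families (location test p > 0.01)."""

    def family_identities(structured):
        out = []
        for k in range(50):
            spec = random_family_spec(
                f"x{k}", rng, structured=structured, n_instances=6, theta=0.2, rho=0.9
            )
            fam = sample_family(spec, rng)
            ids = [
                pairwise_identity(fam.instances[a], fam.instances[b])
                for a in range(6)
                for b in range(a + 1, 6)
            ]
            out.append(float(np.mean(ids)))
        return out

    s = family_identities(True)
    d = family_identities(False)
    p = sps.mannwhitneyu(s, d, alternative="two-sided").pvalue
    assert p > 0.01
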