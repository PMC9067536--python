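"""Scoring a pipeline run against a synthetic truth manifest.

The truth manifest is the sole oracle: planted family instances are matched
to candidate instances by reciprocal overlap, decoy rejection is read off
the covariation gate, and array assignments are compared with the planted
subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Interval
from .pipeline import PipelineResult
from .synthetic_data import GeneratedDataset, TruthManifest


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """Overlap divided by the longer interval's length (0 if disjoint)."""
    if a.contig_id != b.contig_id:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / max(len(a), len(b))


def candidate_for_family(
    truth: TruthManifest,
    family_id: str,
    candidates,
    rtype: str = "family_instance",
    min_ro: float = 0.5,
    min_matched: int = 2,
) -> str | None:
    """The candidate modeling a planted family, if any.

    A candidate matches when at least `min_matched` planted instances of
    the family reciprocally overlap (>= min_ro) one of its instances.
    """
    planted = [t.interval for t in truth.by_type(rtype) if t.family_id == family_id]
    best: tuple[int, str] | None = None
    for cand in candidates:
        matched = sum(
            any(reciprocal_overlap(t, inst.genome) >= min_ro for inst in cand.instances)
            for t in planted
        )
        if matched >= min_matched and (best is None or matched > best[0]):
            best = (matched, cand.candidate_id)
    return best[1] if best else None


def cluster_truth_label(cluster, regions, truth: TruthManifest) -> str:
    """Majority planted-element label among a cluster's nodes ('' if none)."""
    region_map = {r.region_id: r for r in regions}
    votes: dict[str, int] = {}
    labeled = [
        (t.family_id or t.rtype, t.interval)
        for t in truth.records
        if t.rtype in ("family_instance", "decoy_instance", "repeat", "tracr", "antirepeat")
    ]
    for node in cluster.nodes:
        region = region_map[node.region_id]
        g0 = region.interval.start + node.start
        g1 = region.interval.start + node.end
        for label, iv in labeled:
            if iv.contig_id == region.interval.contig_id and iv.start < g1 and g0 < iv.end:
                votes[label] = votes.get(label, 0) + 1
    if not votes:
        return ""
    return sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


@dataclass
class RunEvaluation:
    n_structured: int
    n_structured_recovered: int
    n_decoys: int
    n_decoys_rejected_at_gate: int
    n_direct_repeat_candidates: int
    tracr_recovered: bool
    tracr_categorized_tracr_like: bool
    n_arrays_assigned: int
    subtype_agreement: float | None

    @property
    def family_recovery(self) -> float:
        return (
            self.n_structured_recovered / self.n_structured if self.n_structured else 0.0
        )

    @property
    def decoy_rejection(self) -> float:
        return self.n_decoys_rejected_at_gate / self.n_decoys if self.n_decoys else 1.0


def evaluate_run(dataset: GeneratedDataset, result: PipelineResult) -> RunEvaluation:
    truth = dataset.truth
    fams = truth.family_ids("family_instance")
    recovered = [
        f for f in fams if candidate_for_family(truth, f, result.candidates) is not None
    ]
    decoys = truth.family_ids("decoy_instance")
    # a decoy is rejected "at or before the covariation gate" when no
    # covariation-passing motif is labeled with it
    passing_ids = {m.cluster_id for m in result.motifs}
    passing_labels = {
        cluster_truth_label(c, result.regions, truth)
        for c in result.clusters
        if c.cluster_id in passing_ids
    }
    rejected = [d for d in decoys if d not in passing_labels]
    n_dr = sum(c.category == "direct_repeat" for c in result.candidates)
    tracr_cand = candidate_for_family(truth, "tracr", result.candidates, rtype="tracr")
    tracr_like = False
    if tracr_cand is not None:
        cand = next(c for c in result.candidates if c.candidate_id == tracr_cand)
        tracr_like = cand.category == "tracrRNA_like"
    return RunEvaluation(
        n_structured=len(fams),
        n_structured_recovered=len(recovered),
        n_decoys=len(decoys),
        n_decoys_rejected_at_gate=len(rejected),
        n_direct_repeat_candidates=n_dr,
        tracr_recovered=tracr_cand is not None,
        tracr_categorized_tracr_like=tracr_like,
        n_arrays_assigned=result.assignment_summary["n_arrays_assigned"],
        subtype_agreement=result.assignment_summary["agreement_fraction"],
    )
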