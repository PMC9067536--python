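"""End-to-end orchestration: regions -> homology -> clusters -> motifs ->
search -> classification, with one seed, one config, and a funnel report.

Every stochastic stage draws from its own named stream derived from the
root seed, so identical (config, inputs, seed) produce byte-identical
outputs. The funnel report mirrors the staged retention counts of the
motif-discovery cascade and is strictly nonincreasing along the motif
funnel.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as _classify
from . import clustering as _clustering
from . import homology as _homology
from . import motif as _motif
from . import region_prep as _region_prep
from . import search as _search
from .io_formats import (
    ContigRecord,
    CrisprArray,
    GeneAnnotation,
    Interval,
    write_bed,
    write_hits,
    write_stockholm,
)

log = logging.getLogger(__name__)

# stage codes for deriving independent seed streams from the root seed
_STAGE_COVARIATION = 1
_STAGE_REFINE = 2
_STAGE_CALIBRATE = 3


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric gate of the pipeline, with its published defaults."""

    min_contig_length: int = 3000
    flank: int = 500
    min_hit_len: int = 30
    min_bit: float = 20.0
    exclude_full_identity: bool = True
    seed_word_length: int = 7
    min_cluster_members: int = 2
    structure_score_threshold: float = 10.0
    covariation_alpha: float = 0.05
    n_perm: int = 200
    n_shuffles: int = 5
    search_e_threshold: float = 1e-6
    min_regions: int = 3
    antirepeat_e_threshold: float = 0.05
    tracr_window: int = 100
    palindrome_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in (
            "min_hit_len",
            "min_bit",
            "structure_score_threshold",
            "covariation_alpha",
            "n_perm",
            "search_e_threshold",
            "min_regions",
            "antirepeat_e_threshold",
            "tracr_window",
            "palindrome_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def scoring_params(self) -> _homology.ScoringParams:
        return _homology.ScoringParams(seed_word_length=self.seed_word_length)


@dataclass
class FunnelReport:
    regions: int = 0
    hits: int = 0
    clusters: int = 0
    aligned_motifs: int = 0
    score_passing: int = 0
    covariation_passing: int = 0
    searchable: int = 0
    post_dedup: int = 0
    post_subtraction: int = 0
    categories: dict = field(default_factory=dict)
    candidate_counts: dict = field(default_factory=dict)
    seed: int = 0

    def funnel_counts(self) -> list[int]:
        return [
            self.clusters,
            self.aligned_motifs,
            self.score_passing,
            self.covariation_passing,
            self.searchable,
            self.post_dedup,
            self.post_subtraction,
        ]

    def is_monotone(self) -> bool:
        counts = self.funnel_counts()
        return all(a >= b for a, b in zip(counts, counts[1:]))


@dataclass
class PipelineResult:
    config: PipelineConfig
    regions: list
    hits: list
    clusters: list
    motifs: list  # passing MotifAlignment objects
    candidates: list
    categories: list
    assignments: list
    assignment_summary: dict
    report: FunnelReport

    def report_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "funnel": {
                "regions": self.report.regions,
                "hits": self.report.hits,
                "clusters": self.report.clusters,
                "aligned_motifs": self.report.aligned_motifs,
                "score_passing": self.report.score_passing,
                "covariation_passing": self.report.covariation_passing,
                "searchable": self.report.searchable,
                "post_dedup": self.report.post_dedup,
                "post_subtraction": self.report.post_subtraction,
            },
            "categories": dict(sorted(self.report.categories.items())),
            "candidate_counts": dict(sorted(self.report.candidate_counts.items())),
            "antirepeat_summary": self.assignment_summary,
            "candidates": [
                {
                    "candidate_id": c.candidate_id,
                    "length": c.length,
                    "n_instances": len(c.instances),
                    "n_regions": len(c.regions_hit),
                    "category": c.category,
                    "palindromicity": c.palindromicity,
                    "structure_score": round(c.motif.structure_score, 6),
                    "min_covariation_e": (
                        c.motif.covariation.min_e if c.motif.covariation else None
                    ),
                }
                for c in sorted(self.candidates, key=lambda c: c.candidate_id)
            ],
        }


def _rng(seed: int, stage: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stage, index])


def run_pipeline(
    config: PipelineConfig,
    contigs: list[ContigRecord],
    genes: list[GeneAnnotation],
    arrays: list[CrisprArray],
    known: list[Interval] | None = None,
) -> PipelineResult:
    """Execute all stages in order; deterministic for fixed inputs and seed."""
    t0 = time.time()
    known = known or []
    params = config.scoring_params()

    # --- region preparation ---------------------------------------------
    contigs = _region_prep.filter_contigs(contigs, config.min_contig_length)
    contig_ids = {c.id for c in contigs}
    genes = [g for g in genes if g.interval.contig_id in contig_ids]
    arrays = [a for a in arrays if a.contig_id in contig_ids]
    loci = _region_prep.loci_from_annotations(genes, arrays)
    regions = _region_prep.prepare_regions(contigs, loci, config.flank)
    log.info("regions: %d (%.1fs)", len(regions), time.time() - t0)

    # --- all-vs-all homology --------------------------------------------
    hits = (
        _homology.all_vs_all(
            regions,
            params,
            min_hit_len=config.min_hit_len,
            min_bit=config.min_bit,
            exclude_full_identity=config.exclude_full_identity,
        )
        if regions
        else []
    )
    log.info("hits: %d (%.1fs)", len(hits), time.time() - t0)

    # --- clustering ------------------------------------------------------
    nodes = _clustering.hits_to_nodes(hits) if hits else []
    clusters = (
        _clustering.single_linkage(nodes, hits, regions, config.min_cluster_members)
        if nodes
        else []
    )
    log.info("clusters: %d (%.1fs)", len(clusters), time.time() - t0)

    # --- motif stage: align, fold, score, covariation, refine ------------
    # A cluster may yield several motif units (composition subgroups); the
    # funnel counts clusters with >= 1 unit surviving each gate, so the
    # funnel stays monotone while units are tracked individually.
    aligned_clusters: set[str] = set()
    score_pass_clusters: set[str] = set()
    cov_pass_clusters: set[str] = set()
    passing_motifs: list[_motif.MotifAlignment] = []
    unit_members: dict[str, list[str]] = {}
    bg = _search.background_frequencies(regions) if regions else np.full(4, 0.25)
    for ci, cluster in enumerate(clusters):
        # orientation 2-coloring first: a minus-orientation block marks a
        # reverse-complement-linked subfamily (the repeat/antirepeat case);
        # then composition subgroups within each orientation block
        orients = [cluster.orientations[n.node_id] for n in cluster.nodes]
        plus = [i for i, o in enumerate(orients) if o == "+"]
        minus = [i for i, o in enumerate(orients) if o == "-"]
        if plus and minus and min(len(plus), len(minus)) >= 3:
            # the whole cluster stays a unit (orientation-normalized members
            # of a repeat/antirepeat pair enrich each other's covariation);
            # each orientation block is also tried on its own, which is how
            # a tracrRNA motif separates from the repeats it links to
            base_groups = [list(range(len(cluster.sequences))), plus, minus]
        else:
            base_groups = [list(range(len(cluster.sequences)))]
        groups: list[list[int]] = []
        for base in base_groups:
            for sub in _motif.split_members([cluster.sequences[i] for i in base]):
                groups.append([base[i] for i in sub])
        for gi, group in enumerate(groups):
            seqs = [cluster.sequences[k] for k in group]
            if len(seqs) < 2:
                continue
            unit_id = (
                cluster.cluster_id if len(groups) == 1 else f"{cluster.cluster_id}.{gi}"
            )
            # hit-anchored stacking is exact for same-scale homology windows;
            # clusters mixing single-unit and multi-unit (array-spanning)
            # members have no single per-member register, so they take the
            # de-novo progressive route instead
            lens = sorted(len(s) for s in seqs)
            heterogeneous = lens[-1] >= 2 * lens[len(lens) // 2]
            if heterogeneous:
                aln = _motif.align_cluster(seqs)
            else:
                offs = [cluster.offsets[cluster.nodes[k].node_id] for k in group]
                aln = _motif.align_with_offsets(seqs, offs)
            aln, kept_rows = _motif.prune_outlier_rows(aln)
            seqs = [seqs[k] for k in kept_rows]
            aligned_clusters.add(cluster.cluster_id)
            if aln.n_seqs >= 3:
                # EM-style inner realignment: a column model over the match
                # columns (information-trimmed so flanking context does not
                # widen it), then every member re-placed at its best
                # register — covariation statistics run on clean rows
                try:
                    for _ in range(2):
                        model0 = _search.build_model(
                            _motif.MotifAlignment(unit_id, aln, 0.0), bg
                        )
                        model0 = _search.trim_model(model0)
                        rows = _search.member_placements(model0, seqs)
                        if rows is None:
                            break
                        aln = _motif.StockholmAlignment(
                            names=[f"seq{i}" for i in range(len(rows))], rows=rows
                        )
                except ValueError:
                    pass
                aln, _kept2 = _motif.prune_outlier_rows(aln)
                # identical rows (e.g. exact repeat copies within one array)
                # carry no independent evidence: collapse before scoring
                seen: dict[str, None] = {}
                uniq = [k for k, r in enumerate(aln.rows) if not (r in seen or seen.setdefault(r))]
                if 2 <= len(uniq) < aln.n_seqs:
                    aln = _motif.StockholmAlignment(
                        names=[aln.names[k] for k in uniq],
                        rows=[aln.rows[k] for k in uniq],
                    )
            aln.ss_cons = _motif.fold_consensus(aln)
            sc = _motif.structure_score(aln)
            if sc < config.structure_score_threshold:
                continue
            score_pass_clusters.add(cluster.cluster_id)
            if aln.n_seqs < 4:
                # three rows offer three row pairs: any single coincidence
                # dominates the statistic, so significance is not assessable
                continue
            cov = _motif.covariation_stats(
                aln,
                n_perm=config.n_perm,
                seed=_rng(config.seed, _STAGE_COVARIATION, ci * 64 + gi),
                alpha=config.covariation_alpha,
            )
            log.info(
                "unit %s: N=%d W=%d score=%.1f min_e=%.3f",
                unit_id, aln.n_seqs, aln.width, sc, cov.min_e,
            )
            if not cov.significant:
                continue
            new_ss, cov = _motif.refine_fold(
                aln,
                cov,
                n_perm=config.n_perm,
                seed=_rng(config.seed, _STAGE_REFINE, ci * 64 + gi),
                alpha=config.covariation_alpha,
            )
            aln.ss_cons = new_ss
            cov_pass_clusters.add(cluster.cluster_id)
            passing_motifs.append(
                _motif.MotifAlignment(
                    cluster_id=unit_id,
                    alignment=aln,
                    structure_score=_motif.structure_score(aln),
                    covariation=cov,
                )
            )
            unit_members[unit_id] = seqs
    aligned = len(aligned_clusters)
    score_passing = len(score_pass_clusters)
    covariation_passing = len(cov_pass_clusters)
    log.info(
        "motifs: aligned=%d score_pass=%d cov_pass=%d units=%d (%.1fs)",
        aligned, score_passing, covariation_passing, len(passing_motifs),
        time.time() - t0,
    )

    # --- search: model, refit, calibrate, retain -------------------------
    searchable_input = []
    for mi, motif in enumerate(passing_motifs):
        model = _search.build_model(motif, bg)
        model = _search.refit_model(model, unit_members[motif.cluster_id])
        scans = _search.scan(model, regions)
        efunc = _search.calibrate(
            model,
            regions,
            n_shuffles=config.n_shuffles,
            seed=_rng(config.seed, _STAGE_CALIBRATE, mi),
        )
        instances = _search.find_instances(
            model, scans, efunc, regions, config.search_e_threshold
        )
        searchable_input.append((motif, model, instances))
    candidates = _search.retain_searchable(
        searchable_input, config.search_e_threshold, config.min_regions
    )

    def _cluster_of(candidate_id: str) -> str:
        return candidate_id.split(".")[0]

    searchable = len({_cluster_of(c.candidate_id) for c in candidates})
    n_searchable_candidates = len(candidates)
    candidates = _search.dedup(candidates)
    post_dedup = len({_cluster_of(c.candidate_id) for c in candidates})
    n_post_dedup_candidates = len(candidates)
    candidates = _search.subtract_known(candidates, known)
    post_subtraction = len({_cluster_of(c.candidate_id) for c in candidates})
    n_final_candidates = len(candidates)
    log.info(
        "candidates: searchable=%d post_dedup=%d final=%d (%.1fs)",
        n_searchable_candidates, n_post_dedup_candidates, n_final_candidates,
        time.time() - t0,
    )

    # --- classification ---------------------------------------------------
    operon_subtypes = {g.operon_id: g.subtype for g in genes if g.subtype}
    assignments, summary = _classify.antirepeat_assign(
        arrays,
        candidates,
        regions,
        operon_subtypes,
        params,
        config.antirepeat_e_threshold,
    )
    tracr_ids = {a.candidate_id for a in assignments}
    categories: list[_classify.CategoryCall] = []
    cat_counts: dict[str, int] = {}
    for cand in candidates:
        if len(cand.model.consensus) >= 8:
            cand.palindromicity = _classify.palindromicity(cand.model.consensus, params)
        call = _classify.categorize(
            cand,
            genes,
            arrays,
            tracr_ids,
            window=config.tracr_window,
            palindrome_threshold=config.palindrome_threshold,
        )
        cand.category = call.category
        categories.append(call)
        cat_counts[call.category] = cat_counts.get(call.category, 0) + 1
    log.info("pipeline done in %.1fs", time.time() - t0)

    report = FunnelReport(
        regions=len(regions),
        hits=len(hits),
        clusters=len(clusters),
        aligned_motifs=aligned,
        score_passing=score_passing,
        covariation_passing=covariation_passing,
        searchable=searchable,
        post_dedup=post_dedup,
        post_subtraction=post_subtraction,
        categories=cat_counts,
        candidate_counts={
            "searchable": n_searchable_candidates,
            "post_dedup": n_post_dedup_candidates,
            "final": n_final_candidates,
        },
        seed=config.seed,
    )
    return PipelineResult(
        config=config,
        regions=regions,
        hits=hits,
        clusters=clusters,
        motifs=passing_motifs,
        candidates=candidates,
        categories=categories,
        assignments=assignments,
        assignment_summary=summary,
        report=report,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the standard output set; deterministic byte-for-byte per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    # candidate instances as BED6, score = -log10(E) capped at 300
    ivs, scores = [], []
    for cand in sorted(result.candidates, key=lambda c: c.candidate_id):
        for inst in sorted(
            cand.instances, key=lambda i: (i.genome.contig_id, i.genome.start)
        ):
            iv = inst.genome
            ivs.append(
                Interval(iv.contig_id, iv.start, iv.end, iv.strand, cand.candidate_id)
            )
            e = max(inst.e_value, 1e-300)
            scores.append(round(min(300.0, -np.log10(e)), 2))
    write_bed(ivs, outdir / "candidates.bed", scores)
    _region_prep.write_regions(
        result.regions, outdir / "regions.bed", outdir / "regions.fasta"
    )
    write_hits(result.hits, outdir / "hits.tsv")
    _clustering.write_clusters_table(result.clusters, outdir / "clusters.tsv")
    _classify.write_categories(result.categories, outdir / "categories.tsv")
    _classify.write_assignments(result.assignments, outdir / "assignments.tsv")
    sto_dir = outdir / "candidates"
    sto_dir.mkdir(exist_ok=True)
    for cand in result.candidates:
        aln = cand.motif.alignment
        aln.gf = {
            "ID": cand.candidate_id,
            "STRUCTURE_SCORE": f"{cand.motif.structure_score:.4f}",
            "MIN_COV_E": (
                f"{cand.motif.covariation.min_e:.4g}" if cand.motif.covariation else "NA"
            ),
        }
        sig = (
            [ps for ps in cand.motif.covariation.pair_stats if ps.e_value < result.config.covariation_alpha]
            if cand.motif.covariation
            else []
        )
        write_stockholm(aln, sto_dir / f"{cand.candidate_id}.sto", pair_stats=sig)
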