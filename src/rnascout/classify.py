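"""Candidate categorization, palindromicity, and antirepeat array assignment.

Each surviving candidate is binned into exactly one of four categories, in
priority order: ``direct_repeat`` (a majority of instances overlap CRISPR
array repeat intervals), ``tracrRNA_like`` (the candidate matched an array
repeat by homology — an antirepeat — and a majority of instances sit
within a short window upstream of a cas9 gene or overlap its start),
``coding_overlap`` (a majority overlap annotated genes), else
``intergenic``.

The antirepeat assignment mirrors the repeat-vs-everything search: each
array's consensus repeat is aligned against all regions; significant
non-self hits that land inside a candidate's instances link the array to
that candidate, and the array inherits the modal subtype of the operons
where the candidate occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import ScoringParams, local_align
from .io_formats import CrisprArray, GeneAnnotation, Interval, revcomp
from .region_prep import Region
from .search import Candidate


# ---------------------------------------------------------------------------
# Palindromicity
# ---------------------------------------------------------------------------


def _semiglobal_best(a: str, b: str, params: ScoringParams) -> tuple[int, int]:
    """Free-end-gap alignment of a vs b maximizing (score, matches).

    Affine gaps; end gaps on either sequence are free. Returns the
    lexicographically optimal (score, matches) over all alignments, so the
    match count is well defined even among co-optimal alignments.
    """
    na, nb = len(a), len(b)
    NEG = (-(10**9), 0)
    go, ge = params.gap_open, params.gap_extend
    # cell values are (score, matches) tuples; lexicographic max
    H = [[(0, 0)] * (nb + 1) for _ in range(na + 1)]  # free leading gaps
    E = [[NEG] * (nb + 1) for _ in range(na + 1)]
    F = [[NEG] * (nb + 1) for _ in range(na + 1)]
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            ca, cb = a[i - 1], b[j - 1]
            is_match = ca == cb and ca != "N"
            s = params.match if is_match else params.mismatch
            hd = H[i - 1][j - 1]
            diag = (hd[0] + s, hd[1] + (1 if is_match else 0))
            e1 = (H[i][j - 1][0] + go + ge, H[i][j - 1][1])
            e2 = (E[i][j - 1][0] + ge, E[i][j - 1][1])
            E[i][j] = max(e1, e2)
            f1 = (H[i - 1][j][0] + go + ge, H[i - 1][j][1])
            f2 = (F[i - 1][j][0] + ge, F[i - 1][j][1])
            F[i][j] = max(f1, f2)
            H[i][j] = max(diag, E[i][j], F[i][j])
    best = NEG
    for i in range(na + 1):
        best = max(best, H[i][nb])
    for j in range(nb + 1):
        best = max(best, H[na][j])
    return best


def palindromicity(sequence: str, params: ScoringParams = ScoringParams()) -> float:
    """Identity of a sequence to its own reverse complement, in [0, 1].

    Free-end-gap alignment of the sequence against its reverse complement
    under the local aligner's score system; the value is matches divided
    by sequence length. Undefined below 8 nt.
    """
    if len(sequence) < 8:
        raise ValueError("palindromicity undefined for sequences shorter than 8")
    _, matches = _semiglobal_best(sequence, revcomp(sequence), params)
    return matches / len(sequence)


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------


@dataclass
class CategoryCall:
    candidate_id: str
    category: str  # direct_repeat | tracrRNA_like | coding_overlap | intergenic
    frac_repeat: float
    frac_gene: float
    frac_cas9_upstream: float
    overlapped_genes: tuple[str, ...] = ()
    mean_relative_position: float | None = None
    palindromicity: float | None = None
    palindromic: bool | None = None


def _cas9_window(gene: GeneAnnotation, window: int) -> Interval:
    """The 'within `window` bases upstream of the start, or over the start' zone."""
    iv = gene.interval
    if iv.strand == "-":
        return Interval(iv.contig_id, iv.end - 1, iv.end + window, iv.strand)
    return Interval(iv.contig_id, max(0, iv.start - window), iv.start + 1, iv.strand)


def categorize(
    candidate: Candidate,
    genes: list[GeneAnnotation],
    arrays: list[CrisprArray],
    tracr_candidate_ids: set[str],
    window: int = 100,
    majority: float = 0.5,
    palindrome_threshold: float = 0.7,
) -> CategoryCall:
    """Assign the candidate its single category (priority order above)."""
    instances = [inst.genome for inst in candidate.instances]
    n = len(instances)
    repeat_ivs = [iv for a in arrays for iv in a.repeat_intervals]
    cas9_zones = [_cas9_window(g, window) for g in genes if g.gene_name == "cas9"]

    def frac(zones: list[Interval]) -> float:
        if n == 0:
            return 0.0
        return sum(any(iv.overlaps(z) for z in zones) for iv in instances) / n

    frac_repeat = frac(repeat_ivs)
    frac_gene = frac([g.interval for g in genes])
    frac_cas9 = frac(cas9_zones)

    overlapped: list[str] = []
    relpos: list[float] = []
    for iv in instances:
        for g in genes:
            if iv.overlaps(g.interval):
                overlapped.append(g.gene_name)
                mid = (iv.start + iv.end) / 2
                x = (mid - g.interval.start) / len(g.interval)
                if g.interval.strand == "-":
                    x = 1.0 - x
                relpos.append(min(1.0, max(0.0, x)))

    if frac_repeat > majority:
        category = "direct_repeat"
    elif candidate.candidate_id in tracr_candidate_ids and frac_cas9 > majority:
        category = "tracrRNA_like"
    elif frac_gene > majority:
        category = "coding_overlap"
    else:
        category = "intergenic"

    pal = candidate.palindromicity
    if pal is None and len(candidate.model.consensus) >= 8:
        pal = palindromicity(candidate.model.consensus)
    return CategoryCall(
        candidate_id=candidate.candidate_id,
        category=category,
        frac_repeat=frac_repeat,
        frac_gene=frac_gene,
        frac_cas9_upstream=frac_cas9,
        overlapped_genes=tuple(sorted(set(overlapped))),
        mean_relative_position=(sum(relpos) / len(relpos)) if relpos else None,
        palindromicity=pal,
        palindromic=(pal >= palindrome_threshold) if pal is not None else None,
    )


# ---------------------------------------------------------------------------
# Antirepeat-based array-to-candidate assignment
# ---------------------------------------------------------------------------


@dataclass
class ArrayAssignment:
    array_id: str
    candidate_id: str
    e_value: float
    assigned_subtype: str
    truth_subtype: str
    agreement: bool | None  # None when the array carries no subtype label

    def __post_init__(self):
        if not (self.e_value < 0.05):
            raise ValueError("assignments require e_value < 0.05")


def _modal_subtype(
    candidate: Candidate,
    regions: dict[str, Region],
    operon_subtypes: dict[str, str],
) -> str:
    votes: dict[str, int] = {}
    for inst in candidate.instances:
        region = regions.get(inst.region_id)
        if region is None:
            continue
        for locus in region.member_loci:
            st = operon_subtypes.get(locus)
            if st:
                votes[st] = votes.get(st, 0) + 1
    if not votes:
        return ""
    return sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def antirepeat_assign(
    arrays: list[CrisprArray],
    candidates: list[Candidate],
    regions: list[Region],
    operon_subtypes: dict[str, str],
    params: ScoringParams = ScoringParams(),
    e_threshold: float = 0.05,
) -> tuple[list[ArrayAssignment], dict]:
    """Assign arrays to candidates via repeat-to-region homology.

    Each array's consensus repeat is aligned against every region;
    significant hits (E < e_threshold) that fall inside any array's
    repeat/spacer intervals are discarded as self matches; surviving hits
    intersecting a candidate instance assign the array to that candidate
    with the modal subtype of the operons the candidate occurs in.
    """
    region_map = {r.region_id: r for r in regions}
    array_zones = [iv for a in arrays for iv in a.interleaved()]
    assignments: list[ArrayAssignment] = []
    for array in sorted(arrays, key=lambda a: a.array_id):
        best: dict[str, float] = {}  # candidate_id -> best e_value
        for region in regions:
            if len(region) < params.seed_word_length:
                continue
            hits = local_align(
                array.consensus_repeat,
                region.sequence,
                params,
                query_name=array.array_id,
                subject_name=region.region_id,
            )
            for h in hits:
                if h.e_value >= e_threshold:
                    continue
                giv = Interval(
                    region.interval.contig_id,
                    region.interval.start + h.s_start,
                    region.interval.start + h.s_end,
                    h.strand,
                )
                if any(giv.overlaps(z) for z in array_zones):
                    continue  # self match to a CRISPR array
                for cand in candidates:
                    if any(giv.overlaps(inst.genome) for inst in cand.instances):
                        key = cand.candidate_id
                        if h.e_value < best.get(key, float("inf")):
                            best[key] = h.e_value
        if best:
            cand_id, e = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))[0]
            cand = next(c for c in candidates if c.candidate_id == cand_id)
            assigned = _modal_subtype(cand, region_map, operon_subtypes)
            truth = array.subtype
            assignments.append(
                ArrayAssignment(
                    array_id=array.array_id,
                    candidate_id=cand_id,
                    e_value=e,
                    assigned_subtype=assigned,
                    truth_subtype=truth,
                    agreement=(assigned == truth) if truth else None,
                )
            )
    with_truth = [a for a in assignments if a.agreement is not None]
    summary = {
        "n_arrays_assigned": len(assignments),
        "n_with_subtype_truth": len(with_truth),
        "agreement_fraction": (
            sum(a.agreement for a in with_truth) / len(with_truth) if with_truth else None
        ),
    }
    return assignments, summary


def write_categories(calls: list[CategoryCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "candidate_id\tcategory\tfrac_repeat\tfrac_gene\tfrac_cas9_upstream\t"
            "overlapped_genes\tmean_relative_position\tpalindromicity\tpalindromic\n"
        )
        for c in calls:
            mrp = "" if c.mean_relative_position is None else f"{c.mean_relative_position:.3f}"
            pal = "" if c.palindromicity is None else f"{c.palindromicity:.3f}"
            flag = "" if c.palindromic is None else str(c.palindromic).lower()
            fh.write(
                f"{c.candidate_id}\t{c.category}\t{c.frac_repeat:.3f}\t{c.frac_gene:.3f}\t"
                f"{c.frac_cas9_upstream:.3f}\t{','.join(c.overlapped_genes)}\t{mrp}\t{pal}\t{flag}\n"
            )


def write_assignments(assignments: list[ArrayAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("array_id\tcandidate_id\te_value\tassigned_subtype\ttruth_subtype\tagreement\n")
        for a in assignments:
            ag = "" if a.agreement is None else str(a.agreement).lower()
            fh.write(
                f"{a.array_id}\t{a.candidate_id}\t{a.e_value:.3g}\t{a.assigned_subtype}\t"
                f"{a.truth_subtype}\t{ag}\n"
            )
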