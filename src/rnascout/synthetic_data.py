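"""Synthetic CRISPR-Cas locus generator with a ground-truth manifest.

Generates contigs carrying labeled Cas operons, CRISPR arrays, covarying
structured-RNA families, unstructured conserved decoys, and a tracrRNA whose
antirepeat is near-reverse-complementary to an array repeat. Instances of a
family descend independently from one consensus (star phylogeny): iid
per-site substitution at rate theta, with stem substitutions replaced, with
probability rho, by a random canonical pair applied to both partners —
the compensatory-mutation signal the covariation analysis looks for.

Repeats within one array are exact copies; arrays of one subtype share a
structured repeat consensus with per-array compensatory divergence, which is
what makes direct repeats discoverable as cross-array homology.

Everything planted is recorded in a TruthManifest, the sole oracle used by
the validation layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .io_formats import (
    ContigRecord,
    CrisprArray,
    FormatError,
    GeneAnnotation,
    Interval,
    dotbracket_from_pairs,
    revcomp,
    write_arrays,
    write_fasta,
    write_genes,
)

BASES = "ACGT"
CANONICAL_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]

# gene complements per subtype; the first gene is the operon's 5' gene
SUBTYPE_GENES: dict[str, list[str]] = {
    "II-C": ["cas9", "cas1", "cas2"],
    "I-C": ["cas3", "cas5", "cas8c", "cas7"],
    "I-E": ["cas8e", "cas7", "cas5"],
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# Family specification and sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Helix:
    """A stem of `length` base pairs: positions (start5+k, end3-k) pair up."""

    start5: int
    end3: int
    length: int

    def pairs(self) -> list[tuple[int, int]]:
        return [(self.start5 + k, self.end3 - k) for k in range(self.length)]

    @property
    def loop(self) -> int:
        i_inner = self.start5 + self.length - 1
        j_inner = self.end3 - self.length + 1
        return j_inner - i_inner - 1

    def span(self) -> tuple[int, int]:
        return (self.start5, self.end3 + 1)


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    consensus_length: int
    n_instances: int
    helices: tuple[Helix, ...] = ()
    theta: float = 0.2
    rho: float = 0.9
    structured: bool = True

    def __post_init__(self):
        if self.n_instances < 3:
            raise ValueError(f"{self.family_id}: n_instances must be >= 3")
        if not (0.0 <= self.theta <= 0.5):
            raise ValueError(f"{self.family_id}: theta outside [0, 0.5]")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"{self.family_id}: rho outside [0, 1]")
        if self.structured and not self.helices:
            raise ValueError(f"{self.family_id}: structured family needs helices")
        if not self.structured and self.helices:
            raise ValueError(f"{self.family_id}: decoy family must have no helices")
        occupied: set[int] = set()
        for h in self.helices:
            if not (4 <= h.length <= 8):
                raise ValueError(f"{self.family_id}: helix length {h.length} not in 4-8")
            if h.loop < 3:
                raise ValueError(f"{self.family_id}: hairpin loop {h.loop} < 3")
            sites = {p for ij in h.pairs() for p in ij}
            if sites & occupied:
                raise ValueError(f"{self.family_id}: helices overlap")
            if min(sites) < 0 or max(sites) >= self.consensus_length:
                raise ValueError(f"{self.family_id}: helix outside consensus")
            occupied |= sites

    def pair_map(self) -> dict[int, int]:
        pm: dict[int, int] = {}
        for h in self.helices:
            for i, j in h.pairs():
                pm[i] = j
                pm[j] = i
        return pm

    def structure(self) -> str:
        return dotbracket_from_pairs(
            [p for h in self.helices for p in h.pairs()], self.consensus_length
        )


def random_family_spec(
    family_id: str,
    rng,
    structured: bool = True,
    consensus_length: int | None = None,
    n_instances: int = 10,
    theta: float = 0.2,
    rho: float = 0.9,
) -> FamilySpec:
    """Draw a family spec in the default length regime (32-109 nt)."""
    rng = _as_rng(rng)
    L = int(consensus_length if consensus_length is not None else rng.integers(32, 110))
    helices: list[Helix] = []
    if structured:
        n_helices = int(rng.integers(1, 3)) if L >= 60 else 1
        cursor = int(rng.integers(0, 4))
        for _ in range(n_helices):
            stem = int(rng.integers(4, 9))
            loop = int(rng.integers(3, 8))
            extent = 2 * stem + loop
            if cursor + extent > L:
                break
            start5 = cursor
            end3 = cursor + extent - 1
            helices.append(Helix(start5, end3, stem))
            cursor = end3 + 1 + int(rng.integers(2, 8))
        if not helices:  # short consensus: force one minimal hairpin
            helices = [Helix(0, 2 * 4 + 3 - 1, 4)]
    return FamilySpec(
        family_id=family_id,
        consensus_length=L,
        n_instances=n_instances,
        helices=tuple(helices),
        theta=theta,
        rho=rho,
        structured=structured,
    )


def _random_consensus(length: int, pair_map: dict[int, int], rng, gc: float = 0.5) -> str:
    seq = list(random_sequence(length, rng, gc))
    for i, j in pair_map.items():
        if i < j:
            a, b = CANONICAL_PAIRS[rng.integers(0, len(CANONICAL_PAIRS))]
            seq[i], seq[j] = a, b
    return "".join(seq)


def mutate_sequence(
    consensus: str,
    theta: float,
    rng,
    pair_map: dict[int, int] | None = None,
    rho: float = 0.0,
) -> tuple[str, list[tuple[int, str, str]]]:
    """One instance from a consensus by iid per-site substitution.

    A substitution at a paired site is, with probability rho, replaced by a
    random canonical pair (different from the consensus pair) written to
    both partners; otherwise only the selected side changes. Pair events
    are owned by the 5' partner: a 3'-side trigger that draws the
    compensatory branch is absorbed into its pair's dynamics rather than
    firing a second event. This keeps the realized per-site substitution
    rate of stem positions equal to that of loop positions, so structured
    and unstructured families share one sequence-identity distribution —
    only the pattern (pairing preserved or not) differs. Returns the
    instance and its mutation log (position, consensus base, new base).
    """
    rng = _as_rng(rng)
    pair_map = pair_map or {}
    seq = list(consensus)
    hit = rng.random(len(seq)) < theta
    for pos in np.flatnonzero(hit):
        pos = int(pos)
        if pos in pair_map and rng.random() < rho:
            j = pair_map[pos]
            if pos > j:
                continue  # the 5' partner owns this pair's events
            orig = (consensus[pos], consensus[j])
            # a compensatory event replaces both sides (the classic double
            # substitution); alternatives sharing a side would depress the
            # realized stem substitution rate below the loop rate
            choices = [
                p for p in CANONICAL_PAIRS if p[0] != orig[0] and p[1] != orig[1]
            ]
            a, b = choices[rng.integers(0, len(choices))]
            seq[pos], seq[j] = a, b
        else:
            cur = seq[pos]
            others = [b for b in BASES if b != cur]
            seq[pos] = others[rng.integers(0, 3)]
    instance = "".join(seq)
    log = [
        (k, consensus[k], instance[k])
        for k in range(len(seq))
        if instance[k] != consensus[k]
    ]
    return instance, log


@dataclass
class SampledFamily:
    spec: FamilySpec
    consensus: str
    structure: str
    instances: list[str]
    mutation_logs: list[list[tuple[int, str, str]]]


def sample_family(spec: FamilySpec, seed) -> SampledFamily:
    """Draw a consensus honoring the helices, then independent instances."""
    rng = _as_rng(seed)
    pm = spec.pair_map()
    consensus = _random_consensus(spec.consensus_length, pm, rng)
    instances, logs = [], []
    for _ in range(spec.n_instances):
        inst, log = mutate_sequence(consensus, spec.theta, rng, pm, spec.rho)
        instances.append(inst)
        logs.append(log)
    return SampledFamily(spec, consensus, spec.structure(), instances, logs)


# ---------------------------------------------------------------------------
# CRISPR arrays
# ---------------------------------------------------------------------------


def build_crispr_array(
    repeat: str,
    n_repeats: int,
    spacer_len_range: tuple[int, int],
    seed,
) -> tuple[str, list[Interval], list[Interval]]:
    """Concatenate exact repeat copies separated by iid random spacers.

    Intervals are array-local (contig_id 'array'); callers shift them onto
    the genome.
    """
    if n_repeats < 2:
        raise ValueError("an array needs at least 2 repeats")
    rng = _as_rng(seed)
    lo, hi = spacer_len_range
    parts: list[str] = []
    repeats: list[Interval] = []
    spacers: list[Interval] = []
    pos = 0
    for k in range(n_repeats):
        repeats.append(Interval("array", pos, pos + len(repeat), "+", "repeat"))
        parts.append(repeat)
        pos += len(repeat)
        if k < n_repeats - 1:
            slen = int(rng.integers(lo, hi + 1))
            spacers.append(Interval("array", pos, pos + slen, "+", "spacer"))
            parts.append(random_sequence(slen, rng))
            pos += slen
    return "".join(parts), repeats, spacers


# ---------------------------------------------------------------------------
# Dataset specification / truth manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSpec:
    n_contigs: int = 20
    contig_length_range: tuple[int, int] = (5000, 30000)
    n_operons: int = 10
    families: tuple[FamilySpec, ...] | None = None
    n_structured_families: int = 6
    n_decoy_families: int = 4
    family_instances_range: tuple[int, int] = (8, 12)
    theta: float = 0.2
    rho: float = 0.9
    n_arrays: int = 8
    repeat_length_range: tuple[int, int] = (30, 40)
    spacer_length_range: tuple[int, int] = (30, 40)
    repeats_per_array: tuple[int, int] = (4, 10)
    repeat_divergence: float = 0.08
    tracr: bool = True
    antirepeat_divergence: float = 0.10
    gc: float = 0.5
    seed: int = 0
    # (subtype, number of operons); operons beyond the listed total cycle
    subtype_plan: tuple[tuple[str, int], ...] = (("II-C", 5), ("I-C", 3), ("I-E", 2))

    def __post_init__(self):
        if self.contig_length_range[0] <= 3000:
            raise ValueError("contig lengths must exceed 3000")


@dataclass(frozen=True)
class TruthRecord:
    rtype: str  # family_instance, decoy_instance, repeat, spacer, gene, tracr, antirepeat
    interval: Interval
    family_id: str = ""
    array_id: str = ""
    operon_id: str = ""
    subtype: str = ""


@dataclass
class TruthManifest:
    records: list[TruthRecord] = field(default_factory=list)

    def add(self, rec: TruthRecord) -> None:
        self.records.append(rec)

    def by_type(self, rtype: str) -> list[TruthRecord]:
        return [r for r in self.records if r.rtype == rtype]

    def family_ids(self, rtype: str = "family_instance") -> list[str]:
        return sorted({r.family_id for r in self.by_type(rtype)})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("type\tcontig\tstart\tend\tstrand\tfamily_id\tarray_id\toperon_id\tsubtype\n")
            for r in self.records:
                iv = r.interval
                fh.write(
                    f"{r.rtype}\t{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{r.family_id}\t{r.array_id}\t{r.operon_id}\t{r.subtype}\n"
                )

    @staticmethod
    def read(path: str | Path) -> "TruthManifest":
        manifest = TruthManifest()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("type\t")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                manifest.add(
                    TruthRecord(
                        rtype=f[0],
                        interval=Interval(f[1], int(f[2]), int(f[3]), f[4]),
                        family_id=f[5],
                        array_id=f[6],
                        operon_id=f[7],
                        subtype=f[8],
                    )
                )
        return manifest


@dataclass
class GeneratedDataset:
    spec: DatasetSpec
    contigs: list[ContigRecord]
    genes: list[GeneAnnotation]
    arrays: list[CrisprArray]
    truth: TruthManifest

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "contigs.fasta")
        write_genes(self.genes, outdir / "genes.tsv")
        write_arrays(self.arrays, outdir / "arrays.tsv")
        self.truth.write(outdir / "truth.tsv")


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


class _Occupancy:
    """Per-contig tracker of planted sequence intervals (no overlaps allowed)."""

    def __init__(self):
        self._taken: dict[str, list[tuple[int, int]]] = {}

    def free(self, contig: str, start: int, end: int) -> bool:
        for s, e in self._taken.get(contig, ()):
            if start < e and s < end:
                return False
        return True

    def take(self, contig: str, start: int, end: int) -> None:
        self._taken.setdefault(contig, []).append((start, end))


def _place(
    rng,
    occ: _Occupancy,
    contig: str,
    length: int,
    lo: int,
    hi: int,
    tries: int = 60,
    take: bool = True,
) -> int | None:
    """Random non-overlapping placement of `length` bases within [lo, hi)."""
    if hi - lo < length:
        return None
    for _ in range(tries):
        start = int(rng.integers(lo, hi - length + 1))
        if occ.free(contig, start, start + length):
            if take:
                occ.take(contig, start, start + length)
            return start
    return None


def _repeat_consensus(length: int, rng, gc: float) -> tuple[str, dict[int, int]]:
    """A structured repeat consensus: random sequence with one planted hairpin."""
    stem = int(rng.integers(5, 8))
    loop = int(rng.integers(3, 6))
    extent = 2 * stem + loop
    offset = int(rng.integers(1, max(2, length - extent)))
    helix = Helix(offset, offset + extent - 1, stem)
    pm = {i: j for i, j in helix.pairs()}
    pm.update({j: i for i, j in helix.pairs()})
    seq = list(random_sequence(length, rng, gc))
    for i, j in pm.items():
        if i < j:
            a, b = CANONICAL_PAIRS[rng.integers(0, len(CANONICAL_PAIRS))]
            seq[i], seq[j] = a, b
    return "".join(seq), pm


def generate_dataset(spec: DatasetSpec) -> GeneratedDataset:
    """Generate contigs, annotations and the ground-truth manifest.

    Deterministic: the same spec (including seed) yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    occ = _Occupancy()
    truth = TruthManifest()

    lo, hi = spec.contig_length_range
    contig_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_contigs)]
    contig_ids = [f"contig{i:03d}" for i in range(spec.n_contigs)]
    contig_seqs = {
        cid: list(random_sequence(n, rng, spec.gc))
        for cid, n in zip(contig_ids, contig_lengths)
    }
    length_of = dict(zip(contig_ids, contig_lengths))

    # -- operon plan ------------------------------------------------------
    subtype_seq: list[str] = []
    for st, n in spec.subtype_plan:
        subtype_seq.extend([st] * n)
    while len(subtype_seq) < spec.n_operons:
        subtype_seq.append(spec.subtype_plan[len(subtype_seq) % len(spec.subtype_plan)][0])
    subtype_seq = subtype_seq[: spec.n_operons]

    if spec.n_operons > spec.n_contigs:
        raise FormatError("generator places at most one operon per contig")
    # one operon per contig, on the longest contigs so everything fits
    by_length = sorted(range(spec.n_contigs), key=lambda i: -contig_lengths[i])
    operon_contigs = by_length[: spec.n_operons]

    genes: list[GeneAnnotation] = []
    operons: list[dict] = []
    for k, (st, ci) in enumerate(zip(subtype_seq, operon_contigs)):
        cid = contig_ids[int(ci)]
        operon_id = f"op{k:02d}"
        gene_names = SUBTYPE_GENES.get(st, ["cas1", "cas2"])
        gene_lengths = [
            int(rng.integers(1200, 1801)) if name == "cas9" else int(rng.integers(600, 1001))
            for name in gene_names
        ]
        gaps = [int(rng.integers(60, 201)) for _ in gene_names[:-1]]
        span_len = sum(gene_lengths) + sum(gaps)
        margin = 700  # room for the 500 bp flank plus planted flank elements
        # reserve room downstream for a CRISPR array where one may attach.
        # Only the reserve is marked occupied: gene intervals are annotations
        # over background sequence, so planted RNAs may overlap them (the
        # coding-overlap regime) — they must only avoid other planted elements.
        reserve = 1300 if st in ("II-C", "I-C") else 0
        start = _place(
            rng, occ, cid, span_len + reserve, margin, length_of[cid] - margin, take=False
        )
        if start is None:
            raise FormatError(f"could not place operon {operon_id} on {cid}")
        if reserve:
            occ.take(cid, start + span_len, start + span_len + reserve)
        pos = start
        op_genes: list[GeneAnnotation] = []
        for gi, (name, glen) in enumerate(zip(gene_names, gene_lengths)):
            giv = Interval(cid, pos, pos + glen, "+", name)
            g = GeneAnnotation(giv, name, operon_id, st)
            op_genes.append(g)
            truth.add(TruthRecord("gene", giv, operon_id=operon_id, subtype=st))
            pos += glen
            if gi < len(gaps):
                pos += gaps[gi]
        genes.extend(op_genes)
        operons.append(
            {
                "operon_id": operon_id,
                "contig": cid,
                "subtype": st,
                "span": (start, pos),
                "genes": op_genes,
            }
        )

    # -- subtype repeat consensi and arrays -------------------------------
    rep_lo, rep_hi = spec.repeat_length_range
    repeat_consensus: dict[str, tuple[str, dict[int, int]]] = {}
    arrays: list[CrisprArray] = []
    array_source: dict[str, dict] = {}  # array_id -> operon record
    array_repeat: dict[str, str] = {}

    hosts = [op for op in operons if op["subtype"] in ("II-C", "I-C")]
    hosts = hosts[: spec.n_arrays]
    for k, op in enumerate(hosts):
        st = op["subtype"]
        if st not in repeat_consensus:
            rep_len = int(rng.integers(rep_lo, rep_hi + 1))
            repeat_consensus[st] = _repeat_consensus(rep_len, rng, spec.gc)
        cons, pm = repeat_consensus[st]
        rep, _ = mutate_sequence(cons, spec.repeat_divergence, rng, pm, rho=0.9)
        n_rep = int(rng.integers(spec.repeats_per_array[0], spec.repeats_per_array[1] + 1))
        arr_seq, rep_ivs, spc_ivs = build_crispr_array(
            rep, n_rep, spec.spacer_length_range, rng
        )
        cid = op["contig"]
        gap = int(rng.integers(100, 301))
        # the operon placement reserved 1300 bp downstream for the array
        arr_start = op["span"][1] + gap
        if arr_start + len(arr_seq) > length_of[cid] - 600:
            raise FormatError(f"could not place array near {op['operon_id']}")
        contig_seqs[cid][arr_start : arr_start + len(arr_seq)] = list(arr_seq)
        array_id = f"arr{k:02d}"
        shift = lambda iv: Interval(cid, iv.start + arr_start, iv.end + arr_start, "+", iv.label)  # noqa: E731
        g_reps = tuple(shift(iv) for iv in rep_ivs)
        g_spcs = tuple(shift(iv) for iv in spc_ivs)
        arrays.append(
            CrisprArray(
                array_id=array_id,
                repeat_intervals=g_reps,
                spacer_intervals=g_spcs,
                consensus_repeat=rep,
                subtype=st,
                subtype_probability=float(np.round(rng.uniform(0.7, 0.99), 3)),
            )
        )
        array_source[array_id] = op
        array_repeat[array_id] = rep
        for iv in g_reps:
            truth.add(TruthRecord("repeat", iv, array_id=array_id, operon_id=op["operon_id"], subtype=st))
        for iv in g_spcs:
            truth.add(TruthRecord("spacer", iv, array_id=array_id, operon_id=op["operon_id"], subtype=st))
        op["array_id"] = array_id

    # -- tracrRNA upstream of cas9 in II-C operons ------------------------
    if spec.tracr:
        # conserved 3' stem-loop tail shared by all tracr copies
        tail_stem = int(rng.integers(6, 9))
        tail_loop_len = int(rng.integers(4, 7))
        stem5 = random_sequence(tail_stem, rng, gc=0.6)
        tail_cons = stem5 + random_sequence(tail_loop_len, rng) + revcomp(stem5)
        tail_helix = Helix(0, len(tail_cons) - 1, tail_stem)
        tail_pm = {i: j for i, j in tail_helix.pairs()}
        tail_pm.update({j: i for i, j in tail_helix.pairs()})
        linker = random_sequence(4, rng)
        mu = spec.antirepeat_divergence
        for op in operons:
            if op["subtype"] != "II-C" or "array_id" not in op:
                continue
            cas9 = next((g for g in op["genes"] if g.gene_name == "cas9"), None)
            if cas9 is None:
                continue
            rep = array_repeat[op["array_id"]]
            anti, _ = mutate_sequence(revcomp(rep), mu, rng)
            tail, _ = mutate_sequence(tail_cons, mu, rng, tail_pm, rho=0.9)
            tracr_seq = anti + linker + tail
            gap = int(rng.integers(5, 26))
            end = cas9.interval.start - gap
            start = end - len(tracr_seq)
            cid = op["contig"]
            if start < 0 or not occ.free(cid, start, end):
                raise FormatError(f"could not place tracr upstream of {op['operon_id']}")
            occ.take(cid, start, end)
            contig_seqs[cid][start:end] = list(tracr_seq)
            truth.add(
                TruthRecord(
                    "tracr",
                    Interval(cid, start, end, "+", "tracr"),
                    family_id="tracr",
                    array_id=op["array_id"],
                    operon_id=op["operon_id"],
                    subtype=op["subtype"],
                )
            )
            truth.add(
                TruthRecord(
                    "antirepeat",
                    Interval(cid, start, start + len(anti), "+", "antirepeat"),
                    family_id="tracr",
                    array_id=op["array_id"],
                    operon_id=op["operon_id"],
                    subtype=op["subtype"],
                )
            )

    # -- structured families and decoys -----------------------------------
    families = spec.families
    if families is None:
        fams: list[FamilySpec] = []
        n_lo, n_hi = spec.family_instances_range
        for i in range(spec.n_structured_families):
            fams.append(
                random_family_spec(
                    f"fam{i:02d}",
                    rng,
                    structured=True,
                    n_instances=int(rng.integers(n_lo, n_hi + 1)),
                    theta=spec.theta,
                    rho=spec.rho,
                )
            )
        for i in range(spec.n_decoy_families):
            fams.append(
                random_family_spec(
                    f"decoy{i:02d}",
                    rng,
                    structured=False,
                    n_instances=int(rng.integers(n_lo, n_hi + 1)),
                    theta=spec.theta,
                    rho=spec.rho,
                )
            )
        families = tuple(fams)

    for fam in families:
        sampled = sample_family(fam, rng)
        rtype = "family_instance" if fam.structured else "decoy_instance"
        # spread instances over distinct operon loci where possible
        order = list(rng.permutation(len(operons)))
        for idx, inst in enumerate(sampled.instances):
            placed = False
            for attempt in range(len(operons)):
                op = operons[order[(idx + attempt) % len(operons)]]
                cid = op["contig"]
                span = op["span"]
                zone_lo = max(0, span[0] - 450)
                zone_hi = min(length_of[cid], span[1] + 450)
                start = _place(rng, occ, cid, len(inst), zone_lo, zone_hi, tries=40)
                if start is not None:
                    contig_seqs[cid][start : start + len(inst)] = list(inst)
                    truth.add(
                        TruthRecord(
                            rtype,
                            Interval(cid, start, start + len(inst), "+", fam.family_id),
                            family_id=fam.family_id,
                            operon_id=op["operon_id"],
                            subtype=op["subtype"],
                        )
                    )
                    placed = True
                    break
            if not placed:
                raise FormatError(
                    f"could not place instance {idx} of {fam.family_id}"
                )

    contigs = [ContigRecord(cid, "".join(contig_seqs[cid])) for cid in contig_ids]
    for rec in truth.records:
        iv = rec.interval
        if not (0 <= iv.start < iv.end <= length_of[iv.contig_id]):
            raise FormatError(f"manifest interval out of bounds: {rec}")
    return GeneratedDataset(spec, contigs, genes, arrays, truth)
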