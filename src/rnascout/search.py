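"""Scannable motif models, shuffled-null E-values, and candidate retention.

Each surviving motif becomes an ungapped profile+pair model over its match
columns (columns with under 50% gaps): per-column log-odds plus per-pair
log-odds for the consensus structure's pairs. Models are scanned across
both strands of every region; score significance comes from scanning
dinucleotide-preserving shuffles of the same regions and fitting the
extreme right tail, giving E-values on the scale "expected null windows at
or above this score in a search of this size". Models that re-detect at
least `min_regions` distinct regions at a stringent E-value are retained
as candidates; overlapping candidates are deduplicated longest-first, and
candidates overlapping known structures are subtracted.

The scan is deliberately ungapped and fixed-width: indel-tolerant
covariance-model search is a major tool in its own right, and the model
here preserves the retention semantics (stringent E, multiple distinct
regions) rather than the alignment algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io_formats import Interval, revcomp
from .motif import MotifAlignment, _one_hot_rows
from .region_prep import Region

log = logging.getLogger(__name__)

_ENC = {c: i for i, c in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, 4) for c in seq], dtype=np.int64)


def background_frequencies(regions: list[Region]) -> np.ndarray:
    """Mononucleotide frequencies over the region set (floor 1e-3, renormalized)."""
    counts = np.zeros(4)
    for r in regions:
        enc = _encode(r.sequence)
        for b in range(4):
            counts[b] += int((enc == b).sum())
    total = counts.sum()
    freqs = counts / total if total else np.full(4, 0.25)
    freqs = np.maximum(freqs, 1e-3)
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------


@dataclass
class MotifModel:
    """Ungapped profile+pair log-odds model over match columns."""

    model_id: str
    width: int
    column_lo: np.ndarray = field(repr=False)  # (W, 5); N column = 0
    pairs: list[tuple[int, int]] = field(default_factory=list)
    pair_lo: list[np.ndarray] = field(default_factory=list)  # (5,5) each
    match_columns: np.ndarray = field(default=None, repr=False)
    consensus: str = ""
    bg: np.ndarray = field(default=None, repr=False)


def build_model(
    motif: MotifAlignment, bg: np.ndarray, max_gap_frac: float = 0.5
) -> MotifModel:
    """Profile+pair model from a motif alignment.

    Match columns are those with under `max_gap_frac` gaps. Column
    log-odds: log2((count+1)/(N+4)/bg). Pair log-odds for structure pairs
    with both ends on match columns: log2(((count+1/16)/(n+1))/(bg_a*bg_b)).
    Ambiguous bases score 0 (the background expectation).
    """
    aln = motif.alignment
    X = _one_hot_rows(aln.rows)[:, :, :4]  # (N, width, 4)
    N = aln.n_seqs
    gap_frac = 1.0 - X.sum(axis=2).mean(axis=0)
    match_cols = np.flatnonzero(gap_frac < max_gap_frac)
    if len(match_cols) == 0:
        raise ValueError(f"{motif.cluster_id}: no match columns")
    W = len(match_cols)
    counts = X.sum(axis=0)[match_cols]  # (W, 4)
    lo = np.zeros((W, 5))
    lo[:, :4] = np.log2((counts + 1.0) / (N + 4.0) / bg[None, :])
    col_of = {int(c): k for k, c in enumerate(match_cols)}
    pairs: list[tuple[int, int]] = []
    pair_lo: list[np.ndarray] = []
    for i, j in aln.pairs():
        if i in col_of and j in col_of:
            both = (X[:, i, :].sum(axis=1) > 0) & (X[:, j, :].sum(axis=1) > 0)
            n_ij = int(both.sum())
            joint = X[both, i, :].T @ X[both, j, :]  # (4,4)
            tab = np.zeros((5, 5))
            tab[:4, :4] = np.log2(
                ((joint + 1.0 / 16.0) / (n_ij + 1.0)) / np.outer(bg, bg)
            )
            pairs.append((col_of[i], col_of[j]))
            pair_lo.append(tab)
    consensus = "".join("ACGT"[int(k)] for k in counts.argmax(axis=1))
    return MotifModel(
        model_id=motif.cluster_id,
        width=W,
        column_lo=lo,
        pairs=pairs,
        pair_lo=pair_lo,
        match_columns=match_cols,
        consensus=consensus,
        bg=bg,
    )


def refit_model(
    model: MotifModel, sequences: list[str], rounds: int = 2, min_members: int = 3
) -> MotifModel:
    """Re-estimate model counts from ungapped best-window fits to members.

    Alignment gaps that survive into match columns shift the register of
    some members relative to the model; because the scan is ungapped, a
    shifted register halves a true instance's score. Refitting scans each
    member with the current model, takes its best full-length window, and
    recomputes column and pair counts from those register-consistent
    windows — a small EM-style polish. Pair positions are inherited.

    Safeguards: the input model is returned unchanged when fewer than 80%
    of members span the model width (a refit from a minority would drift
    toward it), and the refit model is only adopted when it scores the
    spanning members at least as well as the original on average.
    """
    spanning = [s for s in sequences if len(s) >= model.width]
    if len(spanning) < max(min_members, int(np.ceil(0.8 * len(sequences)))):
        return model

    def _mean_best(m: MotifModel) -> float:
        return float(
            np.mean([scan_sequence(m, s).max() for s in spanning])
        )

    cur = model
    for _ in range(rounds):
        windows: list[str] = []
        for s in sequences:
            if len(s) < cur.width:
                continue
            sc = scan_sequence(cur, s)
            b = int(np.argmax(sc))
            windows.append(s[b : b + cur.width])
        if len(windows) < min_members:
            return cur
        X = np.zeros((len(windows), cur.width, 4))
        for r, w in enumerate(windows):
            for c, ch in enumerate(w):
                k = _ENC.get(ch, 4)
                if k < 4:
                    X[r, c, k] = 1.0
        N = len(windows)
        counts = X.sum(axis=0)
        lo = np.zeros((cur.width, 5))
        lo[:, :4] = np.log2((counts + 1.0) / (N + 4.0) / cur.bg[None, :])
        pair_lo = []
        for i, j in cur.pairs:
            both = (X[:, i, :].sum(axis=1) > 0) & (X[:, j, :].sum(axis=1) > 0)
            n_ij = int(both.sum())
            joint = X[both, i, :].T @ X[both, j, :]
            tab = np.zeros((5, 5))
            tab[:4, :4] = np.log2(
                ((joint + 1.0 / 16.0) / (n_ij + 1.0)) / np.outer(cur.bg, cur.bg)
            )
            pair_lo.append(tab)
        cur = MotifModel(
            model_id=cur.model_id,
            width=cur.width,
            column_lo=lo,
            pairs=list(cur.pairs),
            pair_lo=pair_lo,
            match_columns=cur.match_columns,
            consensus="".join("ACGT"[int(k)] for k in counts.argmax(axis=1)),
            bg=cur.bg,
        )
    return cur if _mean_best(cur) > _mean_best(model) else model


def trim_model(model: MotifModel, min_info: float = 0.4) -> MotifModel:
    """Trim uninformative edge columns (flank context) off a model.

    Column information content (relative entropy of the implied column
    distribution against the background, in bits) separates conserved
    motif columns (~1 bit at the divergence levels modeled here) from
    flanking background (sampling noise, ~0.1-0.2 bits). The model is cut
    to the first..last column with information >= min_info; structure
    pairs falling outside are dropped.
    """
    probs = model.bg[None, :] * np.exp2(model.column_lo[:, :4])
    probs = probs / probs.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = np.nansum(probs * np.log2(probs / model.bg[None, :]), axis=1)
    core = np.flatnonzero(info >= min_info)
    if len(core) == 0:
        return model
    lo, hi = int(core[0]), int(core[-1]) + 1
    if lo == 0 and hi == model.width:
        return model
    pairs, pair_lo = [], []
    for (i, j), tab in zip(model.pairs, model.pair_lo):
        if lo <= i < hi and lo <= j < hi:
            pairs.append((i - lo, j - lo))
            pair_lo.append(tab)
    return MotifModel(
        model_id=model.model_id,
        width=hi - lo,
        column_lo=model.column_lo[lo:hi],
        pairs=pairs,
        pair_lo=pair_lo,
        match_columns=(
            model.match_columns[lo:hi] if model.match_columns is not None else None
        ),
        consensus=model.consensus[lo:hi],
        bg=model.bg,
    )


def member_placements(
    model: MotifModel,
    sequences: list[str],
    min_cov: float = 0.5,
    min_fraction: float = 0.7,
) -> list[str] | None:
    """Best ungapped placement of each member against the model, gap-padded.

    The motif stage's EM-style inner loop: every member slides freely
    across the model (overhangs allowed, so members near the model width
    are never forced into a shifted register) and is emitted as a width-W
    row, gaps outside its footprint. Placements must cover at least
    min_cov of min(model width, member length); members with no adequate
    placement are dropped. Returns None when fewer than
    max(3, min_fraction*N) members place — the realignment would discard
    too much of the cluster.
    """
    W = model.width
    rows: list[str] = []
    for s in sequences:
        L = len(s)
        enc = _encode(s)
        n_place = W + L - 1  # start columns -(L-1) .. W-1
        ext = np.zeros((n_place + L - 1, 5))
        ext[L - 1 : L - 1 + W] = model.column_lo
        scores = np.zeros(n_place)
        for p in range(L):
            scores += ext[p : p + n_place, enc[p]]
        starts = np.arange(-(L - 1), W)
        overlap = np.minimum(W, starts + L) - np.maximum(0, starts)
        ok = overlap >= min_cov * min(W, L)
        if not ok.any():
            continue
        scores = np.where(ok, scores, -np.inf)
        k = int(np.argmax(scores))
        c = int(starts[k])
        frag = s[max(0, -c) : min(L, W - c)]
        left = max(0, c)
        rows.append("-" * left + frag + "-" * (W - left - len(frag)))
    if len(rows) < max(3, int(np.ceil(min_fraction * len(sequences)))):
        return None
    return rows


def score_window(model: MotifModel, window: str) -> float:
    """Score one length-W window (independent recomputation path)."""
    if len(window) != model.width:
        raise ValueError("window length != model width")
    enc = _encode(window)
    s = float(sum(model.column_lo[c, enc[c]] for c in range(model.width)))
    for (i, j), tab in zip(model.pairs, model.pair_lo):
        s += float(tab[enc[i], enc[j]])
    return s


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def scan_sequence(model: MotifModel, seq: str) -> np.ndarray:
    """Scores of every window on one strand of one sequence (may be empty)."""
    W = model.width
    n_win = len(seq) - W + 1
    if n_win <= 0:
        return np.empty(0)
    enc = _encode(seq)
    scores = np.zeros(n_win)
    for c in range(W):
        scores += model.column_lo[c, enc[c : c + n_win]]
    for (i, j), tab in zip(model.pairs, model.pair_lo):
        scores += tab.ravel()[enc[i : i + n_win] * 5 + enc[j : j + n_win]]
    return scores


def scan(model: MotifModel, regions: list[Region]) -> dict[tuple[str, str], np.ndarray]:
    """All window scores on both strands of every region.

    Keys are (region_id, strand); minus-strand scores index windows on the
    reverse-complemented sequence. Regions shorter than the model are
    skipped with a log entry.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    for r in regions:
        if len(r) < model.width:
            log.info("region %s shorter than model %s; skipped", r.region_id, model.model_id)
            continue
        out[(r.region_id, "+")] = scan_sequence(model, r.sequence)
        out[(r.region_id, "-")] = scan_sequence(model, revcomp(r.sequence))
    return out


# ---------------------------------------------------------------------------
# Null calibration: dinucleotide shuffle + empirical/Gumbel tail
# ---------------------------------------------------------------------------


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    edges.setdefault(seq[-1], [])
    vertices = list(edges)
    last = seq[-1]
    # choose a random "final edge" per vertex forming a tree into `last`
    for _attempt in range(1000):
        final: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            outs = edges[v]
            if not outs:
                ok = False
                break
            final[v] = outs[int(rng.integers(0, len(outs)))]
        if not ok:
            break
        good = True
        for v in final:
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in final:
                    good = False
                    break
                seen.add(u)
                u = final[u]
            if not good:
                break
        if good:
            shuffled: dict[str, list[str]] = {}
            for v in vertices:
                outs = list(edges[v])
                if v in final:
                    outs.remove(final[v])
                perm = rng.permutation(len(outs))
                outs = [outs[int(k)] for k in perm]
                if v in final:
                    outs.append(final[v])
                shuffled[v] = outs
            walk = [seq[0]]
            ptr = {v: 0 for v in vertices}
            u = seq[0]
            for _ in range(len(seq) - 1):
                nxt = shuffled[u][ptr[u]]
                ptr[u] += 1
                walk.append(nxt)
                u = nxt
            return "".join(walk)
    return seq  # degenerate composition; identity preserves dinucleotides


class EValueCalibration:
    """E(s) = M * P(null window score >= s) with a fitted Gumbel right tail.

    The survival probability is empirical inside the null sample's range
    and switches to a Gumbel tail (ML fit on the top 1% of null scores)
    beyond the 99th percentile, keeping E monotone nonincreasing in s.
    """

    def __init__(self, null_scores: np.ndarray, m_total_windows: int):
        null_scores = np.asarray(null_scores, dtype=float)
        if null_scores.std() == 0:
            raise ValueError("degenerate null score variance")
        self.sorted_null = np.sort(null_scores)
        self.m_total = int(m_total_windows)
        self.q99 = float(np.quantile(self.sorted_null, 0.99))
        tail = self.sorted_null[self.sorted_null >= self.q99]
        self.sf99 = len(tail) / len(self.sorted_null)
        if len(tail) >= 10 and tail.std() > 0:
            loc, scale = sps.gumbel_r.fit(tail)
            self.tail_dist = sps.gumbel_r(loc=loc, scale=scale)
            self.tail_ref = max(self.tail_dist.sf(self.q99), 1e-300)
        else:
            self.tail_dist = None
            self.tail_ref = 1.0

    def sf(self, score: float) -> float:
        n = len(self.sorted_null)
        if score <= self.q99 or self.tail_dist is None:
            k = n - np.searchsorted(self.sorted_null, score, side="left")
            return max(float(k), 0.5) / n  # floor: never report a hard zero
        return self.sf99 * float(self.tail_dist.sf(score)) / self.tail_ref

    def __call__(self, score: float) -> float:
        return self.m_total * self.sf(score)


def calibrate(
    model: MotifModel,
    regions: list[Region],
    n_shuffles: int = 5,
    seed=0,
    min_null_windows: int = 10_000,
) -> EValueCalibration:
    """Score dinucleotide-preserving shuffles of all regions to calibrate E.

    The search-space size M is the number of windows in the real search
    (both strands of all regions).
    """
    rng = np.random.default_rng(seed)
    null_scores = []
    m_total = 0
    for r in regions:
        n_win = len(r) - model.width + 1
        if n_win <= 0:
            continue
        m_total += 2 * n_win
        for _ in range(n_shuffles):
            sh = dinucleotide_shuffle(r.sequence, rng)
            null_scores.append(scan_sequence(model, sh))
            null_scores.append(scan_sequence(model, revcomp(sh)))
    if not null_scores:
        raise ValueError("no null windows: all regions shorter than the model")
    null = np.concatenate(null_scores)
    if len(null) < min_null_windows:
        log.warning(
            "null sample for %s has %d windows (< %d)", model.model_id, len(null), min_null_windows
        )
    return EValueCalibration(null, m_total)


# ---------------------------------------------------------------------------
# Candidate retention, dedup, known-structure subtraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Instance:
    region_id: str
    start: int  # region-local, on the scanned strand's coordinates
    end: int
    strand: str
    score: float
    e_value: float
    genome: Interval


@dataclass
class Candidate:
    candidate_id: str
    model: MotifModel
    motif: MotifAlignment
    instances: list[Instance]
    category: str = ""
    palindromicity: float | None = None

    @property
    def length(self) -> int:
        return self.model.width

    @property
    def regions_hit(self) -> set[str]:
        return {inst.region_id for inst in self.instances}


def find_instances(
    model: MotifModel,
    scans: dict[tuple[str, str], np.ndarray],
    efunc: EValueCalibration,
    regions: list[Region] | dict[str, Region],
    e_threshold: float = 1e-6,
) -> list[Instance]:
    """Significant scan windows merged into peak instances.

    Overlapping significant windows on one region/strand collapse to the
    best-scoring window of each run.
    """
    region_map = (
        regions if isinstance(regions, dict) else {r.region_id: r for r in regions}
    )
    W = model.width
    instances: list[Instance] = []
    for (region_id, strand), scores in sorted(scans.items()):
        if len(scores) == 0:
            continue
        evals = efunc.m_total * np.array([efunc.sf(s) for s in scores])
        sig = np.flatnonzero(evals < e_threshold)
        if len(sig) == 0:
            continue
        region = region_map[region_id]
        runs: list[list[int]] = [[int(sig[0])]]
        for p in sig[1:]:
            if int(p) - runs[-1][-1] < W:  # windows overlap
                runs[-1].append(int(p))
            else:
                runs.append([int(p)])
        for run in runs:
            best = max(run, key=lambda p: (scores[p], -p))
            start, end = best, best + W
            if strand == "+":
                g0, g1 = start, end
            else:
                g0, g1 = len(region) - end, len(region) - start
            instances.append(
                Instance(
                    region_id=region_id,
                    start=start,
                    end=end,
                    strand=strand,
                    score=float(scores[best]),
                    e_value=float(evals[best]),
                    genome=Interval(
                        region.interval.contig_id,
                        region.interval.start + g0,
                        region.interval.start + g1,
                        strand,
                    ),
                )
            )
    return instances


def retain_searchable(
    models: list[tuple[MotifAlignment, MotifModel, list[Instance]]],
    e_threshold: float = 1e-6,
    min_regions: int = 3,
) -> list[Candidate]:
    """Keep models whose significant instances cover >= min_regions regions."""
    out: list[Candidate] = []
    for motif, model, instances in models:
        instances = [i for i in instances if i.e_value < e_threshold]
        if len({i.region_id for i in instances}) >= min_regions:
            out.append(
                Candidate(
                    candidate_id=model.model_id,
                    model=model,
                    motif=motif,
                    instances=instances,
                )
            )
    return out


def dedup(candidates: list[Candidate]) -> list[Candidate]:
    """Greedy longest-first removal of candidates sharing genomic loci.

    Candidates are processed in decreasing model width (ties: candidate_id
    ascending); one is kept only if none of its instances overlaps (>= 1 bp,
    genome coordinates) an instance of an already-kept candidate.
    """
    kept: list[Candidate] = []
    for cand in sorted(candidates, key=lambda c: (-c.length, c.candidate_id)):
        clash = any(
            ki.genome.overlaps(ci.genome)
            for k in kept
            for ki in k.instances
            for ci in cand.instances
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: c.candidate_id)
    return kept


def subtract_known(
    candidates: list[Candidate], known: list[Interval]
) -> list[Candidate]:
    """Drop candidates with any instance overlapping a known-structure interval."""
    if not known:
        return list(candidates)
    out = []
    for cand in candidates:
        if any(inst.genome.overlaps(k) for inst in cand.instances for k in known):
            continue
        out.append(cand)
    return out
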