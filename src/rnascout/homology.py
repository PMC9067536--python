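"""All-vs-all seeded local alignment of regions with Karlin-Altschul statistics.

The aligner is a heuristic in the classic seed-and-extend mould: exact seed
words shared between query and subject (both strands) nucleate an ungapped
extension; promising segments are then re-aligned by banded gapped
Smith-Waterman, and locally optimal, non-overlapping alignments are
reported. Raw scores convert to bit scores and E-values with fixed
Karlin-Altschul parameters for the +2/-3 (5,2) score system.

Seed word length: the default is 7. The classic nucleotide-BLAST default of
11 requires ~90% sequence identity before two homologs are likely to share
an exact word; at the 60-70% identity regime this pipeline targets, the
expected number of shared 11-mers between two ~60 nt homologs is well below
one, whereas 7-mers give about one shared word per true pair. Word length
remains configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import revcomp

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (incl. N) = 4; N never matches."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringParams:
    """Fixed score system with its Karlin-Altschul parameters.

    match/mismatch/gap values mirror nucleotide-BLAST defaults (+2/-3,
    gap existence 5, extension 2: a gap of length k costs 5 + 2k). The
    lambda/K pair is the standard table entry for that system.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 0.625
    K: float = 0.41
    seed_word_length: int = 7

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """A filtered local-alignment match between two region substrings.

    Subject coordinates are always on the subject's plus strand; `strand`
    records the strand of the subject segment that aligned.
    """

    query_region: str
    q_start: int
    q_end: int
    subject_region: str
    s_start: int
    s_end: int
    strand: str
    identity_pct: float
    aln_len: int
    matches: int
    raw_score: int
    bit_score: float
    e_value: float

    def __post_init__(self):
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if not (0.0 < self.identity_pct <= 100.0):
            raise ValueError("identity_pct outside (0, 100]")


def bit_and_evalue(
    raw_score: int, params: ScoringParams, m: int, n: int
) -> tuple[float, float]:
    """Karlin-Altschul conversion of a raw local-alignment score.

    bit = (lambda*S - ln K) / ln 2;  E = K * m * n * exp(-lambda*S).
    """
    if m <= 0 or n <= 0:
        raise ValueError("search-space lengths m, n must be positive")
    bit = (params.lam * raw_score - math.log(params.K)) / math.log(2)
    e = params.K * m * n * math.exp(-params.lam * raw_score)
    return bit, e


# ---------------------------------------------------------------------------
# Seeding and ungapped extension
# ---------------------------------------------------------------------------


def _kmer_hashes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for t in range(k):
        chunk = enc[t : t + n]
        h = h * 4 + chunk
        valid &= chunk < 4
    idx = np.flatnonzero(valid)
    return h[idx], idx


def _seed_pairs(
    enc_a: np.ndarray, enc_b: np.ndarray, k: int, cap: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with a[i:i+k] == b[j:j+k], N-free; truncated at cap."""
    ha, ia = _kmer_hashes(enc_a, k)
    hb, ib = _kmer_hashes(enc_b, k)
    if len(ha) == 0 or len(hb) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(hb, kind="stable")
    hb_sorted = hb[order]
    left = np.searchsorted(hb_sorted, ha, side="left")
    right = np.searchsorted(hb_sorted, ha, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qi = np.repeat(ia, counts)
    sj_chunks = [order[l:r] for l, r in zip(left, right) if r > l]
    sj = ib[np.concatenate(sj_chunks)]
    if len(qi) > cap:
        qi, sj = qi[:cap], sj[:cap]
    return qi.astype(np.int64), sj.astype(np.int64)


_NEG = -(10**6)


def _ungapped_stats(
    enc_a: np.ndarray,
    enc_b: np.ndarray,
    qi: np.ndarray,
    sj: np.ndarray,
    params: ScoringParams,
    window: int,
    min_seg_len: int,
):
    """Vectorized Kadane around each seed.

    Returns per-seed best segment score (any length), best score among
    segments of length >= min_seg_len, and the prefix-sum matrix pieces
    needed to recover extents for selected seeds.
    """
    k = params.seed_word_length
    offs = np.arange(-window, window + k, dtype=np.int64)
    ai = qi[:, None] + offs[None, :]
    bj = sj[:, None] + offs[None, :]
    inb = (ai >= 0) & (ai < len(enc_a)) & (bj >= 0) & (bj < len(enc_b))
    av = np.where(inb, ai, 0)
    bv = np.where(inb, bj, 0)
    ea = enc_a[av]
    match = (ea == enc_b[bv]) & (ea < 4) & inb
    step = np.where(match, params.match, params.mismatch).astype(np.int32)
    step[~inb] = _NEG
    prefix = np.zeros((len(qi), step.shape[1] + 1), dtype=np.int64)
    np.cumsum(step, axis=1, out=prefix[:, 1:])
    runmin = np.minimum.accumulate(prefix, axis=1)
    best_any = (prefix[:, 1:] - runmin[:, :-1]).max(axis=1)
    L = min_seg_len
    if prefix.shape[1] > L:
        best_long = (prefix[:, L:] - runmin[:, :-L]).max(axis=1)
    else:
        best_long = np.full(len(qi), _NEG, dtype=np.int64)
    return best_any, best_long, step, offs


def _segment_extent(step_row: np.ndarray, offs: np.ndarray) -> tuple[int, int, int]:
    """Best-scoring segment (Kadane with extents) in one seed window."""
    best = 0
    best_u = best_v = 0
    cur = 0
    cur_u = 0
    for t, s in enumerate(step_row):
        s = int(s)
        if cur <= 0:
            cur = 0
            cur_u = t
        cur += s
        if cur > best:
            best = cur
            best_u, best_v = cur_u, t + 1
    return best, int(offs[best_u]), int(offs[best_v - 1]) + 1


# ---------------------------------------------------------------------------
# Banded gapped Smith-Waterman with traceback
# ---------------------------------------------------------------------------


def banded_sw(
    a: str,
    b: str,
    params: ScoringParams,
    dlo: int,
    dhi: int,
) -> tuple[int, int, int, int, int, int, int] | None:
    """Local affine-gap alignment of a vs b restricted to diagonals j-i in
    [dlo, dhi]. Returns (score, q_start, q_end, s_start, s_end, matches,
    columns) of the best local alignment, or None if no positive score.
    """
    na, nb = len(a), len(b)
    width = dhi - dlo + 1
    if width <= 0:
        return None
    go, ge = params.gap_open, params.gap_extend
    sub_match, sub_mis = params.match, params.mismatch
    neg = _NEG
    # H/E/F indexed [i][j - (i + dlo)]; E = gap in a (left), F = gap in b (up)
    H = [[0] * width for _ in range(na + 1)]
    E = [[neg] * width for _ in range(na + 1)]
    F = [[neg] * width for _ in range(na + 1)]
    ptrH = [[0] * width for _ in range(na + 1)]  # 0 stop, 1 diag, 2 from F, 3 from E
    ptrE = [[0] * width for _ in range(na + 1)]  # 1 opened from H, 0 extended
    ptrF = [[0] * width for _ in range(na + 1)]
    best = 0
    best_cell = None
    for i in range(1, na + 1):
        base = i + dlo
        Hi, Ei, Fi = H[i], E[i], F[i]
        PHi, PEi, PFi = ptrH[i], ptrE[i], ptrF[i]
        Hp, Fp = H[i - 1], F[i - 1]
        ca = a[i - 1]
        for w in range(width):
            j = base + w
            if j < 1 or j > nb:
                if 0 <= j <= nb:
                    Hi[w] = 0
                else:
                    Hi[w] = neg
                continue
            hd = Hp[w]  # diagonal predecessor (i-1, j-1) sits at same w
            cb = b[j - 1]
            s = sub_match if (ca == cb and ca != "N" and cb != "N") else sub_mis
            diag = (hd + s) if hd > neg // 2 else neg
            # F: gap in b, predecessor (i-1, j) at w+1 in previous row
            if w + 1 < width:
                f_open = Hp[w + 1] + go + ge if Hp[w + 1] > neg // 2 else neg
                f_ext = Fp[w + 1] + ge if Fp[w + 1] > neg // 2 else neg
            else:
                f_open = f_ext = neg
            if f_open >= f_ext:
                Fi[w], PFi[w] = f_open, 1
            else:
                Fi[w], PFi[w] = f_ext, 0
            # E: gap in a, predecessor (i, j-1) at w-1 in same row
            if w - 1 >= 0:
                e_open = Hi[w - 1] + go + ge if Hi[w - 1] > neg // 2 else neg
                e_ext = Ei[w - 1] + ge if Ei[w - 1] > neg // 2 else neg
            else:
                e_open = e_ext = neg
            if e_open >= e_ext:
                Ei[w], PEi[w] = e_open, 1
            else:
                Ei[w], PEi[w] = e_ext, 0
            h, p = diag, 1
            if Fi[w] > h:
                h, p = Fi[w], 2
            if Ei[w] > h:
                h, p = Ei[w], 3
            if h <= 0:
                h, p = 0, 0
            Hi[w] = h
            PHi[w] = p
            if h > best:
                best = h
                best_cell = (i, w)
    if best <= 0 or best_cell is None:
        return None
    # three-state traceback
    i, w = best_cell
    j = i + dlo + w
    q_end, s_end = i, j
    matches = 0
    columns = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptrH[i][w]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                    matches += 1
                i -= 1
                j -= 1
                if H[i][w] == 0 and ptrH[i][w] == 0:
                    break
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b: consume a[i-1]
            columns += 1
            opened = ptrF[i][w] == 1
            i -= 1
            w += 1
            if opened:
                state = "H"
        else:  # E: gap in a, consume b[j-1]
            columns += 1
            opened = ptrE[i][w] == 1
            j -= 1
            w -= 1
            if opened:
                state = "H"
    return best, i, q_end, j, s_end, matches, columns


# ---------------------------------------------------------------------------
# The seeded local aligner
# ---------------------------------------------------------------------------


def local_align(
    a: str,
    b: str,
    params: ScoringParams = ScoringParams(),
    *,
    min_score: int = 16,
    any_trigger: int | None = 18,
    long_trigger: int = 15,
    long_len: int = 30,
    window: int = 160,
    band: int = 16,
    pad: int = 40,
    max_seed_pairs: int = 100000,
    suppress_self_diagonal: bool = False,
    query_name: str = "query",
    subject_name: str = "subject",
) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of a against both strands of b.

    Exact `seed_word_length`-mers shared by a and b nucleate an ungapped
    Kadane extension in a fixed window; windows whose best segment reaches
    `any_trigger` (any length) or `long_trigger` (length >= long_len) are
    re-aligned with banded gapped Smith-Waterman, and non-overlapping
    locally optimal alignments with raw score >= min_score are reported.
    Setting any_trigger=None disables the short-segment trigger (used by
    the all-vs-all stage, whose downstream filter discards short hits
    anyway).
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    enc_a = encode(a)
    m, n = len(a), len(b)
    hits: list[AlignmentHit] = []
    for strand in "+-":
        bs = b if strand == "+" else revcomp(b)
        enc_b = encode(bs)
        qi, sj = _seed_pairs(enc_a, enc_b, params.seed_word_length, max_seed_pairs)
        if suppress_self_diagonal and strand == "+":
            keep = qi != sj
            qi, sj = qi[keep], sj[keep]
        if len(qi) == 0:
            continue
        best_any, best_long, step, offs = _ungapped_stats(
            enc_a, enc_b, qi, sj, params, window, long_len
        )
        fired = best_long >= long_trigger
        if any_trigger is not None:
            fired |= best_any >= any_trigger
        order = np.argsort(-best_any[fired], kind="stable")
        sel = np.flatnonzero(fired)[order]
        accepted: list[tuple[int, int, int, int]] = []  # q0,q1,s0,s1 extents of found alignments
        strand_hits: list[AlignmentHit] = []
        for row in sel:
            i0, j0 = int(qi[row]), int(sj[row])
            # skip seeds inside an alignment we already recovered
            inside = False
            for q0, q1, s0, s1 in accepted:
                if q0 <= i0 < q1 and s0 <= j0 < s1:
                    inside = True
                    break
            if inside:
                continue
            seg_score, t0, t1 = _segment_extent(step[row], offs)
            if seg_score <= 0:
                continue
            qs, qe = i0 + t0, i0 + t1
            ss, se = j0 + t0, j0 + t1
            w0q, w1q = max(0, qs - pad), min(m, qe + pad)
            w0s, w1s = max(0, ss - pad), min(len(bs), se + pad)
            # local-window diagonal of the seed
            dseed = (j0 - w0s) - (i0 - w0q)
            res = banded_sw(
                a[w0q:w1q], bs[w0s:w1s], params, dseed - band, dseed + band
            )
            if res is None:
                continue
            score, lq0, lq1, ls0, ls1, matches, columns = res
            if score < min_score or columns < 1 or matches < 1:
                continue
            gq0, gq1 = w0q + lq0, w0q + lq1
            gs0, gs1 = w0s + ls0, w0s + ls1
            if suppress_self_diagonal and strand == "+" and gq0 == gs0 and gq1 == gs1:
                continue
            accepted.append((gq0, gq1, gs0, gs1))
            # non-overlap: drop if both sides overlap an already-kept hit
            clash = False
            for h in strand_hits:
                s_lo, s_hi = h.s_start, h.s_end
                if strand == "-":
                    s_lo, s_hi = n - h.s_end, n - h.s_start
                if gq0 < h.q_end and h.q_start < gq1 and gs0 < s_hi and s_lo < gs1:
                    clash = True
                    break
            if clash:
                continue
            if strand == "+":
                s_start, s_end = gs0, gs1
            else:
                s_start, s_end = n - gs1, n - gs0
            identity = 100.0 * matches / columns
            bit, e = bit_and_evalue(score, params, m, n)
            strand_hits.append(
                AlignmentHit(
                    query_region=query_name,
                    q_start=gq0,
                    q_end=gq1,
                    subject_region=subject_name,
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                    identity_pct=identity,
                    aln_len=columns,
                    matches=matches,
                    raw_score=score,
                    bit_score=bit,
                    e_value=e,
                )
            )
        hits.extend(strand_hits)
    hits.sort(key=lambda h: (-h.raw_score, h.q_start, h.s_start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# All-vs-all with the retention filters
# ---------------------------------------------------------------------------


def hit_passes_filters(
    h: AlignmentHit,
    min_hit_len: int = 30,
    min_bit: float = 20.0,
    exclude_full_identity: bool = True,
) -> bool:
    if exclude_full_identity and h.identity_pct >= 100.0:
        return False
    if h.aln_len < min_hit_len:
        return False
    if h.bit_score < min_bit:
        return False
    return True


def all_vs_all(
    regions,
    params: ScoringParams = ScoringParams(),
    *,
    min_hit_len: int = 30,
    min_bit: float = 20.0,
    exclude_full_identity: bool = True,
) -> list[AlignmentHit]:
    """Align every unordered region pair (including self) and filter hits.

    Retained hits have identity < 100%, alignment length >= min_hit_len and
    bit score >= min_bit. Self-comparisons suppress the trivial full-length
    identity diagonal but keep internal repeats. Symmetric duplicates
    collapse to one canonical orientation.
    """
    regions = list(regions)
    out: list[AlignmentHit] = []
    for i in range(len(regions)):
        for j in range(i, len(regions)):
            ra, rb = regions[i], regions[j]
            raw = local_align(
                ra.sequence,
                rb.sequence,
                params,
                any_trigger=None,
                long_trigger=min(15, min_bit - 5) if min_bit else 15,
                suppress_self_diagonal=(i == j),
                query_name=ra.region_id,
                subject_name=rb.region_id,
            )
            seen: set[tuple] = set()
            for h in raw:
                if not hit_passes_filters(h, min_hit_len, min_bit, exclude_full_identity):
                    continue
                if i == j:
                    key_fwd = (h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
                    key_rev = (h.s_start, h.s_end, h.q_start, h.q_end, h.strand)
                    if key_rev in seen:
                        continue
                    if key_rev < key_fwd:
                        h = replace(
                            h,
                            q_start=h.s_start,
                            q_end=h.s_end,
                            s_start=h.q_start,
                            s_end=h.q_end,
                        )
                        key_fwd = key_rev
                    if key_fwd in seen:
                        continue
                    seen.add(key_fwd)
                out.append(h)
    return out
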