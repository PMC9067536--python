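"""Per-cluster consensus alignment, folding, scoring and covariation.

This stage decides which homology clusters look like conserved RNA
structures. Four explicit stand-ins cooperate:

* ``align_cluster`` — progressive profile alignment under a k-mer guide
  tree (the structural-alignment step);
* ``fold_consensus`` — Nussinov-style maximization of a per-pair
  consensus-support score B(i,j) = c_ij - (n_ij - c_ij), where c_ij counts
  rows whose columns i,j form a canonical pair and n_ij counts rows with
  both columns non-gap;
* ``structure_score`` — a weighted sum rewarding canonical pairing and
  observed pair-type diversity, penalizing non-canonical rows; motifs pass
  at a configurable threshold (default 10);
* ``covariation_stats`` — mutual information with average-product
  correction (MIp) and a column-permutation null giving each structure
  pair an E-value (expected null exceedances per permutation replicate);
  a motif passes when some pair has E below the significance level.

``refine_fold`` is the covariation-guided refinement: pairs gain a bonus
proportional to positive MIp, the alignment is refolded, and the structure
with more significant pairs (ties: higher structure score) is kept.

Scores here are deliberately simple count-based surrogates for
phylogeny-aware methods; their decision semantics (threshold gates on
structure support and covariation significance) are what the pipeline
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io_formats import StockholmAlignment, dotbracket_from_pairs, pairs_from_dotbracket

# DNA alphabet indices A=0 C=1 G=2 T=3; canonical = Watson-Crick + GT wobble
_IDX = {b: i for i, b in enumerate("ACGT")}
CANONICAL_IDX = [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]
MIN_LOOP = 3  # paired columns must satisfy j - i > 3


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

_GAP_SCORE = -2.0  # flat per-column gap cost in profile alignment
# per-character substitution: +1 match, -1 mismatch; N matches nothing
_SUBST = -np.ones((5, 5))
for _i in range(4):
    _SUBST[_i, _i] = 1.0


def _one_hot_rows(rows: list[str]) -> np.ndarray:
    """(n_rows, width, 5) one-hot over A,C,G,T,N; gaps are all-zero."""
    n = len(rows)
    w = len(rows[0]) if rows else 0
    X = np.zeros((n, w, 5))
    for r, row in enumerate(rows):
        for c, ch in enumerate(row):
            if ch != "-":
                X[r, c, _IDX.get(ch, 4)] = 1.0
    return X


def _profile_align(rows_x: list[str], rows_y: list[str]) -> tuple[list[str], list[str]]:
    """Profile-profile alignment with free end gaps, diagonal-first ties.

    End gaps are free because cluster members are homology windows cut at
    different offsets: their terminal overhangs carry no signal, and
    penalizing them scatters gaps through the conserved core. Internal
    gaps cost -2 per column.
    """
    cx = _one_hot_rows(rows_x).sum(axis=0)
    cy = _one_hot_rows(rows_y).sum(axis=0)
    nx, ny = len(rows_x), len(rows_y)
    M = (cx @ _SUBST @ cy.T) / (nx * ny)
    lx, ly = M.shape
    g = _GAP_SCORE
    H = np.zeros((lx + 1, ly + 1))  # free leading end gaps
    jj = np.arange(1, ly + 1)
    for i in range(1, lx + 1):
        cand = np.maximum(H[i - 1, :-1] + M[i - 1, :], H[i - 1, 1:] + g)
        # close the within-row left recurrence for a linear gap cost:
        # H[i,j] = max( cand[j], max_{k<j} H[i,k] + g*(j-k) )
        t = np.maximum.accumulate(np.concatenate(([H[i, 0]], cand - g * jj)))
        H[i, 1:] = np.maximum(cand, t[:-1] + g * jj)
    # free trailing end gaps: best cell on the last row or column,
    # preferring the bottom-right-most on ties for determinism
    best = (-np.inf, -1, -1)
    for i in range(lx + 1):
        best = max(best, (H[i, ly], i, ly))
    for j in range(ly + 1):
        best = max(best, (H[lx, j], lx, j))
    _, bi, bj = best
    out_x = [[] for _ in rows_x]
    out_y = [[] for _ in rows_y]

    def emit(ci: int | None, cj: int | None) -> None:
        for r, row in enumerate(rows_x):
            out_x[r].append(row[ci] if ci is not None else "-")
        for r, row in enumerate(rows_y):
            out_y[r].append(row[cj] if cj is not None else "-")

    for i in range(lx - 1, bi - 1, -1):  # trailing overhang of X
        emit(i, None)
    for j in range(ly - 1, bj - 1, -1):
        emit(None, j)
    i, j = bi, bj
    eps = 1e-9
    while i > 0 and j > 0:
        if abs(H[i, j] - (H[i - 1, j - 1] + M[i - 1, j - 1])) < eps:
            emit(i - 1, j - 1)
            i -= 1
            j -= 1
        elif abs(H[i, j] - (H[i - 1, j] + g)) < eps:
            emit(i - 1, None)
            i -= 1
        elif abs(H[i, j] - (H[i, j - 1] + g)) < eps:
            emit(None, j - 1)
            j -= 1
        else:  # reached the free-start boundary region
            break
    for ci in range(i - 1, -1, -1):  # leading overhang of X
        emit(ci, None)
    for cj in range(j - 1, -1, -1):
        emit(None, cj)
    return ["".join(reversed(r)) for r in out_x], ["".join(reversed(r)) for r in out_y]


def align_with_offsets(
    sequences: list[str], offsets: list[int]
) -> StockholmAlignment:
    """Anchor-based alignment: stack members at their hit-implied offsets.

    The pairwise local alignments that built a cluster already fix the
    relative register of its members; stacking sequences at those offsets
    recovers the alignment directly (exactly, for indel-free homologs),
    where de-novo alignment of ~60-70%-identity windows is noisy. No
    gap-based polishing is applied afterwards: realignment at this
    identity level tends to slide whole rows off register, and jointly
    shifted rows manufacture spurious covariation between columns.
    """
    if len(sequences) < 2:
        raise ValueError("align_with_offsets needs at least 2 sequences")
    offs = _reregister(sequences, list(offsets))
    base = min(offs)
    width = max(o - base + len(s) for s, o in zip(sequences, offs))
    rows = [
        "-" * (o - base) + s + "-" * (width - (o - base) - len(s))
        for s, o in zip(sequences, offs)
    ]
    names = [f"seq{i}" for i in range(len(rows))]
    return StockholmAlignment(names=names, rows=rows)


def _reregister(
    sequences: list[str], offsets: list[int], max_shift: int = 8, passes: int = 2
) -> list[int]:
    """Snap each member to the whole-row shift agreeing best with the rest.

    A single slightly-off anchor edge in the spanning tree shifts a whole
    subtree of members by the same amount; such jointly shifted rows both
    weaken the profile and manufacture covariation. Trying small integer
    shifts of each member against the profile of the others (most agreeing
    wins; ties prefer the smaller |shift|) repairs this without ever
    introducing internal gaps.
    """
    offs = list(offsets)
    n = len(sequences)
    for _ in range(passes):
        changed = False
        for r in range(n):
            # profile of the others: counts per absolute column
            lo = min(offs[i] for i in range(n) if i != r)
            hi = max(offs[i] + len(sequences[i]) for i in range(n) if i != r)
            prof = np.zeros((hi - lo, 4))
            for i in range(n):
                if i == r:
                    continue
                for c, ch in enumerate(sequences[i]):
                    k = _IDX.get(ch, 4)
                    if k < 4:
                        prof[offs[i] - lo + c, k] += 1.0
            best = (-1.0, 0)
            for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
                o = offs[r] + shift
                agree = tot = 0
                for c, ch in enumerate(sequences[r]):
                    p = o - lo + c
                    if p < 0 or p >= len(prof):
                        continue
                    col = prof[p]
                    if col.sum() == 0:
                        continue
                    tot += 1
                    k = _IDX.get(ch, 4)
                    if k < 4 and col[k] == col.max() and col[k] > 0:
                        agree += 1
                frac = agree / tot if tot >= 8 else -1.0
                if frac > best[0]:
                    best = (frac, shift)
            if best[1] != 0 and best[0] >= 0:
                offs[r] += best[1]
                changed = True
        if not changed:
            break
    return offs


def prune_outlier_rows(
    alignment: StockholmAlignment, min_agreement: float = 0.5
) -> tuple[StockholmAlignment, list[int]]:
    """Drop rows that disagree with the column consensus.

    A member pulled into a cluster by a spurious hit sits at an arbitrary
    register: its residues deviate from the consensus at most columns, and
    because whole rows deviate jointly, such members manufacture apparent
    covariation that a column-permutation null flags as significant. True
    members at the divergence levels this pipeline targets agree with the
    consensus at well over half their columns, so a 50% agreement floor
    separates the regimes cleanly. Returns the pruned alignment and the
    kept row indices (all rows, when pruning would leave fewer than 2).
    """
    X = _one_hot_rows(alignment.rows)[:, :, :4]
    counts = X.sum(axis=0)  # (W, 4)
    min_overlap = 8  # a member must share this many columns with the rest
    kept: list[int] = []
    for r, row in enumerate(alignment.rows):
        others = counts - X[r]  # consensus must exclude the row itself
        other_cover = others.sum(axis=1)
        cons = others.argmax(axis=1)
        nongap = 0
        agree = 0
        for c, ch in enumerate(row):
            if ch == "-" or other_cover[c] == 0:
                continue
            nongap += 1
            if _IDX.get(ch, 4) == cons[c]:
                agree += 1
        if nongap >= min_overlap and agree / nongap >= min_agreement:
            kept.append(r)
    if len(kept) < 2 or len(kept) == len(alignment.rows):
        return alignment, list(range(len(alignment.rows)))
    rows = _drop_allgap_columns([alignment.rows[r] for r in kept])
    return (
        StockholmAlignment(names=[alignment.names[r] for r in kept], rows=rows),
        kept,
    )


def split_members(
    sequences: list[str], max_dist: float = 0.7, min_members: int = 3
) -> list[list[int]]:
    """Partition cluster members into composition-coherent motif groups.

    Cuts the 4-mer cosine average-linkage guide tree at `max_dist`; each
    resulting group with at least `min_members` members becomes its own
    motif unit. A single homology cluster can legitimately harbor more
    than one alignable motif (e.g. CRISPR repeats chained to a tracrRNA
    antirepeat by repeat homology): their members differ strongly in
    k-mer composition, while windows of one family do not. Falls back to
    one group containing everything when no cut is warranted.
    """
    n = len(sequences)
    if n < 2 * min_members:
        return [list(range(n))]
    profiles = np.array([_kmer_profile(s) for s in sequences])
    norms = np.linalg.norm(profiles, axis=1)
    safe = profiles / np.where(norms > 0, norms, 1.0)[:, None]
    dist = np.nan_to_num(pdist(safe, metric="cosine"), nan=1.0)
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=max_dist, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    big = [g for g in groups.values() if len(g) >= min_members]
    if len(big) <= 1:
        return [list(range(n))]
    return sorted(big, key=lambda g: (-len(g), g[0]))


def _kmer_profile(seq: str, k: int = 4) -> np.ndarray:
    v = np.zeros(4**k)
    enc = [_IDX.get(c, -1) for c in seq]
    for i in range(len(seq) - k + 1):
        window = enc[i : i + k]
        if min(window) < 0:
            continue
        code = 0
        for c in window:
            code = code * 4 + c
        v[code] += 1.0
    return v


def _drop_allgap_columns(rows: list[str]) -> list[str]:
    keep = [k for k in range(len(rows[0])) if any(r[k] != "-" for r in rows)]
    return ["".join(r[k] for k in keep) for r in rows]


def _refine_rows(rows: list[str], rounds: int) -> list[str]:
    """Iterative refinement: realign each row to the profile of the rest."""
    rows = list(rows)
    for _ in range(rounds):
        for r in range(len(rows)):
            others = _drop_allgap_columns(rows[:r] + rows[r + 1 :])
            seq = rows[r].replace("-", "")
            if not seq or not others:
                continue
            ax, ay = _profile_align(others, [seq])
            rows = _drop_allgap_columns(ax[:r] + ay + ax[r:])
    return rows


def align_cluster(sequences: list[str], refine_budget: int = 8000) -> StockholmAlignment:
    """Progressive multiple alignment of cluster members (no structure yet).

    Guide tree: average linkage on cosine distance between 4-mer count
    profiles; merges follow the linkage order, each one a profile-profile
    alignment (+1 match, -1 mismatch, -2 per gap column, free end gaps).
    The progressive result is polished by iterative refinement (each row
    realigned against the others' profile), skipped for large alignments
    where its cost outweighs its benefit.
    """
    if len(sequences) < 2:
        raise ValueError("align_cluster needs at least 2 sequences")
    names = [f"seq{i}" for i in range(len(sequences))]
    if len(set(sequences)) == 1:
        return StockholmAlignment(names=names, rows=list(sequences))
    profiles = np.array([_kmer_profile(s) for s in sequences])
    norms = np.linalg.norm(profiles, axis=1)
    safe = profiles / np.where(norms > 0, norms, 1.0)[:, None]
    dist = np.nan_to_num(pdist(safe, metric="cosine"), nan=1.0)
    Z = linkage(dist, method="average")
    blocks: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i]]) for i in range(len(sequences))
    }
    nxt = len(sequences)
    for x, y, _, _ in Z:
        ix, rx = blocks.pop(int(x))
        iy, ry = blocks.pop(int(y))
        ax, ay = _profile_align(rx, ry)
        blocks[nxt] = (ix + iy, ax + ay)
        nxt += 1
    order, rows = blocks.popitem()[1]
    by_input = dict(zip(order, rows))
    rows = [by_input[i] for i in range(len(sequences))]
    cells = len(rows) * len(rows[0])
    rounds = 2 if cells <= refine_budget * 5 // 8 else (1 if cells <= refine_budget else 0)
    if rounds:
        rows = _refine_rows(rows, rounds)
    return StockholmAlignment(names=names, rows=rows)


# ---------------------------------------------------------------------------
# Pair counts and consensus folding
# ---------------------------------------------------------------------------


def pair_counts(alignment: StockholmAlignment):
    """(n_ij, c_ij, type_counts) for all column pairs.

    n_ij: rows with both columns non-gap; c_ij: rows forming a canonical
    pair (AT/TA/GC/CG/GT/TG on the DNA alphabet); type_counts[t,i,j]: rows
    forming canonical pair type t. N counts as a gap for pairing purposes.
    """
    X = _one_hot_rows(alignment.rows)[:, :, :4]
    nongap = X.sum(axis=2)
    n = nongap.T @ nongap
    types = np.stack([X[:, :, a].T @ X[:, :, b] for a, b in CANONICAL_IDX])
    c = types.sum(axis=0)
    return n, c, types


def _support_and_mask(alignment: StockholmAlignment):
    n, c, types = pair_counts(alignment)
    N = alignment.n_seqs
    B = 2.0 * c - n
    W = alignment.width
    ii, jj = np.meshgrid(np.arange(W), np.arange(W), indexing="ij")
    mask = (n >= N / 2.0) & (B > 0) & (jj - ii > MIN_LOOP)
    return B, mask


def _nussinov(B: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximize the sum of B over nested structures.

    Traceback tie order: pair (i,j), then leave i, then leave j, then the
    best bifurcation with the smallest split point.
    """
    W = B.shape[0]
    if W == 0:
        return []
    V = np.zeros((W, W))  # closed intervals [i, j]
    for span in range(1, W):
        i_idx = np.arange(0, W - span)
        j_idx = i_idx + span
        best = np.maximum(V[i_idx + 1, j_idx], V[i_idx, j_idx - 1])
        inner = V[i_idx + 1, j_idx - 1] if span >= 2 else np.zeros(len(i_idx))
        pair_val = np.where(mask[i_idx, j_idx], B[i_idx, j_idx] + inner, -np.inf)
        best = np.maximum(best, pair_val)
        if span >= 3:
            for t in range(len(i_idx)):
                i, j = int(i_idx[t]), int(j_idx[t])
                bif = V[i, i + 1 : j - 1] + V[i + 2 : j, j]
                if bif.size:
                    m = bif.max()
                    if m > best[t]:
                        best[t] = m
        V[i_idx, j_idx] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, W - 1)]
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        v = V[i, j]
        if v <= eps:
            continue
        inner = V[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
        if mask[i, j] and abs(v - (B[i, j] + inner)) < eps:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if abs(v - V[i + 1, j]) < eps:
            stack.append((i + 1, j))
            continue
        if abs(v - V[i, j - 1]) < eps:
            stack.append((i, j - 1))
            continue
        placed = False
        for k in range(i + 1, j - 1):
            if abs(v - (V[i, k] + V[k + 1, j])) < eps:
                stack.append((i, k))
                stack.append((k + 1, j))
                placed = True
                break
        if not placed:  # numerical fallback; should not occur
            stack.append((i + 1, j))
    return sorted(pairs)


def fold_consensus(alignment: StockholmAlignment) -> str:
    """Consensus structure maximizing total pair support B over nested pairs.

    A pair (i, j) is admissible only when at least half the rows have both
    columns non-gap, its support B = c - (n - c) is positive, and the
    hairpin loop is at least 3 (j - i > 3).
    """
    if alignment.width == 0:
        return ""
    B, mask = _support_and_mask(alignment)
    return dotbracket_from_pairs(_nussinov(B, mask), alignment.width)


def structure_score(
    alignment: StockholmAlignment,
    g_pair: float = 0.5,
    g_mis: float = 1.0,
    g_cov: float = 2.0,
) -> float:
    """Structure support score over the pairs of ss_cons.

    score = sum over pairs of [g_pair*c - g_mis*(n - c) + g_cov*v], with v
    the number of distinct canonical pair types beyond the first (floored
    at 0). An empty structure scores 0.
    """
    pairs = alignment.pairs()
    if not pairs:
        return 0.0
    n, c, types = pair_counts(alignment)
    total = 0.0
    for i, j in pairs:
        v = max(0, int((types[:, i, j] > 0).sum()) - 1)
        total += g_pair * c[i, j] - g_mis * (n[i, j] - c[i, j]) + g_cov * v
    return float(total)


# ---------------------------------------------------------------------------
# Covariation: MI with APC, permutation E-values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairStat:
    columns: tuple[int, int]
    mi: float
    apc: float
    mip: float
    e_value: float
    cov: float = 0.0  # compensatory covariance (the tested statistic)


@dataclass
class CovariationResult:
    pair_stats: list[PairStat]
    significant: bool
    min_e: float
    mip: np.ndarray = field(repr=False)  # observed MIp for all column pairs
    p_count: float = 1.0  # ladder test: P(null has as many positive pairs)


def _mi_matrix(X: np.ndarray, pseudocount: float) -> np.ndarray:
    """MI (bits) between all column pairs; joint counts over both-non-gap rows."""
    n_rows, W, _ = X.shape
    Xr = X.reshape(n_rows, W * 4)
    J = (Xr.T @ Xr).reshape(W, 4, W, 4).transpose(0, 2, 1, 3)  # (W, W, 4, 4)
    J = J + pseudocount
    tot = J.sum(axis=(2, 3), keepdims=True)
    P = J / tot
    Pi = P.sum(axis=3, keepdims=True)
    Pj = P.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = P * np.log2(P / (Pi * Pj))
    mi = np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    return np.maximum(mi, 0.0)


def _apc_matrix(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: outer product of row means over the mean."""
    W = mi.shape[0]
    if W < 2:
        return np.zeros_like(mi)
    row_mean = mi.sum(axis=1) / (W - 1)  # diagonal is zero
    overall = mi.sum() / (W * (W - 1))
    if overall <= 0:
        return np.zeros_like(mi)
    return np.outer(row_mean, row_mean) / overall


def _mip_matrix(X: np.ndarray, pseudocount: float) -> np.ndarray:
    mi = _mi_matrix(X, pseudocount)
    return mi - _apc_matrix(mi)


# Hamming distance between canonical pair types (how many of the two sides
# differ), the unit of compensatory evidence
_PAIR_HAMMING = np.zeros((6, 6))
for _t, _pa in enumerate(CANONICAL_IDX):
    for _u, _pb in enumerate(CANONICAL_IDX):
        _PAIR_HAMMING[_t, _u] = (_pa[0] != _pb[0]) + (_pa[1] != _pb[1])


def _compensatory_covariance(X: np.ndarray) -> np.ndarray:
    """Alignment-covariance matrix in the RNAalifold tradition.

    For each column pair, rows forming canonical pairs are compared
    pairwise: a pair of rows whose canonical pair types differ on BOTH
    sides (a full compensatory change, Hamming distance 2) contributes 1,
    normalized by all row pairs; rows breaking canonical pairing subtract
    their fraction. One-sided (wobble-type) transitions are excluded: a
    single substitution that happens to preserve pairing arises readily
    in unstructured conserved sequence, whereas a two-sided change
    preserving pairing is the specific signature of a maintained helix.
    Conserved canonical pairs score 0, compensatory variation scores
    positive, and arbitrary (non-canonical) joint variation scores
    negative — insensitive to the coincidental joint substitutions that
    inflate mutual information.
    """
    nongap = X.sum(axis=2)
    n = nongap.T @ nongap
    types = np.stack([X[:, :, a].T @ X[:, :, b] for a, b in CANONICAL_IDX])
    c = types.sum(axis=0)
    cross = np.zeros_like(c)
    for t in range(6):
        for u in range(t + 1, 6):
            if _PAIR_HAMMING[t, u] == 2:
                cross = cross + types[t] * types[u]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * (n - 1) / 2.0
        cov = np.where(denom > 0, cross / np.maximum(denom, 1.0), 0.0)
        cov = cov - np.where(n > 0, (n - c) / np.maximum(n, 1.0), 0.0)
    return cov


def covariation_stats(
    alignment: StockholmAlignment,
    n_perm: int = 200,
    seed=0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    ss_cons: str | None = None,
    selection_aware: bool = False,
) -> CovariationResult:
    """Permutation E-values for the covariation of each structure pair.

    The tested statistic is the compensatory covariance (full canonical
    pair-type changes among pairing rows); mutual information with its
    average-product correction (MIp) is computed alongside and reported
    per pair. Null replicates permute each column's non-gap residues
    independently among its non-gap rows; a pair's E-value is the number
    of null statistic values (across structure pairs and replicates) at
    or above its observed value, divided by the number of replicates —
    the expected null exceedances per replicate.

    Because a single pair's covariation at modest depth can be a
    coincidence the fold happened to select, significance additionally
    requires the ladder test: the number of structure pairs with positive
    covariance must itself beat its permutation null (a conserved helix
    covaries along its whole ladder; a lucky decoy pair stands alone).
    The motif is significant when the smallest E-value is below alpha and
    the ladder test p-value is below alpha.

    With selection_aware=True, each replicate instead contributes the
    covariance of its own best-supported pairs — as many as the tested
    structure has, chosen greedily by pair support B on the permuted data
    under column disjointness — a stricter null that also charges for the
    fold's freedom to choose where to look.
    """
    if alignment.n_seqs < 3:
        raise ValueError("covariation needs at least 3 sequences")
    ss = alignment.ss_cons if ss_cons is None else ss_cons
    struct_pairs = pairs_from_dotbracket(ss) if ss else []
    rng = np.random.default_rng(seed)
    X = _one_hot_rows(alignment.rows)[:, :, :4]
    obs_mip = _mip_matrix(X, pseudocount)
    if not struct_pairs:
        return CovariationResult([], False, float("inf"), obs_mip)
    obs_cov = _compensatory_covariance(X)
    pi = np.array([p[0] for p in struct_pairs])
    pj = np.array([p[1] for p in struct_pairs])
    obs = obs_cov[pi, pj]
    N = alignment.n_seqs
    W = alignment.width
    n_pairs = len(struct_pairs)
    ii, jj = np.meshgrid(np.arange(W), np.arange(W), indexing="ij")
    loop_ok = jj - ii > MIN_LOOP
    nongap_rows = [np.flatnonzero(X[:, w, :].sum(axis=1) > 0) for w in range(W)]
    null_vals = np.empty((n_perm, n_pairs))
    Xp = X.copy()
    for p in range(n_perm):
        for w, rows_w in enumerate(nongap_rows):
            if len(rows_w) > 1:
                Xp[rows_w, w, :] = X[rows_w[rng.permutation(len(rows_w))], w, :]
        null_cov = _compensatory_covariance(Xp)
        if selection_aware:
            nongap = Xp.sum(axis=2)
            nn = nongap.T @ nongap
            cc = sum(Xp[:, :, a].T @ Xp[:, :, b] for a, b in CANONICAL_IDX)
            B = 2.0 * cc - nn
            adm = (nn >= N / 2.0) & (B > 0) & loop_ok
            ai, aj = np.nonzero(adm)
            order = np.argsort(-B[ai, aj], kind="stable")
            # a fold could not use every high-support pair: each column pairs
            # at most once, so the null selects greedily under disjointness
            used = np.zeros(W, dtype=bool)
            vals = []
            for k in order:
                i_, j_ = int(ai[k]), int(aj[k])
                if used[i_] or used[j_]:
                    continue
                used[i_] = used[j_] = True
                vals.append(null_cov[i_, j_])
                if len(vals) == n_pairs:
                    break
            vals = np.asarray(vals)
            if len(vals) < n_pairs:  # pad so pool size stays n_perm * n_pairs
                vals = np.concatenate([vals, np.full(n_pairs - len(vals), -np.inf)])
            null_vals[p] = vals
        else:
            null_vals[p] = null_cov[pi, pj]
    flat = np.sort(null_vals.ravel())
    exceed = len(flat) - np.searchsorted(flat, obs, side="left")
    e_values = exceed / n_perm
    obs_count = int((obs > 0).sum())
    null_counts = (null_vals > 0).sum(axis=1)
    p_count = float((1 + (null_counts >= obs_count).sum()) / (n_perm + 1))
    mi = _mi_matrix(X, pseudocount)
    apc = mi - obs_mip
    stats = [
        PairStat(
            columns=(int(i), int(j)),
            mi=float(mi[i, j]),
            apc=float(apc[i, j]),
            mip=float(obs_mip[i, j]),
            e_value=float(e),
            cov=float(obs_cov[i, j]),
        )
        for (i, j), e in zip(struct_pairs, e_values)
    ]
    min_e = float(e_values.min())
    significant = min_e < alpha and p_count < alpha
    return CovariationResult(stats, significant, min_e, obs_mip, p_count)


def refine_fold(
    alignment: StockholmAlignment,
    cov: CovariationResult,
    n_perm: int = 200,
    seed=0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    weight: float = 1.0,
) -> tuple[str, CovariationResult]:
    """Covariation-guided refolding.

    Pair support becomes B'(i,j) = B(i,j) + weight * max(MIp, 0) * N; the
    alignment is refolded and re-scored, and whichever structure shows more
    significant pairs is kept (ties: higher structure score). Never returns
    a structure with fewer significant pairs than the input.
    """
    B, _ = _support_and_mask(alignment)
    N = alignment.n_seqs
    B2 = B + weight * np.maximum(cov.mip, 0.0) * N
    W = alignment.width
    ii, jj = np.meshgrid(np.arange(W), np.arange(W), indexing="ij")
    n, _, _ = pair_counts(alignment)
    mask2 = (n >= N / 2.0) & (B2 > 0) & (jj - ii > MIN_LOOP)
    new_ss = dotbracket_from_pairs(_nussinov(B2, mask2), W)
    if new_ss == alignment.ss_cons:
        return alignment.ss_cons, cov
    new_cov = covariation_stats(
        alignment,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        pseudocount=pseudocount,
        ss_cons=new_ss,
    )
    n_sig_old = sum(ps.e_value < alpha for ps in cov.pair_stats)
    n_sig_new = sum(ps.e_value < alpha for ps in new_cov.pair_stats)
    if n_sig_new > n_sig_old:
        return new_ss, new_cov
    if n_sig_new == n_sig_old:
        old_aln = StockholmAlignment(
            names=alignment.names, rows=alignment.rows, ss_cons=alignment.ss_cons
        )
        new_aln = StockholmAlignment(
            names=alignment.names, rows=alignment.rows, ss_cons=new_ss
        )
        if structure_score(new_aln) > structure_score(old_aln):
            return new_ss, new_cov
    return alignment.ss_cons, cov


@dataclass
class MotifAlignment:
    """A cluster's alignment with structure, scores and covariation stats."""

    cluster_id: str
    alignment: StockholmAlignment
    structure_score: float
    covariation: CovariationResult | None = None

    @property
    def significant(self) -> bool:
        return self.covariation is not None and self.covariation.significant
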