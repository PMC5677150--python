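"""Sequence-context primitives: inverted repeats, tandem arrays, direct repeats.

All coordinates reported by this module are 1-based inclusive positions in
the scanned sequence. An inverted repeat (IR) is a pair of arms where the
left arm equals the reverse complement of the right arm, separated by a
spacer (the hairpin loop when the sequence folds back on itself). A
quasi-palindrome is an IR whose arms differ by a small number of
mismatches and/or indels ("arm edits").

Reporting convention for perfect IRs: one IR per maximal complementary
run. A reported IR can be extended neither outward (the flanking base
pair does not complement) nor inward (the next inner pair does not
complement, or the spacer is already minimal). This avoids reporting the
combinatorial family of sub-repeats nested inside every long palindrome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._seq import encode, identity


@dataclass(frozen=True)
class InvertedRepeat:
    """An inverted repeat / (quasi-)palindrome.

    ``arm_len`` is the left-arm length; for quasi-palindromes with indel
    edits the right arm may be shorter or longer (see coordinates).
    ``arm_edits`` counts mismatches plus indel bases between the left arm
    and the reverse complement of the right arm.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    arm_len: int
    spacer_len: int
    arm_edits: int

    @property
    def perfect(self) -> bool:
        return self.arm_edits == 0

    @property
    def left_arm(self) -> tuple[int, int]:
        return (self.left_start, self.left_end)

    @property
    def right_arm(self) -> tuple[int, int]:
        return (self.right_start, self.right_end)

    def arm_seqs(self, seq: str) -> tuple[str, str, str]:
        """(left arm, spacer, right arm) substrings of ``seq``."""
        return (
            seq[self.left_start - 1 : self.left_end],
            seq[self.left_end : self.right_start - 1],
            seq[self.right_start - 1 : self.right_end],
        )


@dataclass(frozen=True)
class TandemRepeat:
    unit: str
    period: int
    copy_number: float
    start: int
    end: int
    purity: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class DirectRepeatDecomposition:
    """An (A, B) split explaining an INDEL as ABA <-> ABABA.

    ``A`` is the short direct repeat, ``B`` the unique spacer;
    len(A) + len(B) equals the INDEL length. ``anchors`` are 1-based
    reference (start, end) intervals of the A copies, leftmost first.
    ``similarity`` is the mean pairwise identity of the A copies;
    ``unit_similarity`` the identity between the INDEL unit and its
    reference-adjacent copy.
    """

    A: str
    B: str
    len_A: int
    len_B: int
    similarity: float
    unit_similarity: float
    anchors: tuple[tuple[int, int], ...] = field(default=())


# ---------------------------------------------------------------------------
# inverted repeats
# ---------------------------------------------------------------------------


def _anchor_masks(x: np.ndarray, max_spacer: int, min_loop: int):
    """Yield (spacer, anchor_index_array, match_array) per spacer.

    An anchor is the innermost complementary pair of a maximal run along
    an anti-diagonal: the pair itself complements, and the next inner
    pair (same midpoint, spacer-2) does not, or would fall below
    ``min_loop``.
    """
    n = x.size
    m_cache: dict[int, np.ndarray] = {}
    for s in range(min_loop, min(max_spacer, n - 2) + 1):
        length = n - s - 1
        if length <= 0:
            break
        m = (x[:length] + x[s + 1 : s + 1 + length]) == 3
        m_cache[s] = m
        anchor = m.copy()
        inner_s = s - 2
        if inner_s >= min_loop and inner_s in m_cache:
            inner = m_cache[inner_s]
            anchor &= ~inner[1 : length + 1]
        yield s, np.flatnonzero(anchor), m
        if inner_s - 1 in m_cache:
            del m_cache[inner_s - 1]


def _perfect_scan(
    seq: str, min_arm: int, max_spacer: int, min_loop: int = 0
) -> list[InvertedRepeat]:
    x = encode(seq)
    n = x.size
    out: list[InvertedRepeat] = []
    for s, idx, _m in _anchor_masks(x, max_spacer, min_loop):
        if idx.size == 0:
            continue
        arm = np.ones(idx.size, dtype=np.int64)
        alive = np.arange(idx.size)
        j = 1
        while alive.size:
            a = idx[alive] - j
            b = idx[alive] + s + 1 + j
            ok = (a >= 0) & (b < n)
            w = np.flatnonzero(ok)
            if w.size:
                good = (x[a[w]] + x[b[w]]) == 3
                ok[w[~good]] = False
            alive = alive[ok]
            arm[alive] += 1
            j += 1
        keep = arm >= min_arm
        for a0, k in zip(idx[keep], arm[keep]):
            a0 = int(a0)
            k = int(k)
            out.append(
                InvertedRepeat(
                    left_start=a0 - k + 2,
                    left_end=a0 + 1,
                    right_start=a0 + s + 2,
                    right_end=a0 + s + 1 + k,
                    arm_len=k,
                    spacer_len=s,
                    arm_edits=0,
                )
            )
    out.sort(key=lambda r: (r.left_start, -r.arm_len, r.spacer_len))
    return out


def _banded_outward_dp(
    u: list[int], v: list[int], max_edits: int, min_arm: int
) -> list[tuple[int, int, int]]:
    """Pareto-optimal outward arm extensions from an anchored center.

    ``u``/``v`` are code lists read center-outward (left arm reversed /
    right arm complemented). Returns (left_arm_len, right_arm_len,
    edits) tuples — for each edit count, the longest left arm whose
    alignment ends on an exact complementary match — filtered so that
    spending more edits must strictly lengthen the arm.
    """
    U, V = len(u), len(v)
    band = max_edits
    INF = max_edits + 1
    width = 2 * band + 1
    prev = [INF] * width
    prev[band] = 0  # cost(0, 0)
    for d in range(1, band + 1):
        prev[band + d] = d  # cost(0, j) = j leading gaps
    # best arm per exact edit count
    by_edits: list[Optional[tuple[int, int]]] = [None] * (max_edits + 1)
    for i in range(1, U + 1):
        cur = [INF] * width
        for d in range(-band, band + 1):
            j = i + d
            if j < 0 or j > V:
                continue
            if j == 0:
                cur[band + d] = i if i <= max_edits else INF
                continue
            is_match = u[i - 1] == v[j - 1] and u[i - 1] < 4
            c_diag = prev[band + d] + (0 if is_match else 1)
            c_up = prev[band + d + 1] + 1 if d + 1 <= band else INF
            c_left = cur[band + d - 1] + 1 if d - 1 >= -band else INF
            cur[band + d] = min(c_diag, c_up, c_left)
            if is_match and prev[band + d] <= max_edits and i >= min_arm:
                e = prev[band + d]
                old = by_edits[e]
                if old is None or i > old[0] or (i == old[0] and abs(j - i) < abs(old[1] - old[0])):
                    by_edits[e] = (i, j)
        prev = cur
        if min(cur) > max_edits:
            break
    out: list[tuple[int, int, int]] = []
    best_arm = 0
    for e, entry in enumerate(by_edits):
        if entry is not None and entry[0] > best_arm:
            out.append((entry[0], entry[1], e))
            best_arm = entry[0]
    return out


def _quasi_scan(
    seq: str,
    min_arm: int,
    max_spacer: int,
    max_arm_edits: int,
    min_loop: int = 0,
    max_arm_len: int = 60,
    focus: Optional[tuple[int, int]] = None,
) -> list[InvertedRepeat]:
    x = encode(seq)
    n = x.size
    cands: list[InvertedRepeat] = []
    f_lo, f_hi = focus if focus is not None else (0, n - 1)
    for s, idx, _m in _anchor_masks(x, max_spacer, min_loop):
        for a0 in idx:
            a0 = int(a0)
            b0 = a0 + s + 1
            if focus is not None:
                left_ok = a0 >= f_lo and a0 - (max_arm_len - 1) <= f_hi
                right_ok = b0 <= f_hi and b0 + (max_arm_len - 1) >= f_lo
                if not (left_ok or right_ok):
                    continue
            U = min(a0 + 1, max_arm_len)
            V = min(n - b0, max_arm_len + max_arm_edits)
            u = [int(x[a0 - i]) for i in range(U)]
            v = [9 if x[b0 + j] >= 4 else 3 - int(x[b0 + j]) for j in range(V)]
            for arm_l, arm_r, edits in _banded_outward_dp(u, v, max_arm_edits, min_arm):
                if edits < 1:
                    continue  # perfect: reported by the perfect scan
                # arms must not contain N
                if 4 in x[a0 - arm_l + 1 : a0 + 1] or 4 in x[b0 : b0 + arm_r]:
                    continue
                cands.append(
                    InvertedRepeat(
                        left_start=a0 - arm_l + 2,
                        left_end=a0 + 1,
                        right_start=b0 + 1,
                        right_end=b0 + arm_r,
                        arm_len=arm_l,
                        spacer_len=s,
                        arm_edits=edits,
                    )
                )
    return cands


def _score(ir: InvertedRepeat) -> int:
    # alignment-like quality: each edit costs about two matched positions
    return ir.arm_len - 2 * ir.arm_edits


def _dedup_quasi(cands: list[InvertedRepeat]) -> list[InvertedRepeat]:
    """Keep the best-scoring report among heavily-overlapping candidates.

    Candidates whose matched positions do not outweigh their edits
    (arm_len - 2 * arm_edits < 1) are degenerate descriptions of shorter
    structures and are dropped.
    """
    cands = sorted((c for c in cands if _score(c) >= 1),
                   key=lambda r: (-_score(r), r.arm_edits, r.left_start,
                                  r.spacer_len))
    kept: list[InvertedRepeat] = []
    for c in cands:
        dup = False
        for k in kept:
            lo = max(c.left_start, k.left_start)
            hi = min(c.right_end, k.right_end)
            ov = max(0, hi - lo + 1)
            span_c = c.right_end - c.left_start + 1
            span_k = k.right_end - k.left_start + 1
            if ov >= 0.8 * span_c and ov >= 0.8 * span_k:
                dup = True
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda r: (r.left_start, -r.arm_len, r.spacer_len))
    return kept


def find_inverted_repeats(
    seq: str,
    min_arm: int = 5,
    max_spacer: int = 70,
    max_arm_edits: int = 0,
    min_loop: int = 0,
) -> list[InvertedRepeat]:
    """All maximal inverted repeats with arms >= min_arm and spacer <= max_spacer.

    With ``max_arm_edits`` = 0 only perfect IRs are returned; with a
    positive budget, quasi-palindromes (1..max_arm_edits arm edits) are
    appended. Arms never contain N. Results are sorted by left-arm start,
    then arm length descending.
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    if not seq:
        return []
    out = _perfect_scan(seq, min_arm, max_spacer, min_loop)
    if max_arm_edits > 0:
        quasi = _dedup_quasi(_quasi_scan(seq, min_arm, max_spacer, max_arm_edits, min_loop))
        out = out + quasi
        out.sort(key=lambda r: (r.left_start, -r.arm_len, r.spacer_len))
    return out


def find_quasi_palindromes(
    seq: str,
    min_arm: int = 5,
    max_spacer: int = 70,
    max_arm_edits: int = 1,
    min_loop: int = 0,
    focus_region: Optional[tuple[int, int]] = None,
) -> list[InvertedRepeat]:
    """Quasi-palindromes only: IRs with 1..max_arm_edits arm edits.

    Arm differences are scored by banded unit-cost edit distance between
    the left arm and the reverse complement of the right arm, anchored at
    the innermost complementary pair; the minimising edit count is
    reported. Perfect IRs are excluded (see find_inverted_repeats).

    ``focus_region`` (1-based inclusive) is a performance hint: only IRs
    whose arms could intersect the region are considered.
    """
    if max_arm_edits < 1:
        raise ValueError("max_arm_edits must be >= 1 for quasi-palindromes")
    if not seq:
        return []
    focus = None
    if focus_region is not None:
        focus = (focus_region[0] - 1, focus_region[1] - 1)
    out = _dedup_quasi(
        _quasi_scan(seq, min_arm, max_spacer, max_arm_edits, min_loop, focus=focus)
    )
    # drop indel-shifted re-descriptions of perfect IRs: a quasi whose
    # matched positions are no more than those of a perfect IR covering
    # the same footprint describes that perfect IR, not a new structure
    perfect = _perfect_scan(seq, max(2, min_arm - max_arm_edits), max_spacer, min_loop)
    kept = []
    for q in out:
        span_q = q.right_end - q.left_start + 1
        covered = False
        for p in perfect:
            if p.arm_len < q.arm_len - q.arm_edits:
                continue
            ov = min(q.right_end, p.right_end) - max(q.left_start, p.left_start) + 1
            if ov >= 0.8 * span_q:
                covered = True
                break
        if not covered:
            kept.append(q)
    return kept


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------


def find_tandem_repeats(
    seq: str,
    min_period: int = 1,
    max_period: int = 6,
    min_copies: float = 2.0,
    min_purity: float = 0.9,
) -> list[TandemRepeat]:
    """Maximal tandem arrays by self-match seeding and purity-scored extension.

    A seed is an exact self-match run at lag p covering two full copies;
    seeds are extended across mismatch gaps while overall purity (the
    fraction of matching bases at lag p over the span) stays above
    ``min_purity``. Overlapping reports are deduplicated preferring
    highest purity, then longest span, then smallest period.
    """
    n = len(seq)
    if n < 2 * min_period:
        return []
    if max_period > n // 2:
        max_period = n // 2
    x = encode(seq)
    cands: list[TandemRepeat] = []
    for p in range(max(1, min_period), max_period + 1):
        m = (x[:-p] == x[p:]) & (x[:-p] < 4)
        if not m.any():
            continue
        # maximal runs of True
        mi = np.flatnonzero(m)
        breaks = np.flatnonzero(np.diff(mi) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [mi.size - 1]))
        runs = [(int(mi[a]), int(mi[b])) for a, b in zip(run_starts, run_ends)]
        seen_spans = set()
        for ri, (rs, re) in enumerate(runs):
            if re - rs + 1 < p:
                continue  # not a two-copy exact seed
            lo, hi = rs, re
            matches = re - rs + 1
            # greedily absorb neighbouring runs while purity holds
            left_i, right_i = ri - 1, ri + 1
            changed = True
            while changed:
                changed = False
                if right_i < len(runs):
                    nrs, nre = runs[right_i]
                    gap = nrs - hi - 1
                    new_matches = matches + (nre - nrs + 1)
                    if gap <= p and new_matches / (nre - lo + 1) >= min_purity:
                        matches, hi = new_matches, nre
                        right_i += 1
                        changed = True
                if left_i >= 0:
                    prs, pre = runs[left_i]
                    gap = lo - pre - 1
                    new_matches = matches + (pre - prs + 1)
                    if gap <= p and new_matches / (hi - prs + 1) >= min_purity:
                        matches, lo = new_matches, prs
                        left_i -= 1
                        changed = True
            start0, end0 = lo, hi + p  # inclusive, 0-based sequence coords
            if (start0, end0) in seen_spans:
                continue
            seen_spans.add((start0, end0))
            span = end0 - start0 + 1
            copy_number = span / p
            purity = matches / (span - p)
            if copy_number < min_copies or purity < min_purity:
                continue
            cands.append(
                TandemRepeat(
                    unit=seq[start0 : start0 + p],
                    period=p,
                    copy_number=copy_number,
                    start=start0 + 1,
                    end=end0 + 1,
                    purity=purity,
                )
            )
    cands.sort(key=lambda t: (-t.purity, -(t.end - t.start), t.period, t.start))
    kept: list[TandemRepeat] = []
    for c in cands:
        span_c = c.end - c.start + 1
        clash = False
        for k in kept:
            ov = max(0, min(c.end, k.end) - max(c.start, k.start) + 1)
            if ov > 0.5 * span_c:
                clash = True
                break
        if not clash:
            kept.append(c)
    kept.sort(key=lambda t: (t.start, t.period))
    return kept


# ---------------------------------------------------------------------------
# direct-repeat (ABA <-> ABABA) decomposition
# ---------------------------------------------------------------------------


def _mean_pairwise_identity(copies: list[str]) -> float:
    tot, k = 0.0, 0
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            tot += identity(copies[i], copies[j])
            k += 1
    return tot / k if k else 0.0


def decompose_direct_repeat(event, min_similarity: float = 0.9):
    """Explain an INDEL as a direct-repeat-mediated ABA <-> ABABA change.

    The inserted (or deleted) unit of length L must approximately match
    the adjacent reference L-mer (a tandem duplication), and the split
    into A (direct repeat) + B (unique spacer) requires a third A copy on
    the far side, so that the long form reads A B A B A and the short
    form A B A. len(A) + len(B) equals the INDEL length. Among valid
    splits the one maximising A-copy similarity wins; ties prefer larger
    len_A, then the leftmost anchor. Returns None when no split reaches
    ``min_similarity``.
    """
    if event.event_type not in ("insertion", "deletion"):
        raise ValueError("decompose_direct_repeat requires an insertion or deletion")
    U = event.alt_allele if event.event_type == "insertion" else event.ref_allele
    L = len(U)
    if L < 2:
        return None
    left = event.flank_left or ""
    right = event.flank_right or ""
    pos = event.pos
    # 1-based reference coordinates of the flank boundaries
    # insertion: left ends at pos-1, right starts at pos
    # deletion:  left ends at pos-1, deleted unit at pos..pos+L-1, right at pos+L
    right_at = pos if event.event_type == "insertion" else pos + L

    best = None  # (similarity, len_A, -leftmost_anchor) ordering

    def consider(sim_a, a, anchors, A, B, unit_sim):
        nonlocal best
        if sim_a < min_similarity:
            return
        key = (sim_a, a, -anchors[0][0])
        if best is None or key > best[0]:
            best = (key, DirectRepeatDecomposition(
                A=A, B=B, len_A=a, len_B=L - a,
                similarity=sim_a, unit_similarity=unit_sim,
                anchors=tuple(anchors)))

    P = left[-L:] if len(left) >= L else None
    F = right[:L] if len(right) >= L else None

    if P is not None:
        unit_sim = identity(U, P)
        if unit_sim >= min_similarity:
            p_start = pos - L  # 1-based start of P in reference
            for a in range(1, L):
                # A is the unit suffix; third copy immediately left of P
                if len(left) >= L + a:
                    pre = left[-(L + a) : -L]
                    sim_a = _mean_pairwise_identity([U[-a:], P[-a:], pre])
                    anchors = [
                        (p_start - a, p_start - 1),
                        (p_start + (L - a), p_start + L - 1),
                    ]
                    consider(sim_a, a, anchors, P[-a:], P[: L - a], unit_sim)
                # A is the unit prefix; third copy immediately right of the site
                if len(right) >= a:
                    post = right[:a]
                    sim_a = _mean_pairwise_identity([U[:a], P[:a], post])
                    anchors = [(p_start, p_start + a - 1), (right_at, right_at + a - 1)]
                    consider(sim_a, a, anchors, P[:a], P[a:], unit_sim)
    if F is not None:
        unit_sim = identity(U, F)
        if unit_sim >= min_similarity:
            for a in range(1, L):
                # A is the unit prefix; third copy right of F
                if len(right) >= L + a:
                    post = right[L : L + a]
                    sim_a = _mean_pairwise_identity([U[:a], F[:a], post])
                    anchors = [
                        (right_at, right_at + a - 1),
                        (right_at + L, right_at + L + a - 1),
                    ]
                    consider(sim_a, a, anchors, F[:a], F[a:], unit_sim)
                # A is the unit suffix; third copy immediately left of the site
                if len(left) >= a:
                    pre = left[-a:]
                    sim_a = _mean_pairwise_identity([U[-a:], F[-a:], pre])
                    anchors = [
                        (pos - a, pos - 1),
                        (right_at + (L - a), right_at + L - 1),
                    ]
                    consider(sim_a, a, anchors, F[-a:], F[: L - a], unit_sim)
    return None if best is None else best[1]
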