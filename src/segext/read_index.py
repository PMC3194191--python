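"""FM-index over the concatenated insertion-read-set mate sequences.

The anchoring step of segment extension must find, for every length-l
substring of the anchor window, all whole mates in the insertion read set
(IRS) matching it with at most ``d`` substitutions. Scanning every IRS mate
per window position is quadratic in total insertion content; indexing the
concatenation R' of the mates with a Burrows–Wheeler transform makes each
lookup independent of |IRS|.

Both mates of every IRS pair are indexed in both orientations (four strings
per pair), so the anchor window never has to be reverse-complemented and a
hit's orientation is read off the offset map. Strings are separated by
sentinels; matches crossing a string boundary are discarded.

Search strategy: for patterns long enough to split into ``d+1`` blocks of at
least 6 bases, the pigeonhole variant is used (each block searched exactly by
FM backward search — any occurrence with ≤ d mismatches contains an exact
block — then candidates verified by a vectorised Hamming count). Shorter
patterns fall back to bounded backtracking over the BWT. Both are exact for
the budget.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from ._seq import revcomp_rows
from .classify import InsertionReadSet

SENTINEL = 4
_MAGIC = b"SEGEXTIDX1"


class ReadHit(NamedTuple):
    """One ≤ d-mismatch occurrence of a pattern inside an indexed mate."""

    pair: int  # index into the full pair array
    mate: int  # 0 = forward-file mate, 1 = reverse-file mate
    orient: int  # 0 = as sequenced, 1 = reverse complement
    offset_in_read: int
    mismatches: int


class ReadIndex:
    """BWT/FM-index over the concatenated IRS mate strings."""

    def __init__(self, strings: np.ndarray, pair_of_string: np.ndarray,
                 mate_of_string: np.ndarray, orient_of_string: np.ndarray,
                 seed: int = 0, _memo_cap: int = 1 << 20):
        if strings.ndim != 2:
            raise ValueError("strings must be a (m, l) matrix")
        self.l = int(strings.shape[1]) if strings.size else 0
        self.n_strings = int(strings.shape[0])
        self.pair_of_string = np.asarray(pair_of_string, dtype=np.int64)
        self.mate_of_string = np.asarray(mate_of_string, dtype=np.int8)
        self.orient_of_string = np.asarray(orient_of_string, dtype=np.int8)

        S = np.ascontiguousarray(strings, dtype=np.uint8)
        self.n_flagged = 0
        if S.size and (S >= 4).any():
            rng = np.random.default_rng([606, seed])
            mask = S >= 4
            self.n_flagged = int(mask.any(axis=1).sum())
            S = S.copy()
            S[mask] = rng.integers(0, 4, size=int(mask.sum()), dtype=np.uint8)
        self.strings = S
        self.string_bytes = [row.tobytes() for row in S]

        self.search_calls = 0  # instrumented bwt_search counter
        self._memo: dict[tuple[bytes, int], tuple] = {}
        self._memo_cap = _memo_cap
        self._build()

    # ------------------------------------------------------------------
    def _build(self) -> None:
        l = self.l
        m = self.n_strings
        stride = l + 1
        n = m * stride
        self.stride = stride
        self.n = n
        if n == 0:
            self.text = np.empty(0, dtype=np.uint8)
            self.sa = np.empty(0, dtype=np.int64)
            self.bwt = np.empty(0, dtype=np.uint8)
            self.occ = np.zeros((4, 1), dtype=np.int32)
            self.C = np.zeros(4, dtype=np.int64)
            return
        text = np.full(n, SENTINEL, dtype=np.uint8)
        text.reshape(m, stride)[:, :l] = self.strings
        self.text = text

        # suffix order: sort by the first (l+1) symbols (base 5, sentinel=4)
        # with position as a tie-break. Tie-breaking by text position is
        # self-consistent under the LF shift, and patterns never exceed l
        # symbols, so backward search is exact.
        pad = np.full(stride, SENTINEL, dtype=np.uint8)
        tp = np.concatenate([text, pad]).astype(np.int64)
        k1_len = min(19, stride)
        k2_len = stride - k1_len
        k1 = np.zeros(n, dtype=np.int64)
        for j in range(k1_len):
            k1 *= 5
            k1 += tp[j : j + n]
        if k2_len > 0:
            k2 = np.zeros(n, dtype=np.int64)
            for j in range(k1_len, stride):
                k2 *= 5
                k2 += tp[j : j + n]
            sa = np.lexsort((np.arange(n), k2, k1))
        else:
            sa = np.lexsort((np.arange(n), k1))
        self.sa = sa.astype(np.int32)  # text length stays below 2^31

        self.bwt = text[(self.sa - 1) % n]
        occ = np.zeros((4, n + 1), dtype=np.int32)
        for c in range(4):
            occ[c, 1:] = np.cumsum(self.bwt == c, dtype=np.int32)
        self.occ = occ
        counts = np.bincount(text, minlength=5).astype(np.int64)
        self.C = np.concatenate([[0], np.cumsum(counts[:4])])[:4]

    # ------------------------------------------------------------------
    def _backward_exact(self, pattern: np.ndarray,
                        sp: int = 0, ep: int | None = None) -> tuple[int, int]:
        """Exact backward search; returns the SA range [sp, ep)."""
        if ep is None:
            ep = self.n
        occ = self.occ
        C = self.C
        for c in pattern[::-1]:
            if c >= 4:
                return 0, 0
            sp = int(C[c]) + int(occ[c, sp])
            ep = int(C[c]) + int(occ[c, ep])
            if sp >= ep:
                return 0, 0
        return sp, ep

    _block_bounds: dict[tuple[int, int], tuple[tuple[int, int], ...]] = {}

    def _search_pigeonhole(self, p: np.ndarray, d: int):
        """Exact ≤ d-mismatch occurrences via pigeonhole blocks."""
        m = len(p)
        nb = d + 1
        bounds = self._block_bounds.get((m, nb))
        if bounds is None:
            edges = np.linspace(0, m, nb + 1).astype(int)
            bounds = tuple((int(edges[b]), int(edges[b + 1]))
                           for b in range(nb))
            self._block_bounds[(m, nb)] = bounds
        cands = []
        for lo, hi in bounds:
            block = p[lo:hi]
            if (block >= 4).any():
                continue  # a block containing N cannot be the exact block
            sp, ep = self._backward_exact(block)
            if sp < ep:
                cands.append(self.sa[sp:ep] - lo)
        if not cands:
            return (np.empty(0, np.int64), np.empty(0, np.int32))
        starts = cands[0] if len(cands) == 1 else np.unique(np.concatenate(cands))
        starts = starts[(starts >= 0) & (starts + m <= self.n)]
        if len(starts) == 0:
            return (np.empty(0, np.int64), np.empty(0, np.int32))
        win = self.text[starts[:, None] + np.arange(m)]
        mm = ((win != p) | (win >= 4) | (p >= 4)).sum(axis=1).astype(np.int32)
        keep = mm <= d
        return starts[keep], mm[keep]

    def _search_backtrack(self, p: np.ndarray, d: int):
        """Bounded-backtracking FM search (short patterns)."""
        results: list[tuple[int, int, int]] = []

        def go(i: int, sp: int, ep: int, mm: int) -> None:
            if i < 0:
                results.append((sp, ep, mm))
                return
            want = p[i]
            for c in range(4):
                cost = 0 if c == want else 1
                if mm + cost > d:
                    continue
                nsp = int(self.C[c]) + int(self.occ[c, sp])
                nep = int(self.C[c]) + int(self.occ[c, ep])
                if nsp < nep:
                    go(i - 1, nsp, nep, mm + cost)

        if self.n:
            go(len(p) - 1, 0, self.n, 0)
        if not results:
            return (np.empty(0, np.int64), np.empty(0, np.int32))
        starts = np.concatenate([self.sa[sp:ep] for sp, ep, _ in results])
        mm = np.concatenate([np.full(ep - sp, m, np.int32)
                             for sp, ep, m in results])
        order = np.argsort(starts, kind="stable")
        return starts[order], mm[order]

    # ------------------------------------------------------------------
    def search(self, pattern: np.ndarray, d: int):
        """All within-read occurrences of ``pattern`` with ≤ d substitutions.

        Returns ``(string_ids, offsets_in_read, mismatches)`` arrays;
        occurrences crossing a string boundary are discarded. Memoised.
        """
        if d > 3:
            raise ValueError("mismatch budget d > 3 is not supported")
        if self.n == 0:
            return (np.empty(0, np.int64), np.empty(0, np.int64),
                    np.empty(0, np.int32))
        if len(pattern) > self.l:
            raise ValueError("pattern longer than the indexed read length")
        self.search_calls += 1
        key = (pattern.tobytes(), d)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        if self.n == 0 or len(pattern) == 0:
            out = (np.empty(0, np.int64), np.empty(0, np.int64),
                   np.empty(0, np.int32))
        else:
            if d == 0:
                sp, ep = self._backward_exact(pattern)
                starts = np.sort(self.sa[sp:ep])
                mm = np.zeros(len(starts), dtype=np.int32)
            elif len(pattern) // (d + 1) >= 6:
                starts, mm = self._search_pigeonhole(pattern, d)
            else:
                starts, mm = self._search_backtrack(pattern, d)
            offs = starts % self.stride
            ok = offs + len(pattern) <= self.l
            out = (starts[ok] // self.stride, offs[ok], mm[ok])
        if len(self._memo) >= self._memo_cap:
            self._memo.clear()
        self._memo[key] = out
        return out

    def bwt_search(self, pattern: np.ndarray, d: int) -> list[ReadHit]:
        """Occurrence list resolved through the offset map."""
        sids, offs, mm = self.search(np.asarray(pattern, dtype=np.uint8), d)
        return [ReadHit(int(self.pair_of_string[s]),
                        int(self.mate_of_string[s]),
                        int(self.orient_of_string[s]), int(o), int(m))
                for s, o, m in zip(sids, offs, mm)]

    def partner_sid(self, sid: int, orient: int) -> int:
        """String id of the opposite mate of ``sid``'s pair, in ``orient``."""
        base = (sid // 4) * 4
        mate = (sid % 4) // 2
        return base + 2 * (1 - mate) + orient

    def to_file(self, path) -> None:
        """Serialize to a single binary file with a versioned magic header."""
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            np.save(fh, np.array([self.l, self.n_strings], dtype=np.int64))
            np.save(fh, self.strings)
            np.save(fh, self.pair_of_string)
            np.save(fh, self.mate_of_string)
            np.save(fh, self.orient_of_string)

    @classmethod
    def from_file(cls, path) -> "ReadIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(_MAGIC))
            if magic != _MAGIC:
                raise ValueError("not a read-index file (bad magic)")
            np.load(fh)  # shape echo
            strings = np.load(fh)
            pair_of = np.load(fh)
            mate_of = np.load(fh)
            orient_of = np.load(fh)
        return cls(strings, pair_of, mate_of, orient_of)


class AnchorHit(NamedTuple):
    """A whole-mate match anchored at a window position."""

    window_pos: int
    sid: int  # string id in the index
    mismatches: int


def build_read_index(reads1: np.ndarray, reads2: np.ndarray,
                     irs: InsertionReadSet, seed: int = 0) -> ReadIndex:
    """Index both mates of every IRS pair in both orientations.

    String ids are laid out four per pair: ``4i`` = mate1 forward, ``4i+1`` =
    mate1 reverse complement, ``4i+2`` / ``4i+3`` the same for mate2.
    """
    rows = irs.pair_indices
    l = reads1.shape[1] if reads1.ndim == 2 else 0
    m = len(rows)
    S = np.empty((4 * m, l), dtype=np.uint8)
    if m:
        m1 = reads1[rows]
        m2 = reads2[rows]
        S[0::4] = m1
        S[1::4] = revcomp_rows(m1)
        S[2::4] = m2
        S[3::4] = revcomp_rows(m2)
    sid = np.arange(4 * m)
    pair_of = np.repeat(rows, 4) if m else np.empty(0, np.int64)
    mate_of = (sid % 4) // 2
    orient_of = sid % 2
    return ReadIndex(S, pair_of, mate_of, orient_of, seed=seed)


def find_anchored(index: ReadIndex, window: np.ndarray, l: int | None = None,
                  d: int = 2) -> list[AnchorHit]:
    """Whole mates anchored inside the window.

    Issues exactly ``|window| − l + 1`` search calls (one per length-l
    substring), keeping hits with offset_in_read = 0 — whole-mate matches
    only, as the anchoring condition requires the anchor mate to lie wholly
    inside the window.
    """
    if l is None:
        l = index.l
    window = np.asarray(window, dtype=np.uint8)
    out: list[AnchorHit] = []
    for w in range(len(window) - l + 1):
        sids, offs, mm = index.search(window[w : w + l], d)
        for s, o, m in zip(sids, offs, mm):
            if o == 0:
                out.append(AnchorHit(w, int(s), int(m)))
    return out
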