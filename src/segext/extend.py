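"""Iterative segment extension: the core insertion assembler.

Starting from a reference-derived flank next to an insertion locus, the
assembler repeatedly determines the next donor base. For the next unknown
position ``pos`` it:

1. finds mates *anchored* in the anchor window
   ``Donor[pos − l − Δmax : pos − Δmin]`` (condition Φ_A, via the read
   index — one search per window substring);
2. keeps anchored pairs whose opposite mate *extends* the known sequence:
   its length-``ext`` prefix aligns (⊕, ungapped, mismatch fraction
   ≤ 1 − τ) to the segment suffix, with ``κ < ext < l`` (condition Φ_E);
   that mate's base at index ``ext`` is its vote for ``Donor[pos]``;
3. takes the consensus: a base with vote fraction ≥ ε is called; two or
   more bases above ε_branch signal a *divergence* and both branches are
   explored; otherwise the branch terminates.

Branch exploration is depth-first with a beam cap and a per-call node
budget. Reverse-direction extension reverse-complements the segment,
extends forward, and reverse-complements the result. Among the surviving
hypotheses the one accounting for the greatest number of IRS reads wins.

The production engine is an incremental (sliding-window) evaluation of the
same covering-set definition exposed by :func:`covering_set`: anchors enter
when the window's newest substring is searched, and each anchored partner is
tested once per candidate alignment start (the earliest informative overlap,
``ext = κ+1``, is matched exactly; mismatch tolerance then accrues with the
growing overlap). The definitional and incremental routes are tested to
agree on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._seq import revcomp
from .classify import InsertSizeModel
from .read_index import ReadIndex, find_anchored


@dataclass
class AlignParams:
    """Tunables of the ⊕ alignment test and the consensus/branch rules.

    tau — minimum identity fraction for ⊕ (ungapped; score = matches/length).
    kappa — minimum informative overlap (bp); shorter overlaps are noise.
    eps — vote fraction for an immediately confident consensus call.
    eps_branch — support threshold: bases at or above it are candidate
        column values (two or more trigger a divergence; a lone one is
        called even below eps; none terminates the branch). Kept distinct
        from eps so confident calls and branch support can be tuned apart.
    d — substitution budget for the anchoring search.
    max_branches — beam cap on simultaneously surviving hypotheses.
    max_extension — safety cap (bp) on one endpoint's extension.
    node_budget — total consensus columns one extend_segment call may spend.
    relax_delta — tau reduction used by the single relaxed retry.
    """

    tau: float = 0.9
    kappa: int = 5
    eps: float = 0.7
    eps_branch: float = 0.35
    d: int = 2
    max_branches: int = 8
    max_extension: int = 4500
    node_budget: int = 60000
    relax_delta: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.eps <= 1.0:
            raise ValueError("eps must be in (0, 1]")
        if not 0.0 < self.eps_branch <= 1.0:
            raise ValueError("eps_branch must be in (0, 1]")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.max_branches < 1:
            raise ValueError("max_branches must be >= 1")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")

    def max_mismatches(self, length: int) -> int:
        """Largest mismatch count with identity still above tau."""
        return int((1.0 - self.tau) * length)

    def relaxed(self) -> "AlignParams":
        return AlignParams(tau=self.tau - self.relax_delta, kappa=self.kappa,
                           eps=self.eps, eps_branch=self.eps_branch, d=self.d,
                           max_branches=self.max_branches,
                           max_extension=self.max_extension,
                           node_budget=self.node_budget,
                           relax_delta=self.relax_delta)


@dataclass
class Segment:
    """A reference-derived donor segment between insertion loci."""

    sequence: np.ndarray  # uint8 codes; the core is never rewritten
    left_locus: int = -1
    right_locus: int = -1
    seg_id: str = ""


class CoveringRead(NamedTuple):
    """One member of the covering set for a position."""

    pair: int
    mate: int
    orient: int
    ext: int  # overlap of the extending mate's prefix with the known suffix
    vote: int  # the mate's base at index ext
    anchor_pos: int  # window offset of the anchored partner
    sid: int  # string id of the extending mate in the index


@dataclass
class Hypothesis:
    """One candidate extended sequence for a segment endpoint."""

    sequence: np.ndarray  # core + appended bases (codes)
    core_len: int
    ext_len: int
    path: list[tuple[int, int]]  # (position, base) branch decisions
    consumed: set[int]  # pair ids used up during extension
    support: np.ndarray  # covering-set size per appended position
    reason: str  # "consensus", "max_extension", "budget"
    accounted_read_count: int | None = None


# ---------------------------------------------------------------------------
# definitional operations (also the oracle surface)
# ---------------------------------------------------------------------------

def anchor_window(segment_length: int, pos: int, model: InsertSizeModel,
                  l: int) -> tuple[int, int]:
    """Anchor-window interval [pos − l − Δmax, pos − Δmin) in segment coords."""
    dmin = int(round(model.delta_min))
    dmax = int(round(model.delta_max))
    start = pos - l - dmax
    end = pos - dmin
    if start < 0:
        raise RuntimeError(
            f"known flank too short for extension at pos {pos} "
            f"(need {l + dmax} determined bases)")
    if end > segment_length:
        raise RuntimeError("anchor window extends past determined sequence")
    return start, end


def compute_ext(mate: np.ndarray, known: np.ndarray,
                params: AlignParams) -> tuple[int, int] | None:
    """Largest ext in (κ, l) whose prefix/suffix overlap passes ⊕.

    ``known`` is the determined sequence up to (excluding) the position being
    decided. Returns ``(ext, vote)`` or None; the vote is ``mate[ext]``.
    """
    l = len(mate)
    hi = min(l - 1, len(known))
    for ext in range(hi, params.kappa, -1):
        a = mate[:ext]
        b = known[len(known) - ext:]
        mm = int(np.count_nonzero((a != b) | (a >= 4) | (b >= 4)))
        if mm <= params.max_mismatches(ext):
            return ext, int(mate[ext])
    return None


def _phi_e_candidates(index: ReadIndex, anchors, known: np.ndarray,
                      params: AlignParams) -> list[CoveringRead]:
    """Φ_E pass shared by the definitional covering-set routes."""
    out: list[CoveringRead] = []
    settled: set[int] = set()
    for hit in anchors:
        sid = hit.sid
        pair = int(index.pair_of_string[sid])
        if pair in settled:
            continue
        for orient in (0, 1):
            psid = index.partner_sid(sid, orient)
            res = compute_ext(index.strings[psid], known, params)
            if res is not None:
                ext, vote = res
                out.append(CoveringRead(
                    pair=pair, mate=int(index.mate_of_string[psid]),
                    orient=orient, ext=ext, vote=vote,
                    anchor_pos=hit.window_pos, sid=psid))
                settled.add(pair)
                break
    return out


def covering_set(pos: int, segment: np.ndarray, index: ReadIndex,
                 params: AlignParams, model: InsertSizeModel
                 ) -> list[CoveringRead]:
    """Reads covering ``segment[pos]``: anchored (Φ_A) and extending (Φ_E).

    Both orientations of the anchored pair's opposite mate are tested and the
    first that extends is settled on.
    """
    l = index.l
    ws, we = anchor_window(len(segment) if len(segment) > pos else pos,
                           pos, model, l)
    window = segment[ws:we]
    anchors = find_anchored(index, window, l, params.d)
    return _phi_e_candidates(index, anchors, segment[:pos], params)


def covering_set_naive(pos: int, segment: np.ndarray, index: ReadIndex,
                       params: AlignParams, model: InsertSizeModel
                       ) -> list[CoveringRead]:
    """Brute-force covering set: direct Φ_A ∧ Φ_E over every IRS mate.

    The per-read anchoring scan is linear in |IRS|; this is the oracle the
    indexed route is tested against, and the slow arm of the scaling
    comparison.
    """
    from .read_index import AnchorHit

    l = index.l
    ws, we = anchor_window(len(segment) if len(segment) > pos else pos,
                           pos, model, l)
    window = segment[ws:we]
    anchors: list[AnchorHit] = []
    S = index.strings
    for w in range(len(window) - l + 1):
        sub = window[w : w + l]
        mm = ((S != sub) | (S >= 4) | (sub >= 4)).sum(axis=1)
        for sid in np.flatnonzero(mm <= params.d):
            anchors.append(AnchorHit(w, int(sid), int(mm[sid])))
    anchors.sort(key=lambda h: (h.window_pos, h.sid))
    return _phi_e_candidates(index, anchors, segment[:pos], params)


CALL = "call"
DIVERGENCE = "divergence"
TERMINATE = "terminate"


def consensus_step(votes, params: AlignParams):
    """Decide one consensus column from covering-set votes.

    ``votes`` is an iterable of base codes (one read, one vote). Returns
    ``(CALL, base)``, ``(DIVERGENCE, [bases])`` ordered by support, or
    ``(TERMINATE, None)``.

    A base is *supported* when its vote fraction reaches ε_branch. Exactly
    one supported base is called (immediately when it also clears ε); two or
    more supported bases are a divergence; none is insufficient consensus.
    Calling the lone supported plurality matters at copy junctions, where
    extenders from the losing population keep voting for a few columns
    (their ⊕ mismatch budget is not yet spent) and dilute the true base
    below any strict-majority threshold.
    """
    counts = np.zeros(4, dtype=np.int64)
    for v in votes:
        if v < 4:
            counts[v] += 1
    total = int(counts.sum())
    if total == 0:
        return TERMINATE, None
    frac = counts / total
    branchable = [int(c) for c in np.argsort(-counts, kind="stable")
                  if frac[c] >= params.eps_branch and counts[c] > 0]
    if len(branchable) >= 2:
        return DIVERGENCE, branchable
    top = int(np.argmax(counts))
    if frac[top] >= params.eps or branchable:
        return CALL, top
    return TERMINATE, None


# ---------------------------------------------------------------------------
# the incremental extension engine
# ---------------------------------------------------------------------------

class _BranchState:
    __slots__ = ("seq", "pos", "live", "active", "active_pairs", "consumed",
                 "support", "path")

    def __init__(self, seq, pos, live, active, active_pairs, consumed,
                 support, path):
        self.seq = seq
        self.pos = pos
        self.live = live  # partner sid -> expiry pos
        self.active = active  # partner sid -> [start, mismatches]
        self.active_pairs = active_pairs
        self.consumed = consumed
        self.support = support
        self.path = path

    def fork(self) -> "_BranchState":
        return _BranchState(self.seq.copy(), self.pos, dict(self.live),
                            {k: v.copy() for k, v in self.active.items()},
                            set(self.active_pairs), set(self.consumed),
                            list(self.support), list(self.path))


def _ingest_anchors(index: ReadIndex, st: _BranchState, w: int, kappa: int,
                    dmin: int, dmax: int, l: int, d: int,
                    params: AlignParams) -> None:
    """Search the window substring starting at ``w``; register new anchors."""
    sids, offs, _mm = index.search(st.seq[w : w + l], d)
    if len(sids) == 0:
        return
    pos = st.pos
    seq = st.seq
    kp1 = kappa + 1
    for sid, off in zip(sids.tolist(), offs.tolist()):
        if off != 0:
            continue
        a = w  # anchor start in segment coordinates
        pair = int(index.pair_of_string[sid])
        if pair in st.active_pairs:
            continue
        for orient in (0, 1):
            psid = index.partner_sid(sid, orient)
            if psid in st.active or psid in st.live:
                continue
            st.live[psid] = a + dmax - l + kappa + 1
            # backlog: alignment starts already past their earliest overlap
            s_lo = max(a + dmin - l, pos - l + 1)
            s_hi = min(pos - kappa - 1, a + dmax - l)
            if s_lo > s_hi:
                continue
            partner = index.strings[psid]
            starts = np.arange(s_lo, s_hi + 1)
            head = seq[starts[:, None] + np.arange(kp1)]
            cand = starts[(head == partner[:kp1]).all(axis=1)]
            for s in cand.tolist():
                ext = pos - s
                aseg = partner[:ext]
                bseg = seq[s:pos]
                mmc = int(np.count_nonzero(aseg != bseg))
                if mmc <= params.max_mismatches(ext):
                    if pair not in st.active_pairs:
                        st.active[psid] = [s, mmc]
                        st.active_pairs.add(pair)
                        st.live.pop(psid, None)
                    break


def _advance_live(index: ReadIndex, st: _BranchState, kappa: int) -> None:
    """Test every live candidate at the newly informative start s_new."""
    if not st.live:
        return
    pos = st.pos
    s_new = pos - kappa - 1
    kp1 = kappa + 1
    expired = [sid for sid, exp in st.live.items() if pos > exp]
    for sid in expired:
        del st.live[sid]
    if not st.live or s_new < 0:
        return
    sids = np.fromiter(st.live.keys(), dtype=np.int64, count=len(st.live))
    head = index.strings[sids, :kp1]
    hitrows = np.flatnonzero((head == st.seq[s_new : s_new + kp1]).all(axis=1))
    for r in hitrows.tolist():
        psid = int(sids[r])
        pair = int(index.pair_of_string[psid])
        if pair in st.active_pairs:
            continue
        st.active[psid] = [s_new, 0]
        st.active_pairs.add(pair)
        del st.live[psid]


def _column(index: ReadIndex, st: _BranchState, params: AlignParams):
    """Gather votes from the active extenders for the current position."""
    counts = [0, 0, 0, 0]
    voters = []
    pos = st.pos
    sb = index.string_bytes
    for psid, rec in st.active.items():
        ext = pos - rec[0]
        v = sb[psid][ext]
        counts[v] += 1
        voters.append((psid, ext, v))
    return counts, voters


def _apply_call(index: ReadIndex, st: _BranchState, base: int, voters,
                params: AlignParams) -> None:
    l = index.l
    drop = []
    for psid, ext, v in voters:
        rec = st.active[psid]
        if v != base:
            rec[1] += 1
            if rec[1] > params.max_mismatches(ext + 1):
                pair = int(index.pair_of_string[psid])
                st.active_pairs.discard(pair)
                drop.append(psid)
                continue
        if ext + 1 >= l:  # extender exhausted: the whole mate was used
            st.consumed.add(int(index.pair_of_string[psid]))
            drop.append(psid)
    for psid in drop:
        st.active.pop(psid, None)
    st.seq[st.pos] = base
    st.pos += 1


def extend_segment(segment: Segment | np.ndarray, direction: str,
                   index: ReadIndex, params: AlignParams,
                   model: InsertSizeModel, use_index: bool = True,
                   trace=None) -> list[Hypothesis]:
    """Extend one endpoint of a segment; returns all surviving hypotheses.

    ``direction`` is ``"forward"`` (grow past the right end) or ``"reverse"``
    (grow past the left end, implemented by reverse-complementing).
    """
    core = segment.sequence if isinstance(segment, Segment) else segment
    core = np.asarray(core, dtype=np.uint8)
    if direction == "reverse":
        hyps = extend_segment(revcomp(core), "forward", index, params, model,
                              use_index=use_index, trace=trace)
        for h in hyps:
            h.sequence = revcomp(h.sequence)
            h.support = h.support[::-1].copy()
        return hyps
    if direction != "forward":
        raise ValueError("direction must be 'forward' or 'reverse'")

    l = index.l
    dmin = int(round(model.delta_min))
    dmax = int(round(model.delta_max))
    if len(core) < 2 * l + dmax:
        raise RuntimeError(
            f"flank of {len(core)} bp is shorter than the required "
            f"2l + Δmax = {2 * l + dmax} bp base case")
    core_len = len(core)
    cap = core_len + params.max_extension + 8
    seq0 = np.empty(cap, dtype=np.uint8)
    seq0[:core_len] = core

    st0 = _BranchState(seq0, core_len, {}, {}, set(), set(), [], [])
    # initial window fill for the first position
    w_first, w_last = core_len - l - dmax, core_len - dmin - l
    for w in range(w_first, w_last + 1):
        if use_index:
            _ingest_anchors(index, st0, w, params.kappa, dmin, dmax, l,
                            params.d, params)
    done: list[Hypothesis] = []
    stack = [st0]
    nodes = 0
    n_branches = 1

    def finalize(st: _BranchState, reason: str) -> None:
        ext_len = st.pos - core_len
        done.append(Hypothesis(
            sequence=st.seq[: st.pos].copy(), core_len=core_len,
            ext_len=ext_len, path=st.path, consumed=st.consumed,
            support=np.asarray(st.support[:ext_len], dtype=np.int64),
            reason=reason))

    while stack:
        st = stack.pop()
        reason = None
        while reason is None:
            if st.pos - core_len >= params.max_extension:
                reason = "max_extension"
                break
            if nodes >= params.node_budget:
                reason = "budget"
                break
            nodes += 1
            if use_index:
                _ingest_anchors(index, st, st.pos - dmin - l, params.kappa,
                                dmin, dmax, l, params.d, params)
                _advance_live(index, st, params.kappa)
                counts, voters = _column(index, st, params)
            else:
                cov = covering_set_naive(st.pos, st.seq[: st.pos], index,
                                         params, model)
                counts = [0, 0, 0, 0]
                voters = []
                for cr in cov:
                    counts[cr.vote] += 1
                decision_votes = [cr.vote for cr in cov]
            st.support.append(int(sum(counts)))
            if trace is not None:
                trace(st, counts)
            total = sum(counts)
            if total == 0:
                reason = "consensus"
                break
            frac = [c / total for c in counts]
            branchable = sorted((c for c in range(4)
                                 if frac[c] >= params.eps_branch and counts[c]),
                                key=lambda c: -counts[c])
            if len(branchable) >= 2:
                for alt in branchable[1:]:
                    if n_branches >= params.max_branches:
                        break
                    alt_st = st.fork()
                    alt_st.path = alt_st.path + [(alt_st.pos, int(alt))]
                    if use_index:
                        _apply_call(index, alt_st, int(alt), voters, params)
                    else:
                        alt_st.seq[alt_st.pos] = int(alt)
                        alt_st.pos += 1
                    stack.append(alt_st)
                    n_branches += 1
                chosen = branchable[0]
                st.path = st.path + [(st.pos, int(chosen))]
            elif branchable or frac[int(np.argmax(counts))] >= params.eps:
                chosen = int(np.argmax(counts))
            else:
                reason = "consensus"
                break
            if use_index:
                _apply_call(index, st, int(chosen), voters, params)
            else:
                st.seq[st.pos] = int(chosen)
                st.pos += 1
        finalize(st, reason)
    return done


# ---------------------------------------------------------------------------
# hypothesis selection
# ---------------------------------------------------------------------------

def accounted_reads(hyp: Hypothesis, index: ReadIndex,
                    params: AlignParams) -> set[int]:
    """Pairs with at least one mate ⊕-placeable somewhere on the hypothesis."""
    l = index.l
    d = min(3, params.max_mismatches(l))
    seq = hyp.sequence
    pairs: set[int] = set()
    for w in range(len(seq) - l + 1):
        sids, offs, _ = index.search(seq[w : w + l], d)
        for sid, off in zip(sids.tolist(), offs.tolist()):
            if off == 0:
                pairs.add(int(index.pair_of_string[sid]))
    return pairs


def score_and_select(hypotheses: list[Hypothesis], index: ReadIndex,
                     params: AlignParams) -> Hypothesis:
    """Pick the hypothesis accounting for the most IRS reads.

    Ties go to the earliest hypothesis in branch order (deterministic).
    """
    if not hypotheses:
        raise ValueError("no hypotheses to select from")
    if len(hypotheses) == 1:
        h = hypotheses[0]
        if h.accounted_read_count is None:
            h.accounted_read_count = len(h.consumed)
        return h
    best = None
    best_score = -1
    for h in hypotheses:
        h.accounted_read_count = len(accounted_reads(h, index, params))
        if h.accounted_read_count > best_score:
            best = h
            best_score = h.accounted_read_count
    return best
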