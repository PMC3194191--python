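"""Contig merging and accuracy evaluation against planted truth.

After both flanks of an insertion have been extended toward each other, the
two extended segments are merged at their best ungapped overlap (≥ one read
length, passing ⊕). An insertion is scored correct when the truth sequence
places within the assembled contig at ≤ 10 edits (Levenshtein; best local
placement on either strand, since assembled contigs carry reference flanks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import decode, revcomp_str
from .extend import AlignParams, Hypothesis

MERGED = "merged"
PARTIAL = "partial"

_CORE_SUPPORT = 1 << 30  # reference-derived bases outrank any covering set


def _support_profile(h: Hypothesis, ext_at_start: bool) -> np.ndarray:
    """Per-position support: core positions get effectively infinite weight."""
    core = np.full(h.core_len, _CORE_SUPPORT, dtype=np.int64)
    ext = h.support
    if len(ext) != h.ext_len:  # defensive; support is per appended base
        ext = np.resize(ext, h.ext_len)
    return np.concatenate([ext, core] if ext_at_start else [core, ext])


def merge_adjacent(left: Hypothesis, right: Hypothesis,
                   params: AlignParams | None = None,
                   min_overlap: int = 36) -> tuple[np.ndarray | None, str]:
    """Merge a forward-extended left segment with a reverse-extended right one.

    Finds the ungapped overlap of at least one read length maximising
    matches under ⊕; disagreeing overlap columns take the base from the side
    with the larger covering support. Returns ``(contig, "merged")`` or
    ``(None, "partial")`` when no acceptable overlap exists.
    """
    params = params or AlignParams()
    L = left.sequence
    R = right.sequence
    min_o = min_overlap  # at least one read length of overlap
    best: tuple[int, int] | None = None  # (score, o)
    o_max = min(len(L), len(R))
    for o in range(min_o, o_max + 1):
        a = L[len(L) - o:]
        b = R[:o]
        mm = int(np.count_nonzero(a != b))
        if mm <= params.max_mismatches(o):
            score = o - mm
            if best is None or score > best[0] or (score == best[0] and o > best[1]):
                best = (score, o)
    if best is None:
        return None, PARTIAL
    o = best[1]
    supL = _support_profile(left, ext_at_start=False)
    supR = _support_profile(right, ext_at_start=True)
    a = L[len(L) - o:].copy()
    b = R[:o]
    disagree = np.flatnonzero(a != b)
    if len(disagree):
        wl = supL[len(L) - o + disagree]
        wr = supR[disagree]
        take_right = wr > wl
        a[disagree[take_right]] = b[disagree[take_right]]
    contig = np.concatenate([L[: len(L) - o], a, R[o:]])
    return contig, MERGED


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (substitutions + indels)."""
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def _best_local_distance(truth_seq: str, contig: str) -> int:
    """Min edit distance of the truth placed anywhere within the contig."""
    if not contig:
        return len(truth_seq)
    d_f = edlib.align(truth_seq, contig, mode="HW",
                      task="distance")["editDistance"]
    d_r = edlib.align(revcomp_str(truth_seq), contig, mode="HW",
                      task="distance")["editDistance"]
    return int(min(d_f, d_r))


@dataclass
class InsertionResult:
    insertion_id: str
    distance: int
    correct: bool
    status: str  # merged / partial / failed


@dataclass
class ReplicateResult:
    n_insertions: int
    n_correct: int
    details: list[InsertionResult] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        """Percent of insertions assembled within the edit threshold."""
        if self.n_insertions == 0:
            return 100.0
        return 100.0 * self.n_correct / self.n_insertions


@dataclass
class AccuracyReport:
    """Aggregate accuracy over replicates (mean ± sample SD, percent)."""

    replicates: list[ReplicateResult]
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.replicates]))

    @property
    def sd_accuracy(self) -> float:
        accs = [r.accuracy for r in self.replicates]
        if len(accs) < 2:
            return 0.0
        return float(np.std(accs, ddof=1))


def score_assembly(assembled: dict[str, list[str] | str | None],
                   truth, threshold: int = 10) -> ReplicateResult:
    """Score one replicate's assemblies against its truth records.

    ``assembled`` maps insertion_id to a contig, a list of partial fragments,
    or None (explicit failure). An insertion is correct when the truth
    sequence locally places within any of its fragments at ≤ ``threshold``
    edits on either strand.
    """
    ids = {t.insertion_id for t in truth}
    extra = set(assembled) - ids
    if extra:
        raise ValueError(f"assembled ids not in truth: {sorted(extra)[:3]}")
    details = []
    n_correct = 0
    for t in truth:
        entry = assembled.get(t.insertion_id)
        if entry is None:
            details.append(InsertionResult(t.insertion_id,
                                           len(t.true_sequence), False,
                                           "failed"))
            continue
        frags = [entry] if isinstance(entry, str) else list(entry)
        dist = min(_best_local_distance(t.true_sequence, f) for f in frags)
        ok = dist <= threshold
        n_correct += ok
        status = MERGED if isinstance(entry, str) else PARTIAL
        details.append(InsertionResult(t.insertion_id, dist, bool(ok), status))
    return ReplicateResult(n_insertions=len(truth), n_correct=n_correct,
                           details=details)


def write_report_tsv(report: AccuracyReport, path, label: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("label\treplicate\tn_insertions\tn_correct\taccuracy_pct\n")
        for i, r in enumerate(report.replicates):
            fh.write(f"{label}\t{i}\t{r.n_insertions}\t{r.n_correct}\t"
                     f"{r.accuracy:.2f}\n")
        fh.write(f"{label}\tmean\t-\t-\t{report.mean_accuracy:.2f}\n")
        fh.write(f"{label}\tsd\t-\t-\t{report.sd_accuracy:.2f}\n")


def write_details_tsv(result: ReplicateResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("insertion_id\tedit_distance\tcorrect\tstatus\n")
        for d in result.details:
            fh.write(f"{d.insertion_id}\t{d.distance}\t"
                     f"{int(d.correct)}\t{d.status}\n")


def contigs_to_fasta(contigs: dict[str, np.ndarray | None], path) -> None:
    from ._seq import write_fasta

    records = []
    for name, seq in contigs.items():
        if seq is None:
            continue
        records.append((name, decode(seq) if not isinstance(seq, str) else seq))
    write_fasta(path, records)
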