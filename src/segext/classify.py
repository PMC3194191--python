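"""Read-pair classification and the insertion read set (IRS).

Pairs are partitioned into four categories from their mapping location sets:

* ``ORPHAN`` — neither mate maps (both mates inside unique inserted sequence),
* ``OEA`` — exactly one mate maps (one-end anchored; mate in unique content),
* ``CONCORDANT`` — some location pair has opposite strands and an outer
  fragment span within [Δmin, Δmax],
* ``DISCORDANT`` — both map but no location pair is concordant.

Over-coverage is a flag on concordant pairs, not a fifth partition cell: a
concordant pair whose local read depth is k times the genome mean is admitted
to the IRS with probability (k−1)/k, so a doubled region contributes the ~50%
of its reads that originated from the copy. The IRS is the union of OEA,
orphan, discordant and admitted over-coverage pairs.

Concordance quantifies existentially over the cross-product of the two
mates' location sets; the fragment span is measured outer-to-outer
(rightmost base of the reverse-strand mate minus leftmost base of the
forward-strand mate, plus one read length implicitly via the rightmost end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import FORWARD, MappingLoc, MappingTable

# partition labels
OEA = 0
ORPHAN = 1
CONCORDANT = 2
DISCORDANT = 3
LABEL_NAMES = {OEA: "OEA", ORPHAN: "ORPHAN", CONCORDANT: "CONCORDANT",
               DISCORDANT: "DISCORDANT"}

# IRS membership flags
FLAG_OEA = 1
FLAG_ORPHAN = 2
FLAG_DISCORDANT = 4
FLAG_OVER_COVERAGE = 8


@dataclass(frozen=True)
class InsertSizeModel:
    """Normal fragment-length model with hard 3σ bounds."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.delta_min <= 0:
            raise ValueError("mu - 3*sigma must be positive")

    @property
    def delta_min(self) -> float:
        return self.mu - 3.0 * self.sigma

    @property
    def delta_max(self) -> float:
        return self.mu + 3.0 * self.sigma


def _concordant_span(f: MappingLoc, r: MappingLoc, l: int) -> float:
    """Outer fragment span for a forward hit f and reverse hit r."""
    return r.position + l - f.position


def classify_pair(plus_locs, minus_locs, model: InsertSizeModel,
                  read_length: int) -> int:
    """Classify one pair from its two location sets (reference semantics)."""
    plus_locs = list(plus_locs)
    minus_locs = list(minus_locs)
    if not plus_locs and not minus_locs:
        return ORPHAN
    if not plus_locs or not minus_locs:
        return OEA
    for a in plus_locs:
        for b in minus_locs:
            if a.strand == b.strand:
                continue
            f, r = (a, b) if a.strand == FORWARD else (b, a)
            span = _concordant_span(f, r, read_length)
            if model.delta_min <= span <= model.delta_max:
                return CONCORDANT
    return DISCORDANT


def classify_pairs(table: MappingTable, model: InsertSizeModel) -> np.ndarray:
    """Vectorised classification of every pair; returns a label array."""
    n = table.n_pairs
    l = table.read_length
    c1 = table.hit_counts(0)
    c2 = table.hit_counts(1)
    labels = np.full(n, DISCORDANT, dtype=np.uint8)
    labels[(c1 == 0) & (c2 == 0)] = ORPHAN
    labels[(c1 == 0) ^ (c2 == 0)] = OEA

    both = np.flatnonzero((c1 > 0) & (c2 > 0))
    if len(both) == 0:
        return labels
    cnt = (c1[both] * c2[both]).astype(np.int64)
    total = int(cnt.sum())
    start = np.cumsum(cnt) - cnt
    tt = np.arange(total) - np.repeat(start, cnt)
    c2r = np.repeat(c2[both], cnt)
    plus_idx = np.repeat(table.offsets[0][both], cnt) + tt // c2r
    minus_idx = np.repeat(table.offsets[1][both], cnt) + tt % c2r
    s1 = table.strand[0][plus_idx]
    s2 = table.strand[1][minus_idx]
    p1 = table.pos[0][plus_idx]
    p2 = table.pos[1][minus_idx]
    fpos = np.where(s1 == FORWARD, p1, p2)
    rpos = np.where(s1 == FORWARD, p2, p1)
    span = rpos + l - fpos
    ok = (s1 != s2) & (span >= model.delta_min) & (span <= model.delta_max)
    pair_of = np.repeat(both, cnt)
    conc = np.zeros(n, dtype=bool)
    conc[pair_of[ok]] = True
    labels[both] = np.where(conc[both], CONCORDANT, DISCORDANT)
    return labels


# ---------------------------------------------------------------------------
# depth of coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-position depth plus the derived per-read mean depths.

    Multi-mapped mates contribute a single placement chosen uniformly at
    random (seeded); the genome mean is taken over covered positions only, so
    unsequenced gaps do not deflate it.
    """

    depth: np.ndarray
    mu_doc: float
    mu_doc_read: list[np.ndarray]  # per mate, NaN where unmapped
    placement: list[np.ndarray]  # chosen position per mate, -1 where unmapped

    def mu_doc_pair(self) -> np.ndarray:
        """Per-pair mean of the two mates' per-read depths (NaN-aware)."""
        a, b = self.mu_doc_read
        ok_a, ok_b = np.isfinite(a), np.isfinite(b)
        s = np.where(ok_a, a, 0.0) + np.where(ok_b, b, 0.0)
        cnt = ok_a.astype(np.int64) + ok_b
        out = np.full(len(a), np.nan)
        nz = cnt > 0
        out[nz] = s[nz] / cnt[nz]
        return out


def compute_coverage(table: MappingTable, ref_length: int,
                     seed: int = 0) -> CoverageProfile:
    """Depth profile from one seeded placement per mapped mate."""
    rng = np.random.default_rng([404, seed])
    l = table.read_length
    diff = np.zeros(ref_length + 1, dtype=np.int64)
    placements: list[np.ndarray] = []
    for mate in (0, 1):
        counts = table.hit_counts(mate)
        mapped = np.flatnonzero(counts > 0)
        pick = (rng.random(len(mapped)) * counts[mapped]).astype(np.int64)
        idx = table.offsets[mate][mapped] + pick
        starts = table.pos[mate][idx]
        place = np.full(table.n_pairs, -1, dtype=np.int64)
        place[mapped] = starts
        placements.append(place)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + l, -1)
    depth = np.cumsum(diff[:-1])
    covered = depth > 0
    mu_doc = float(depth[covered].mean()) if covered.any() else 0.0
    prefix = np.concatenate([[0], np.cumsum(depth)])
    mu_doc_read = []
    for mate in (0, 1):
        place = placements[mate]
        vals = np.full(table.n_pairs, np.nan)
        mapped = place >= 0
        s = place[mapped]
        vals[mapped] = (prefix[s + l] - prefix[s]) / l
        mu_doc_read.append(vals)
    return CoverageProfile(depth=depth, mu_doc=mu_doc,
                           mu_doc_read=mu_doc_read, placement=placements)


def over_coverage_probability(mu_doc: float, mu_doc_read: float) -> float:
    """Admission probability max(0, 1 − µ_DOC / µ_DOC[r])."""
    if mu_doc <= 0:
        raise RuntimeError("coverage profile not computed (mu_doc == 0)")
    if not np.isfinite(mu_doc_read) or mu_doc_read <= 0:
        return 0.0
    return max(0.0, 1.0 - mu_doc / mu_doc_read)


def select_over_coverage(pair: int, profile: CoverageProfile,
                         rng: np.random.Generator) -> bool:
    """Seeded Bernoulli draw admitting a concordant pair as over-coverage."""
    p = over_coverage_probability(profile.mu_doc,
                                  float(profile.mu_doc_pair()[pair]))
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# insertion read set
# ---------------------------------------------------------------------------

@dataclass
class InsertionReadSet:
    """Pairs likely sampled from insertions, with their triggering flags."""

    pair_indices: np.ndarray  # sorted indices into the pair array
    flags: np.ndarray  # bitmask aligned with pair_indices
    n_total_pairs: int

    def __len__(self) -> int:
        return len(self.pair_indices)

    def membership(self) -> dict[int, int]:
        return {int(p): int(f) for p, f in zip(self.pair_indices, self.flags)}


def build_irs(labels: np.ndarray, profile: CoverageProfile,
              seed: int = 0) -> InsertionReadSet:
    """Union of the OEA / orphan / discordant / over-coverage predicates."""
    rng = np.random.default_rng([505, seed])
    n = len(labels)
    flags = np.zeros(n, dtype=np.uint8)
    flags[labels == OEA] |= FLAG_OEA
    flags[labels == ORPHAN] |= FLAG_ORPHAN
    flags[labels == DISCORDANT] |= FLAG_DISCORDANT
    conc = np.flatnonzero(labels == CONCORDANT)
    if len(conc) and profile.mu_doc > 0:
        mu_pair = profile.mu_doc_pair()[conc]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.maximum(0.0, 1.0 - profile.mu_doc / mu_pair)
        p[~np.isfinite(p)] = 0.0
        admit = rng.random(len(conc)) < p
        flags[conc[admit]] |= FLAG_OVER_COVERAGE
    members = np.flatnonzero(flags)
    return InsertionReadSet(pair_indices=members, flags=flags[members],
                            n_total_pairs=n)


def write_irs_tsv(irs: InsertionReadSet, path) -> None:
    names = [(FLAG_OEA, "OEA"), (FLAG_ORPHAN, "ORPHAN"),
             (FLAG_DISCORDANT, "DISCORDANT"),
             (FLAG_OVER_COVERAGE, "OVER_COVERAGE")]
    with open(path, "w") as fh:
        fh.write("read_id\tcategories\n")
        for p, f in zip(irs.pair_indices, irs.flags):
            cat = ",".join(name for bit, name in names if f & bit)
            fh.write(f"p{p}\t{cat}\n")


# ---------------------------------------------------------------------------
# OEA clustering into candidate insertion loci
# ---------------------------------------------------------------------------

def cluster_oea(table: MappingTable, labels: np.ndarray,
                model: InsertSizeModel, min_support: int = 2
                ) -> list[tuple[int, int, int]]:
    """Cluster OEA anchors into candidate insertion loci.

    Each anchored mate implies a breakpoint interval downstream (forward
    anchors) or upstream (reverse anchors) of its mapping, within fragment
    reach. Anchors whose intervals mutually overlap form one cluster; the
    reported interval is the intersection. Returns ``(start, end, support)``
    records (0-based half-open), clusters under ``min_support`` dropped.
    """
    l = table.read_length
    dmax = int(model.delta_max)
    intervals: list[tuple[int, int]] = []
    for pair in np.flatnonzero(labels == OEA):
        for mate in (0, 1):
            for loc in table.locs(int(pair), mate):
                if loc.strand == FORWARD:
                    intervals.append((loc.position + l, loc.position + dmax))
                else:
                    intervals.append((max(0, loc.position + l - dmax),
                                      loc.position))
    if not intervals:
        return []
    intervals.sort()
    out: list[tuple[int, int, int]] = []
    cur_start, cur_end = intervals[0]
    support = 1
    for s, e in intervals[1:]:
        if s <= cur_end:  # mutual overlap with the running intersection
            cur_start = max(cur_start, s)
            cur_end = min(cur_end, e)
            support += 1
        else:
            if support >= min_support:
                out.append((cur_start, cur_end + 1, support))
            cur_start, cur_end = s, e
            support = 1
    if support >= min_support:
        out.append((cur_start, cur_end + 1, support))
    return out


def write_clusters_bed(clusters, path, chrom: str = "ref") -> None:
    with open(path, "w") as fh:
        for i, (s, e, sup) in enumerate(clusters):
            fh.write(f"{chrom}\t{s}\t{e}\tcluster{i}\t{sup}\n")
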