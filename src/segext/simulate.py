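"""Synthetic references, donors with planted insertions, and paired-end reads.

The simulator emulates the study design used to benchmark insertion assembly:
a haploid reference, a donor genome derived from it by planting insertions of
three categories, and paired-end short reads sampled from the donor.

Insertion categories
--------------------
* ``case1_unique`` — the inserted sequence is uniform-random, occurring nowhere
  else (one-end-anchored and orphan pairs are its read signature).
* ``case2_copied`` — the inserted sequence is a verbatim copy of a uniformly
  chosen reference window (its reads map back to the source locus, producing
  discordant and over-coverage pairs).
* ``case3_mixed`` — a copied window that itself contains a unique segment: the
  copied half is split at its midpoint and the unique half inserted between the
  two quarters (an insertion inside an insertion; equal parts copied and
  unique content overall).

Fragment lengths are Normal(``frag_mean``, ``frag_sd``) re-drawn until they lie
in the hard interval [µ−3σ, µ+3σ], so simulated data satisfy the concordance
model's bounded-insert assumption exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import decode, encode, random_codes, revcomp_rows, write_fasta

CASE1 = "case1_unique"
CASE2 = "case2_copied"
CASE3 = "case3_mixed"
CATEGORIES = (CASE1, CASE2, CASE3)

PHRED_CONST = "I"  # constant Q40 placeholder quality


@dataclass
class TruthRecord:
    """A planted insertion: where it went, what it was, and its category."""

    insertion_id: str
    ref_locus: int  # 0-based reference position the insertion precedes
    true_sequence: str
    category: str
    copied_source_locus: int | None = None  # absent for case 1
    donor_locus: int = -1  # filled in by plant_insertions (debugging sidecar)

    def __post_init__(self) -> None:
        if len(self.true_sequence) == 0:
            raise ValueError("true_sequence must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class SimulationSpec:
    """All knobs of one simulated experiment.

    Defaults follow the benchmark protocol: 2 kb ± 200 bp insertions, 40X
    coverage, 36 bp reads, fragment length 200 ± 25 bp, 0.1% substitution
    errors.
    """

    reference_length: int
    n_insertions: int
    category: str = CASE1
    insert_size_mean: float = 2000.0
    insert_size_sd: float = 200.0
    min_insert_size: int = 200
    coverage: float = 40.0
    read_length: int = 36
    frag_mean: float = 200.0
    frag_sd: float = 25.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        for name in ("insert_size_mean", "insert_size_sd", "coverage",
                     "read_length", "frag_mean", "frag_sd", "min_insert_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.frag_mean < 2 * self.read_length:
            raise ValueError("frag_mean must be >= 2 * read_length")

    @property
    def delta_min(self) -> int:
        return int(round(self.frag_mean - 3 * self.frag_sd))

    @property
    def delta_max(self) -> int:
        return int(round(self.frag_mean + 3 * self.frag_sd))


@dataclass
class ReadSet:
    """Paired reads as code matrices plus the sampling truth (sidecar only)."""

    reads1: np.ndarray  # (n_pairs, l) uint8, forward mate as sequenced
    reads2: np.ndarray  # (n_pairs, l) uint8, reverse mate as sequenced
    frag_start: np.ndarray  # donor coordinate of fragment start
    frag_len: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.reads1.shape[0]

    @property
    def read_length(self) -> int:
        return self.reads1.shape[1]

    def pair_id(self, i: int) -> str:
        return f"p{i}"


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    reference: str
    donor: str
    truth: list[TruthRecord]
    reads: ReadSet
    loci: list[int] = field(default_factory=list)  # = sorted ref loci


def generate_reference(length: int, seed: int) -> str:
    """Uniform-random nucleotide sequence of the given length."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng([101, seed])
    return decode(random_codes(rng, length))


def _insertion_lengths(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    raw = np.rint(rng.normal(spec.insert_size_mean, spec.insert_size_sd,
                             size=spec.n_insertions)).astype(np.int64)
    return np.maximum(raw, spec.min_insert_size)


def min_locus_spacing(spec: SimulationSpec, max_len: int) -> int:
    """Minimum distance between insertion loci.

    Each insertion needs a clean flanking segment of at least 2(Δmax + l) on
    both sides for the extension base case, plus room for the longest
    neighbouring insertion's copy-source not to matter.
    """
    return 2 * (spec.delta_max + spec.read_length) + max_len


def plant_insertions(reference: str, spec: SimulationSpec
                     ) -> tuple[str, list[TruthRecord]]:
    """Plant ``spec.n_insertions`` insertions into the reference.

    Returns the donor sequence and the truth records (ordered by locus).
    Deleting each ``true_sequence`` at its ``donor_locus`` restores the
    reference exactly.
    """
    rng = np.random.default_rng([202, spec.seed])
    ref_len = len(reference)
    if spec.n_insertions == 0:
        return reference, []

    lengths = _insertion_lengths(spec, rng)
    spacing = min_locus_spacing(spec, int(lengths.max()))
    slack = ref_len - (spec.n_insertions + 1) * spacing
    if slack <= 0:
        raise ValueError(
            f"reference of {ref_len} bp cannot hold {spec.n_insertions} loci "
            f"with minimum spacing {spacing} bp "
            f"(need > {(spec.n_insertions + 1) * spacing} bp)")
    u = np.sort(rng.integers(0, slack, size=spec.n_insertions))
    loci = u + spacing * (np.arange(spec.n_insertions) + 1)

    truth: list[TruthRecord] = []
    pieces: list[str] = []
    prev = 0
    offset = 0
    for i, (locus, length) in enumerate(zip(loci.tolist(), lengths.tolist())):
        source: int | None = None
        if spec.category == CASE1:
            seq = decode(random_codes(rng, length))
        elif spec.category == CASE2:
            source = int(rng.integers(0, ref_len - length + 1))
            seq = reference[source : source + length]
        else:  # CASE3: copied window with a unique middle
            copied_len = length // 2
            unique_len = length - copied_len
            source = int(rng.integers(0, ref_len - copied_len + 1))
            copied = reference[source : source + copied_len]
            half = copied_len // 2
            seq = copied[:half] + decode(random_codes(rng, unique_len)) + copied[half:]
        pieces.append(reference[prev:locus])
        pieces.append(seq)
        rec = TruthRecord(
            insertion_id=f"ins{i}", ref_locus=int(locus), true_sequence=seq,
            category=spec.category, copied_source_locus=source,
            donor_locus=int(locus) + offset)
        truth.append(rec)
        offset += length
        prev = locus
    pieces.append(reference[prev:])
    donor = "".join(pieces)
    assert len(donor) == ref_len + int(lengths.sum())
    return donor, truth


def excise_insertions(donor: str, truth: list[TruthRecord]) -> str:
    """Remove every planted insertion from the donor (truth-guided inverse)."""
    out = []
    prev = 0
    for rec in sorted(truth, key=lambda r: r.donor_locus):
        out.append(donor[prev : rec.donor_locus])
        prev = rec.donor_locus + len(rec.true_sequence)
    out.append(donor[prev:])
    return "".join(out)


def expected_pairs(donor_length: int, spec: SimulationSpec) -> int:
    """Pair count giving the requested coverage: round(c·|donor| / 2l)."""
    return int(round(spec.coverage * donor_length /
                     (2 * spec.read_length)))


def sample_reads(donor: str, spec: SimulationSpec) -> ReadSet:
    """Sample paired-end reads from the donor.

    Fragment starts are uniform; fragment lengths Normal(µ, σ) re-drawn into
    [Δmin, Δmax]; the forward mate is the first l bases of the fragment and the
    reverse mate the reverse complement of the last l; substitution errors are
    applied i.i.d. at ``error_rate``.
    """
    rng = np.random.default_rng([303, spec.seed])
    l = spec.read_length
    dlen = len(donor)
    if dlen < spec.delta_max:
        raise ValueError("donor shorter than the maximum fragment length")
    n = expected_pairs(dlen, spec)

    frag = np.rint(rng.normal(spec.frag_mean, spec.frag_sd, size=n)).astype(np.int64)
    bad = (frag < spec.delta_min) | (frag > spec.delta_max)
    while bad.any():
        frag[bad] = np.rint(rng.normal(spec.frag_mean, spec.frag_sd,
                                       size=int(bad.sum()))).astype(np.int64)
        bad = (frag < spec.delta_min) | (frag > spec.delta_max)

    start = (rng.random(n) * (dlen - frag + 1)).astype(np.int64)
    codes = encode(donor)
    reads1 = np.empty((n, l), dtype=np.uint8)
    reads2 = np.empty((n, l), dtype=np.uint8)
    cols = np.arange(l)
    for lo in range(0, n, 262144):  # chunked gather keeps memory flat
        hi = min(lo + 262144, n)
        reads1[lo:hi] = codes[start[lo:hi, None] + cols]
        reads2[lo:hi] = revcomp_rows(codes[(start[lo:hi] + frag[lo:hi] - l)[:, None] + cols])
    if spec.error_rate > 0:
        for mat in (reads1, reads2):
            n_err = rng.binomial(mat.size, spec.error_rate)
            flat = rng.integers(0, mat.size, size=n_err)
            shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
            view = mat.reshape(-1)
            view[flat] = (view[flat] + shift) % 4
    return ReadSet(reads1=reads1, reads2=reads2, frag_start=start, frag_len=frag)


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Full simulation: reference → donor + truth → reads."""
    reference = generate_reference(spec.reference_length, spec.seed)
    donor, truth = plant_insertions(reference, spec)
    reads = sample_reads(donor, spec)
    return SimulatedDataset(spec=spec, reference=reference, donor=donor,
                            truth=truth, reads=reads,
                            loci=[t.ref_locus for t in truth])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fastq_pair(reads: ReadSet, path1, path2) -> None:
    qual = PHRED_CONST * reads.read_length
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i in range(reads.n_pairs):
            pid = reads.pair_id(i)
            f1.write(f"@{pid}/1\n{decode(reads.reads1[i])}\n+\n{qual}\n")
            f2.write(f"@{pid}/2\n{decode(reads.reads2[i])}\n+\n{qual}\n")


def write_truth_tsv(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("insertion_id\tref_locus\tcategory\tlength\tsequence\n")
        for t in truth:
            fh.write(f"{t.insertion_id}\t{t.ref_locus}\t{t.category}\t"
                     f"{len(t.true_sequence)}\t{t.true_sequence}\n")


def read_truth_tsv(path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("insertion_id")
        for line in fh:
            iid, locus, cat, _length, seq = line.rstrip("\n").split("\t")
            out.append(TruthRecord(insertion_id=iid, ref_locus=int(locus),
                                   true_sequence=seq, category=cat))
    return out


def write_loci_bed(truth: list[TruthRecord], path, chrom: str = "ref") -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{chrom}\t{t.ref_locus}\t{t.ref_locus + 1}\t{t.insertion_id}\n")


def write_sidecar_tsv(reads: ReadSet, path) -> None:
    """Donor sampling coordinates per pair — debugging only, never consumed."""
    with open(path, "w") as fh:
        fh.write("pair_id\tfrag_start\tfrag_len\n")
        for i in range(reads.n_pairs):
            fh.write(f"{reads.pair_id(i)}\t{reads.frag_start[i]}\t{reads.frag_len[i]}\n")


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "reference.fa", [("ref", ds.reference)])
    write_fasta(out / "donor.fa", [("donor", ds.donor)])
    write_fastq_pair(ds.reads, out / "reads_1.fastq", out / "reads_2.fastq")
    write_truth_tsv(ds.truth, out / "truth.tsv")
    write_loci_bed(ds.truth, out / "loci.bed")
    write_sidecar_tsv(ds.reads, out / "frags.tsv")
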