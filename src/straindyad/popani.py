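"""Read pileups and population ANI (popANI) between two samples.

Reads are placed on a reference by exact 21-mer seed anchoring with
ungapped evaluation (substitution-only regime); reads below a 95% identity
floor are discarded. popANI compares two pileups site by site: a position
covered at >= 5x in both samples is *divergent* only when the two samples'
detected allele sets (alleles at >= 5% frequency with >= 2 supporting
reads, the published inStrain defaults) are disjoint — sharing even a
minor allele keeps a site non-divergent, which is what distinguishes
popANI from consensus ANI. Two samples share a strain when
popANI >= 99.999% and both cover more than 50% of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from straindyad.errors import InputError, ParameterError
from straindyad.simcohort import Genome, ReadSet, encode_sequence

POPANI_THRESHOLD = 99.999
BREADTH_THRESHOLD = 50.0

_K = 21  # seed length for read anchoring


@dataclass
class Pileup:
    """Per-position allele counts of one read set against one reference.

    ``allele_counts`` is a (length, 4) int array over A/C/G/T; coverage at
    a position is the row sum.
    """

    reference_id: str
    length: int
    allele_counts: np.ndarray
    sample_id: str = ""
    reads_mapped: int = 0
    reads_total: int = 0

    def __post_init__(self) -> None:
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int64)
        if self.allele_counts.shape != (self.length, 4):
            raise InputError("allele_counts must have shape (length, 4)")
        if np.any(self.allele_counts < 0):
            raise InputError("allele counts must be >= 0")

    @property
    def coverage(self) -> np.ndarray:
        return self.allele_counts.sum(axis=1)

    def breadth(self) -> float:
        """Percent of reference positions covered by >= 1 read."""
        return 100.0 * float(np.count_nonzero(self.coverage)) / self.length

    def mean_depth(self) -> float:
        return float(self.coverage.mean())


@dataclass(frozen=True)
class PopANIResult:
    sample_a: str
    sample_b: str
    reference_id: str
    popani: float | None  # None when no site was compared
    compared_sites: int
    divergent_sites: int
    breadth_a: float
    breadth_b: float

    def __post_init__(self) -> None:
        if self.divergent_sites > self.compared_sites:
            raise InputError("divergent_sites > compared_sites")
        if self.compared_sites > 0:
            expected = 100.0 * (self.compared_sites - self.divergent_sites) / self.compared_sites
            if self.popani is None or abs(self.popani - expected) > 1e-9:
                raise InputError("popani inconsistent with compared/divergent counts")
        elif self.popani is not None:
            raise InputError("popani must be None when no site was compared")
        for b in (self.breadth_a, self.breadth_b):
            if not 0.0 <= b <= 100.0:
                raise InputError("breadth outside [0, 100]")


def _kmer_code(codes: np.ndarray) -> int:
    weights = 4 ** np.arange(len(codes), dtype=np.uint64)
    return int(codes.astype(np.uint64) @ weights)


def reference_seed_index(reference: Genome, k: int = _K) -> dict:
    """k-mer -> leftmost position map for read anchoring (cacheable)."""
    codes = reference.codes
    code = np.zeros(len(codes) - k + 1, dtype=np.uint64)
    for i in range(k):  # Horner accumulation, little-endian base 4
        code = code * np.uint64(4) + codes[k - 1 - i : len(codes) - i].astype(np.uint64)
    pos = np.arange(len(code))
    return dict(zip(code[::-1].tolist(), pos[::-1].tolist()))


def map_reads(
    reads: ReadSet,
    reference: Genome,
    min_read_identity: float = 0.95,
    *,
    seed_index: dict | None = None,
) -> Pileup:
    """Ungapped seed-anchored placement of reads onto a reference pileup.

    Each read is anchored by exact 21-mer seeds at consecutive offsets;
    every distinct implied start is evaluated over the full read and the
    best placement kept (ties -> leftmost). Reads with best identity below
    ``min_read_identity`` or with no anchor are discarded. Each retained
    read adds one count at every position it covers.
    """
    L = len(reference)
    rcodes = reference.codes
    if seed_index is None:
        seed_index = reference_seed_index(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    mapped = 0
    for _rid, seq, _qual in reads.reads:
        read = encode_sequence(seq)
        rl = len(read)
        if rl < _K:
            raise InputError(f"read length {rl} shorter than seed length {_K}")
        if rl > L:
            raise InputError("reference shorter than read")
        best_ident, best_start = -1.0, L
        seen: set[int] = set()
        for off in range(0, rl - _K + 1, _K):
            pos = seed_index.get(_kmer_code(read[off : off + _K]))
            if pos is None:
                continue
            start = pos - off
            if start < 0 or start + rl > L or start in seen:
                continue
            seen.add(start)
            ident = float(np.count_nonzero(read == rcodes[start : start + rl])) / rl
            if ident > best_ident or (ident == best_ident and start < best_start):
                best_ident, best_start = ident, start
        if best_ident >= min_read_identity:
            counts[np.arange(best_start, best_start + rl), read] += 1
            mapped += 1
    return Pileup(reference.genome_id, L, counts, reads.source_sample, mapped, len(reads.reads))


def detected_alleles(pileup: Pileup, min_allele_freq: float = 0.05, min_allele_count: int = 2) -> np.ndarray:
    """Boolean (length, 4) mask of alleles considered present at each site:
    frequency >= ``min_allele_freq`` and >= ``min_allele_count`` reads."""
    cov = pileup.coverage[:, None].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cov > 0, pileup.allele_counts / cov, 0.0)
    return (pileup.allele_counts >= min_allele_count) & (freq >= min_allele_freq)


def compute_popani(
    pileup_a: Pileup,
    pileup_b: Pileup,
    min_cov: int = 5,
    min_allele_freq: float = 0.05,
    min_allele_count: int = 2,
) -> PopANIResult:
    """popANI between two pileups on the same reference.

    Compared sites have coverage >= ``min_cov`` in both samples; a compared
    site is divergent iff the detected allele sets are disjoint. With no
    compared site, popANI is undefined and reported as None (never 0).
    """
    if pileup_a.reference_id != pileup_b.reference_id or pileup_a.length != pileup_b.length:
        raise InputError("pileups must be against the same reference")
    if min_cov < 1:
        raise ParameterError("min_cov must be >= 1")
    compared = (pileup_a.coverage >= min_cov) & (pileup_b.coverage >= min_cov)
    n_compared = int(np.count_nonzero(compared))
    if n_compared == 0:
        return PopANIResult(
            pileup_a.sample_id, pileup_b.sample_id, pileup_a.reference_id,
            None, 0, 0, pileup_a.breadth(), pileup_b.breadth(),
        )
    det_a = detected_alleles(pileup_a, min_allele_freq, min_allele_count)
    det_b = detected_alleles(pileup_b, min_allele_freq, min_allele_count)
    shared = np.any(det_a & det_b, axis=1)
    divergent = int(np.count_nonzero(compared & ~shared))
    popani = 100.0 * (n_compared - divergent) / n_compared
    return PopANIResult(
        pileup_a.sample_id, pileup_b.sample_id, pileup_a.reference_id,
        popani, n_compared, divergent, pileup_a.breadth(), pileup_b.breadth(),
    )


def popani_share_call(
    result: PopANIResult,
    popani_threshold: float = POPANI_THRESHOLD,
    breadth_threshold: float = BREADTH_THRESHOLD,
) -> bool:
    """Strain-sharing rule: popANI >= 99.999% (unrounded) and coverage
    breadth strictly over 50% in *both* samples. An undefined popANI (no
    compared sites) is never a sharing call."""
    if result.popani is None:
        return False
    return (
        result.popani >= popani_threshold
        and min(result.breadth_a, result.breadth_b) > breadth_threshold
    )
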