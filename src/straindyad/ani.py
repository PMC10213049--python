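"""Fragment-based average nucleotide identity (ANI).

The query genome is tiled into non-overlapping fragments (default 1 kb,
scaled to the 100 kb desk-scale genomes); each fragment is placed on the
reference by exact 16-mer seed anchoring with ungapped evaluation, and ANI
is the mean identity over fragments whose best placement reaches the
retention floor (default 80% identity, mirroring how fastANI discards
unmapped fragments). This is adequate for substitution-only assemblies; it
does not handle indels or rearrangements.

Two thresholds matter downstream: ANI >= 98% delimits a species, and
ANI >= 99.9% marks two isolates as the same strain lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from straindyad.distance import DistanceMatrix
from straindyad.errors import InputError, UndefinedStatisticError
from straindyad.simcohort import Genome

SPECIES_ANI_THRESHOLD = 98.0
LINEAGE_ANI_THRESHOLD = 99.9

_K = 16  # seed length


@dataclass(frozen=True)
class ANIResult:
    """One directed query-vs-reference ANI estimate.

    ``ani`` is ``None`` when no fragment was retained (undefined — distinct
    from 0, which would mean "compared and maximally divergent").
    """

    query_id: str
    reference_id: str
    ani: float | None
    fragments_mapped: int
    fragments_total: int

    def __post_init__(self) -> None:
        if self.ani is not None and not 0.0 <= self.ani <= 100.0:
            raise InputError(f"ani {self.ani} outside [0, 100]")
        if self.fragments_mapped > self.fragments_total:
            raise InputError("fragments_mapped > fragments_total")


def _kmer_codes(codes: np.ndarray, k: int = _K) -> np.ndarray:
    """Integer code of every k-mer (base 4), dtype uint64, via Horner."""
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        out = out * np.uint64(4) + codes[i : n + i].astype(np.uint64)
    return out


def build_reference_index(reference: Genome, k: int = _K) -> dict:
    """k-mer -> leftmost position map for seed anchoring (cacheable)."""
    kmers = _kmer_codes(reference.codes, k)
    pos = np.arange(len(kmers))
    # reversed zip: earlier positions overwrite later, keeping the leftmost
    return dict(zip(kmers[::-1].tolist(), pos[::-1].tolist()))


def fragment_ani(
    query: Genome,
    reference: Genome,
    fragment_length: int = 1000,
    min_fragment_identity: float = 0.8,
    *,
    anchor_step: int = 64,
    ref_index: dict | None = None,
    query_kmers: np.ndarray | None = None,
) -> ANIResult:
    """Directed fragment ANI of ``query`` against ``reference``.

    Each fragment is anchored by exact 16-mer seeds sampled every
    ``anchor_step`` bases; every distinct implied diagonal is evaluated
    ungapped over the whole fragment and the best identity kept (ties
    broken by leftmost reference coordinate). Fragments whose best identity
    is below ``min_fragment_identity`` are dropped, as are fragments with
    no anchored placement.
    """
    if len(query) < fragment_length or len(reference) < fragment_length:
        raise InputError("both genomes must be at least one fragment long")
    q, r = query.codes, reference.codes
    if ref_index is None:
        ref_index = build_reference_index(reference)
    qk = query_kmers if query_kmers is not None else _kmer_codes(q)
    n_frag = len(q) // fragment_length
    identities: list[float] = []
    rlen = len(r)
    for f in range(n_frag):
        s = f * fragment_length
        best_ident = -1.0
        best_start = rlen
        seen: set[int] = set()
        for off in range(0, fragment_length - _K + 1, anchor_step):
            pos = ref_index.get(int(qk[s + off]))
            if pos is None:
                continue
            start = pos - off
            if start < 0 or start + fragment_length > rlen or start in seen:
                continue
            seen.add(start)
            ident = float(np.count_nonzero(q[s : s + fragment_length] == r[start : start + fragment_length])) / fragment_length
            if ident > best_ident or (ident == best_ident and start < best_start):
                best_ident, best_start = ident, start
        if best_ident >= min_fragment_identity:
            identities.append(best_ident)
    if not identities:
        return ANIResult(query.genome_id, reference.genome_id, None, 0, n_frag)
    ani = 100.0 * float(np.mean(identities))
    return ANIResult(query.genome_id, reference.genome_id, ani, len(identities), n_frag)


def fragment_ani_both(
    a: Genome, b: Genome, **kwargs
) -> tuple[ANIResult, ANIResult]:
    """Both directions of the asymmetric fragment ANI."""
    return fragment_ani(a, b, **kwargs), fragment_ani(b, a, **kwargs)


def combine_directions(res_ab: ANIResult, res_ba: ANIResult, orientation: str = "max") -> float:
    """Collapse the two directed estimates to one value (``max`` for
    classification, following fastANI's reported orientation; ``min`` for a
    conservative symmetric value). NaN if both directions are undefined."""
    vals = [v for v in (res_ab.ani, res_ba.ani) if v is not None]
    if not vals:
        return math.nan
    return max(vals) if orientation == "max" else min(vals)


def ani_matrix(
    genomes: list[Genome],
    fragment_length: int = 1000,
    min_fragment_identity: float = 0.8,
    orientation: str = "max",
    anchor_step: int = 64,
) -> tuple[DistanceMatrix, list[ANIResult]]:
    """All-pairs fragment ANI over a genome set.

    Returns an ``ani_percent`` DistanceMatrix (NaN where both directions
    were undefined, i.e. the pair shares no anchors) and the long-form list
    of directed results. One reference index is alive at a time so memory
    stays flat for large genome sets; query k-mer arrays are precomputed.
    """
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise InputError("genome ids must be unique")
    n = len(genomes)
    directed = np.full((n, n), np.nan)
    query_kmers = [_kmer_codes(g.codes) for g in genomes]
    results: list[ANIResult] = []
    for j in range(n):
        index_j = build_reference_index(genomes[j])
        for i in range(n):
            if i == j:
                continue
            res = fragment_ani(
                genomes[i], genomes[j], fragment_length, min_fragment_identity,
                anchor_step=anchor_step, ref_index=index_j,
                query_kmers=query_kmers[i],
            )
            results.append(res)
            directed[i, j] = res.ani if res.ani is not None else np.nan
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pair = directed[[i, j], [j, i]]
            finite = pair[np.isfinite(pair)]
            if len(finite):
                values[i, j] = values[j, i] = (
                    finite.max() if orientation == "max" else finite.min()
                )
    return DistanceMatrix(ids, values, "ani_percent"), results


def exact_ani_oracle(a: Genome, b: Genome) -> float:
    """Exact ANI for equal-length substitution-only pairs:
    100 * (1 - Hamming(a, b) / L). Ground truth for fragment_ani."""
    if len(a) != len(b):
        raise InputError("exact_ani_oracle requires equal-length genomes")
    hamming = int(np.count_nonzero(a.codes != b.codes))
    return 100.0 * (1.0 - hamming / len(a))


def classify_species(matrix: DistanceMatrix, threshold: float = SPECIES_ANI_THRESHOLD) -> dict[str, str]:
    """Single-linkage species clusters at an ANI threshold (default 98%).

    Single linkage at a fixed threshold is the connected components of the
    graph with edges ani >= threshold; undefined (NaN) pairs contribute no
    edge. Cluster labels are the lexicographically smallest member id.
    """
    if matrix.kind != "ani_percent":
        raise InputError(f"classify_species needs an ani_percent matrix, got {matrix.kind!r}")
    parent = {t: t for t in matrix.taxa}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(matrix.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if np.isfinite(v) and v >= threshold:
                ri, rj = find(matrix.taxa[i]), find(matrix.taxa[j])
                if ri != rj:
                    parent[ri] = rj
    roots: dict[str, list[str]] = {}
    for t in matrix.taxa:
        roots.setdefault(find(t), []).append(t)
    out: dict[str, str] = {}
    for members in roots.values():
        label = min(members)
        for m in members:
            out[m] = label
    return out


def same_lineage(ani: float, threshold: float = LINEAGE_ANI_THRESHOLD) -> bool:
    """Same-strain-lineage rule: ANI >= 99.9% (inclusive boundary)."""
    if math.isnan(ani):
        raise UndefinedStatisticError("ANI is undefined; cannot apply lineage threshold")
    if not 0.0 <= ani <= 100.0:
        raise InputError(f"ani {ani} outside [0, 100]")
    return ani >= threshold
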