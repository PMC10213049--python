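"""Integration of isolate, popANI and nPD evidence into transmission calls.

Each evidence stream produces, per (dyad, species), a flag that is True,
False or *absent* (None). Absent means the method could not be applied —
no isolate on one side, species not detected in a metagenome, no profiled
read pair — and is deliberately distinct from False: the methods disagree
partly because of differential detectability, and a method's blindness
must not veto a positive call from another. The integrated call is the OR
over available flags; when every flag is absent no call is emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from straindyad.distance import DistanceMatrix
from straindyad.errors import InputError
from straindyad.phylo import NPD_SHARE_THRESHOLD, is_monophyletic, npd_share_call
from straindyad.popani import PopANIResult, popani_share_call
from straindyad.simcohort import CohortTruth, Genome

METHODS = ("isolate", "popani", "npd")


@dataclass
class TransmissionCall:
    """Integrated per-(dyad, species) transmission call.

    ``evidence`` holds one flag per method (True/False/None-absent);
    ``transmitted`` is the OR over the available flags. ``support`` carries
    the numbers behind any True flag (ANI %, SNP count pre/post masking,
    monophyly, best popANI, min nPD). ``direction_note`` records the
    mother-side sample type of the best supporting pair.
    """

    dyad_id: str
    species: str
    evidence: dict[str, bool | None]
    transmitted: bool
    support: dict = field(default_factory=dict)
    direction_note: str = ""

    def __post_init__(self) -> None:
        available = [v for v in self.evidence.values() if v is not None]
        if not available:
            raise InputError("a call requires at least one available evidence flag")
        if self.transmitted != any(available):
            raise InputError("transmitted must equal OR of available evidence flags")


@dataclass(frozen=True)
class DominanceLabel:
    genome_id: str
    label: str  # dominant | non_dominant | not_detected

    def __post_init__(self) -> None:
        if self.label not in ("dominant", "non_dominant", "not_detected"):
            raise InputError(f"unknown dominance label {self.label!r}")


# ----------------------------------------------------------------------
# per-method calls
# ----------------------------------------------------------------------

def call_isolate_transmission(
    mother_taxa: Sequence[str],
    infant_taxa: Sequence[str],
    ani: DistanceMatrix,
    snp_matrix: DistanceMatrix,
    tree,
    max_snps: int = 200,
    ani_threshold: float = 99.9,
    snp_matrix_unmasked: DistanceMatrix | None = None,
) -> tuple[bool | None, dict]:
    """Isolate (culture-genome) rule for one dyad and species.

    The best mother-infant isolate pair (highest ANI, then lowest SNP
    distance) transmits iff ANI >= 99.9%, SNP distance strictly below
    ``max_snps`` (post-masking; the unmasked value is recorded alongside
    when available) and the dyad's same-lineage isolates form a
    monophyletic group on the midpoint-rooted species tree. With no
    isolate on either side the flag is absent (None), not False.
    """
    if not mother_taxa or not infant_taxa:
        return None, {}
    best = None
    for m in sorted(mother_taxa):
        for i in sorted(infant_taxa):
            a = ani.get(m, i)
            s = snp_matrix.get(m, i)
            key = (-(a if math.isfinite(a) else -1.0), s, m, i)
            if best is None or key < best[0]:
                best = (key, m, i, a, s)
    _, m, i, a, s = best
    support: dict = {"ani": a, "snp": int(s), "mother_taxon": m, "infant_taxon": i}
    if snp_matrix_unmasked is not None:
        support["snp_unmasked"] = int(snp_matrix_unmasked.get(m, i))
    if not math.isfinite(a) or a < ani_threshold or s >= max_snps:
        support["monophyletic"] = None
        return False, support
    # clade to test: the pair plus any same-lineage isolates of this dyad
    dyad_taxa = set(mother_taxa) | set(infant_taxa)
    clade = {m, i}
    for t in dyad_taxa - clade:
        am, ai = ani.get(t, m), ani.get(t, i)
        if (math.isfinite(am) and am >= ani_threshold) or (math.isfinite(ai) and ai >= ani_threshold):
            clade.add(t)
    mono = is_monophyletic(tree, clade)
    support["monophyletic"] = mono
    return bool(mono), support


def call_npd_transmission(
    mother_leaves: Sequence[str],
    infant_leaves: Sequence[str],
    npd: DistanceMatrix | None,
    threshold: float = NPD_SHARE_THRESHOLD,
) -> tuple[bool | None, dict]:
    """Marker-tree rule: share iff the minimum nPD over mother-leaf x
    infant-leaf pairs is below the threshold. Absent when either side has
    no leaf in the tree (species not profiled)."""
    if npd is None:
        return None, {}
    mothers = [t for t in mother_leaves if t in npd.taxa]
    infants = [t for t in infant_leaves if t in npd.taxa]
    if not mothers or not infants:
        return None, {}
    best = min(
        ((npd.get(m, i), m, i) for m in sorted(mothers) for i in sorted(infants)),
        key=lambda x: (x[0], x[1], x[2]),
    )
    val, m, i = best
    return npd_share_call(val, threshold), {"npd": val, "mother_leaf": m, "infant_leaf": i}


def call_popani_transmission(
    results: Sequence[PopANIResult],
    sample_types: Mapping[str, str] | None = None,
    popani_threshold: float = 99.999,
    breadth_threshold: float = 50.0,
    min_compared_sites: int = 0,
) -> tuple[bool | None, dict]:
    """Read-pileup rule: share iff any mother-sample x infant-sample pair
    passes the popANI (>= 99.999%) and breadth (> 50%) thresholds. Absent
    when no pair was profiled. ``min_compared_sites`` guards against
    vacuous popANI=100 calls on a handful of jointly covered sites (the
    fraction-of-genome-compared filter of read-pileup practice); pairs
    below it never pass. ``sample_types`` maps sample id to its body site
    for the direction note."""
    results = list(results)
    if not results:
        return None, {}
    passing = [
        r for r in results
        if r.compared_sites >= min_compared_sites
        and popani_share_call(r, popani_threshold, breadth_threshold)
    ]
    pool = passing or [r for r in results if r.popani is not None] or results
    best = max(pool, key=lambda r: (r.popani if r.popani is not None else -1.0,
                                    min(r.breadth_a, r.breadth_b)))
    support = {
        "popani": best.popani,
        "compared_sites": best.compared_sites,
        "divergent_sites": best.divergent_sites,
        "breadth_a": best.breadth_a,
        "breadth_b": best.breadth_b,
        "sample_a": best.sample_a,
        "sample_b": best.sample_b,
    }
    if sample_types:
        support["source_sample_type"] = sample_types.get(best.sample_a, "")
    return bool(passing), support


# ----------------------------------------------------------------------
# integration and summaries
# ----------------------------------------------------------------------

def integrate_calls(
    evidence: Mapping[tuple[str, str], Mapping[str, tuple[bool | None, dict]]],
) -> list[TransmissionCall]:
    """Combine per-method evidence into one call per (dyad, species).

    ``evidence`` maps (dyad_id, species) to {method: (flag, support)}.
    The integrated call is the OR over available flags; entries whose
    flags are all absent produce no call.
    """
    calls: list[TransmissionCall] = []
    for (dyad_id, species) in sorted(evidence):
        per_method = evidence[(dyad_id, species)]
        flags = {m: None for m in METHODS}
        support: dict = {}
        direction = ""
        for method in METHODS:
            flag, sup = per_method.get(method, (None, {}))
            flags[method] = flag
            for k, v in sup.items():
                support[f"{method}_{k}"] = v
            if flag and not direction:
                direction = sup.get("source_sample_type", "maternal_stool")
        available = [v for v in flags.values() if v is not None]
        if not available:
            continue
        calls.append(
            TransmissionCall(dyad_id, species, flags, any(available), support, direction)
        )
    return calls


def method_overlap(calls: Sequence[TransmissionCall]) -> dict:
    """Counts per non-empty method subset (upset-plot table).

    A transmitted call contributes to the subset of methods whose flag is
    True. Returns subset counts (keys like ``isolate+npd``), per-method
    marginals (sums of subsets containing the method) and the total number
    of transmitted calls.
    """
    subset_counts = {
        "+".join(sub): 0
        for r in range(1, len(METHODS) + 1)
        for sub in combinations(METHODS, r)
    }
    total = 0
    for call in calls:
        if not call.transmitted:
            continue
        sub = tuple(m for m in METHODS if call.evidence.get(m) is True)
        if sub:
            subset_counts["+".join(sub)] += 1
            total += 1
    marginals = {
        m: sum(c for key, c in subset_counts.items() if m in key.split("+"))
        for m in METHODS
    }
    return {"subset_counts": subset_counts, "marginals": marginals, "total": total}


def classify_dominance(
    isolate: Genome,
    profile: Mapping[str, float] | None,
) -> DominanceLabel | None:
    """Dominance of an isolate within its source sample's genus profile.

    Dominant iff the isolate's species has the (inclusively tied) highest
    relative abundance; not_detected when the whole genus is at zero;
    None (label absent) when the sample was not profiled.
    """
    if profile is None:
        return None
    if any(v < 0 for v in profile.values()):
        raise InputError("abundances must be >= 0")
    if all(v == 0 for v in profile.values()) or not profile:
        return DominanceLabel(isolate.genome_id, "not_detected")
    top = max(profile.values())
    own = profile.get(isolate.species_label, 0.0)
    label = "dominant" if own == top and own > 0 else "non_dominant"
    return DominanceLabel(isolate.genome_id, label)


def detection_limit_summary(
    truth: CohortTruth,
    calls: Sequence[TransmissionCall],
    sample_depths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-method detection limits on the simulated cohort.

    For each method: the minimum true relative abundance (the smaller of
    the mother's and infant's sample abundance of the species) among truly
    transmitted events the method detected, and, when depths are given,
    the minimum read depth with >= 1 detection.
    """
    true_pairs = {(t.dyad_id, t.species) for t in truth.true_transmissions}
    dyad_by_id = {d.dyad_id: d for d in truth.dyads}
    rows = []
    for method in METHODS + ("integrated",):
        abundances, depths = [], []
        for call in calls:
            flag = call.transmitted if method == "integrated" else call.evidence.get(method)
            if flag is not True or (call.dyad_id, call.species) not in true_pairs:
                continue
            dyad = dyad_by_id[call.dyad_id]
            sm = CohortTruth.stool_sample(dyad.mother_id)
            si = CohortTruth.stool_sample(dyad.infant_id)
            ab = min(
                truth.abundances.get(sm, {}).get(call.species, 0.0),
                truth.abundances.get(si, {}).get(call.species, 0.0),
            )
            abundances.append(ab)
            if sample_depths:
                depths.append(min(sample_depths.get(sm, 0), sample_depths.get(si, 0)))
        rows.append({
            "method": method,
            "n_detected": len(abundances),
            "min_abundance_detected": min(abundances) if abundances else math.nan,
            "min_depth_detected": min(depths) if depths else math.nan,
        })
    return pd.DataFrame(rows)


def summarize_cohort(
    calls: Sequence[TransmissionCall],
    n_dyads: int,
    truth: CohortTruth | None = None,
) -> dict:
    """Cohort-level summary: event counts, dyad coverage, per-species
    counts, and (with truth) recovery metrics and per-method unique
    detections among true events."""
    transmitted = [c for c in calls if c.transmitted]
    dyads_with_event = sorted({c.dyad_id for c in transmitted})
    per_species: dict[str, int] = {}
    for c in transmitted:
        per_species[c.species] = per_species.get(c.species, 0) + 1
    summary = {
        "n_calls": len(calls),
        "n_events": len(transmitted),
        "n_dyads_with_event": len(dyads_with_event),
        "pct_dyads_with_event": 100.0 * len(dyads_with_event) / n_dyads if n_dyads else 0.0,
        "events_per_species": per_species,
    }
    if truth is not None:
        from straindyad.cohortstats import recovery_metrics

        metrics = recovery_metrics(calls, truth)
        summary["recovery"] = metrics.set_index("method").to_dict(orient="index")
        true_pairs = {(t.dyad_id, t.species) for t in truth.true_transmissions}
        unique = {m: 0 for m in METHODS}
        for c in transmitted:
            if (c.dyad_id, c.species) not in true_pairs:
                continue
            hits = [m for m in METHODS if c.evidence.get(m) is True]
            if len(hits) == 1:
                unique[hits[0]] += 1
        summary["method_unique_true_detections"] = unique
    return summary
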