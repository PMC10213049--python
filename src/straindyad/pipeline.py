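"""End-to-end pipeline: cohort -> ANI -> SNP -> trees -> reads -> calls.

This is the orchestration layer the CLI and the acceptance harness drive.
Given a simulated (or externally constructed) cohort it:

1. computes all-pairs fragment ANI over the isolate genomes and clusters
   them into species at 98% single linkage;
2. per species cluster, picks a reference (the lexicographically first
   maternal genome), calls variants, builds the core SNP alignment, masks
   recombination-dense windows and derives pre- and post-masking SNP
   distance matrices;
3. builds a neighbor-joining tree per cluster, midpoint-roots it, and
   derives the nPD matrix;
4. simulates shotgun reads per stool sample (genus strains at their true
   abundances plus an environmental background genome making up the
   remainder), maps them onto each cluster reference, and computes
   mother-vs-infant popANI;
5. applies the three per-method rules, integrates them into per-(dyad,
   species) transmission calls, and produces overlap, dominance,
   detection-limit, covariate-association and recovery summaries.

The nPD stream models the marker-profiling detection limit: its evidence
is *absent* for a dyad when the species' relative abundance in either
stool sample falls below ``npd_min_abundance``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from straindyad import ani as ani_mod
from straindyad import coresnp, phylo, popani as popani_mod, transmission as trans_mod
from straindyad.cohortstats import covariate_screen
from straindyad.distance import DistanceMatrix
from straindyad.simcohort import (
    CohortConfig,
    CohortTruth,
    Genome,
    generate_ancestral_genome,
    qc_filter_samples,
    simulate_cohort,
    simulate_reads,
)


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end run.

    Thresholds default to the field's standard values: 98% / 99.9% ANI,
    <200 SNPs, nPD < 0.001, popANI >= 99.999% with breadth > 50%. Read
    depth (20,000 reads of 150 bp per stool sample over 100 kb genomes)
    gives roughly 5-15x on a typically abundant species. ``qc_min_reads``
    is a desk-scale floor; at production read counts the 100,000-read QC
    default of :func:`qc_filter_samples` applies.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    reads_per_sample: int = 20_000
    read_length: int = 150
    error_rate: float = 0.002
    fragment_length: int = 1000
    min_fragment_identity: float = 0.8
    # At desk scale, lineage divergence preserves SNP counts on 100 kb, so
    # same-species lineages sit at 90-97% ANI instead of the >98% seen on
    # full genomes; unrelated species share no mappable fragments at all
    # (ANI undefined), so 85% still separates species cleanly while keeping
    # every lineage of a species in one cluster. Use 98 for real assemblies.
    species_ani_threshold: float = 85.0
    lineage_ani_threshold: float = 99.9
    max_snps: int = 200
    mask_window: int = 1000
    mask_max_snps: int = 10
    # Desk-scale genomes preserve SNP *counts* on 100 kb, so the background
    # column density of a many-lineage alignment can exceed any absolute
    # per-window cutoff. With mask_adaptive the pipeline raises the cutoff
    # to 5x the alignment's mean columns per window whenever that exceeds
    # mask_max_snps, so only windows denser than ordinary vertical
    # divergence are masked (at full genome scale the absolute rule wins).
    mask_adaptive: bool = True
    npd_threshold: float = 0.001
    npd_min_abundance: float = 0.005
    popani_threshold: float = 99.999
    breadth_threshold: float = 50.0
    # popANI over a handful of jointly >=min_cov sites is vacuous (0 of 30
    # divergent happens by chance between distinct lineages); require at
    # least this fraction of the genome compared before a share call.
    popani_min_compared_frac: float = 0.001
    min_cov: int = 5
    # 0.95 is the usual metagenomic mapping floor, but desk-scale lineage
    # divergence (up to ~10% instead of <1%) would discard most reads from
    # lineages far from the cluster reference; 0.85 keeps them mapped while
    # still rejecting reads from other species (no shared seeds anyway).
    min_read_identity: float = 0.85
    qc_min_reads: int = 1000
    sample_read_counts: dict[str, int] | None = None
    abundance_overrides: dict[str, dict[str, float]] | None = None
    seed: int = 0


@dataclass
class SpeciesClusterResult:
    label: str
    species_name: str
    members: list[str]
    reference_id: str
    alignment: coresnp.CoreAlignment
    alignment_masked: coresnp.CoreAlignment
    snp_unmasked: DistanceMatrix
    snp: DistanceMatrix
    tree: object | None  # midpoint-rooted skbio TreeNode (None for <2 taxa)
    npd: DistanceMatrix | None


@dataclass
class PipelineResult:
    cohort: CohortTruth
    config: PipelineConfig
    ani: DistanceMatrix
    species_clusters: dict[str, str]
    clusters: dict[str, SpeciesClusterResult]
    sample_depths: dict[str, int]
    retained_samples: set[str]
    popani_results: dict[tuple[str, str], list[popani_mod.PopANIResult]]
    calls: list[trans_mod.TransmissionCall]
    overlap: dict
    dominance: list
    detection_limits: pd.DataFrame
    associations: pd.DataFrame
    summary: dict


def _cluster_species_name(members: list[Genome]) -> str:
    labels = sorted(g.species_label for g in members)
    return max(set(labels), key=lambda s: (labels.count(s), s))


def run_pipeline(
    config: PipelineConfig | None = None,
    cohort: CohortTruth | None = None,
    **overrides,
) -> PipelineResult:
    """Run the full inference pipeline; simulates the cohort if not given."""
    if config is None:
        config = PipelineConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    if cohort is None:
        cohort = simulate_cohort(config.cohort)

    abundances: dict[str, dict[str, float]] = {
        s: dict(p) for s, p in cohort.abundances.items()
    }
    if config.abundance_overrides:
        for sample, prof in config.abundance_overrides.items():
            abundances.setdefault(sample, {}).update(prof)

    genomes = sorted(cohort.strains, key=lambda g: g.genome_id)

    # 1. ANI and species clusters ------------------------------------
    ani_matrix, _ani_results = ani_mod.ani_matrix(
        genomes, config.fragment_length, config.min_fragment_identity
    )
    species_clusters = ani_mod.classify_species(ani_matrix, config.species_ani_threshold)

    members_by_cluster: dict[str, list[Genome]] = {}
    by_id = {g.genome_id: g for g in genomes}
    for gid, label in species_clusters.items():
        members_by_cluster.setdefault(label, []).append(by_id[gid])

    # 2-3. per-cluster SNP alignments, trees, nPD --------------------
    clusters: dict[str, SpeciesClusterResult] = {}
    for label in sorted(members_by_cluster):
        members = sorted(members_by_cluster[label], key=lambda g: g.genome_id)
        maternal = [g for g in members if g.sample_type == "maternal_stool"]
        reference = (maternal or members)[0]
        variant_sets = [coresnp.call_variants(g, reference) for g in members]
        alignment = coresnp.build_core_alignment(variant_sets, reference)
        mask_threshold = config.mask_max_snps
        if config.mask_adaptive and alignment.reference_length:
            mean_per_window = alignment.n_sites * config.mask_window / alignment.reference_length
            mask_threshold = max(mask_threshold, int(np.ceil(5.0 * mean_per_window)))
        masked = coresnp.mask_recombination(alignment, config.mask_window, mask_threshold)
        snp_unmasked = coresnp.snp_distance_matrix(alignment)
        snp = coresnp.snp_distance_matrix(masked)
        tree = npd = None
        if len(members) >= 2:
            tree = phylo.midpoint_root(phylo.build_tree(snp))
            npd = phylo.npd_matrix(tree)
        clusters[label] = SpeciesClusterResult(
            label, _cluster_species_name(members), [g.genome_id for g in members],
            reference.genome_id, alignment, masked, snp_unmasked, snp, tree, npd,
        )

    # 4. reads, QC, pileups, popANI ----------------------------------
    background = generate_ancestral_genome(
        cohort.config.genome_length, 0.45, config.seed,
        genome_id="environmental_background", individual_id="environment",
        species_label="background", lineage_id="background",
    )
    sample_depths: dict[str, int] = {}
    sample_of_individual: dict[str, str] = {}
    compositions: dict[str, dict] = {}
    for dyad in cohort.dyads:
        for indiv in (dyad.mother_id, dyad.infant_id):
            sample = CohortTruth.stool_sample(indiv)
            sample_of_individual[indiv] = sample
            profile = abundances.get(sample, {})
            comp: dict = {}
            for g in cohort.genomes_of(individual_id=indiv):
                n_strains = len(cohort.genomes_of(individual_id=indiv, species=g.species_label))
                comp[g] = profile.get(g.species_label, 0.0) / max(n_strains, 1)
            genus_total = sum(comp.values())
            comp[background] = max(0.0, 1.0 - genus_total)
            compositions[sample] = comp
            if config.sample_read_counts and sample in config.sample_read_counts:
                sample_depths[sample] = config.sample_read_counts[sample]
            else:
                sample_depths[sample] = config.reads_per_sample

    dyad_pairs = [
        (CohortTruth.stool_sample(d.mother_id), CohortTruth.stool_sample(d.infant_id))
        for d in cohort.dyads
    ]
    retained = qc_filter_samples(sample_depths, config.qc_min_reads, dyad_pairs)

    popani_results: dict[tuple[str, str], list[popani_mod.PopANIResult]] = {}
    sample_types: dict[str, str] = {}
    for dyad in cohort.dyads:
        sample_types[sample_of_individual[dyad.mother_id]] = "maternal_stool"
        sample_types[sample_of_individual[dyad.infant_id]] = "infant_stool"
    for label in sorted(clusters):
        cluster = clusters[label]
        reference = by_id[cluster.reference_id]
        seed_index = popani_mod.reference_seed_index(reference)
        pileups: dict[str, popani_mod.Pileup] = {}
        for sample in sorted(retained):
            reads = simulate_reads(
                compositions[sample], sample_depths[sample], config.read_length,
                config.error_rate, config.seed, source_sample=sample,
            )
            pileups[sample] = popani_mod.map_reads(
                reads, reference, config.min_read_identity, seed_index=seed_index,
            )
        for dyad in cohort.dyads:
            sm = sample_of_individual[dyad.mother_id]
            si = sample_of_individual[dyad.infant_id]
            if sm in pileups and si in pileups:
                res = popani_mod.compute_popani(
                    pileups[sm], pileups[si], config.min_cov
                )
                popani_results[(dyad.dyad_id, label)] = [res]

    # 5. per-method evidence and integration -------------------------
    evidence: dict[tuple[str, str], dict] = {}
    for label in sorted(clusters):
        cluster = clusters[label]
        species_name = cluster.species_name
        member_set = set(cluster.members)
        for dyad in cohort.dyads:
            mother_taxa = sorted(
                g.genome_id for g in cohort.genomes_of(individual_id=dyad.mother_id)
                if g.genome_id in member_set
            )
            infant_taxa = sorted(
                g.genome_id for g in cohort.genomes_of(individual_id=dyad.infant_id)
                if g.genome_id in member_set
            )
            per_method: dict = {}
            if cluster.tree is not None:
                per_method["isolate"] = trans_mod.call_isolate_transmission(
                    mother_taxa, infant_taxa, ani_matrix, cluster.snp, cluster.tree,
                    config.max_snps, config.lineage_ani_threshold,
                    snp_matrix_unmasked=cluster.snp_unmasked,
                )
            else:
                per_method["isolate"] = (None, {})
            sm = sample_of_individual[dyad.mother_id]
            si = sample_of_individual[dyad.infant_id]
            ab_m = abundances.get(sm, {}).get(species_name, 0.0)
            ab_i = abundances.get(si, {}).get(species_name, 0.0)
            npd_available = (
                cluster.npd is not None
                and min(ab_m, ab_i) >= config.npd_min_abundance
                and sm in retained and si in retained
            )
            per_method["npd"] = trans_mod.call_npd_transmission(
                mother_taxa, infant_taxa,
                cluster.npd if npd_available else None, config.npd_threshold,
            )
            per_method["popani"] = trans_mod.call_popani_transmission(
                popani_results.get((dyad.dyad_id, label), []),
                sample_types, config.popani_threshold, config.breadth_threshold,
                min_compared_sites=int(
                    config.popani_min_compared_frac * cohort.config.genome_length),
            )
            key = (dyad.dyad_id, species_name)
            if key in evidence:  # a split cluster: keep the stronger evidence
                for m, (flag, sup) in per_method.items():
                    old_flag, _ = evidence[key].get(m, (None, {}))
                    rank = {True: 2, False: 1, None: 0}
                    if rank[flag] > rank[old_flag]:
                        evidence[key][m] = (flag, sup)
            else:
                evidence[key] = per_method

    calls = trans_mod.integrate_calls(evidence)
    overlap = trans_mod.method_overlap(calls)

    dominance = []
    for g in genomes:
        sample = sample_of_individual.get(g.individual_id)
        profile = abundances.get(sample) if sample else None
        label = trans_mod.classify_dominance(g, profile)
        if label is not None:
            dominance.append(label)

    detection_limits = trans_mod.detection_limit_summary(cohort, calls, sample_depths)

    shared_by_dyad = {
        d.dyad_id: any(c.transmitted for c in calls if c.dyad_id == d.dyad_id)
        for d in cohort.dyads
    }
    covariates = pd.DataFrame(
        [dict(d.covariates) for d in cohort.dyads],
        index=[d.dyad_id for d in cohort.dyads],
    )
    associations = covariate_screen(shared_by_dyad, covariates)
    summary = trans_mod.summarize_cohort(calls, len(cohort.dyads), truth=cohort)

    return PipelineResult(
        cohort, config, ani_matrix, species_clusters, clusters, sample_depths,
        retained, popani_results, calls, overlap, dominance, detection_limits,
        associations, summary,
    )
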