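"""Readers/writers for the pipeline's on-disk formats.

Genomes travel as multi-record FASTA, reads as Sanger/Phred+33 FASTQ
(via Biopython), tables as TSV, trees as newick, summaries as JSON, and
the cohort configuration as a YAML echo. Variant and pileup tables are
1-based on output (VCF convention); everything in memory is 0-based
half-open. All writers are byte-deterministic for a fixed input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from straindyad.coresnp import CoreAlignment, VariantSet
from straindyad.distance import DistanceMatrix
from straindyad.popani import Pileup, PopANIResult
from straindyad.simcohort import (
    CohortConfig,
    CohortTruth,
    Dyad,
    Genome,
    ReadSet,
    TrueTransmission,
)
from straindyad.transmission import METHODS, TransmissionCall

_FLOAT_FMT = "%.10g"


def _to_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


# ----------------------------------------------------------------------
# genomes and reads
# ----------------------------------------------------------------------

def write_genomes_fasta(genomes: Iterable[Genome], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.genome_id, description="")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genomes_fasta(path, metadata: pd.DataFrame | None = None) -> list[Genome]:
    """Load genomes; per-genome labels come from a strains table when given,
    otherwise placeholder labels are used."""
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = None
        if metadata is not None and rec.id in metadata.index:
            row = metadata.loc[rec.id]
        genomes.append(
            Genome(
                rec.id,
                str(rec.seq).upper(),
                str(row["individual_id"]) if row is not None else "unknown",
                str(row["sample_type"]) if row is not None else "maternal_stool",
                str(row["species_label"]) if row is not None else "unknown",
                str(row["lineage_id"]) if row is not None else "unknown",
            )
        )
    return genomes


def write_reads_fastq(readset: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in readset.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_reads_fastq(path, source_sample: str | None = None) -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append((rec.id, str(rec.seq).upper(), quals))
    return ReadSet(reads, source_sample or Path(path).stem, {})


# ----------------------------------------------------------------------
# cohort round trip
# ----------------------------------------------------------------------

def write_cohort(truth: CohortTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genomes_fasta(truth.strains, outdir / "genomes.fasta")
    _to_tsv(
        pd.DataFrame(
            [
                {
                    "genome_id": g.genome_id,
                    "individual_id": g.individual_id,
                    "sample_type": g.sample_type,
                    "species_label": g.species_label,
                    "lineage_id": g.lineage_id,
                }
                for g in truth.strains
            ]
        ),
        outdir / "strains.tsv",
    )
    _to_tsv(
        pd.DataFrame(
            [
                {"dyad_id": d.dyad_id, "mother_id": d.mother_id, "infant_id": d.infant_id,
                 **dict(d.covariates)}
                for d in truth.dyads
            ]
        ),
        outdir / "dyads.tsv",
    )
    _to_tsv(
        pd.DataFrame(
            [dataclasses.asdict(t) for t in truth.true_transmissions]
            or [],
            columns=["dyad_id", "species", "mother_genome_id", "infant_genome_id",
                     "n_snps", "lineage_id"],
        ),
        outdir / "truth.tsv",
    )
    ab_rows = [
        {"sample_id": sample, "species": sp, "relative_abundance": frac}
        for sample in sorted(truth.abundances)
        for sp, frac in sorted(truth.abundances[sample].items())
    ]
    _to_tsv(pd.DataFrame(ab_rows, columns=["sample_id", "species", "relative_abundance"]),
            outdir / "abundances.tsv")
    cfg = dataclasses.asdict(truth.config)
    cfg["species"] = list(cfg["species"])
    cfg["transmitted_snp_range"] = list(cfg["transmitted_snp_range"])
    cfg["distinct_snp_range"] = list(cfg["distinct_snp_range"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_cohort(indir) -> CohortTruth:
    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    cfg["species"] = tuple(cfg["species"])
    cfg["transmitted_snp_range"] = tuple(cfg["transmitted_snp_range"])
    cfg["distinct_snp_range"] = tuple(cfg["distinct_snp_range"])
    config = CohortConfig(**cfg)
    meta = pd.read_csv(indir / "strains.tsv", sep="\t").set_index("genome_id", drop=False)
    strains = read_genomes_fasta(indir / "genomes.fasta", meta)
    dyads_df = pd.read_csv(indir / "dyads.tsv", sep="\t")
    cov_cols = [c for c in dyads_df.columns if c not in ("dyad_id", "mother_id", "infant_id")]
    dyads = [
        Dyad(r["dyad_id"], r["mother_id"], r["infant_id"],
             {c: str(r[c]) for c in cov_cols})
        for _, r in dyads_df.iterrows()
    ]
    truth_df = pd.read_csv(indir / "truth.tsv", sep="\t")
    transmissions = [
        TrueTransmission(r["dyad_id"], r["species"], r["mother_genome_id"],
                         r["infant_genome_id"], int(r["n_snps"]), r["lineage_id"])
        for _, r in truth_df.iterrows()
    ]
    ab_df = pd.read_csv(indir / "abundances.tsv", sep="\t")
    abundances: dict[str, dict[str, float]] = {}
    for _, r in ab_df.iterrows():
        abundances.setdefault(r["sample_id"], {})[r["species"]] = float(r["relative_abundance"])
    return CohortTruth(dyads, strains, transmissions, abundances, config)


# ----------------------------------------------------------------------
# analysis artifacts
# ----------------------------------------------------------------------

def write_variants_tsv(variant_sets: Sequence[VariantSet], path) -> None:
    """Long-form variant table; POS is 1-based (VCF convention)."""
    rows = [
        {"CHROM": vs.reference_id, "POS": p + 1, "REF": ref, "ALT": alt,
         "SAMPLE": vs.sample_id}
        for vs in variant_sets
        for p, ref, alt in vs.variants
    ]
    _to_tsv(pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT", "SAMPLE"]), path)


def write_core_alignment(alignment: CoreAlignment, fasta_path, positions_path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in alignment.sequences().items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    df = pd.DataFrame({"position_1based": alignment.positions + 1})
    _to_tsv(df, positions_path)


def write_pileup_tsv(pileup: Pileup, path) -> None:
    cov = pileup.coverage
    df = pd.DataFrame({
        "POS": pd.RangeIndex(1, pileup.length + 1),
        "COV": cov,
        "A": pileup.allele_counts[:, 0],
        "C": pileup.allele_counts[:, 1],
        "G": pileup.allele_counts[:, 2],
        "T": pileup.allele_counts[:, 3],
    })
    _to_tsv(df[df["COV"] > 0], path)


def ani_long_frame(results) -> pd.DataFrame:
    """Long-form directed ANI table (one row per query/reference pair)."""
    return pd.DataFrame(
        [
            {"query": r.query_id, "reference": r.reference_id,
             "ani": r.ani if r.ani is not None else float("nan"),
             "fragments_mapped": r.fragments_mapped,
             "fragments_total": r.fragments_total}
            for r in results
        ],
        columns=["query", "reference", "ani", "fragments_mapped", "fragments_total"],
    )


def popani_frame(results: Sequence[PopANIResult], calls: Sequence[bool] | None = None) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        rows.append({
            "sample_a": r.sample_a, "sample_b": r.sample_b, "reference": r.reference_id,
            "popANI": r.popani if r.popani is not None else float("nan"),
            "compared": r.compared_sites, "divergent": r.divergent_sites,
            "breadth_a": r.breadth_a, "breadth_b": r.breadth_b,
            "call": (calls[i] if calls is not None else ""),
        })
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "reference", "popANI",
                                       "compared", "divergent", "breadth_a", "breadth_b", "call"])


def calls_frame(calls: Sequence[TransmissionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"dyad_id": c.dyad_id, "species": c.species}
        for m in METHODS:
            flag = c.evidence.get(m)
            row[m] = "absent" if flag is None else str(bool(flag))
        row["transmitted"] = str(c.transmitted)
        row["direction_note"] = c.direction_note
        for key in sorted(c.support):
            row[key] = c.support[key]
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_pipeline_outputs(result, outdir) -> list[Path]:
    """Write the deterministic report bundle of a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    write_cohort(result.cohort, outdir / "cohort")
    written.extend(sorted((outdir / "cohort").iterdir()))
    emit("ani.tsv", result.ani.to_tsv)
    emit("species_clusters.tsv", lambda p: _to_tsv(
        pd.DataFrame(sorted(result.species_clusters.items()),
                     columns=["genome_id", "species_cluster"]), p))
    for label in sorted(result.clusters):
        cluster = result.clusters[label]
        safe = label.replace("/", "_")
        emit(f"snp_{safe}.tsv", cluster.snp.to_tsv)
        emit(f"snp_unmasked_{safe}.tsv", cluster.snp_unmasked.to_tsv)
        if cluster.tree is not None:
            emit(f"tree_{safe}.nwk", lambda p, t=cluster.tree: t.write(str(p), format="newick"))
            emit(f"npd_{safe}.tsv", cluster.npd.to_tsv)
    popani_rows = []
    for (dyad_id, label) in sorted(result.popani_results):
        for r in result.popani_results[(dyad_id, label)]:
            popani_rows.append({"dyad_id": dyad_id, "species_cluster": label,
                                **popani_frame([r]).iloc[0].to_dict()})
    emit("popani.tsv", lambda p: _to_tsv(pd.DataFrame(popani_rows), p))
    emit("calls.tsv", lambda p: _to_tsv(calls_frame(result.calls), p))
    emit("overlap.tsv", lambda p: _to_tsv(
        pd.DataFrame(sorted(result.overlap["subset_counts"].items()),
                     columns=["methods", "n_events"]), p))
    emit("dominance.tsv", lambda p: _to_tsv(
        pd.DataFrame([{"genome_id": d.genome_id, "label": d.label}
                      for d in result.dominance]), p))
    emit("detection_limits.tsv", lambda p: _to_tsv(result.detection_limits, p))
    emit("associations.tsv", lambda p: _to_tsv(result.associations, p))
    emit("summary.json", lambda p: write_summary_json(result.summary, p))
    return written
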