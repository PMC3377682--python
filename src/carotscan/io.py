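"""Readers and writers for the study's on-disk formats.

Formats: one FASTA per sequence locus (outgroup row named ``outgroup``); TSV
sample metadata (``id``, ``group``, ``color``); TSV diploid genotypes (``id``,
``locus``, ``allele1``, ``allele2`` as repeat counts); YAML locus registry.
All readers tolerate CRLF line endings and lower-case nucleotides.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    COLORS,
    GROUPS,
    LocusAlignment,
    LocusInfo,
    MicrosatLocus,
    Sample,
    StudyBundle,
)

logger = logging.getLogger(__name__)

OUTGROUP_LABEL = "outgroup"


def read_metadata(path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "group", "color"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        if row.group not in GROUPS:
            raise ValueError(f"metadata row id={row.id!r}: unknown group {row.group!r}")
        if row.color not in COLORS:
            raise ValueError(f"metadata row id={row.id!r}: unknown color {row.color!r}")
        samples.append(Sample(id=row.id, group=row.group, color=row.color))
    return samples


def read_locus_fasta(path, name: str | None = None) -> LocusAlignment:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    labels = [r.id for r in records]
    dup = [lab for lab, c in Counter(labels).items() if c > 1]
    if dup:
        raise ValueError(f"{path}: duplicate sequence labels {sorted(dup)}")
    seqs = {r.id: str(r.seq).upper() for r in records}
    outgroup = seqs.pop(OUTGROUP_LABEL, None)
    return LocusAlignment(name=name or path.stem, sequences=seqs, outgroup=outgroup)


def read_genotype_table(path) -> dict[str, dict[str, tuple[int, int]]]:
    """locus -> {individual -> (allele1, allele2)} from the long-format TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "locus", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genotypes {path}: missing columns {sorted(missing)}")
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.locus), {})[str(row.id)] = (int(row.allele1), int(row.allele2))
    return out


def read_registry(path) -> dict[str, LocusInfo]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {}
    for entry in raw["loci"]:
        info = LocusInfo(
            name=entry["name"],
            kind=entry["kind"],
            length=int(entry["length"]),
            position=entry.get("position"),
        )
        registry[info.name] = info
    return registry


def _registry_ssr_meta(raw_entry: dict) -> tuple[int, tuple[int, int]]:
    motif = int(raw_entry.get("motif", 2))
    rng = raw_entry.get("allele_range", None)
    if rng is None:
        raise ValueError(f"SSR registry entry {raw_entry.get('name')!r} needs allele_range")
    return motif, (int(rng[0]), int(rng[1]))


def read_study_bundle(fasta_paths, genotype_table_path, metadata_path, registry_path) -> StudyBundle:
    """Load and cross-validate all observed inputs into one StudyBundle."""
    samples = read_metadata(metadata_path)
    with open(registry_path) as fh:
        raw_registry = yaml.safe_load(fh)["loci"]
    registry = {e["name"]: LocusInfo(name=e["name"], kind=e["kind"],
                                     length=int(e["length"]), position=e.get("position"))
                for e in raw_registry}
    raw_by_name = {e["name"]: e for e in raw_registry}

    alignments = {}
    for path in fasta_paths:
        aln = read_locus_fasta(path)
        alignments[aln.name] = aln

    genotypes = read_genotype_table(genotype_table_path)
    microsats = {}
    for locus, geno in genotypes.items():
        if locus not in raw_by_name:
            raise ValueError(f"genotype locus {locus!r} missing from registry")
        motif, allele_range = _registry_ssr_meta(raw_by_name[locus])
        microsats[locus] = MicrosatLocus(
            name=locus, motif=motif, allele_range=allele_range, genotypes=geno
        )

    bundle = StudyBundle(
        samples=samples, alignments=alignments, microsats=microsats, registry=registry
    )
    group_counts = Counter(s.group for s in samples)
    color_counts = Counter(s.color for s in samples)
    logger.info(
        "loaded bundle: %d samples (groups %s; colors %s), %d alignments, %d SSR loci",
        len(samples), dict(group_counts), dict(color_counts),
        len(alignments), len(microsats),
    )
    return bundle


# ---------------------------------------------------------------- writers

def write_locus_fasta(aln: LocusAlignment, path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.sequences.items()]
    if aln.outgroup is not None:
        records.append(SeqRecord(Seq(aln.outgroup), id=OUTGROUP_LABEL, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_metadata(samples, path) -> None:
    pd.DataFrame(
        [(s.id, s.group, s.color) for s in samples], columns=["id", "group", "color"]
    ).to_csv(path, sep="\t", index=False)


def write_genotype_table(microsats, path) -> None:
    rows = []
    for locus in microsats.values():
        for sid, (a1, a2) in locus.genotypes.items():
            rows.append((sid, locus.name, a1, a2))
    pd.DataFrame(rows, columns=["id", "locus", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def write_registry(registry, path, microsats=None) -> None:
    entries = []
    for info in registry.values():
        entry: dict = {"name": info.name, "kind": info.kind, "length": info.length}
        if info.position is not None:
            entry["position"] = info.position
        if microsats and info.name in microsats:
            ssr = microsats[info.name]
            entry["motif"] = ssr.motif
            entry["allele_range"] = list(ssr.allele_range)
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump({"loci": entries}, fh, sort_keys=False)


def write_study_bundle(bundle: StudyBundle, outdir) -> dict[str, list[str] | str]:
    """Write a bundle to a directory; returns the paths read_study_bundle needs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_paths = []
    for name, aln in bundle.alignments.items():
        p = outdir / f"{name}.fasta"
        write_locus_fasta(aln, p)
        fasta_paths.append(str(p))
    meta = outdir / "samples.tsv"
    geno = outdir / "genotypes.tsv"
    reg = outdir / "registry.yaml"
    write_metadata(bundle.samples, meta)
    write_genotype_table(bundle.microsats, geno)
    write_registry(bundle.registry, reg, microsats=bundle.microsats)
    return {
        "fasta_paths": fasta_paths,
        "genotype_table_path": str(geno),
        "metadata_path": str(meta),
        "registry_path": str(reg),
    }
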