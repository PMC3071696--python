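"""File-format helpers shared by the simulator and the pipeline CLI.

Coordinates are 0-based half-open internally; conversions happen only at
file boundaries (.sgr is 1-based, BED stays 0-based).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hoxchip.synthetic import AccessibilityDomain, GeneModel, TrueRegion


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genes_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed BED6 line {lineno}")
            genes.append(GeneModel(parts[3], parts[0], int(parts[1]), int(parts[2]), parts[5]))
    return genes


def write_domains_bed(domains: list[AccessibilityDomain], path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.state}\t0\t.\n")


def read_domains_bed(path) -> list[AccessibilityDomain]:
    domains = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 4:
                domains.append(AccessibilityDomain(parts[0], int(parts[1]),
                                                   int(parts[2]), parts[3]))
    return domains


def write_truth_tsv(regions: list[TrueRegion], path) -> None:
    rows = [(r.chrom, r.center, r.half_width, r.enrichment_fold,
             r.cluster_id or "", r.planted_motif or "", r.target_gene or "")
            for r in regions]
    pd.DataFrame(rows, columns=["chrom", "center", "half_width", "enrichment_fold",
                                "cluster_id", "planted_motif", "target_gene"]
                 ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TrueRegion]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [TrueRegion(row.chrom, int(row.center), int(row.half_width),
                       float(row.enrichment_fold),
                       row.cluster_id or None, row.planted_motif or None,
                       row.target_gene or None)
            for row in df.itertuples()]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, entries: dict, path_name: str = "manifest.json") -> Path:
    """Write a manifest listing every artefact with a content hash."""
    outdir = Path(outdir)
    files = {p.name: file_sha256(p) for p in sorted(outdir.iterdir())
             if p.is_file() and p.name != path_name and p.suffix != ".log"}
    manifest = {"files": files, **entries}
    path = outdir / path_name
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
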