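"""Plain-text readers/writers: minimal VCFv4.2 emitter, BED/GFF3 annotations, TSV tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GT-only VCFv4.2 file for a genotype matrix.

    Heterozygotes are emitted as ``0/1`` and missing calls as ``./.``; the
    dialect is deliberately minimal so that any VCF reader accepts it.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=divscan"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(gm.samples)
    lines.append("\t".join(header))

    scaffolds = gm.sites["scaffold"].to_numpy()
    positions = gm.sites["pos"].to_numpy()
    refs = gm.sites["ref"].to_numpy()
    alts = gm.sites["alt"].to_numpy()
    for i in range(gm.n_sites):
        gts = "\t".join(_GT_CODE[int(c)] for c in gm.calls[i])
        lines.append(
            f"{scaffolds[i]}\t{positions[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Read CDS annotation from BED6 or GFF3 into a uniform frame.

    Returns columns ``gene_id, scaffold, start, end`` with 0-based half-open
    intervals (GFF3's 1-based closed coordinates are converted).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    return _read_bed6(path)


def _read_bed6(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["scaffold", "start", "end", "gene_id", "score", "strand"],
        usecols=range(6),
    )
    return df[["gene_id", "scaffold", "start", "end"]]


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene = attrs.get("gene_id") or attrs.get("ID") or attrs.get("Parent")
            if gene is None:
                log.warning("CDS without an identifier skipped: %s", line.strip())
                continue
            rows.append((gene, fields[0], int(fields[3]) - 1, int(fields[4])))
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end"])


def read_proteome_flags(path) -> pd.DataFrame:
    """Read the protein-detection flag table (gene_id, in_larva, in_egg)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("in_larva", "in_egg"):
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    return df


def read_go_map(path) -> pd.DataFrame:
    """Read the gene -> GO term table (gene_id, go_id, namespace)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "go_id", "namespace"}
    if not required.issubset(df.columns):
        raise ValueError(f"GO map {path} must have columns {sorted(required)}")
    return df


def read_survival(path) -> pd.DataFrame:
    """Read per-tank survival counts (tank, day, alive, total, condition)."""
    df = pd.read_csv(path, sep="\t")
    required = {"tank", "day", "alive", "total", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table {path} must have columns {sorted(required)}")
    return df
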