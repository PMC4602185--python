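"""Text-format I/O: FASTA (via Biopython), fixed-step wiggle tracks, TSV tables.

Wiggle dialect: one ``fixedStep chrom=<gene_id> start=1 step=1`` block per
gene, one value per CDS nucleotide, 1-based positions along the CDS.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CodingRegion, CodonProfile, InputError, NucleotideProfile
from .mapping import FootprintRead


# ---------------------------------------------------------------- FASTA

def read_cds_fasta(path: str | Path) -> list[CodingRegion]:
    genes = [CodingRegion(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not genes:
        raise InputError(f"no FASTA records in {path}")
    return genes


def write_cds_fasta(genes: list[CodingRegion], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.gene_id, description="") for g in genes]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- wiggle

def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6g}"


def write_wiggle(profiles: dict[str, NucleotideProfile], path: str | Path,
                 track_name: str | None = None) -> None:
    with open(path, "w") as fh:
        if track_name:
            fh.write(f"track type=wiggle_0 name={track_name}\n")
        for gene_id in sorted(profiles):
            fh.write(f"fixedStep chrom={gene_id} start=1 step=1\n")
            for v in profiles[gene_id].values:
                fh.write(_format_value(v) + "\n")


def read_wiggle(path: str | Path, assay: str) -> dict[str, NucleotideProfile]:
    profiles: dict[str, NucleotideProfile] = {}
    gene_id: str | None = None
    values: list[float] = []

    def _flush() -> None:
        if gene_id is not None:
            profiles[gene_id] = NucleotideProfile(gene_id, np.array(values), assay)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                _flush()
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                if int(fields.get("start", 1)) != 1 or int(fields.get("step", 1)) != 1:
                    raise InputError(f"{path}: only start=1 step=1 tracks are supported")
                gene_id = fields["chrom"]
                values = []
            else:
                values.append(float(line))
    _flush()
    if not profiles:
        raise InputError(f"no wiggle tracks in {path}")
    return profiles


# ---------------------------------------------------------------- footprints

def read_footprints(path: str | Path) -> dict[str, list[FootprintRead]]:
    """Read a footprint TSV (gene_id, start, length) grouped by gene."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["gene_id", "start", "length"], header=0)
    reads: dict[str, list[FootprintRead]] = {}
    for row in df.itertuples(index=False):
        reads.setdefault(str(row.gene_id), []).append(
            FootprintRead(str(row.gene_id), int(row.start), int(row.length))
        )
    return reads


def write_footprints(reads: dict[str, list[FootprintRead]], path: str | Path) -> None:
    rows = [(r.gene_id, r.start, r.length)
            for g in sorted(reads) for r in reads[g]]
    pd.DataFrame(rows, columns=["gene_id", "start", "length"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------- codon TSVs

def write_codon_profiles(profiles: dict[str, CodonProfile], path: str | Path) -> None:
    rows = []
    for gene_id in sorted(profiles):
        p = profiles[gene_id]
        for i, (v, m) in enumerate(zip(p.values, p.mask)):
            rows.append((gene_id, i, v, int(m)))
    pd.DataFrame(rows, columns=["gene_id", "codon_index", "value", "mask"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_codon_profiles(path: str | Path, assay: str) -> dict[str, CodonProfile]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, CodonProfile] = {}
    for gene_id, sub in df.groupby("gene_id", sort=True):
        sub = sub.sort_values("codon_index")
        out[str(gene_id)] = CodonProfile(
            str(gene_id), sub["value"].to_numpy(float), assay,
            sub["mask"].to_numpy(bool))
    return out
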