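"""Readers and writers for the pipeline's exchange formats.

FASTA for sequences (Biopython-backed), GTF + genome FASTA for gene
models (gffutils-backed), and header-carrying TSV for count matrices and
score/expression tables.  All genomic intervals are converted to 0-based
half-open on read; GTF is written back as 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomecomp import GeneModel
from .seqdesign import CodingSequence
from .sortquant import BinCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_gene_models",
    "write_gtf",
    "read_counts",
    "write_counts",
]


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read coding sequences; ids must be unique; lowercase is upcased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("normalized lowercase bases in %s to uppercase", rec.id)
        out.append(CodingSequence(id=rec.id, cds=seq.upper()))
    return out


def write_fasta(sequences: list[CodingSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.cds), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_gene_models(gtf_path: str | Path, fasta_path: str | Path | None = None):
    """Parse a GTF into gene models (plus the genome when FASTA is given).

    Exons are ranked in transcription order on both strands; transcripts
    whose CDS falls outside their exons are skipped with a log entry.
    Returns ``models`` or ``(models, genome)``.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    models: list[GeneModel] = []
    for tx in db.features_of_type("transcript"):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(tx, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(tx, featuretype="CDS", order_by="start")
        ]
        if not exons:
            logger.warning("transcript %s has no exons; skipped", tx.id)
            continue
        ok = all(any(s <= cs and ce <= e for s, e in exons) for cs, ce in cds)
        if not ok:
            logger.warning("transcript %s: CDS outside exons; skipped", tx.id)
            continue
        models.append(
            GeneModel(
                gene_id=tx.attributes.get("gene_id", [tx.id])[0],
                transcript_id=tx.attributes.get("transcript_id", [tx.id])[0],
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds_intervals=cds,
            )
        )
    if fasta_path is None:
        return models
    return models, read_genome_fasta(fasta_path)


def write_gtf(models: list[GeneModel], path: str | Path, source: str = "gcsplice") -> None:
    """Write transcript/exon/CDS features as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = (
                min(s for s, _ in m.exons) + 1,
                max(e for _, e in m.exons),
            )
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for s, e in sorted(m.cds_intervals):
                fh.write(
                    f"{m.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t{attrs}\n"
                )


def read_counts(path: str | Path, compartments: tuple[str, ...]) -> BinCountMatrix:
    """Read a variant x compartment count TSV.

    The header must contain ``variant_id`` plus every compartment (order
    in the file is irrelevant; the schema order is authoritative).
    Missing cells and negative or non-integer counts are errors, with the
    offending row reported.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in ("variant_id", *compartments) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.set_index("variant_id")[list(compartments)]
    na = df.isna()
    if na.values.any():
        row = df.index[na.any(axis=1)][0]
        raise ValueError(f"{path}: missing count in row for variant {row!r}")
    values = df.to_numpy()
    if (values < 0).any():
        row = df.index[(values < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative count in row for variant {row!r}")
    if not (values == values.astype(int)).all():
        row = df.index[(values != values.astype(int)).any(axis=1)][0]
        raise ValueError(f"{path}: non-integer count in row for variant {row!r}")
    return BinCountMatrix(counts=df.astype(int), replicate_id=Path(str(path)).stem)


def write_counts(m: BinCountMatrix, path: str | Path) -> None:
    m.counts.astype(int).to_csv(path, sep="\t", index_label="variant_id")
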