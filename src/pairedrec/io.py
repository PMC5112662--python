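"""File formats: FASTA and GFF3 in, TSV/GFF3 out.

GFF3 is 1-based inclusive on disk and converted to 0-based half-open
internally (and back on writing); strand is preserved.  FASTA goes
through Biopython's SeqIO; GFF3 parsing goes through gffutils.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Exon, GeneModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "GffRecord",
    "read_gff3",
    "write_gff3",
    "genes_to_gff_records",
    "genes_from_gff3",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class GffRecord:
    """One GFF3 feature, internal 0-based half-open coordinates."""

    seqid: str
    source: str
    type: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start + 1),  # back to 1-based inclusive
                str(self.end),
                ".",
                self.strand,
                ".",
                attrs or ".",
            ]
        )


def read_gff3(path: str | Path) -> list[GffRecord]:
    """Parse GFF3 into records with 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: list[GffRecord] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        attrs = {k: v[0] if isinstance(v, list) else v for k, v in feat.attributes.items()}
        out.append(
            GffRecord(
                seqid=feat.seqid,
                source=feat.source,
                type=feat.featuretype,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                attributes=attrs,
            )
        )
    return out


def write_gff3(records: list[GffRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def genes_to_gff_records(genes: list[GeneModel], source: str = "pairedrec") -> list[GffRecord]:
    """GFF3 records (gene + exon features) for a list of gene models."""
    records: list[GffRecord] = []
    for gene in genes:
        attrs = {"ID": gene.id}
        if gene.subgroup:
            attrs["subgroup"] = gene.subgroup
        if gene.homeolog:
            attrs["homeolog"] = gene.homeolog
        if gene.anchoring:
            attrs["anchoring"] = gene.anchoring
        if gene.species:
            attrs["species"] = gene.species
        records.append(
            GffRecord(gene.chromosome, source, "gene", gene.start, gene.end, gene.strand, attrs)
        )
        for k, exon in enumerate(gene.exons):
            records.append(
                GffRecord(
                    gene.chromosome,
                    source,
                    "exon",
                    exon.start,
                    exon.end,
                    gene.strand,
                    {
                        "ID": f"{gene.id}.exon{k + 1}",
                        "Parent": gene.id,
                        "exon_type": exon.kind,
                    },
                )
            )
    return records


def genes_from_gff3(path: str | Path) -> list[GeneModel]:
    """Reconstruct gene models from a GFF3 written by this package.

    Exons are matched to parents via the Parent attribute and ordered
    5'->3' on the coding strand; exon kinds come from the ``exon_type``
    attribute.
    """
    records = read_gff3(path)
    genes: dict[str, GffRecord] = {}
    exons: dict[str, list[GffRecord]] = {}
    for rec in records:
        if rec.type == "gene":
            genes[rec.attributes["ID"]] = rec
        elif rec.type == "exon":
            parent = rec.attributes.get("Parent", "")
            exons.setdefault(parent, []).append(rec)
    out: list[GeneModel] = []
    for gid, grec in genes.items():
        ex = [
            Exon(e.start, e.end, e.attributes.get("exon_type", "other"))
            for e in exons.get(gid, [])
        ]
        ex.sort(key=lambda e: e.start, reverse=(grec.strand == "-"))
        out.append(
            GeneModel(
                id=gid,
                chromosome=grec.seqid,
                strand=grec.strand,
                exons=ex,
                subgroup=grec.attributes.get("subgroup", ""),
                homeolog=grec.attributes.get("homeolog", ""),
                anchoring=grec.attributes.get("anchoring", ""),
                species=grec.attributes.get("species", ""),
            )
        )
    out.sort(key=lambda g: (g.chromosome, g.start))
    return out
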