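"""Genome, annotation, and essentiality-table I/O.

Reads a genome FASTA plus a GFF3 annotation and produces
:class:`~introness.records.GeneRecord` objects whose introns come from the
transcript with the longest total coding sequence.  Essentiality labels in
the style of OGEE (per-gene counts of studies calling the gene essential)
are read from a TSV and attached with the majority-of-studies rule.

Coordinates are handled 0-based half-open internally; GFF3 1-based
inclusive coordinates are converted at the parsing boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .records import EssentialityLabel, GeneRecord, IntronRecord

__all__ = [
    "read_genome",
    "extract_introns",
    "read_essentiality",
    "assign_label",
    "label_genes",
    "write_intron_fasta",
    "read_intron_fasta",
    "write_manifest",
    "read_manifest",
]


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a contig-id -> uppercase-sequence map.

    Raises ``ValueError`` on a file that does not start with a FASTA
    header (naming the offending line) or on duplicate contig ids.
    """
    fasta_path = Path(fasta_path)
    with open(fasta_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{fasta_path}: line {lineno} is not FASTA "
                    f"(expected '>' header before sequence data)"
                )
            break
        else:
            raise ValueError(f"{fasta_path}: empty FASTA")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"{fasta_path}: duplicate contig id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def _cds_length(db: gffutils.FeatureDB, transcript: gffutils.Feature) -> int:
    return sum(f.end - f.start + 1 for f in db.children(transcript, featuretype="CDS"))


def extract_introns(
    gff_path: str | Path, genome: dict[str, str]
) -> list[GeneRecord]:
    """Extract introns for every gene from its longest-CDS transcript.

    One transcript is chosen per gene: the mRNA with the maximal total CDS
    length, ties broken by lexicographically smallest transcript id.
    Introns are the gaps between consecutive exons of that transcript;
    minus-strand introns are reverse-complemented and ordinals follow
    transcript 5'->3' order.  Intronless genes yield empty intron lists.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="error", keep_order=False
    )
    out: list[GeneRecord] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if not transcripts:
            continue
        chosen = max(transcripts, key=lambda t: (_cds_length(db, t), _neg_id(t.id)))
        exons = sorted(
            ((f.start, f.end) for f in db.children(chosen, featuretype="exon")),
        )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {chosen.id}: exons overlap or are unsorted "
                    f"([{s1},{e1}] vs [{s2},{e2}])"
                )
        contig = genome.get(gene.seqid)
        if contig is None:
            raise ValueError(f"gene {gene.id}: contig {gene.seqid!r} not in genome")
        introns_plus: list[str] = []
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            # gap between exons, converted to 0-based half-open [e1, s2-1)
            if s2 - 1 > len(contig):
                raise ValueError(
                    f"transcript {chosen.id}: intron [{e1 + 1},{s2 - 1}] outside "
                    f"contig {gene.seqid} (length {len(contig)})"
                )
            introns_plus.append(contig[e1 : s2 - 1])
        if gene.strand == "-":
            intron_seqs = [
                str(Seq(s).reverse_complement()) for s in reversed(introns_plus)
            ]
        else:
            intron_seqs = introns_plus
        rec = GeneRecord(
            gene_id=gene.id,
            strand=gene.strand,
            introns=[
                IntronRecord(gene.id, chosen.id, k, seq)
                for k, seq in enumerate(intron_seqs, start=1)
            ],
        )
        out.append(rec)
    return out


class _neg_id(str):
    """String wrapper whose ordering is reversed, for max() tie-breaks."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


@dataclass(frozen=True)
class StudyCounts:
    n_essential: int
    n_total: int
    category: str


def read_essentiality(table_path: str | Path) -> dict[str, StudyCounts]:
    """Read the gene-essentiality table (gene_id, n_essential, n_total, category)."""
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    required = {"gene_id", "n_essential", "n_total", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{table_path}: missing columns {sorted(missing)}")
    out: dict[str, StudyCounts] = {}
    for row in df.itertuples(index=False):
        gid = row.gene_id
        if gid in out:
            raise ValueError(f"{table_path}: duplicate gene id {gid!r}")
        try:
            n_ess, n_tot = int(row.n_essential), int(row.n_total)
        except (TypeError, ValueError) as err:
            raise ValueError(f"{table_path}: malformed counts for gene {gid!r}") from err
        if n_ess < 0 or n_tot < 0 or n_ess > n_tot:
            raise ValueError(
                f"{table_path}: gene {gid!r} has n_essential={n_ess} > "
                f"n_total={n_tot} or negative counts"
            )
        out[gid] = StudyCounts(n_ess, n_tot, row.category)
    return out


def assign_label(
    n_essential: int,
    n_total: int,
    category: str,
    *,
    half_is_essential: bool = True,
) -> EssentialityLabel:
    """Map study counts and the three-way category to a binary label.

    Conditional genes found essential in fewer than half of studies are
    discarded from binary classification; the remainder are grouped with
    essential genes.  At exactly half, ``half_is_essential`` (default True)
    keeps the gene in the essential class.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_essential <= n_total:
        raise ValueError("require 0 <= n_essential <= n_total")
    if category == "essential":
        binary = "essential"
    elif category == "nonessential":
        binary = "nonessential"
    elif category == "conditional":
        frac = n_essential / n_total
        thresh_met = frac >= 0.5 if half_is_essential else frac > 0.5
        binary = "essential" if thresh_met else "discarded"
    else:
        raise ValueError(f"unknown category {category!r}")
    return EssentialityLabel(category=category, binary=binary)


def label_genes(
    genes: list[GeneRecord],
    table: dict[str, StudyCounts],
    *,
    half_is_essential: bool = True,
    require_all: bool = True,
) -> list[GeneRecord]:
    """Attach labels and essential fractions to extracted genes, in place."""
    labeled = []
    for g in genes:
        counts = table.get(g.gene_id)
        if counts is None:
            if require_all:
                raise KeyError(f"gene {g.gene_id} missing from essentiality table")
            continue
        g.label = assign_label(
            counts.n_essential,
            counts.n_total,
            counts.category,
            half_is_essential=half_is_essential,
        )
        g.essential_fraction = counts.n_essential / counts.n_total
        labeled.append(g)
    return labeled


# ---------------------------------------------------------------------------
# Stage interchange formats: intron FASTA + gene manifest TSV

def write_intron_fasta(genes: list[GeneRecord], path: str | Path) -> None:
    """Write introns as FASTA with headers gene|transcript|ordinal|label."""
    with open(path, "w") as fh:
        for g in genes:
            cat = g.label.category if g.label else "NA"
            for i in g.introns:
                fh.write(f">{i.gene_id}|{i.transcript_id}|{i.ordinal}|{cat}\n")
                for k in range(0, len(i.sequence), 80):
                    fh.write(i.sequence[k : k + 80] + "\n")


def read_intron_fasta(path: str | Path) -> list[GeneRecord]:
    """Re-read an intron FASTA written by :func:`write_intron_fasta`."""
    by_gene: dict[str, GeneRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid, tid, ordinal, _cat = rec.id.split("|")
        gene = by_gene.get(gid)
        if gene is None:
            gene = by_gene[gid] = GeneRecord(gene_id=gid, strand="+")
        gene.introns.append(IntronRecord(gid, tid, int(ordinal), str(rec.seq)))
    for g in by_gene.values():
        g.introns.sort(key=lambda i: i.ordinal)
    return list(by_gene.values())


def write_manifest(genes: list[GeneRecord], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "strand": g.strand,
                "category": g.label.category if g.label else "NA",
                "binary": g.label.binary if g.label else "NA",
                "essential_fraction": g.essential_fraction,
                "n_introns": g.n_introns,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
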