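"""Annotated-genome input/output and the normalized gene model.

Everything downstream (composition statistics, homology, the gene array,
variant effect annotation, the reduction simulator) works on
:class:`GenomeRecord` / :class:`GeneRecord`.  Coordinates are 0-based
half-open internally; GenBank's 1-based inclusive convention is converted
at the I/O boundary.  Circular replicons are linearized at position 0 of
the record; a feature spanning the origin is kept as a single gene with a
two-span location so its extracted sequence concatenates both spans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: feature kinds retained from annotation; anything else is dropped with a warning
GENE_KINDS = ("CDS", "tRNA", "rRNA", "ncRNA", "tmRNA")

#: NCBI genetic code for bacteria/archaea (used for all translations)
BACTERIAL_TABLE = 11


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene feature on a genome.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    linearized record.  For an origin-spanning feature on a circular
    genome, ``parts`` holds the individual spans in transcription order
    and ``end`` may be smaller than ``start`` + length; use
    :meth:`extract` for the spliced sequence.
    """

    gene_id: str
    name: str = ""
    kind: str = "CDS"
    start: int = 0
    end: int = 0
    strand: str = "+"
    pseudo: bool = False
    translation: str = ""
    parts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.parts and not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def spans(self) -> tuple[tuple[int, int], ...]:
        return self.parts if self.parts else ((self.start, self.end),)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)

    def extract(self, sequence: str) -> str:
        """Spliced, strand-oriented nucleotide sequence of the gene."""
        raw = "".join(sequence[s:e] for s, e in self.spans)
        if self.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw


@dataclass
class GenomeRecord:
    """A single-contig annotated genome with its ordered gene features."""

    genome_id: str
    organism: str = ""
    circular: bool = True
    sequence: str = ""
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"{self.genome_id}: duplicate gene ids {dupes}")
        for g in self.genes:
            for s, e in g.spans:
                if not (0 <= s < e <= len(self.sequence)):
                    raise ValueError(
                        f"{self.genome_id}/{g.gene_id}: span [{s}, {e}) outside "
                        f"genome of length {len(self.sequence)}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def coding_genes(self, include_pseudo: bool = False) -> list[GeneRecord]:
        """Protein-coding genes; pseudogenes excluded unless asked for."""
        return [
            g
            for g in self.genes
            if g.kind == "CDS" and (include_pseudo or not g.pseudo)
        ]

    def gene_sequence(self, gene_id: str) -> str:
        gene = next((g for g in self.genes if g.gene_id == gene_id), None)
        if gene is None:
            raise KeyError(f"{self.genome_id}: no gene {gene_id!r}")
        return gene.extract(self.sequence)


class ProteomeResult(NamedTuple):
    """Translations plus the genes whose CDS carries a premature stop."""

    proteins: dict[str, str]
    internal_stop_genes: list[str]


def _kind_of(feature: SeqFeature) -> str | None:
    if feature.type in GENE_KINDS:
        return feature.type
    if feature.type == "tmRNA":
        return "tmRNA"
    return None


def _feature_to_gene(feature: SeqFeature, index: int) -> GeneRecord | None:
    kind = _kind_of(feature)
    if kind is None:
        return None
    quals = feature.qualifiers
    gene_id = (
        quals.get("locus_tag", [None])[0]
        or quals.get("gene", [None])[0]
        or f"{kind}_{index:05d}"
    )
    name = quals.get("gene", [""])[0]
    pseudo = "pseudo" in quals or "pseudogene" in quals
    translation = quals.get("translation", [""])[0]
    strand = "-" if feature.location.strand == -1 else "+"
    loc = feature.location
    if isinstance(loc, CompoundLocation):
        # spans kept in location (transcription) order so that extract()
        # concatenates across the origin correctly
        parts = tuple((int(p.start), int(p.end)) for p in loc.parts)
        start, end = parts[0][0], parts[-1][1]
    else:
        start, end = int(loc.start), int(loc.end)
        parts = ()
    return GeneRecord(
        gene_id=gene_id,
        name=name,
        kind=kind,
        start=start,
        end=end,
        strand=strand,
        pseudo=pseudo,
        translation=translation,
        parts=parts,
    )


def read_genbank(path) -> GenomeRecord:
    """Read a single-contig GenBank flat file into a :class:`GenomeRecord`.

    Coordinates are converted from GenBank 1-based inclusive to 0-based
    half-open.  Features of unrecognized type are dropped with a logged
    warning; pseudogenes are retained and flagged.

    Raises
    ------
    ValueError
        if the file holds more than one record or lacks sequence.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    if len(records) > 1:
        ids = ", ".join(r.id for r in records)
        raise ValueError(f"{path}: expected a single record, found: {ids}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"{path}: record {rec.id} has no usable sequence (missing ORIGIN?)")
    circular = rec.annotations.get("topology", "linear") == "circular"

    genes: list[GeneRecord] = []
    dropped: set[str] = set()
    seen_ids: set[str] = set()
    for i, feat in enumerate(rec.features):
        if feat.type in ("source", "gene"):
            continue
        gene = _feature_to_gene(feat, i)
        if gene is None:
            dropped.add(feat.type)
            continue
        if gene.gene_id in seen_ids:  # e.g. CDS + mat_peptide sharing a locus_tag
            continue
        seen_ids.add(gene.gene_id)
        genes.append(gene)
    if dropped:
        logger.warning("%s: dropped features of unknown kind: %s", rec.id, sorted(dropped))
    return GenomeRecord(
        genome_id=rec.id,
        organism=rec.annotations.get("organism", ""),
        circular=circular,
        sequence=seq,
        genes=genes,
    )


def write_genbank(genome: GenomeRecord, path) -> None:
    """Write a :class:`GenomeRecord` back out as a GenBank flat file."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.genome_id,
        name=genome.genome_id.split(".")[0][:16],
        description=genome.organism,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.organism,
        },
    )
    for g in genome.genes:
        strand = -1 if g.strand == "-" else 1
        if g.parts:
            loc = CompoundLocation(
                [FeatureLocation(s, e, strand) for s, e in g.parts]
            )
        else:
            loc = FeatureLocation(g.start, g.end, strand)
        quals: dict[str, list[str]] = {"locus_tag": [g.gene_id]}
        if g.name:
            quals["gene"] = [g.name]
        if g.pseudo:
            quals["pseudo"] = [""]
        if g.translation:
            quals["translation"] = [g.translation]
        rec.features.append(SeqFeature(loc, type=g.kind, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def write_fasta(genome: GenomeRecord, path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.genome_id} {genome.organism}\n")
        seq = genome.sequence
        for i in range(0, len(seq), wrap):
            fh.write(seq[i : i + wrap] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def translate_cds(nt: str, table: int = BACTERIAL_TABLE) -> tuple[str, bool]:
    """Translate a strand-oriented CDS; return (protein, had_internal_stop).

    The trailing stop is removed.  A premature stop truncates the protein
    at that stop.  A length not divisible by 3 triggers a warning and
    truncation to the codon boundary.
    """
    if len(nt) % 3 != 0:
        warnings.warn(f"CDS length {len(nt)} not divisible by 3; truncating")
        nt = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        return aa[: aa.index("*")], True
    return aa, False


def extract_proteome(
    genome: GenomeRecord,
    table: int = BACTERIAL_TABLE,
    include_pseudo: bool = False,
) -> ProteomeResult:
    """Translate every (non-pseudo) CDS with the bacterial genetic code.

    Genes whose CDS contains an internal stop codon are translated up to
    the first stop and reported in ``internal_stop_genes`` — they are the
    primary split-gene candidates for the gene array.
    """
    cds = genome.coding_genes(include_pseudo=include_pseudo)
    if not cds:
        raise ValueError(f"{genome.genome_id}: no non-pseudo CDS to translate")
    proteins: dict[str, str] = {}
    split_candidates: list[str] = []
    for g in cds:
        aa, internal = translate_cds(g.extract(genome.sequence), table=table)
        if internal:
            split_candidates.append(g.gene_id)
        if aa:
            proteins[g.gene_id] = aa
    return ProteomeResult(proteins, split_candidates)


def gene_table(genome: GenomeRecord) -> pd.DataFrame:
    """Per-gene summary: id, kind, coordinates, strand, length, %GC, pseudo."""
    from .gc_metrics import gc_percent

    if not genome.genes:
        warnings.warn(f"{genome.genome_id}: empty annotation")
        return pd.DataFrame(
            columns=[
                "gene_id", "kind", "start", "end", "strand",
                "length", "gc_percent", "pseudo",
            ]
        )
    rows = []
    for g in genome.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "kind": g.kind,
                "start": g.start,
                "end": g.spans[-1][1],
                "strand": g.strand,
                "length": g.length,
                "gc_percent": gc_percent(g.extract(genome.sequence)),
                "pseudo": g.pseudo,
            }
        )
    return pd.DataFrame(rows)


def kind_counts(genome: GenomeRecord, include_pseudo: bool = False) -> dict[str, int]:
    """Per-kind gene counts plus 'total' and the merged 'other_rna' count.

    tmRNA is reported both on its own and inside ``other_rna`` (ncRNA +
    tmRNA) because annotation conventions differ on where ssrA belongs.
    """
    counts = {k: 0 for k in GENE_KINDS}
    for g in genome.genes:
        if g.pseudo and not include_pseudo:
            continue
        counts[g.kind] += 1
    counts["other_rna"] = counts["ncRNA"] + counts["tmRNA"]
    counts["total"] = sum(counts[k] for k in GENE_KINDS)
    return counts


def write_gene_table(genome: GenomeRecord, path) -> None:
    gene_table(genome).to_csv(path, sep="\t", index=False)
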