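"""Allele-frequency analytics for detecting co-resident endosymbiont strains.

A maternally transmitted endosymbiont is expected to be clonal within a
host, so polymorphic sites with intermediate alternate-allele
frequencies (20-80%) in deep read pileups are evidence of multiple
co-resident genotypes.  This module filters per-site allele-count tables
(or VCFs with allele depths) into variant calls, classifies variable
sites, intersects variant sets across host populations, and annotates
coding effects against the genome annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from Bio.Seq import Seq

from .genome_io import BACTERIAL_TABLE, GeneRecord, GenomeRecord

PILEUP_COLUMNS = ["position", "ref", "A", "C", "G", "T", "ins", "del", "mean_qual"]

EFFECTS = ("synonymous", "missense", "stop_gained", "frameshift", "intergenic")


@dataclass(frozen=True)
class VariantSite:
    """One polymorphic position in one population's pileup."""

    population: str
    position: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int
    frequency: float
    mean_base_quality: float
    gene_id: str | None = None
    effect: str | None = None
    aa_change: str | None = None
    quadrant: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError("need 0 <= alt_count <= depth")
        if abs(self.frequency - self.alt_count / self.depth) > 1e-9:
            raise ValueError("frequency inconsistent with counts")

    @property
    def key(self) -> tuple[int, str, str]:
        """Site identity across populations: position plus both alleles."""
        return (self.position, self.ref_allele, self.alt_allele)


def read_pileup(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: pileup table missing columns {sorted(missing)}")
    return table


def call_variants(
    pileup: pd.DataFrame,
    population: str = "",
    min_depth: int = 100,
    min_qual: float = 20.0,
    min_freq: float = 0.20,
) -> list[VariantSite]:
    """Filter a per-site allele-count table into variant calls.

    A site is emitted when depth >= ``min_depth``, mean base quality >=
    ``min_qual`` and some non-reference allele reaches frequency >=
    ``min_freq`` (all thresholds inclusive).  Multi-allelic sites emit
    one record per passing alternate allele; ``ins``/``del`` columns are
    treated as single alternate alleles named ``ins``/``del``.
    """
    sites: list[VariantSite] = []
    for line_no, row in enumerate(pileup.to_dict("records"), start=2):
        try:
            pos = int(row["position"])
            ref = str(row["ref"]).upper()
            counts = {b: int(row[b]) for b in "ACGT"}
            counts["ins"] = int(row["ins"])
            counts["del"] = int(row["del"])
            qual = float(row["mean_qual"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed pileup row at line {line_no}: {exc}") from exc
        depth = sum(counts.values())
        if depth < min_depth or qual < min_qual:
            continue
        for allele, count in counts.items():
            if allele == ref or count == 0:
                continue
            freq = count / depth
            if freq >= min_freq:
                sites.append(
                    VariantSite(
                        population=population,
                        position=pos,
                        ref_allele=ref,
                        alt_allele=allele,
                        depth=depth,
                        alt_count=count,
                        frequency=freq,
                        mean_base_quality=qual,
                    )
                )
    return sites


def read_vcf_sites(path, population: str = "") -> list[VariantSite]:
    """Read variant sites from a VCF with AD (allele depth) FORMAT fields."""
    from cyvcf2 import VCF

    sites = []
    for v in VCF(str(path)):
        ad = v.format("AD")
        if ad is None:
            continue
        depths = [int(x) for x in ad[0]]
        total = sum(depths)
        if total == 0:
            continue
        for alt, alt_depth in zip(v.ALT, depths[1:]):
            if alt_depth == 0:
                continue
            sites.append(
                VariantSite(
                    population=population,
                    position=int(v.POS) - 1,  # VCF is 1-based
                    ref_allele=v.REF,
                    alt_allele=alt,
                    depth=total,
                    alt_count=alt_depth,
                    frequency=alt_depth / total,
                    mean_base_quality=float(v.QUAL or 0.0),
                )
            )
    return sites


def classify_variable_sites(
    sites: list[VariantSite], low: float = 0.20, high: float = 0.80
) -> list[VariantSite]:
    """Sites with intermediate allele frequency (inclusive bounds) —
    the multi-strain signal; near-fixed sites are excluded."""
    return [s for s in sites if low <= s.frequency <= high]


def shared_variants(site_sets: dict[str, list[VariantSite]]) -> dict:
    """Venn-style report over populations, keyed by position + alleles."""
    if len(site_sets) < 2:
        raise ValueError("need at least two populations")
    keys = {pop: {s.key for s in sites} for pop, sites in site_sets.items()}
    union = set().union(*keys.values())
    membership = {
        k: frozenset(pop for pop, ks in keys.items() if k in ks) for k in union
    }
    subset_counts: dict[frozenset, int] = {}
    for k, pops in membership.items():
        subset_counts[pops] = subset_counts.get(pops, 0) + 1
    shared = sum(1 for pops in membership.values() if len(pops) >= 2)
    return {
        "per_population": {pop: len(ks) for pop, ks in keys.items()},
        "union": len(union),
        "shared": shared,
        "unique": {
            pop: subset_counts.get(frozenset([pop]), 0) for pop in site_sets
        },
        "subset_counts": {
            "+".join(sorted(pops)): n for pops, n in subset_counts.items()
        },
    }


def _gene_at(genome: GenomeRecord, position: int) -> GeneRecord | None:
    for g in genome.genes:
        for s, e in g.spans:
            if s <= position < e:
                return g
    return None


def annotate_effect(site: VariantSite, genome: GenomeRecord) -> VariantSite:
    """Attach the coding effect of a variant.

    SNVs inside a CDS are classified by re-translating the affected codon
    (strand-aware): synonymous, missense or stop_gained.  Insertions or
    deletions whose length is not a multiple of 3 are frameshifts.
    Positions outside genes are intergenic.
    """
    if site.position >= len(genome):
        raise ValueError(
            f"position {site.position} beyond genome length {len(genome)}"
        )
    gene = _gene_at(genome, site.position)
    if gene is None or gene.kind != "CDS":
        return replace(site, gene_id=gene.gene_id if gene else None, effect="intergenic")
    if site.alt_allele in ("ins", "del") or len(site.alt_allele) != len(site.ref_allele):
        shift = (
            1
            if site.alt_allele in ("ins", "del")
            else abs(len(site.alt_allele) - len(site.ref_allele))
        )
        effect = "frameshift" if shift % 3 else "missense"
        return replace(site, gene_id=gene.gene_id, effect=effect)
    # SNV: locate the codon in the strand-oriented CDS
    offset_fwd = site.position - gene.start
    cds = gene.extract(genome.sequence)
    if gene.strand == "+":
        offset = offset_fwd
        alt_base = site.alt_allele
    else:
        offset = (gene.end - 1) - site.position
        alt_base = str(Seq(site.alt_allele).reverse_complement())
    codon_i = offset // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return replace(site, gene_id=gene.gene_id, effect="missense")
    within = offset % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate(table=BACTERIAL_TABLE))
    aa_alt = str(Seq(alt_codon).translate(table=BACTERIAL_TABLE))
    if aa_alt == "*" and aa_ref != "*":
        effect = "stop_gained"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    else:
        effect = "missense"
    return replace(
        site,
        gene_id=gene.gene_id,
        effect=effect,
        aa_change=f"{aa_ref}{codon_i + 1}{aa_alt}",
    )


def snp_quadrant_distribution(
    sites: list[VariantSite], gene_quadrants: dict[str, str]
) -> dict[str, int]:
    """Count genic variants per conservation quadrant of their gene.

    Intergenic sites are excluded; genic sites whose gene has no quadrant
    are tallied under ``unclassified``.
    """
    counts = {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0, "unclassified": 0}
    for s in sites:
        if s.gene_id is None or s.effect == "intergenic":
            continue
        q = gene_quadrants.get(s.gene_id)
        if q in counts:
            counts[q] += 1
        else:
            counts["unclassified"] += 1
    return counts


def sites_frame(sites: list[VariantSite]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in sites])
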