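import pytest

from endoreduce import genome_io, homology, synthetic_data
from endoreduce.gene_array import build_array
from endoreduce.genome_io import GeneRecord, GenomeRecord


def make_genome(genome_id, gene_specs, spacer=10, circular=True, seq_gc="AT"):
    """Build a toy genome from (gene_id, name, sense_seq, strand) tuples,
    separated by fixed AT spacers."""
    from Bio.Seq import Seq

    parts, genes, pos = [], [], 0
    for gene_id, name, sense, strand in gene_specs:
        filler = ("AT" * spacer)[:spacer]
        parts.append(filler)
        pos += len(filler)
        fwd = sense if strand == "+" else str(Seq(sense).reverse_complement())
        parts.append(fwd)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                name=name,
                kind="CDS",
                start=pos,
                end=pos + len(fwd),
                strand=strand,
            )
        )
        pos += len(fwd)
    return GenomeRecord(
        genome_id=genome_id,
        organism="toy",
        circular=circular,
        sequence="".join(parts),
        genes=genes,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small reduction simulation shared across array-level tests:
    3 descendants of a 40-gene ancestor, with RBH assignments and the
    built gene array."""
    cfg = synthetic_data.SimulationConfig.mild(
        seed=1, n_descendants=3, n_ancestor_genes=40
    )
    ancestor, ref_proteome = synthetic_data.generate_ancestor(cfg)
    descendants, truth = synthetic_data.simulate_reduction(ancestor, cfg)
    assignments, proteomes, stops = {}, {}, {}
    for d in descendants:
        pr = genome_io.extract_proteome(d)
        proteomes[d.genome_id] = pr.proteins
        stops[d.genome_id] = pr.internal_stop_genes
        assignments[d.genome_id] = homology.reciprocal_best_hits(
            pr.proteins, ref_proteome, min_score=40.0
        )
    array = build_array(descendants, assignments, proteomes)
    return {
        "cfg": cfg,
        "ancestor": ancestor,
        "ref_proteome": ref_proteome,
        "descendants": descendants,
        "truth": truth,
        "assignments": assignments,
        "proteomes": proteomes,
        "internal_stops": stops,
        "array": array,
    }
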