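import numpy as np
import pandas as pd
import pytest

from endoreduce import synthetic_data
from endoreduce.strain_variation import (
    VariantSite,
    annotate_effect,
    call_variants,
    classify_variable_sites,
    shared_variants,
    snp_quadrant_distribution,
)

from conftest import make_genome


def _pileup(rows):
    return pd.DataFrame(
        rows, columns=["position", "ref", "A", "C", "G", "T", "ins", "del", "mean_qual"]
    )


def _site(freq, population="p", position=0, depth=1000):
    alt = int(round(freq * depth))
    return VariantSite(
        population=population,
        position=position,
        ref_allele="A",
        alt_allele="G",
        depth=depth,
        alt_count=alt,
        frequency=alt / depth,
        mean_base_quality=30.0,
    )


class TestCallVariants:
    def test_passing_site_emitted_with_frequency(self):
        sites = call_variants(_pileup([[10, "A", 105, 0, 45, 0, 0, 0, 30.0]]))
        assert len(sites) == 1
        assert sites[0].alt_allele == "G"
        assert sites[0].frequency == pytest.approx(45 / 150)

    @pytest.mark.parametrize(
        "row,reason",
        [
            ([10, "A", 40, 0, 40, 0, 0, 0, 30.0], "coverage 80 < 100"),
            ([10, "A", 170, 0, 30, 0, 0, 0, 30.0], "frequency 0.15 < 0.20"),
            ([10, "A", 100, 0, 100, 0, 0, 0, 15.0], "quality Q15 < Q20"),
        ],
    )
    def test_each_filter_rejects(self, row, reason):
        assert call_variants(_pileup([row])) == [], reason

    def test_thresholds_inclusive_at_boundary(self):
        sites = call_variants(_pileup([[5, "C", 20, 80, 0, 0, 0, 0, 20.0]]))
        assert len(sites) == 1  # depth 100, freq 0.20, Q20: all boundaries pass

    def test_multiallelic_site_emits_record_per_passing_allele(self):
        sites = call_variants(_pileup([[7, "A", 100, 80, 60, 0, 0, 0, 30.0]]))
        assert {s.alt_allele for s in sites} == {"C", "G"}

    def test_filtering_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        rows = []
        for pos in range(60):
            depth = int(rng.integers(50, 400))
            alt = int(rng.integers(0, depth + 1))
            rows.append(
                [pos, "A", depth - alt, 0, alt, 0, 0, 0, float(rng.integers(10, 40))]
            )
        pileup = _pileup(rows)
        base = {(s.position, s.alt_allele) for s in call_variants(pileup)}
        for kwargs in (
            {"min_depth": 150},
            {"min_qual": 25.0},
            {"min_freq": 0.30},
            {"min_depth": 200, "min_qual": 30.0, "min_freq": 0.4},
        ):
            tighter = {(s.position, s.alt_allele) for s in call_variants(pileup, **kwargs)}
            assert tighter <= base

    def test_malformed_row_reports_line(self):
        bad = _pileup([[3, "A", "oops", 0, 5, 0, 0, 0, 30.0]])
        with pytest.raises(ValueError, match="line"):
            call_variants(bad)


class TestVariableSites:
    @pytest.mark.parametrize(
        "freq,variable",
        [(0.50, True), (0.20, True), (0.80, True), (0.95, False), (0.19, False)],
    )
    def test_intermediate_band_inclusive(self, freq, variable):
        got = classify_variable_sites([_site(freq)])
        assert (len(got) == 1) is variable

    def test_two_strain_mixture_sites_classified_variable(self):
        genome = make_genome(
            "g", [("a", "", "ATG" + "GAC" * 30 + "TAA", "+")], spacer=20
        )
        variants = {25: "T", 60: "C", 90: "A"}
        variants = {
            p: b for p, b in variants.items() if genome.sequence[p] != b
        }
        pileup, truth = synthetic_data.simulate_pileup(
            genome,
            [({}, 0.7), (variants, 0.3)],
            depth=1000,
            error_rate=0.0,
            seed=11,
            n_background=50,
        )
        sites = call_variants(pileup)
        by_pos = {s.position: s for s in sites}
        for pos in truth["planted_positions"]:
            s = by_pos[pos]
            sd3 = 3 * np.sqrt(0.3 * 0.7 / s.depth)
            assert abs(s.frequency - 0.30) < sd3
        assert len(classify_variable_sites(sites)) == len(truth["planted_positions"])


class TestSharedVariants:
    def test_toy_overlap(self):
        a, b, c = (_site(0.5, position=p) for p in (1, 2, 3))
        report = shared_variants({"P1": [a, b], "P2": [b, c]})
        assert report["shared"] == 1
        assert report["unique"] == {"P1": 1, "P2": 1}
        assert report["union"] == 3

    def test_disjoint_sets_share_nothing(self):
        report = shared_variants(
            {"P1": [_site(0.5, position=1)], "P2": [_site(0.5, position=2)]}
        )
        assert report["shared"] == 0

    def test_subset_counts_sum_to_union_on_simulated_pools(self):
        rng = np.random.default_rng(23)
        pool_a = [_site(0.5, position=int(p)) for p in rng.choice(200, 40, replace=False)]
        pool_b = [_site(0.5, position=int(p)) for p in rng.choice(200, 40, replace=False)]
        pops = {}
        for i in range(5):
            pool = pool_a if i < 3 else pool_b
            take = rng.random(len(pool)) < 0.6
            pops[f"P{i}"] = [s for s, t in zip(pool, take) if t]
        report = shared_variants(pops)
        assert sum(report["subset_counts"].values()) == report["union"]
        # set-algebra oracle for the shared count
        from collections import Counter

        counts = Counter(
            key for sites in pops.values() for key in {s.key for s in sites}
        )
        assert report["shared"] == sum(1 for v in counts.values() if v >= 2)


class TestAnnotateEffect:
    # gene 'a' is ATG GCT TGG TAA at offset 20 on the plus strand
    GENOME = make_genome("g", [("a", "", "ATGGCTTGGTAA", "+")], spacer=20)

    def _snv(self, position, ref, alt):
        return VariantSite(
            population="p",
            position=position,
            ref_allele=ref,
            alt_allele=alt,
            depth=500,
            alt_count=250,
            frequency=0.5,
            mean_base_quality=30.0,
        )

    def test_synonymous_codon_change(self):
        # GCT -> GCC is still alanine
        site = annotate_effect(self._snv(25, "T", "C"), self.GENOME)
        assert site.effect == "synonymous"
        assert site.gene_id == "a"

    def test_missense_codon_change(self):
        # GCT -> GTT: Ala -> Val
        site = annotate_effect(self._snv(24, "C", "T"), self.GENOME)
        assert site.effect == "missense"
        assert site.aa_change == "A2V"

    def test_stop_gained(self):
        # TGG -> TGA: Trp -> stop
        site = annotate_effect(self._snv(28, "G", "A"), self.GENOME)
        assert site.effect == "stop_gained"

    def test_indel_in_cds_is_frameshift(self):
        site = VariantSite(
            population="p", position=24, ref_allele="C", alt_allele="del",
            depth=400, alt_count=200, frequency=0.5, mean_base_quality=30.0,
        )
        assert annotate_effect(site, self.GENOME).effect == "frameshift"

    def test_intergenic_position(self):
        site = annotate_effect(self._snv(5, "A", "G"), self.GENOME)
        assert site.effect == "intergenic"

    def test_position_beyond_genome_rejected(self):
        with pytest.raises(ValueError):
            annotate_effect(self._snv(10_000, "A", "G"), self.GENOME)

    def test_codon_annotation_matches_full_retranslation_oracle(self, small_sim):
        from endoreduce.genome_io import translate_cds

        genome = small_sim["descendants"][0]
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 100:
            gene = genome.genes[int(rng.integers(len(genome.genes)))]
            pos = int(rng.integers(gene.start, gene.end))
            ref = genome.sequence[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            site = annotate_effect(self._snv(pos, ref, str(alt)), genome)
            # oracle: mutate the whole genome, re-extract, re-translate
            mutated = genome.sequence[:pos] + str(alt) + genome.sequence[pos + 1 :]
            before, _ = translate_cds(gene.extract(genome.sequence))
            after, _ = translate_cds(gene.extract(mutated))
            if len(after) < len(before):
                expected = "stop_gained"
            elif after == before:
                expected = "synonymous"
            else:
                expected = "missense"
            assert site.effect == expected, (gene.gene_id, pos, ref, alt)
            checked += 1


class TestQuadrantDistribution:
    def test_one_site_per_quadrant(self):
        sites = [
            annotate_effect(
                VariantSite(
                    population="p", position=p, ref_allele="A", alt_allele="G",
                    depth=100, alt_count=50, frequency=0.5, mean_base_quality=30.0,
                ),
                make_genome("g", [(f"x{i}", "", "ATGAAATAA", "+")], spacer=1),
            )
            for i, p in enumerate([2, 2, 2, 2])
        ]
        sites = [s.__class__(**{**s.__dict__, "gene_id": f"x{i}"}) for i, s in enumerate(sites)]
        quadrants = {f"x{i}": q for i, q in enumerate(["Q1", "Q2", "Q3", "Q4"])}
        counts = snp_quadrant_distribution(sites, quadrants)
        assert counts == {"Q1": 1, "Q2": 1, "Q3": 1, "Q4": 1, "unclassified": 0}

    def test_intergenic_sites_excluded(self):
        site = VariantSite(
            population="p", position=1, ref_allele="A", alt_allele="G",
            depth=100, alt_count=50, frequency=0.5,
            mean_base_quality=30.0, effect="intergenic",
        )
        counts = snp_quadrant_distribution([site], {})
        assert sum(counts.values()) == 0

    def test_planted_low_gc_enrichment_recovered(self):
        rng = np.random.default_rng(13)
        quadrants = {}
        sites = []
        gene_pool = {"Q2": 40, "Q3": 10, "Q1": 5, "Q4": 5}
        i = 0
        for quadrant, n_genes in gene_pool.items():
            for _ in range(n_genes):
                g = f"g{i}"
                quadrants[g] = quadrant
                n_sites = int(rng.poisson(2.0 if quadrant == "Q2" else 0.5))
                for k in range(n_sites):
                    sites.append(
                        VariantSite(
                            population="p", position=i * 100 + k, ref_allele="A",
                            alt_allele="G", depth=200, alt_count=100, frequency=0.5,
                            mean_base_quality=30.0, gene_id=g, effect="missense",
                        )
                    )
                i += 1
        counts = snp_quadrant_distribution(sites, quadrants)
        assert counts["Q2"] == max(counts.values())
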