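"""Gene-locus classification, annotation joins, prioritization, recurrence."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest
from Bio.Seq import Seq

from conftest import G1, G2
from fetcall.annotate import (
    AnnotatedVariant,
    AnnotationTables,
    Gene,
    GeneModel,
    LocusAnnotation,
    attach_annotations,
    classify_locus,
    find_recurrent_genes,
    load_gene_model_tsv,
    prioritize,
    write_example_tables,
)


def _region_oracle(pos: int, model: GeneModel) -> str:
    """Independent per-base region labeling by explicit position sets."""
    best = None
    rank = {"cds": 0, "splice_site": 1, "utr": 2, "intron": 3, "promoter": 4}
    for g in model.genes:
        cds = {p for s, e in g.cds for p in range(s, e + 1)}
        exon = {p for s, e in g.exons for p in range(s, e + 1)}
        splice = set()
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            splice |= {e1 + 1, e1 + 2, s2 - 2, s2 - 1}
        tx = set(range(g.tx_start, g.tx_end + 1))
        if g.strand == "+":
            prom = set(range(g.tx_start - 2000, g.tx_start))
        else:
            prom = set(range(g.tx_end + 1, g.tx_end + 2001))
        if pos in cds:
            cat = "cds"
        elif pos in splice and pos not in exon:
            cat = "splice_site"
        elif pos in exon:
            cat = "utr"
        elif pos in tx:
            cat = "intron"
        elif pos in prom:
            cat = "promoter"
        else:
            continue
        if best is None or rank[cat] < rank[best]:
            best = cat
    return best or "intergenic"


class TestClassifyLocus:
    def test_agrees_with_per_base_region_oracle_genomewide(self, genome, gene_model):
        from conftest import GENOME_LEN

        coarse = {
            "synonymous": "cds", "missense": "cds", "nonsense": "cds",
            "frameshift": "cds", "inframe_indel": "cds",
            "splice_site": "splice_site", "utr5": "utr", "utr3": "utr",
            "intron": "intron", "promoter": "promoter",
            "intergenic": "intergenic",
        }
        seq = genome["chr1"]
        for pos in range(1, GENOME_LEN + 1, 3):  # every third base, both strands hit
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "C"
            got = classify_locus("chr1", pos, ref, alt, gene_model, genome).category
            assert coarse[got] == _region_oracle(pos, gene_model), f"pos {pos}"

    @pytest.mark.parametrize(
        "pos,alt,expected,aa",
        [
            (2130, "C", "synonymous", "A10A"),  # GCT -> GCC, Ala
            (2129, "T", "missense", "A10V"),  # GCT -> GTT
            (2497, "G", "nonsense", "Y99*"),  # TAC -> TAG
        ],
    )
    def test_plus_strand_coding_consequences(self, genome, gene_model, pos, alt,
                                             expected, aa):
        seq = genome["chr1"]
        ann = classify_locus("chr1", pos, seq[pos - 1], alt, gene_model, genome)
        assert (ann.category, ann.gene, ann.aa_change) == (expected, "G1", aa)

    def test_coding_consequences_match_whole_protein_translation(
        self, genome, gene_model
    ):
        # independent oracle: mutate the genome, re-splice the whole CDS,
        # translate with the standard code and diff the two proteins
        seq = genome["chr1"]
        for pos in list(range(2101, 2201, 7)) + list(range(2301, 2501, 11)):
            ref = seq[pos - 1]
            alt = "A" if ref != "A" else "G"
            mutated = seq[: pos - 1] + alt + seq[pos:]
            orig_cds = "".join(seq[s - 1 : e] for s, e in G1.cds)
            mut_cds = "".join(mutated[s - 1 : e] for s, e in G1.cds)
            p0 = str(Seq(orig_cds).translate())
            p1 = str(Seq(mut_cds).translate())
            if p0 == p1:
                expected = "synonymous"
            elif any(a == "*" and b != "*" for a, b in zip(p1, p0)):
                expected = "nonsense"
            else:
                expected = "missense"
            got = classify_locus("chr1", pos, ref, alt, gene_model, genome)
            assert got.category == expected, f"pos {pos}"

    def test_minus_strand_synonymous(self, genome, gene_model):
        # G2 codon 10 third base (transcript T), genomic complement at 4272
        seq = genome["chr1"]
        assert seq[4271] == "A"
        ann = classify_locus("chr1", 4272, "A", "G", gene_model, genome)
        assert (ann.category, ann.gene) == ("synonymous", "G2")

    def test_minus_strand_promoter_is_downstream_in_genome_coords(
        self, genome, gene_model
    ):
        ann = classify_locus("chr1", 4500, genome["chr1"][4499], "A", gene_model,
                             genome)
        assert (ann.category, ann.gene) == ("promoter", "G2")

    def test_frameshift_and_inframe_deletions(self, genome, gene_model):
        seq = genome["chr1"]
        two = classify_locus("chr1", 2150, seq[2149:2152], seq[2149], gene_model,
                             genome)
        assert (two.category, two.gene) == ("frameshift", "G1")
        three = classify_locus("chr1", 2150, seq[2149:2153], seq[2149], gene_model,
                               genome)
        assert three.category == "inframe_indel"

    def test_splice_site_takes_precedence_over_intron(self, genome, gene_model):
        seq = genome["chr1"]
        for pos, expected in [(2201, "splice_site"), (2202, "splice_site"),
                              (2250, "intron"), (2299, "splice_site"),
                              (2300, "splice_site")]:
            ann = classify_locus("chr1", pos, seq[pos - 1], "A" if seq[pos - 1] != "A"
                                 else "C", gene_model, genome)
            assert ann.category == expected, f"pos {pos}"

    def test_utrs_and_promoter(self, genome, gene_model):
        seq = genome["chr1"]
        cases = [(2050, "utr5"), (2550, "utr3"), (1500, "promoter")]
        for pos, expected in cases:
            ref = seq[pos - 1]
            ann = classify_locus("chr1", pos, ref, "A" if ref != "A" else "C",
                                 gene_model, genome)
            assert (ann.category, ann.gene) == (expected, "G1")

    def test_intergenic_reports_flanking_genes(self, genome, gene_model):
        seq = genome["chr1"]
        ann = classify_locus("chr1", 2750, seq[2749], "A" if seq[2749] != "A"
                             else "C", gene_model, genome)
        assert ann.category == "intergenic"
        assert ann.flanking == ("G1", "G2")

    def test_reference_mismatch_raises(self, genome, gene_model):
        seq = genome["chr1"]
        wrong = "C" if seq[2129] != "C" else "G"
        with pytest.raises(ValueError, match="mismatch"):
            classify_locus("chr1", 2130, wrong, "T", gene_model, genome)


@pytest.fixture
def tables(tmp_path):
    write_example_tables(
        tmp_path / "tables",
        variants=[("chr1", 2129, "C", "T"), ("chr1", 2497, "C", "G")],
        genes=["G1"],
    )
    return AnnotationTables.load(tmp_path / "tables")


class TestAttachAnnotations:
    def test_fully_annotated_variant(self, tables):
        locus = LocusAnnotation("missense", "G1", "A10V")
        ann = attach_annotations("chr1", 2129, "C", "T", locus, tables)
        assert ann.rsid == "rs0000001"
        assert ann.max_score == 0.92
        assert ann.has_clinical
        assert ann.haploinsufficient  # percentage 8 lies in [0, 10]
        assert [d["drug"] for d in ann.drugs] == ["demodrug"]
        assert ann.priority == "High"

    def test_absent_keys_yield_empty_annotation(self, tables):
        locus = LocusAnnotation("intron", "G1")
        ann = attach_annotations("chr1", 9999, "A", "T", locus, tables)
        assert ann.rsid is None and ann.scores == {} and ann.drugs == []
        assert ann.priority == "Low"

    def test_haploinsufficiency_boundary(self, tables):
        tables.haploinsufficiency.loc["G1", "percentage"] = 25.0
        locus = LocusAnnotation("missense", "G1")
        ann = attach_annotations("chr1", 2129, "C", "T", locus, tables)
        assert not ann.haploinsufficient

    def test_stringent_vs_flexible_drug_mapping(self, tables):
        # variant 2 has no rsID: stringent finds no drugs, flexible maps by gene
        locus = LocusAnnotation("nonsense", "G1", "Y99*")
        strict = attach_annotations("chr1", 2497, "C", "G", locus, tables,
                                    drug_mode="stringent")
        assert strict.drugs == []
        flexible = attach_annotations("chr1", 2497, "C", "G", locus, tables,
                                      drug_mode="flexible")
        assert [d["drug"] for d in flexible.drugs] == ["demodrug"]

    def test_bad_drug_mode_rejected(self, tables):
        with pytest.raises(ValueError):
            attach_annotations("chr1", 1, "A", "T", LocusAnnotation("intron"),
                               tables, drug_mode="loose")

    def test_malformed_table_raises_at_load(self, tmp_path):
        write_example_tables(tmp_path / "t", variants=[], genes=[])
        bad = pd.read_csv(tmp_path / "t" / "impact.tsv", sep="\t")
        bad.drop(columns=["sift"]).to_csv(tmp_path / "t" / "impact.tsv",
                                          sep="\t", index=False)
        with pytest.raises(ValueError, match="sift"):
            AnnotationTables.load(tmp_path / "t")


def _ann(score=None, clinical=False, drug=False):
    ann = AnnotatedVariant("chr1", 1, "A", "T", LocusAnnotation("missense", "G1"))
    if score is not None:
        ann.scores = {"sift": score}
    if clinical:
        ann.clinical = {"cosmic_id": "COSM1"}
    if drug:
        ann.drugs = [{"drug": "d", "association_type": "t", "confidence_level": "1"}]
    return ann


class TestPrioritize:
    def test_all_three_categories_is_high(self):
        assert prioritize(_ann(0.9, True, True)) == "High"

    def test_single_category_is_medium(self):
        assert prioritize(_ann(0.9)) == "Medium"
        assert prioritize(_ann(clinical=True)) == "Medium"
        assert prioritize(_ann(drug=True)) == "Medium"

    def test_no_annotation_is_low(self):
        assert prioritize(_ann()) == "Low"

    def test_score_threshold_is_strict(self):
        assert prioritize(_ann(0.65)) == "Low"
        assert prioritize(_ann(0.651)) == "Medium"

    def test_monotone_in_annotation_categories(self):
        order = {"Low": 0, "Medium": 1, "High": 2}
        combos = list(itertools.product([None, 0.9], [False, True], [False, True]))
        for (s1, c1, d1) in combos:
            for (s2, c2, d2) in combos:
                if (s1 is None or s2 is not None) and (not c1 or c2) and (
                    not d1 or d2
                ):
                    # combo 2 dominates combo 1
                    assert (
                        order[prioritize(_ann(s2, c2, d2))]
                        >= order[prioritize(_ann(s1, c1, d1))]
                    )

    def test_rejoin_is_deterministic(self, tables):
        locus = LocusAnnotation("missense", "G1", "A10V")
        a = attach_annotations("chr1", 2129, "C", "T", locus, tables)
        b = attach_annotations("chr1", 2129, "C", "T", locus, tables)
        assert a == b


class TestRecurrentGenes:
    def test_fraction_and_retention(self):
        per_sample = {f"s{i}": (["TP53"] if i < 13 else ["KRAS"]) for i in range(24)}
        table = find_recurrent_genes(per_sample, min_fraction=0.15)
        assert table.loc["TP53", "fraction"] == pytest.approx(13 / 24)
        assert table.loc["TP53", "n_samples"] == 13

    def test_min_fraction_one_drops_non_universal(self):
        per_sample = {"a": ["G1", "G2"], "b": ["G1"]}
        table = find_recurrent_genes(per_sample, min_fraction=1.0)
        assert list(table.index) == ["G1"]

    def test_gene_level_incidence_ignores_which_variant(self):
        # same variant vs different variants in a gene: identical incidence
        same = find_recurrent_genes({"a": ["G1"], "b": ["G1"]}, 0.1)
        diff = find_recurrent_genes({"a": ["G1", "G1"], "b": ["G1"]}, 0.1)
        assert same.loc["G1", "n_samples"] == diff.loc["G1", "n_samples"] == 2

    def test_sorted_by_recurrence_then_name(self):
        per_sample = {"a": ["B", "A", "C"], "b": ["B", "A"], "c": ["B"]}
        table = find_recurrent_genes(per_sample, min_fraction=0.0)
        assert list(table.index) == ["B", "A", "C"]


class TestGeneModelIO:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "genes.tsv"
        rows = [
            {
                "name": g.name, "chrom": g.chrom, "strand": g.strand,
                "tx_start": g.tx_start, "tx_end": g.tx_end,
                "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
                "cds": ",".join(f"{s}-{e}" for s, e in g.cds) or ".",
                "biotype": "protein_coding",
            }
            for g in (G1, G2)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        model = load_gene_model_tsv(path)
        assert [g.name for g in model.genes] == ["G1", "G2"]
        assert model.genes[0].exons == G1.exons
        assert model.genes[1].strand == "-"

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            Gene("bad", "chr1", "+", 1, 100, ((1, 50), (40, 90)), ())
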