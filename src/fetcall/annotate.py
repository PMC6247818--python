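"""Gene-locus annotation, table-driven functional annotation, prioritization.

Annotation is a pure local join, with no live database access.  Three
categories of evidence are attached to each called variant:

1. functional-impact scores (SIFT, PolyPhen2, MutationTaster, PhyloP, LRT,
   each in [0, 1], 1 = most deleterious), keyed by (chrom, pos, ref, alt);
2. clinical associations (clinical significance and phenotype, COSMIC and
   OMIM identifiers), plus a per-gene haploinsufficiency percentage
   (haploinsufficient when the percentage lies in [0, 10]);
3. variant/gene-drug associations, joined either by rsID ("stringent"
   mode) or by gene name ("flexible" mode).

Priority is High when all three categories support the variant (some
impact score strictly above 0.65, at least one clinical association, at
least one drug association), Medium when at least one category is
present, Low otherwise.

Table schemas (tab-separated, one header line; all optional fields may be
left empty):

* ``impact.tsv``: chrom, pos, ref, alt, sift, polyphen2, mutation_taster,
  phylop, lrt
* ``known_variants.tsv``: chrom, pos, ref, alt, rsid
* ``clinical.tsv``: chrom, pos, ref, alt, clin_sign, phenotype, cosmic_id,
  omim_id
* ``haploinsufficiency.tsv``: gene, probability, percentage
* ``drugs.tsv``: rsid, gene, drug, association_type, confidence_level
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "GeneModel",
    "AnnotationTables",
    "AnnotatedVariant",
    "classify_locus",
    "attach_annotations",
    "prioritize",
    "find_recurrent_genes",
    "load_gene_model_tsv",
    "write_example_tables",
]

IMPACT_SCORES = ("sift", "polyphen2", "mutation_taster", "phylop", "lrt")
IMPACT_HIGH = 0.65

CODING_CATEGORIES = {"synonymous", "missense", "nonsense", "frameshift", "inframe_indel"}
_SEVERITY = {
    "nonsense": 0, "frameshift": 0, "missense": 0, "inframe_indel": 0,
    "synonymous": 0, "splice_site": 1, "utr5": 2, "utr3": 2, "intron": 3,
    "promoter": 4,
}


@dataclass(frozen=True)
class Gene:
    """One protein-coding gene model; all coordinates 1-based inclusive."""

    name: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.name}")
        for ivs in (self.exons, self.cds):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"gene {self.name}: intervals unsorted/overlap")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def cds_span(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        return self.cds[0][0], self.cds[-1][1]


class GeneModel:
    """A collection of gene models with interval queries.

    ``promoter_window`` (bp upstream of the TSS, strand-aware, default
    2000) and ``splice_window`` (bp of intron flanking each junction,
    default 2) parameterize the non-coding categories.
    """

    def __init__(
        self,
        genes: Sequence[Gene],
        promoter_window: int = 2000,
        splice_window: int = 2,
    ) -> None:
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.tx_start))
        self.promoter_window = promoter_window
        self.splice_window = splice_window
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])


@dataclass
class LocusAnnotation:
    category: str
    gene: Optional[str] = None
    aa_change: Optional[str] = None
    flanking: Optional[tuple[Optional[str], Optional[str]]] = None  # intergenic


def _in_intervals(pos: int, ivs: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in ivs)


def _coding_offset(gene: Gene, pos: int) -> int:
    """0-based offset of ``pos`` within the spliced CDS, in transcription order."""
    off = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            off += pos - s
            break
        off += e - s + 1
    total = sum(e - s + 1 for s, e in gene.cds)
    return off if gene.strand == "+" else total - 1 - off


def _spliced_cds(gene: Gene, seq: str) -> str:
    cds = "".join(seq[s - 1 : e] for s, e in gene.cds)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _classify_in_gene(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: Gene,
    model: GeneModel,
    reference: Optional[Mapping[str, str]],
) -> Optional[LocusAnnotation]:
    """Category of the variant w.r.t. one gene, or None if outside it."""
    is_indel = len(ref) != len(alt)
    # Reference span touched by the variant (the anchor base for SNVs and
    # insertions; anchor plus deleted bases for deletions).
    span = range(pos, pos + max(len(ref) - 1, 0) + 1)

    if any(_in_intervals(p, gene.cds) for p in span):
        if is_indel:
            if abs(len(ref) - len(alt)) % 3 != 0:
                return LocusAnnotation("frameshift", gene.name)
            return LocusAnnotation("inframe_indel", gene.name)
        seq = reference.get(chrom) if reference is not None else None
        if seq is None:
            return LocusAnnotation("missense", gene.name)  # untranslatable
        if seq[pos - 1].upper() != ref.upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: model has "
                f"{seq[pos - 1]!r}, variant says {ref!r}"
            )
        cds_seq = _spliced_cds(gene, seq)
        off = _coding_offset(gene, pos)
        codon_i = off // 3
        codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
        base = alt if gene.strand == "+" else str(Seq(alt).complement())
        mut = codon[: off % 3] + base + codon[off % 3 + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mut).translate())
        change = f"{aa_ref}{codon_i + 1}{aa_alt}"
        if aa_alt == aa_ref:
            return LocusAnnotation("synonymous", gene.name, change)
        if aa_alt == "*":
            return LocusAnnotation("nonsense", gene.name, change)
        return LocusAnnotation("missense", gene.name, change)

    # Splice sites: the first/last splice_window intronic bases of each
    # intron between consecutive exons.
    w = model.splice_window
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        intron = (e1 + 1, s2 - 1)
        for p in span:
            if intron[0] <= p <= intron[1] and (
                p - intron[0] < w or intron[1] - p < w
            ):
                return LocusAnnotation("splice_site", gene.name)

    if _in_intervals(pos, gene.exons):
        cds_span = gene.cds_span
        if cds_span is None:
            return LocusAnnotation("utr5", gene.name)
        before = pos < cds_span[0]
        five_prime = before if gene.strand == "+" else not before
        return LocusAnnotation("utr5" if five_prime else "utr3", gene.name)

    if gene.tx_start <= pos <= gene.tx_end:
        return LocusAnnotation("intron", gene.name)

    if gene.strand == "+":
        pstart, pend = gene.tx_start - model.promoter_window, gene.tx_start - 1
    else:
        pstart, pend = gene.tx_end + 1, gene.tx_end + model.promoter_window
    if pstart <= pos <= pend:
        return LocusAnnotation("promoter", gene.name)
    return None


def classify_locus(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    reference: Optional[Mapping[str, str]] = None,
) -> LocusAnnotation:
    """Gene-locus category of a variant.

    Coding variants are translated with the standard genetic code,
    strand-aware, when a reference sequence is supplied.  Overlapping
    genes are resolved toward the most consequential category.  Variants
    hitting no gene feature are intergenic, reporting the nearest
    preceding and following genes.
    """
    hits = []
    for gene in model.genes_on(chrom):
        ann = _classify_in_gene(chrom, pos, ref, alt, gene, model, reference)
        if ann is not None:
            hits.append(ann)
    if hits:
        return min(hits, key=lambda a: _SEVERITY[a.category])
    preceding = following = None
    for gene in model.genes_on(chrom):
        if gene.tx_end < pos:
            preceding = gene.name
        elif gene.tx_start > pos and following is None:
            following = gene.name
    return LocusAnnotation("intergenic", flanking=(preceding, following))


# ---------------------------------------------------------------------------
# Annotation tables

_SCHEMAS = {
    "impact": ["chrom", "pos", "ref", "alt", *IMPACT_SCORES],
    "known_variants": ["chrom", "pos", "ref", "alt", "rsid"],
    "clinical": ["chrom", "pos", "ref", "alt", "clin_sign", "phenotype",
                 "cosmic_id", "omim_id"],
    "haploinsufficiency": ["gene", "probability", "percentage"],
    "drugs": ["rsid", "gene", "drug", "association_type", "confidence_level"],
}
_FILENAMES = {k: f"{k}.tsv" for k in _SCHEMAS}


class AnnotationTables:
    """Local lookup tables standing in for the public annotation databases."""

    def __init__(
        self,
        impact: pd.DataFrame,
        known_variants: pd.DataFrame,
        clinical: pd.DataFrame,
        haploinsufficiency: pd.DataFrame,
        drugs: pd.DataFrame,
    ) -> None:
        frames = {
            "impact": impact,
            "known_variants": known_variants,
            "clinical": clinical,
            "haploinsufficiency": haploinsufficiency,
            "drugs": drugs,
        }
        for name, df in frames.items():
            missing = set(_SCHEMAS[name]) - set(df.columns)
            if missing:
                raise ValueError(f"table {name!r} missing columns {sorted(missing)}")
        bad = impact[list(IMPACT_SCORES)].apply(pd.to_numeric, errors="coerce")
        if ((bad < 0) | (bad > 1)).any().any():
            raise ValueError("impact scores must lie in [0, 1]")
        self.impact = impact.set_index(["chrom", "pos", "ref", "alt"])
        self.known_variants = known_variants.set_index(
            ["chrom", "pos", "ref", "alt"]
        )["rsid"]
        self.clinical = clinical.set_index(["chrom", "pos", "ref", "alt"])
        self.haploinsufficiency = haploinsufficiency.set_index("gene")
        self.drugs = drugs
        for name, df in (
            ("impact", self.impact),
            ("known_variants", self.known_variants),
            ("clinical", self.clinical),
            ("haploinsufficiency", self.haploinsufficiency),
        ):
            if df.index.has_duplicates:
                raise ValueError(f"table {name!r} has duplicate keys")

    @classmethod
    def load(cls, directory) -> "AnnotationTables":
        directory = Path(directory)
        frames = {}
        for name, fname in _FILENAMES.items():
            path = directory / fname
            if not path.exists():
                raise FileNotFoundError(f"annotation table missing: {path}")
            frames[name] = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(**frames)


@dataclass
class AnnotatedVariant:
    """A call joined with its locus category and the three annotation levels."""

    chrom: str
    pos: int
    ref: str
    alt: str
    locus: LocusAnnotation
    rsid: Optional[str] = None
    scores: dict[str, float] = field(default_factory=dict)
    clinical: dict[str, str] = field(default_factory=dict)
    haploinsufficient: bool = False
    drugs: list[dict[str, str]] = field(default_factory=list)
    priority: Optional[str] = None

    @property
    def max_score(self) -> Optional[float]:
        return max(self.scores.values()) if self.scores else None

    @property
    def has_clinical(self) -> bool:
        """At least one clinical association (significance, COSMIC or OMIM)."""
        return any(
            self.clinical.get(k) not in (None, "")
            for k in ("clin_sign", "cosmic_id", "omim_id")
        )


def attach_annotations(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    locus: LocusAnnotation,
    tables: AnnotationTables,
    drug_mode: str = "stringent",
) -> AnnotatedVariant:
    """Join one variant against all tables; absent keys leave fields empty.

    ``drug_mode="stringent"`` joins drug records by rsID; ``"flexible"``
    joins by the gene carrying the variant.
    """
    if drug_mode not in ("stringent", "flexible"):
        raise ValueError(f"drug_mode must be stringent or flexible, got {drug_mode!r}")
    key = (chrom, pos, ref, alt)
    ann = AnnotatedVariant(chrom, pos, ref, alt, locus)

    if key in tables.impact.index:
        row = tables.impact.loc[key]
        ann.scores = {
            k: float(row[k]) for k in IMPACT_SCORES if pd.notna(row[k])
        }
    if key in tables.known_variants.index:
        ann.rsid = str(tables.known_variants.loc[key])
    if key in tables.clinical.index:
        row = tables.clinical.loc[key]
        ann.clinical = {
            k: str(row[k])
            for k in ("clin_sign", "phenotype", "cosmic_id", "omim_id")
            if pd.notna(row[k]) and str(row[k]) != ""
        }
    if locus.gene is not None and locus.gene in tables.haploinsufficiency.index:
        pct = float(tables.haploinsufficiency.loc[locus.gene, "percentage"])
        ann.haploinsufficient = 0.0 <= pct <= 10.0

    if drug_mode == "stringent":
        hits = (
            tables.drugs[tables.drugs["rsid"] == ann.rsid]
            if ann.rsid is not None
            else tables.drugs.iloc[0:0]
        )
    else:
        hits = (
            tables.drugs[tables.drugs["gene"] == locus.gene]
            if locus.gene is not None
            else tables.drugs.iloc[0:0]
        )
    ann.drugs = hits[["drug", "association_type", "confidence_level"]].to_dict(
        "records"
    )
    ann.priority = prioritize(ann)
    return ann


def prioritize(ann: AnnotatedVariant) -> str:
    """High/Medium/Low priority from the three annotation categories.

    High needs all three: an impact score strictly above 0.65 from any of
    the five resources, a clinical association, and a drug association.
    Medium needs at least one of the three.  Low otherwise.
    """
    impact = ann.max_score is not None and ann.max_score > IMPACT_HIGH
    clinical = ann.has_clinical
    drug = bool(ann.drugs)
    if impact and clinical and drug:
        return "High"
    if impact or clinical or drug:
        return "Medium"
    return "Low"


def find_recurrent_genes(
    genes_per_sample: Mapping[str, Sequence[str]], min_fraction: float = 0.15
) -> pd.DataFrame:
    """Gene-by-sample mutation incidence for recurrently mutated genes.

    A gene counts once per sample regardless of how many (or which)
    variants hit it.  Genes mutated in at least ``min_fraction`` of the
    samples are retained, sorted by recurrence descending then name.
    """
    samples = list(genes_per_sample)
    if not samples:
        raise ValueError("need at least one sample")
    all_genes = sorted({g for gs in genes_per_sample.values() for g in gs})
    table = pd.DataFrame(
        {s: [g in set(genes_per_sample[s]) for g in all_genes] for s in samples},
        index=pd.Index(all_genes, name="gene"),
    )
    table["n_samples"] = table[samples].sum(axis=1)
    table["fraction"] = table["n_samples"] / len(samples)
    table = table[table["fraction"] >= min_fraction]
    return table.sort_values(
        ["fraction", "gene"], ascending=[False, True], kind="stable"
    )


# ---------------------------------------------------------------------------
# Gene-model and table I/O helpers

def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text == ".":
        return ()
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def load_gene_model_tsv(path, **kwargs) -> GeneModel:
    """Load a gene model from the 8-column TSV dialect.

    Columns: name, chrom, strand, tx_start, tx_end, exons, cds, biotype.
    ``exons`` and ``cds`` are comma-separated ``start-end`` intervals
    (1-based inclusive); ``cds`` may be ``.`` for non-coding genes.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str},
    )
    required = ["name", "chrom", "strand", "tx_start", "tx_end", "exons", "cds",
                "biotype"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"gene model TSV missing columns {sorted(missing)}")
    genes = [
        Gene(
            name=row["name"],
            chrom=row["chrom"],
            strand=row["strand"],
            tx_start=int(row["tx_start"]),
            tx_end=int(row["tx_end"]),
            exons=_parse_intervals(str(row["exons"])),
            cds=_parse_intervals(str(row["cds"])),
        )
        for _, row in df.iterrows()
    ]
    return GeneModel(genes, **kwargs)


def write_example_tables(directory, variants: Sequence[tuple[str, int, str, str]],
                         genes: Sequence[str]) -> None:
    """Write a synthetic, schema-valid set of annotation tables.

    A deterministic desk-scale stand-in for the public databases: the
    first variant gets the full three-category annotation, the second (if
    any) gets scores only, the rest are left unannotated.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = {name: [] for name in _SCHEMAS}
    if variants:
        c, p, r, a = variants[0]
        rows["impact"].append([c, p, r, a, 0.92, 0.88, 0.7, 0.81, 0.9])
        rows["known_variants"].append([c, p, r, a, "rs0000001"])
        rows["clinical"].append([c, p, r, a, "Pathogenic", "demo phenotype",
                                 "COSM0001", "100001"])
        rows["drugs"].append(["rs0000001", genes[0] if genes else "GENE1",
                              "demodrug", "efficacy", "1A"])
    if len(variants) > 1:
        c, p, r, a = variants[1]
        rows["impact"].append([c, p, r, a, 0.70, 0.2, 0.3, 0.1, 0.5])
    for g in genes:
        rows["haploinsufficiency"].append([g, 0.5, 8.0])
    for name, cols in _SCHEMAS.items():
        pd.DataFrame(rows[name], columns=cols).to_csv(
            directory / _FILENAMES[name], sep="\t", index=False
        )
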