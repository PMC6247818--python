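"""Per-site variant calling for the three data types.

*Germline* mode handles one sample: filters, the variant p-value (VPV)
against the sequencing-error null, and a HOM/HET zygosity call.

*Somatic* mode handles a tumor-normal pair: both samples are genotyped
independently with the germline logic; when the genotypes disagree, a
one-tailed Fisher exact test on the tumor-vs-normal allele counts (the
somatic p-value, SPV) separates Somatic, LOH and Unknown calls from
Germline ones, and every call gets a High/Low confidence grade.

*Population* mode runs the germline logic per sample across N samples,
reports up to two alternate alleles with 0/1-style genotype codes, and
computes the cohort minor allele frequency (MAF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from . import core
from .core import HET, HOM, HOMREF, AlleleTally, CallerConfig, FisherTable
from .pileup import REF, PileupSite, ReadObservation

__all__ = [
    "SampleEvidence",
    "VariantCall",
    "PopulationCall",
    "call_germline_site",
    "call_germline",
    "genotype_sample",
    "somatic_pvalue",
    "classify_paired_site",
    "call_somatic",
    "assign_confidence",
    "call_population_site",
    "call_population",
    "compute_maf",
    "classify_maf",
    "pair_streams",
]

GERMLINE = "Germline"
SOMATIC = "Somatic"
LOH = "LOH"
UNKNOWN = "Unknown"

HIGH = "High"
LOW = "Low"


def left_anchor(ref_base: str, allele: str) -> tuple[str, str]:
    """VCF left-anchored REF/ALT for an mpileup allele at its anchor base.

    SNVs map directly; an insertion ``+SEQ`` becomes REF=anchor,
    ALT=anchor+SEQ; a deletion ``-SEQ`` becomes REF=anchor+SEQ, ALT=anchor.
    """
    if allele.startswith("+"):
        return ref_base, ref_base + allele[1:]
    if allele.startswith("-"):
        return ref_base + allele[1:], ref_base
    return ref_base, allele


@dataclass
class SampleEvidence:
    """One sample's evidence for the reported allele at a called site."""

    genotype: str
    depth: int
    alt_count: int

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class VariantCall:
    """A called variant in VCF coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    vaf: float
    depth: int
    alt_count: int
    gq: float
    variant_p: Optional[float] = None
    somatic_p: Optional[float] = None
    status: Optional[str] = None
    confidence: Optional[str] = None
    tumor: Optional[SampleEvidence] = None
    normal: Optional[SampleEvidence] = None


@dataclass
class _SampleCall:
    """Internal result of genotyping one sample at one site."""

    genotype: str
    tally: AlleleTally
    allele: Optional[str] = None  # top-ranked candidate, if any
    log_p: Optional[float] = None

    def counts_for(self, allele: Optional[str]) -> tuple[int, int]:
        """(ref-side, variant-side) high-quality counts for ``allele``."""
        var = self.tally.count(allele) if allele else 0
        return self.tally.hq_depth - var, var


def _genotype_tally(tally: AlleleTally, cfg: CallerConfig) -> _SampleCall:
    if not core.passes_coverage(tally, cfg):
        return _SampleCall(HOMREF, tally)
    candidates = core.candidate_alleles(tally, cfg)
    if not candidates:
        return _SampleCall(HOMREF, tally)
    allele = candidates[0]
    rec = tally.alleles[allele]
    if core.strand_bias_discard(rec.fwd_count, rec.rev_count, cfg):
        return _SampleCall(HOMREF, tally)
    log_p = core.log_variant_pvalue(tally.hq_depth - rec.count, rec.count, cfg)
    if log_p > math.log(cfg.p_germline):
        return _SampleCall(HOMREF, tally)
    vaf = rec.count / tally.hq_depth
    return _SampleCall(core.zygosity(vaf, cfg), tally, allele, log_p)


def genotype_sample(
    observations: Sequence[ReadObservation] | AlleleTally, cfg: CallerConfig
) -> str:
    """HOMREF/HET/HOM genotype for one sample's site evidence.

    A sample failing any filter (coverage, allele support/VAF, strand
    bias, significance) is homozygous-reference.
    """
    tally = (
        observations
        if isinstance(observations, AlleleTally)
        else core.tally_alleles(observations, cfg)
    )
    return _genotype_tally(tally, cfg).genotype


def call_germline_site(site: PileupSite, cfg: CallerConfig) -> Optional[VariantCall]:
    """Single-sample calling pipeline; ``None`` when any stage fails."""
    if len(site.samples) != 1:
        raise ValueError(f"germline mode expects 1 sample, got {len(site.samples)}")
    tally = core.tally_alleles(site.samples[0], cfg)
    sc = _genotype_tally(tally, cfg)
    if sc.genotype == HOMREF:
        return None
    ref, alt = left_anchor(site.ref_base, sc.allele)
    count = tally.count(sc.allele)
    return VariantCall(
        chrom=site.chrom,
        pos=site.pos,
        ref=ref,
        alt=alt,
        genotype=sc.genotype,
        vaf=count / tally.hq_depth,
        depth=tally.hq_depth,
        alt_count=count,
        gq=core.genotype_quality_from_log(sc.log_p, cfg),
        variant_p=math.exp(sc.log_p),
    )


def call_germline(
    sites: Iterable[PileupSite], cfg: CallerConfig
) -> Iterator[VariantCall]:
    for site in sites:
        call = call_germline_site(site, cfg)
        if call is not None:
            yield call


def somatic_pvalue(
    tum_ref: int, tum_var: int, nor_ref: int, nor_var: int
) -> float:
    """One-tailed FET p for variant-allele enrichment in the tumor.

    The table is oriented so the tail sweep moves reference reads out of
    the tumor row (and variant reads out of the normal row): small p means
    the variant allele is over-represented in the tumor relative to the
    normal.
    """
    return math.exp(log_somatic_pvalue(tum_ref, tum_var, nor_ref, nor_var))


def log_somatic_pvalue(
    tum_ref: int, tum_var: int, nor_ref: int, nor_var: int
) -> float:
    if tum_ref + tum_var + nor_ref + nor_var == 0:
        raise ValueError("somatic p-value undefined on an all-zero table")
    return core.log_one_tailed_fet(
        FisherTable(a=tum_var, b=tum_ref, c=nor_var, d=nor_ref)
    )


def assign_confidence(
    status: str,
    tumor_vaf: float,
    normal_vaf: float,
    somatic_p: Optional[float],
    cfg: CallerConfig,
) -> str:
    """High/Low confidence grade for a paired-mode call."""
    if status == SOMATIC:
        if (
            tumor_vaf >= cfg.conf_vaf_tumor
            and normal_vaf < cfg.conf_vaf_normal
            and somatic_p is not None
            and somatic_p < cfg.conf_p
        ):
            return HIGH
    elif status == LOH:
        if (
            normal_vaf >= cfg.conf_vaf_tumor
            and somatic_p is not None
            and somatic_p < cfg.conf_p
        ):
            return HIGH
    elif status == GERMLINE:
        if tumor_vaf >= cfg.conf_vaf_tumor and normal_vaf >= cfg.conf_vaf_tumor:
            return HIGH
    return LOW


def classify_paired_site(
    site: PileupSite, cfg: CallerConfig, tumor_index: int = 0
) -> Optional[VariantCall]:
    """Somatic-mode classification of one tumor-normal site.

    Both samples are genotyped independently.  Matching genotypes (or a
    non-significant tumor-normal contrast) give a Germline call whose VPV
    pools the read counts of both samples; a significant contrast gives
    Somatic (normal homozygous-reference), LOH (normal heterozygous) or
    Unknown.  A variant homozygous in the normal but absent or
    heterozygous in the tumor is Unknown regardless of the contrast.
    """
    if len(site.samples) != 2:
        raise ValueError(f"somatic mode expects 2 samples, got {len(site.samples)}")
    t_obs = site.samples[tumor_index]
    n_obs = site.samples[1 - tumor_index]
    tum = _genotype_tally(core.tally_alleles(t_obs, cfg), cfg)
    nor = _genotype_tally(core.tally_alleles(n_obs, cfg), cfg)
    if tum.genotype == HOMREF and nor.genotype == HOMREF:
        return None

    allele = tum.allele if tum.allele is not None else nor.allele
    genotypes_match = tum.genotype == nor.genotype and (
        tum.genotype == HOMREF or tum.allele == nor.allele
    )
    t_ref, t_var = tum.counts_for(allele)
    n_ref, n_var = nor.counts_for(allele)

    status: str
    log_spv: Optional[float] = None
    if not genotypes_match:
        log_spv = log_somatic_pvalue(t_ref, t_var, n_ref, n_var)
        if nor.genotype == HOM and tum.genotype in (HOMREF, HET):
            status = UNKNOWN
        elif log_spv <= math.log(cfg.p_somatic):
            if nor.genotype == HOMREF:
                status = SOMATIC
            elif nor.genotype == HET:
                status = LOH
            else:
                status = UNKNOWN
        else:
            status = GERMLINE
    else:
        status = GERMLINE

    pooled_depth = tum.tally.hq_depth + nor.tally.hq_depth
    pooled_var = t_var + n_var
    log_vpv = (
        core.log_variant_pvalue(pooled_depth - pooled_var, pooled_var, cfg)
        if pooled_depth >= 1
        else 0.0
    )
    if status == GERMLINE:
        log_for_gq = log_vpv
    else:
        log_for_gq = log_spv if log_spv is not None else log_vpv

    t_ev = SampleEvidence(tum.genotype, tum.tally.hq_depth, t_var)
    n_ev = SampleEvidence(nor.genotype, nor.tally.hq_depth, n_var)
    genotype = tum.genotype if tum.genotype != HOMREF else nor.genotype
    spv = math.exp(log_spv) if log_spv is not None else None
    ref, alt = left_anchor(site.ref_base, allele)
    call = VariantCall(
        chrom=site.chrom,
        pos=site.pos,
        ref=ref,
        alt=alt,
        genotype=genotype,
        vaf=t_ev.vaf,
        depth=pooled_depth,
        alt_count=pooled_var,
        gq=core.genotype_quality_from_log(log_for_gq, cfg),
        variant_p=math.exp(log_vpv),
        somatic_p=spv,
        status=status,
        tumor=t_ev,
        normal=n_ev,
    )
    call.confidence = assign_confidence(status, t_ev.vaf, n_ev.vaf, spv, cfg)
    return call


def call_somatic(
    sites: Iterable[PileupSite], cfg: CallerConfig, tumor_index: int = 0
) -> Iterator[VariantCall]:
    for site in sites:
        call = classify_paired_site(site, cfg, tumor_index=tumor_index)
        if call is not None:
            yield call


def pair_streams(
    tumor: Iterable[PileupSite], normal: Iterable[PileupSite]
) -> Iterator[PileupSite]:
    """Merge two single-sample streams into two-sample sites.

    Streams must be position-matched line by line; a coordinate mismatch
    raises.
    """
    t_it, n_it = iter(tumor), iter(normal)
    for t, n in zip(t_it, n_it, strict=True):
        if (t.chrom, t.pos) != (n.chrom, n.pos):
            raise ValueError(
                f"pairing error: tumor at {t.chrom}:{t.pos}, "
                f"normal at {n.chrom}:{n.pos}"
            )
        if t.ref_base != n.ref_base:
            raise ValueError(f"reference base mismatch at {t.chrom}:{t.pos}")
        yield PileupSite(t.chrom, t.pos, t.ref_base, [t.samples[0], n.samples[0]])


@dataclass
class PopulationCall:
    """A multi-sample genotyped site with up to two alternate alleles."""

    chrom: str
    pos: int
    ref: str
    alts: list[str]  # VCF-form ALT alleles, index 1 and 2 in genotype codes
    genotypes: list[str]  # one 0/0-style code per sample
    depths: list[int]
    alt_counts: list[int]
    maf: Optional[float] = None  # percentage, None = NA

    @property
    def maf_classification(self) -> str:
        return classify_maf(self.maf / 100.0 if self.maf is not None else None)


def call_population_site(
    site: PileupSite, cfg: CallerConfig
) -> Optional[PopulationCall]:
    """Run germline logic per sample; report up to two alternate alleles.

    Alleles are ranked by total supporting reads across samples (ties by
    allele string); a sample whose variant allele is not among the two
    reported is coded 0/0, as is any sample failing the filters.
    """
    per_sample = [
        _genotype_tally(core.tally_alleles(obs, cfg), cfg) for obs in site.samples
    ]
    support: dict[str, int] = {}
    for sc in per_sample:
        if sc.allele is not None:
            support[sc.allele] = support.get(sc.allele, 0) + sc.tally.count(sc.allele)
    if not support:
        return None
    ranked = sorted(support, key=lambda a: (-support[a], a))[:2]
    index = {allele: i + 1 for i, allele in enumerate(ranked)}

    genotypes: list[str] = []
    depths: list[int] = []
    alt_counts: list[int] = []
    for sc in per_sample:
        depths.append(sc.tally.hq_depth)
        i = index.get(sc.allele) if sc.allele is not None else None
        if sc.genotype == HOMREF or i is None:
            genotypes.append("0/0")
            alt_counts.append(0)
        elif sc.genotype == HET:
            genotypes.append(f"0/{i}")
            alt_counts.append(sc.tally.count(sc.allele))
        else:
            genotypes.append(f"{i}/{i}")
            alt_counts.append(sc.tally.count(sc.allele))

    # Anchor all reported alleles at the site's reference base.  With a
    # mix of SNV and indel alleles the REF must be the longest deletion's
    # span; only same-anchor alleles are combined here, so pick REF from
    # the first allele and re-express the second against it.
    refs_alts = [left_anchor(site.ref_base, a) for a in ranked]
    ref = max((r for r, _ in refs_alts), key=len)
    alts = [alt + ref[len(r):] for r, alt in refs_alts]

    call = PopulationCall(
        chrom=site.chrom,
        pos=site.pos,
        ref=ref,
        alts=alts,
        genotypes=genotypes,
        depths=depths,
        alt_counts=alt_counts,
    )
    call.maf = compute_maf(call)
    return call


def call_population(
    sites: Iterable[PileupSite], cfg: CallerConfig
) -> Iterator[PopulationCall]:
    for site in sites:
        call = call_population_site(site, cfg)
        if call is not None:
            yield call


def compute_maf(pop_call: PopulationCall) -> Optional[float]:
    """Cohort minor allele frequency as a percentage, or ``None`` (NA).

    Each sample contributes two allele copies read off its genotype code.
    The MAF is the frequency of the second most common allele; at an exact
    tie the reference ranks first, so the alternate allele is reported as
    the minor one.  Monomorphic sites have no minor allele.
    """
    n_alleles = len(pop_call.alts) + 1
    copies = [0] * n_alleles
    for code in pop_call.genotypes:
        for tok in code.split("/"):
            copies[int(tok)] += 1
    total = sum(copies)
    if total == 0:
        return None
    # Stable sort: descending count, reference (index 0) winning ties.
    order = sorted(range(n_alleles), key=lambda i: (-copies[i], i))
    if copies[order[1]] == 0:
        return None
    return 100.0 * copies[order[1]] / total


def classify_maf(maf: Optional[float]) -> str:
    """rare (< 0.01) / common (>= 0.01) / NA, for a MAF given as a fraction."""
    if maf is None:
        return "NA"
    return "rare" if maf < 0.01 else "common"
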