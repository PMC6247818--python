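"""Site-level statistics shared by all calling modes.

The caller is heuristic/statistical in the VarScan lineage: hard filters on
depth, base quality, variant allele frequency (VAF) and strandedness, then a
one-tailed Fisher exact test (FET) against a sequencing-error-only null.

For a 2x2 contingency table with cells ``a, b, c, d`` (rows ``a+b`` and
``c+d``, columns ``a+c`` and ``b+d``) the hypergeometric probability of the
table at fixed margins is::

    P = C(a+b, a) * C(c+d, c) / C(N, a+c)

and the one-tailed p-value implemented here is the sum of ``P`` over the
observed table and every table reached by decrementing ``b`` and ``c`` while
incrementing ``a`` and ``d`` (margins fixed), down to ``b = 0`` or
``c = 0``.  Callers orient the table so that this sweep runs toward the
alternative of interest (more variant reads than error predicts; variant
enrichment in tumor).  The sum is evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .pileup import REF, ReadObservation

__all__ = [
    "CallerConfig",
    "AlleleCount",
    "AlleleTally",
    "FisherTable",
    "tally_alleles",
    "passes_coverage",
    "candidate_alleles",
    "strand_bias_discard",
    "one_tailed_fet",
    "log_one_tailed_fet",
    "variant_pvalue",
    "log_variant_pvalue",
    "genotype_quality",
    "zygosity",
]

HOM = "HOM"
HET = "HET"
HOMREF = "HOMREF"


@dataclass(frozen=True)
class CallerConfig:
    """All tunable thresholds of the caller, with their defaults.

    qbase:
        Minimum Phred base quality for a read to count at a site.
    rd_th:
        Minimum high-quality depth for a site to be considered.
    var_th:
        Minimum number of reads supporting a variant allele.
    vaf_th:
        Minimum variant allele frequency (fraction of high-quality reads).
    vaf_homo:
        VAF strictly above this calls the genotype homozygous.
    p_germline:
        FET p-value cutoff for calling a variant against the error null.
    p_somatic:
        FET p-value cutoff for somatic/LOH classification in paired mode.
    strand_bias_on / strand_frac:
        Discard a variant whose strand support is >= ``strand_frac`` (or
        <= 1 - ``strand_frac``) on one strand.
    err_rate:
        Assumed per-base sequencing error rate of the null model.
    conf_vaf_tumor / conf_vaf_normal / conf_p:
        High-confidence bounds for paired-mode calls (tumor VAF >= 0.10,
        normal VAF < 0.05, somatic p < 0.07).
    gq_cap:
        Maximum reported genotype quality.
    """

    qbase: int = 15
    rd_th: int = 10
    var_th: int = 2
    vaf_th: float = 0.20
    vaf_homo: float = 0.75
    p_germline: float = 0.01
    p_somatic: float = 0.05
    strand_bias_on: bool = True
    strand_frac: float = 0.90
    err_rate: float = 0.001
    conf_vaf_tumor: float = 0.10
    conf_vaf_normal: float = 0.05
    conf_p: float = 0.07
    gq_cap: float = 255.0

    def __post_init__(self) -> None:
        if not (0 < self.vaf_th <= self.vaf_homo <= 1):
            raise ValueError("need 0 < vaf_th <= vaf_homo <= 1")
        if not (0 < self.err_rate < 1):
            raise ValueError("err_rate must be in (0, 1)")
        for name in ("p_germline", "p_somatic", "conf_p"):
            p = getattr(self, name)
            if not (0 < p <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0.5 < self.strand_frac <= 1):
            raise ValueError("strand_frac must be in (0.5, 1]")

    def with_(self, **kwargs) -> "CallerConfig":
        return replace(self, **kwargs)


@dataclass
class AlleleCount:
    """High-quality read support for one allele at one site in one sample."""

    allele: str
    count: int = 0
    fwd_count: int = 0
    rev_count: int = 0
    phred_sum: int = 0

    @property
    def mean_phred(self) -> float:
        return self.phred_sum / self.count if self.count else 0.0


@dataclass
class AlleleTally:
    """Per-allele high-quality counts for one sample at one site."""

    hq_depth: int = 0
    alleles: dict[str, AlleleCount] = field(default_factory=dict)

    def count(self, allele: str) -> int:
        rec = self.alleles.get(allele)
        return rec.count if rec else 0

    @property
    def ref_count(self) -> int:
        return self.count(REF)


def tally_alleles(
    observations: Sequence[ReadObservation], cfg: CallerConfig
) -> AlleleTally:
    """Count allele support among reads with phred >= ``cfg.qbase``.

    Low-quality observations are excluded entirely (they contribute to
    neither the high-quality depth nor any allele).  Placeholder
    observations (``*``, reference skips) count toward the depth but are
    never alleles.
    """
    tally = AlleleTally()
    for o in observations:
        if o.phred < cfg.qbase:
            continue
        tally.hq_depth += 1
        if not o.is_allele:
            continue
        rec = tally.alleles.get(o.allele)
        if rec is None:
            rec = tally.alleles[o.allele] = AlleleCount(o.allele)
        rec.count += 1
        if o.forward:
            rec.fwd_count += 1
        else:
            rec.rev_count += 1
        rec.phred_sum += o.phred
    return tally


def passes_coverage(tally: AlleleTally, cfg: CallerConfig) -> bool:
    """High-quality depth meets the minimum coverage threshold."""
    return tally.hq_depth >= cfg.rd_th


def candidate_alleles(tally: AlleleTally, cfg: CallerConfig) -> list[str]:
    """Non-reference alleles passing the support and VAF filters.

    Ordered by count descending, then mean base quality descending, then
    allele string (a final deterministic tie-break).
    """
    if tally.hq_depth == 0:
        return []
    out = [
        rec
        for allele, rec in tally.alleles.items()
        if allele != REF
        and rec.count >= cfg.var_th
        and rec.count / tally.hq_depth >= cfg.vaf_th
    ]
    out.sort(key=lambda r: (-r.count, -r.mean_phred, r.allele))
    return [r.allele for r in out]


def strand_bias_discard(fwd: int, rev: int, cfg: CallerConfig) -> bool:
    """Whether to discard a variant for one-strand-dominated support.

    Discards when the forward fraction is >= ``strand_frac`` or
    <= ``1 - strand_frac``; skipped entirely when the filter is off.
    """
    if not cfg.strand_bias_on:
        return False
    total = fwd + rev
    if total == 0:
        raise ValueError("strand bias undefined with no supporting reads")
    # cross-multiplied with a small slack so 1/10 vs 0.10 compares exactly
    return (
        fwd >= cfg.strand_frac * total - 1e-9
        or fwd <= (1.0 - cfg.strand_frac) * total + 1e-9
    )


@dataclass(frozen=True)
class FisherTable:
    """A 2x2 contingency table with non-negative integer cells."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_hypergeom_terms(table: FisherTable) -> np.ndarray:
    """Log-probabilities of the observed table and all more-extreme tables.

    Term ``k`` is the table ``(a+k, b-k, c-k, d+k)``, ``k = 0 ..
    min(b, c)``; margins are fixed.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    k = np.arange(min(b, c) + 1)
    ak, bk, ck, dk = a + k, b - k, c - k, d + k
    r1, r2, n, c1 = a + b, c + d, table.n, np.asarray(ak + ck)
    # log C(r1, ak) + log C(r2, ck) - log C(n, ak+ck), via log-gamma
    def lc(n_, k_):
        n_ = np.asarray(n_, dtype=float)
        k_ = np.asarray(k_, dtype=float)
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return lc(r1, ak) + lc(r2, ck) - lc(n, c1)


def log_one_tailed_fet(table: FisherTable) -> float:
    """Natural log of the one-tailed FET p-value (see module docstring)."""
    if table.n == 0:
        return 0.0
    val = float(logsumexp(_log_hypergeom_terms(table)))
    return min(val, 0.0)  # guard tiny positive rounding


def one_tailed_fet(table: FisherTable) -> float:
    """One-tailed Fisher exact p-value, in (0, 1]."""
    return math.exp(log_one_tailed_fet(table))


def _error_null_table(n_obs_ref: int, n_obs_var: int, cfg: CallerConfig) -> FisherTable:
    n_obs = n_obs_ref + n_obs_var
    exp_var = math.floor(n_obs * cfg.err_rate)
    return FisherTable(a=n_obs_var, b=exp_var, c=n_obs_ref, d=n_obs - exp_var)


def log_variant_pvalue(n_obs_ref: int, n_obs_var: int, cfg: CallerConfig) -> float:
    """Log variant p-value (VPV) against the sequencing-error-only null.

    The observed counts are compared with the expected split at the site's
    depth under the error rate: expected variant reads
    ``floor(depth * err_rate)``, the rest reference.
    """
    if n_obs_ref + n_obs_var < 1:
        raise ValueError("variant p-value undefined at zero depth")
    return log_one_tailed_fet(_error_null_table(n_obs_ref, n_obs_var, cfg))


def variant_pvalue(n_obs_ref: int, n_obs_var: int, cfg: CallerConfig) -> float:
    return math.exp(log_variant_pvalue(n_obs_ref, n_obs_var, cfg))


def genotype_quality(p: float, cfg: CallerConfig) -> float:
    """Phred-scaled call quality, ``-10 * log10(p)``, capped at ``gq_cap``."""
    if not (0 < p <= 1):
        raise ValueError("p-value must be in (0, 1]")
    return min(-10.0 * math.log10(p), cfg.gq_cap)


def genotype_quality_from_log(log_p: float, cfg: CallerConfig) -> float:
    """As :func:`genotype_quality` but from a natural-log p (underflow-safe)."""
    if log_p > 0:
        raise ValueError("log p-value must be <= 0")
    return min(-10.0 * log_p / math.log(10.0), cfg.gq_cap)


def zygosity(vaf: float, cfg: CallerConfig) -> str:
    """HOM when the VAF is strictly above ``vaf_homo``, else HET."""
    if not (0 <= vaf <= 1):
        raise ValueError("VAF must be in [0, 1]")
    return HOM if vaf > cfg.vaf_homo else HET
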