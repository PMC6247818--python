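"""VCF v4.1 serialization of calls, and status-based splitting.

Column mapping follows the VarScan lineage: QUAL carries the genotype
quality, per-sample FREQ is a percentage string, AD is the count of reads
supporting the reported alternate allele.  Site-level statistics go to
INFO: VPV (variant p-value against the error null), SPV (tumor-vs-normal
somatic p-value), STATUS (Somatic/Germline/LOH/Unknown), CONF (High/Low),
MAF (population minor allele frequency, percent, or NA).  FILTER is PASS
for every emitted record: filters discard, they never flag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence

from . import __version__
from .core import HET, HOM, HOMREF, CallerConfig
from .modes import PopulationCall, VariantCall

__all__ = ["write_vcf", "split_vcf", "STATUSES"]

STATUSES = ("Somatic", "Germline", "LOH", "Unknown")

_INFO_DEFS = [
    ('VPV', 1, 'Float', 'Variant p-value (one-tailed Fisher exact test vs sequencing-error null)'),
    ('SPV', 1, 'Float', 'Somatic p-value (one-tailed Fisher exact test, tumor vs normal)'),
    ('STATUS', 1, 'String', 'Paired-mode classification: Somatic, Germline, LOH or Unknown'),
    ('CONF', 1, 'String', 'Call confidence: High or Low'),
    ('MAF', 1, 'String', 'Minor allele frequency in the cohort, percent, or NA'),
]
_FORMAT_DEFS = [
    ('GT', 1, 'String', 'Genotype'),
    ('GQ', 1, 'Float', 'Genotype quality, -10*log10(p-value)'),
    ('DP', 1, 'Integer', 'High-quality read depth'),
    ('AD', 1, 'Integer', 'Reads supporting the reported alternate allele'),
    ('FREQ', 1, 'String', 'Variant allele frequency, percent'),
]


def _header(sample_names: Sequence[str], cfg: Optional[CallerConfig]) -> list[str]:
    lines = [
        "##fileformat=VCFv4.1",
        f"##source=fetcall-{__version__}",
    ]
    if cfg is not None:
        params = ",".join(
            f"{f.name}={getattr(cfg, f.name)}" for f in dataclasses.fields(cfg)
        )
        lines.append(f"##fetcall_params={params}")
    for key, num, typ, desc in _INFO_DEFS:
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    for key, num, typ, desc in _FORMAT_DEFS:
        lines.append(
            f'##FORMAT=<ID={key},Number={num},Type={typ},Description="{desc}">'
        )
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols.extend(sample_names)
    lines.append("\t".join(cols))
    return lines


def _gt_code(genotype: str) -> str:
    return {HOMREF: "0/0", HET: "0/1", HOM: "1/1"}[genotype]


def _fmt_p(p: Optional[float]) -> str:
    return f"{p:.4g}" if p is not None else "."


def _freq(vaf: float) -> str:
    return f"{100.0 * vaf:.2f}%"


def _sample_field(
    genotype: str, gq: float, depth: int, alt_count: int
) -> str:
    vaf = alt_count / depth if depth else 0.0
    return f"{_gt_code(genotype)}:{gq:.1f}:{depth}:{alt_count}:{_freq(vaf)}"


def _variant_record(call: VariantCall) -> str:
    info = [f"VPV={_fmt_p(call.variant_p)}"]
    if call.somatic_p is not None:
        info.append(f"SPV={_fmt_p(call.somatic_p)}")
    if call.status is not None:
        info.append(f"STATUS={call.status}")
    if call.confidence is not None:
        info.append(f"CONF={call.confidence}")
    fields = [
        call.chrom,
        str(call.pos),
        ".",
        call.ref,
        call.alt,
        f"{call.gq:.1f}",
        "PASS",
        ";".join(info),
        "GT:GQ:DP:AD:FREQ",
    ]
    if call.tumor is not None and call.normal is not None:
        for ev in (call.tumor, call.normal):
            fields.append(_sample_field(ev.genotype, call.gq, ev.depth, ev.alt_count))
    else:
        fields.append(_sample_field(call.genotype, call.gq, call.depth, call.alt_count))
    return "\t".join(fields)


def _population_record(call: PopulationCall) -> str:
    maf = f"{call.maf:.2f}" if call.maf is not None else "NA"
    fields = [
        call.chrom,
        str(call.pos),
        ".",
        call.ref,
        ",".join(call.alts),
        ".",
        "PASS",
        f"MAF={maf}",
        "GT:DP:AD",
    ]
    for gt, dp, ad in zip(call.genotypes, call.depths, call.alt_counts):
        fields.append(f"{gt}:{dp}:{ad}")
    return "\t".join(fields)


def write_vcf(
    calls: Iterable[VariantCall | PopulationCall],
    sample_names: Sequence[str],
    handle: IO[str],
    cfg: Optional[CallerConfig] = None,
) -> int:
    """Write calls as VCF v4.1; returns the number of records written.

    Calls must be (chrom, pos)-sorted within each chromosome.
    """
    for line in _header(sample_names, cfg):
        handle.write(line + "\n")
    n = 0
    prev: Optional[tuple[str, int]] = None
    for call in calls:
        if prev is not None and call.chrom == prev[0] and call.pos < prev[1]:
            raise ValueError(
                f"unsorted calls: {prev[0]}:{prev[1]} followed by "
                f"{call.chrom}:{call.pos}"
            )
        prev = (call.chrom, call.pos)
        if isinstance(call, PopulationCall):
            handle.write(_population_record(call) + "\n")
        else:
            handle.write(_variant_record(call) + "\n")
        n += 1
    return n


def _record_status(line: str) -> str:
    info = line.split("\t")[7]
    for entry in info.split(";"):
        if entry.startswith("STATUS="):
            return entry[len("STATUS="):]
    raise ValueError("record has no STATUS INFO key")


def split_vcf(vcf_path, out_prefix) -> dict[str, Path]:
    """Split a paired-mode VCF into four files, one per STATUS value.

    Every record lands in exactly one output (``<prefix>.Somatic.vcf``
    etc.); headers are copied verbatim to all four.
    """
    vcf_path = Path(vcf_path)
    out_prefix = str(out_prefix)
    header: list[str] = []
    records: dict[str, list[str]] = {s: [] for s in STATUSES}
    with open(vcf_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            status = _record_status(line)
            if status not in records:
                raise ValueError(f"unrecognized STATUS value {status!r}")
            records[status].append(line)
    paths: dict[str, Path] = {}
    for status in STATUSES:
        path = Path(f"{out_prefix}.{status}.vcf")
        with open(path, "w") as out:
            out.write("\n".join(header + records[status]) + "\n")
        paths[status] = path
    return paths
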