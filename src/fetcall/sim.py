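"""Desk-scale simulation benchmark: plant variants, simulate reads, score.

The protocol mirrors a classic caller benchmark: variants are planted in a
copy of a reference sequence, the mutated copy is paired with either
itself (homozygous) or the unmutated reference (heterozygous) to form a
diploid genome, reads are drawn uniformly from both haplotypes with a
uniform per-base substitution error, and calls are scored against the
planted truth with sensitivity (recall), precision and F-score:

    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F-score     = 2 * sensitivity * precision / (sensitivity + precision)

Reads are placed by construction (their true haplotype coordinates are
known), so no aligner runs: the caller, not the alignment, is under test.
Consequently alignment-driven effects — notably the read-length dependence
of large-indel recall — are deliberately absent from this benchmark.

Error model: substitutions only, uniform over the three alternative bases,
constant base quality (default Phred 35); errors falling inside inserted
bases are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import CallerConfig
from .modes import VariantCall, call_germline
from .pileup import read_mpileup

__all__ = [
    "PlannedEvent",
    "VariantPlan",
    "Diploid",
    "ReadSet",
    "Metrics",
    "random_reference",
    "snv_plan",
    "indel_plan",
    "build_diploid",
    "simulate_reads",
    "reads_to_mpileup",
    "truth_records",
    "evaluate",
    "run_germline_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlannedEvent:
    """One planted variant.

    ``pos`` is the 1-based reference coordinate: the substituted base for
    an SNV, the anchor base for an indel (insertion after ``pos``;
    deletion of the ``length`` bases following ``pos``).
    """

    pos: int
    kind: str  # SNV | INS | DEL
    zygosity: str  # HOM | HET
    alt: str = ""  # SNV alternate base or inserted sequence
    length: int = 0  # deletion length

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "INS", "DEL"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.zygosity not in ("HOM", "HET"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def ref_span_end(self) -> int:
        """Last 1-based reference position touched by the event."""
        return self.pos + (self.length if self.kind == "DEL" else 0)


@dataclass
class VariantPlan:
    """A set of planted events, validated against a reference length."""

    events: list[PlannedEvent]
    ref_length: int
    min_spacing: int = 100

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.pos)
        prev: Optional[PlannedEvent] = None
        for ev in self.events:
            if ev.pos < 1 or ev.ref_span_end > self.ref_length:
                raise ValueError(f"event at {ev.pos} outside reference")
            if prev is not None and ev.pos - prev.ref_span_end < self.min_spacing:
                raise ValueError(
                    f"events at {prev.pos} and {ev.pos} closer than "
                    f"{self.min_spacing} bp"
                )
            prev = ev


def random_reference(length: int, seed: int) -> str:
    """A uniform-composition random DNA reference sequence."""
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def _spaced_positions(
    n: int, length: int, margin: int, spacing: int, rng: np.random.Generator
) -> list[int]:
    """n positions, one per equal-width bin, >= spacing apart, off the ends."""
    usable = length - 2 * margin
    if usable < n * spacing:
        raise ValueError("reference too short for the requested plan")
    bin_w = usable // n
    pos = []
    for i in range(n):
        lo = margin + i * bin_w
        hi = margin + (i + 1) * bin_w - spacing
        pos.append(int(rng.integers(lo, max(hi, lo + 1))) + 1)  # 1-based
    return pos


def snv_plan(
    reference: str,
    n: int = 12,
    zygosity: str = "HOM",
    seed: int = 0,
    margin: int = 200,
    spacing: int = 150,
) -> VariantPlan:
    """Plant ``n`` SNVs of one zygosity at spaced random positions."""
    rng = np.random.default_rng(seed)
    events = []
    for pos in _spaced_positions(n, len(reference), margin, spacing, rng):
        ref_base = reference[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        events.append(PlannedEvent(pos, "SNV", zygosity, alt=alt))
    return VariantPlan(events, len(reference), min_spacing=spacing)


def indel_plan(
    reference: str,
    sizes: Sequence[int] = (1, 2, 5, 10),
    zygosity: str = "HOM",
    seed: int = 0,
    margin: int = 200,
    spacing: int = 150,
) -> VariantPlan:
    """Plant one insertion and one deletion of each size."""
    rng = np.random.default_rng(seed)
    kinds = [("INS", s) for s in sizes] + [("DEL", s) for s in sizes]
    events = []
    for (kind, size), pos in zip(
        kinds, _spaced_positions(len(kinds), len(reference), margin, spacing, rng)
    ):
        if kind == "INS":
            seq = "".join(rng.choice(_BASES, size=size).astype(str))
            events.append(PlannedEvent(pos, "INS", zygosity, alt=seq))
        else:
            events.append(PlannedEvent(pos, "DEL", zygosity, length=size))
    return VariantPlan(events, len(reference), min_spacing=spacing)


@dataclass
class Diploid:
    """Two haplotypes plus per-haplotype maps to reference coordinates.

    ``maps[h][i]`` is the 0-based reference position of haplotype ``h``'s
    base ``i``, or -1 for an inserted base.
    """

    reference: str
    chrom: str
    haplotypes: tuple[str, str]
    maps: tuple[np.ndarray, np.ndarray]


def _apply_events(
    reference: str, events: Sequence[PlannedEvent]
) -> tuple[str, np.ndarray]:
    chunks: list[str] = []
    map_chunks: list[np.ndarray] = []
    cur = 0  # 0-based cursor into the reference
    for ev in events:
        r0 = ev.pos - 1
        if ev.kind == "SNV":
            chunks.append(reference[cur:r0] + ev.alt)
            map_chunks.append(np.arange(cur, r0 + 1))
            cur = r0 + 1
        elif ev.kind == "INS":
            chunks.append(reference[cur : r0 + 1] + ev.alt)
            map_chunks.append(np.arange(cur, r0 + 1))
            map_chunks.append(np.full(len(ev.alt), -1))
            cur = r0 + 1
        else:  # DEL
            chunks.append(reference[cur : r0 + 1])
            map_chunks.append(np.arange(cur, r0 + 1))
            cur = r0 + 1 + ev.length
    chunks.append(reference[cur:])
    map_chunks.append(np.arange(cur, len(reference)))
    return "".join(chunks), np.concatenate(map_chunks)


def build_diploid(reference: str, plan: VariantPlan, chrom: str = "ref") -> Diploid:
    """Mutated-vs-mutated (homozygous events) and mutated-vs-reference
    (heterozygous events) diploid construction.

    Haplotype 0 carries every planted event; haplotype 1 carries only the
    homozygous ones.
    """
    hap0, map0 = _apply_events(reference, plan.events)
    hom = [ev for ev in plan.events if ev.zygosity == "HOM"]
    hap1, map1 = _apply_events(reference, hom)
    return Diploid(reference, chrom, (hap0, hap1), (map0, map1))


@dataclass
class ReadSet:
    """Simulated reads with their true origin coordinates.

    Errors are stored sparsely as (read index, offset, substituted base).
    """

    read_len: int
    qual: int
    hap: np.ndarray  # (n,) int8, source haplotype
    start: np.ndarray  # (n,) int64, 0-based start in haplotype coordinates
    forward: np.ndarray  # (n,) bool
    err_read: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    err_off: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    err_base: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U1"))

    @property
    def n_reads(self) -> int:
        return len(self.start)


def simulate_reads(
    diploid: Diploid,
    coverage: float,
    read_len: int,
    err_rate: float = 0.001,
    seed: int = 0,
    qual: int = 35,
) -> ReadSet:
    """Draw reads uniformly from both haplotypes to a target mean depth.

    The read count is ``round(coverage * len(reference) / read_len)``;
    haplotype, start and strand are uniform; per-base substitution errors
    occur at ``err_rate``, uniformly over the three alternative bases.
    Fully reproducible from ``seed``.
    """
    if read_len >= min(len(h) for h in diploid.haplotypes):
        raise ValueError("read length must be shorter than the haplotypes")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * len(diploid.reference) / read_len))
    hap = rng.integers(0, 2, size=n_reads).astype(np.int8)
    lengths = np.array([len(h) for h in diploid.haplotypes])
    start = (rng.random(n_reads) * (lengths[hap] - read_len + 1)).astype(np.int64)
    forward = rng.random(n_reads) < 0.5

    reads = ReadSet(read_len, qual, hap, start, forward)
    if err_rate > 0:
        total = n_reads * read_len
        k = rng.binomial(total, err_rate)
        flat = rng.choice(total, size=k, replace=False)
        flat.sort()
        err_read = flat // read_len
        err_off = flat % read_len
        hseqs = [np.frombuffer(h.encode(), dtype="S1") for h in diploid.haplotypes]
        err_base = np.empty(k, dtype="U1")
        pick = rng.integers(0, 3, size=k)
        for i in range(k):
            orig = hseqs[hap[err_read[i]]][start[err_read[i]] + err_off[i]].decode()
            alts = [b for b in "ACGT" if b != orig]
            err_base[i] = alts[pick[i]]
        reads.err_read, reads.err_off, reads.err_base = err_read, err_off, err_base
    return reads


def _hap_mismatches(diploid: Diploid, h: int) -> dict[int, str]:
    """0-based reference positions where haplotype ``h`` differs by substitution."""
    hseq = np.frombuffer(diploid.haplotypes[h].encode(), dtype="S1")
    rseq = np.frombuffer(diploid.reference.encode(), dtype="S1")
    m = diploid.maps[h]
    aligned = m >= 0
    idx = np.nonzero(aligned & (hseq != rseq[np.maximum(m, 0)]))[0]
    return {int(m[i]): hseq[i].decode() for i in idx}


def _irregular_indices(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(inserted positions, gap-after positions) of a haplotype->ref map."""
    ins = np.nonzero(m < 0)[0]
    step = np.diff(m)
    gap = np.nonzero((m[:-1] >= 0) & (m[1:] >= 0) & (step > 1))[0]
    return ins, gap


def reads_to_mpileup(reads: ReadSet, diploid: Diploid) -> str:
    """Stack reads into single-sample mpileup text by their true placement.

    Substitutions appear as base characters (case encodes strand), planted
    insertions/deletions as ``+n``/``-n`` events at their anchor, deleted
    positions as ``*``.  Positions with zero depth are omitted, as
    samtools does.
    """
    L = len(diploid.reference)
    rl = reads.read_len
    ref = diploid.reference
    # diff arrays for (hap, strand) coverage in reference coordinates
    diff = np.zeros((2, 2, L + 1), dtype=np.int32)
    stars = np.zeros(L, dtype=np.int32)
    # per-position list of (hap, fwd, token) indel suffixes, and
    # (hap, fwd, base) error overrides
    suffixes: dict[int, list[tuple[int, bool, str]]] = {}
    overrides: dict[int, list[tuple[int, bool, str]]] = {}
    mismatches = [_hap_mismatches(diploid, h) for h in (0, 1)]

    irregular = []
    for h in (0, 1):
        ins, gap = _irregular_indices(diploid.maps[h])
        irregular.append((ins, gap))

    hap, start, forward = reads.hap, reads.start, reads.forward
    end = start + rl
    is_irregular = np.zeros(reads.n_reads, dtype=bool)
    for h in (0, 1):
        ins, gap = irregular[h]
        sel = hap == h
        # any inserted base in [start, end) or any gap index in [start, end-1)
        n_ins = np.searchsorted(ins, end[sel]) > np.searchsorted(ins, start[sel])
        n_gap = np.searchsorted(gap, end[sel] - 1) > np.searchsorted(gap, start[sel])
        is_irregular[sel] = n_ins | n_gap

    # Regular reads: contiguous reference span.
    for h in (0, 1):
        m = diploid.maps[h]
        for fwd in (True, False):
            sel = (hap == h) & (forward == fwd) & ~is_irregular
            if not sel.any():
                continue
            r0 = m[start[sel]]
            np.add.at(diff[h, int(fwd)], r0, 1)
            np.add.at(diff[h, int(fwd)], r0 + rl, -1)

    # Irregular reads: walk base by base.
    for i in np.nonzero(is_irregular)[0]:
        h, s, fwd = int(hap[i]), int(start[i]), bool(forward[i])
        m = diploid.maps[h]
        j = s
        last_r = -1
        while j < s + rl:
            r = int(m[j])
            if r < 0:
                # inserted bases: collect the full run present in the read
                j0 = j
                while j < s + rl and m[j] < 0:
                    j += 1
                seq = diploid.haplotypes[h][j0:j]
                if last_r >= 0:
                    suffixes.setdefault(last_r, []).append(
                        (h, fwd, f"+{len(seq)}{seq}")
                    )
                continue
            diff[h, int(fwd), r] += 1
            diff[h, int(fwd), r + 1] -= 1
            if last_r >= 0 and r - last_r > 1:
                dseq = ref[last_r + 1 : r]
                suffixes.setdefault(last_r, []).append(
                    (h, fwd, f"-{len(dseq)}{dseq}")
                )
                stars[last_r + 1 : r] += 1
            last_r = r
            j += 1

    # Sequencing errors override single read bases.
    for t in range(len(reads.err_read)):
        i = int(reads.err_read[t])
        h = int(hap[i])
        hp = int(start[i]) + int(reads.err_off[t])
        r = int(diploid.maps[h][hp])
        if r < 0:
            continue  # error inside an inserted base: not modeled
        overrides.setdefault(r, []).append((h, bool(forward[i]), str(reads.err_base[t])))

    cov = np.cumsum(diff[:, :, :-1], axis=2)
    covered = np.nonzero(cov.sum(axis=(0, 1)) + stars > 0)[0]

    def base_char(h: int, p: int, fwd: bool) -> str:
        alt = mismatches[h].get(p)
        if alt is None:
            return "." if fwd else ","
        return alt if fwd else alt.lower()

    qc = chr(reads.qual + 33)
    lines = []
    for p in covered:
        p = int(p)
        n = {(h, f): int(cov[h, int(f), p]) for h in (0, 1) for f in (True, False)}
        col: list[str] = []
        for h, fwd, base in overrides.get(p, ()):  # errors first
            if n[(h, fwd)] > 0:
                n[(h, fwd)] -= 1
                c = base if base.upper() != ref[p] else "."
                col.append(c if fwd else c.lower().replace(".", ","))
        for h, fwd, token in suffixes.get(p, ()):
            if n[(h, fwd)] > 0:
                n[(h, fwd)] -= 1
                tok = token if fwd else token[0] + token[1:].lower()
                col.append(base_char(h, p, fwd) + tok)
        for (h, fwd), k in n.items():
            col.extend([base_char(h, p, fwd)] * k)
        col.extend(["*"] * int(stars[p]))
        depth = len(col)
        quals = qc * depth
        lines.append(
            f"{diploid.chrom}\t{p + 1}\t{ref[p]}\t{depth}\t{''.join(col)}\t{quals}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def truth_records(
    plan: VariantPlan, reference: str, chrom: str = "ref"
) -> list[tuple[str, int, str, str, str]]:
    """Planted events as left-anchored VCF tuples (chrom, pos, ref, alt, zygosity)."""
    out = []
    for ev in plan.events:
        r0 = ev.pos - 1
        if ev.kind == "SNV":
            out.append((chrom, ev.pos, reference[r0], ev.alt, ev.zygosity))
        elif ev.kind == "INS":
            anchor = reference[r0]
            out.append((chrom, ev.pos, anchor, anchor + ev.alt, ev.zygosity))
        else:
            out.append(
                (
                    chrom,
                    ev.pos,
                    reference[r0 : r0 + ev.length + 1],
                    reference[r0],
                    ev.zygosity,
                )
            )
    return out


@dataclass
class Metrics:
    """TP/FP/FN-derived detection accuracy, plus zygosity concordance."""

    tp: int
    fp: int
    fn: int
    zygosity_matches: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f_score(self) -> float:
        s, p = self.sensitivity, self.precision
        return 2 * s * p / (s + p) if s + p else 0.0

    @property
    def zygosity_concordance(self) -> float:
        return self.zygosity_matches / self.tp if self.tp else 0.0


def evaluate(
    truth: Sequence[tuple[str, int, str, str, str]],
    calls: Iterable[VariantCall],
) -> Metrics:
    """Score calls against planted truth by exact (chrom, pos, ref, alt) match."""
    truth_map = {(c, p, r, a): z for c, p, r, a, z in truth}
    tp = fp = 0
    zyg = 0
    seen: set[tuple] = set()
    for call in calls:
        key = (call.chrom, call.pos, call.ref, call.alt)
        if key in truth_map and key not in seen:
            tp += 1
            seen.add(key)
            if call.genotype == truth_map[key]:
                zyg += 1
        else:
            fp += 1
    fn = len(truth_map) - tp
    return Metrics(tp=tp, fp=fp, fn=fn, zygosity_matches=zyg)


def run_germline_benchmark(
    reference: str,
    plan: VariantPlan,
    coverage: float,
    read_len: int,
    err_rate: float = 0.001,
    seed: int = 0,
    cfg: Optional[CallerConfig] = None,
) -> Metrics:
    """One end-to-end replicate: simulate, pile up, call, score."""
    import io

    cfg = cfg or CallerConfig()
    diploid = build_diploid(reference, plan)
    reads = simulate_reads(diploid, coverage, read_len, err_rate, seed=seed)
    text = reads_to_mpileup(reads, diploid)
    calls = list(call_germline(read_mpileup(io.StringIO(text), 1), cfg))
    return evaluate(truth_records(plan, reference), calls)
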