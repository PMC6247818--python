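"""Reading and writing samtools-style mpileup text.

An mpileup line stacks, for one reference position, the read bases and base
qualities of every read covering it, for one or more samples.  The first
three columns are chromosome, 1-based position and reference base; sample
``m`` (1-based) then contributes depth, base string and quality string in
columns ``4+3(m-1)``, ``5+3(m-1)`` and ``6+3(m-1)``.

The base-string grammar decoded here:

* ``.`` / ``,`` — read base matches the reference, forward / reverse strand;
* ``ACGT`` / ``acgt`` — substitution, forward / reverse strand;
* ``+<n><seq>`` / ``-<n><seq>`` — insertion / deletion of ``n`` bases
  following this position, attached to the preceding read observation;
* ``^X`` — read start; ``X`` is the mapping quality character (consumed,
  not a base); ``$`` — read end;
* ``*`` — base deleted in this read (a placeholder that counts toward
  depth but is never a variant allele);
* ``>`` / ``<`` — reference skip (spliced alignment), likewise depth-only.

Base qualities are Phred+33 ASCII.  Strand is taken from character case,
which is how the format encodes it.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "REF",
    "DELETED",
    "SKIP",
    "ReadObservation",
    "PileupSite",
    "PileupFormatError",
    "decode_bases",
    "parse_mpileup_line",
    "read_mpileup",
    "write_mpileup",
]

#: Allele sentinel for a read base matching the reference.
REF = "REF"
#: Allele sentinel for a ``*`` placeholder (base deleted in this read).
DELETED = "*"
#: Allele sentinel for a ``>``/``<`` reference skip.
SKIP = ">"

_DNA = set("ACGTN")


class PileupFormatError(ValueError):
    """Raised when mpileup text violates the format grammar."""


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at one site.

    ``allele`` is :data:`REF`, an upper-case SNV base, ``+SEQ`` /
    ``-SEQ`` for an indel anchored at this position, :data:`DELETED`
    or :data:`SKIP`.  ``forward`` is the strand; ``phred`` the base
    quality.  ``read_start``/``read_end`` record ``^``/``$`` markers.
    """

    allele: str
    forward: bool
    phred: int
    read_start: bool = False
    read_end: bool = False

    @property
    def is_allele(self) -> bool:
        """Whether this observation can support a variant or reference call."""
        return self.allele not in (DELETED, SKIP)


@dataclass
class PileupSite:
    """All samples' read evidence at one genomic position."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    samples: list[list[ReadObservation]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


def _decode_indel(bases: str, i: int) -> tuple[str, int]:
    """Decode ``+<n><seq>``/``-<n><seq>`` starting at index ``i``.

    Returns the signed allele string (``+SEQ`` or ``-SEQ``, upper-cased)
    and the index just past the consumed characters.
    """
    sign = bases[i]
    j = i + 1
    while j < len(bases) and bases[j].isdigit():
        j += 1
    if j == i + 1:
        raise PileupFormatError(f"'{sign}' not followed by a length at column {i}")
    n = int(bases[i + 1 : j])
    seq = bases[j : j + n]
    if len(seq) < n:
        raise PileupFormatError(f"indel of length {n} truncated at column {i}")
    seq = seq.upper()
    if not set(seq) <= _DNA:
        raise PileupFormatError(f"indel sequence {seq!r} is not DNA")
    return sign + seq, j + n


def decode_bases(bases: str, quals: str, ref_base: str) -> list[ReadObservation]:
    """Decode one sample's base and quality strings into read observations.

    Every character of ``bases`` is consumed exactly once; the number of
    observations returned equals the number of quality characters, and each
    quality is ``ord(char) - 33``.
    """
    obs: list[ReadObservation] = []
    qi = 0
    i = 0
    n = len(bases)
    pending_start = False
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupFormatError("dangling '^' at end of base string")
            pending_start = True
            i += 2  # skip the mapping-quality character
            continue
        if c == "$":
            if not obs:
                raise PileupFormatError("'$' with no preceding observation")
            last = obs[-1]
            obs[-1] = ReadObservation(
                last.allele, last.forward, last.phred, last.read_start, True
            )
            i += 1
            continue
        if c in "+-":
            if not obs:
                raise PileupFormatError(f"'{c}' with no preceding observation")
            allele, i = _decode_indel(bases, i)
            last = obs[-1]
            obs[-1] = ReadObservation(
                allele, last.forward, last.phred, last.read_start, last.read_end
            )
            continue
        # A character that consumes one quality.
        if qi >= len(quals):
            raise PileupFormatError("more base observations than quality characters")
        phred = ord(quals[qi]) - 33
        if phred < 0:
            raise PileupFormatError(f"quality character {quals[qi]!r} below '!'")
        qi += 1
        if c == ".":
            allele, fwd = REF, True
        elif c == ",":
            allele, fwd = REF, False
        elif c in "ACGTN":
            allele, fwd = c, True
        elif c in "acgtn":
            allele, fwd = c.upper(), False
        elif c == "*":
            allele, fwd = DELETED, True
        elif c == ">":
            allele, fwd = SKIP, True
        elif c == "<":
            allele, fwd = SKIP, False
        else:
            raise PileupFormatError(f"unrecognized pileup character {c!r}")
        obs.append(ReadObservation(allele, fwd, phred, pending_start, False))
        pending_start = False
        i += 1
    if qi != len(quals):
        raise PileupFormatError(
            f"decoded {qi} observations but {len(quals)} quality characters given"
        )
    return obs


def parse_mpileup_line(line: str, n_samples: int, lineno: int = 0) -> PileupSite:
    """Parse one mpileup line carrying ``n_samples`` samples."""
    fields = line.rstrip("\n").split("\t")
    expected = 3 + 3 * n_samples
    if len(fields) != expected:
        # samtools emits "0\t*\t*" for zero-depth samples; also tolerate a
        # bare "0" with empty base/qual columns.
        raise PileupFormatError(
            f"line {lineno}: expected {expected} tab-separated fields for "
            f"{n_samples} sample(s), got {len(fields)}"
        )
    chrom, pos_s, ref_base = fields[0], fields[1], fields[2]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise PileupFormatError(f"line {lineno}: bad position {pos_s!r}") from exc
    site = PileupSite(chrom, pos, ref_base.upper())
    for m in range(n_samples):
        depth_s, bases, quals = fields[3 + 3 * m : 6 + 3 * m]
        try:
            depth = int(depth_s)
        except ValueError as exc:
            raise PileupFormatError(
                f"line {lineno}: bad depth {depth_s!r} for sample {m + 1}"
            ) from exc
        if depth == 0:
            site.samples.append([])
            continue
        obs = decode_bases(bases, quals, site.ref_base)
        if len(obs) != depth:
            raise PileupFormatError(
                f"line {lineno}: sample {m + 1} declares depth {depth} but "
                f"{len(obs)} observations decoded"
            )
        site.samples.append(obs)
    return site


def _open_text(path_or_handle) -> IO[str]:
    if hasattr(path_or_handle, "read"):
        return path_or_handle
    path = str(path_or_handle)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_mpileup(source, n_samples: int) -> Iterator[PileupSite]:
    """Stream :class:`PileupSite` objects from a path or text handle.

    Gzip-transparent when given a ``.gz`` path.
    """
    handle = _open_text(source)
    for lineno, line in enumerate(handle, start=1):
        if not line.strip():
            continue
        yield parse_mpileup_line(line, n_samples, lineno=lineno)


def _encode_observation(o: ReadObservation, ref_base: str) -> str:
    if o.allele == DELETED:
        core = "*"
    elif o.allele == SKIP:
        core = ">" if o.forward else "<"
    elif o.allele == REF:
        core = "." if o.forward else ","
    elif o.allele[0] in "+-":
        anchor = "." if o.forward else ","
        seq = o.allele[1:] if o.forward else o.allele[1:].lower()
        core = f"{anchor}{o.allele[0]}{len(o.allele) - 1}{seq}"
    else:
        core = o.allele if o.forward else o.allele.lower()
    prefix = "^~" if o.read_start else ""
    suffix = "$" if o.read_end else ""
    return prefix + core + suffix


def format_site(site: PileupSite) -> str:
    """Serialize one site back to an mpileup line."""
    cols = [site.chrom, str(site.pos), site.ref_base]
    for obs in site.samples:
        if not obs:
            cols.extend(["0", "*", "*"])
            continue
        bases = "".join(_encode_observation(o, site.ref_base) for o in obs)
        quals = "".join(chr(o.phred + 33) for o in obs)
        cols.extend([str(len(obs)), bases, quals])
    return "\t".join(cols)


def write_mpileup(sites: Iterable[PileupSite], handle: IO[str]) -> None:
    """Write sites as mpileup text; input must be (chrom, pos)-sorted."""
    prev: tuple[str, int] | None = None
    for site in sites:
        key = (site.chrom, site.pos)
        if prev is not None and site.chrom == prev[0] and site.pos <= prev[1]:
            raise ValueError(f"unsorted sites: {prev} followed by {key}")
        prev = key
        handle.write(format_site(site) + "\n")
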