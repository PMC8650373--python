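"""Junction-read processing: trim viral/adaptor sequence, map the flank.

Reads from the linker-mediated-PCR library begin with the nested LTR primer,
continue into host DNA up to the restriction cut, and (read length
permitting) end in the reverse complement of the nested adaptor primer.
Trimming strips both primers; mapping locates the remaining flank in the
genome by exact matching (both strands) and reports the junction coordinate:
the first host base 3' of the LTR end, 0-based.

Exact substring matching deliberately replaces read alignment: the synthetic
genomes here are unambiguous, and real, pre-aligned data enters through
:func:`import_mapped_bed` instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .simgen import Genome, ProtocolParams
from .util import hamming, revcomp


@dataclass
class RawRead:
    read_id: str
    sequence: str
    quality: list | None = None

    def __post_init__(self):
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: sequence must be non-empty A/C/G/T/N")


@dataclass
class TrimmedFlank:
    read_id: str
    flank: str
    ltr_offset: int = 0
    ltr_mismatches: int = 0
    adaptor_found: bool = False


@dataclass
class Rejection:
    read_id: str
    reason: str


@dataclass
class MappedSite:
    """A junction call: first genomic base after the LTR junction (0-based)."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    unique: bool = True
    tumor_id: str | None = None
    specimen_id: str | None = None
    read_support: int = 1


def read_fastx(path) -> Iterator[RawRead]:
    """Yield RawRead from a FASTQ or FASTA file (format from extension)."""
    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "fastq"
    for rec in SeqIO.parse(str(path), fmt):
        qual = rec.letter_annotations.get("phred_quality")
        yield RawRead(rec.id, str(rec.seq).upper(), qual)


def trim_read(
    read: RawRead,
    protocol: ProtocolParams = ProtocolParams(),
    min_flank: int = 20,
    max_mismatches: int = 2,
    adaptor_mismatches: int = 1,
    max_offset: int = 2,
    min_adaptor_overlap: int = 8,
):
    """Strip the LTR primer from the 5' end and the adaptor from the 3' end.

    The LTR nested primer must occur at the read start, at an offset of at
    most ``max_offset``, with at most ``max_mismatches`` substitutions; the
    smallest qualifying offset wins.  The adaptor (reverse complement of the
    nested adaptor primer) is removed on a full match with at most
    ``adaptor_mismatches`` substitutions anywhere in the remainder, or — for
    reads truncated mid-adaptor — on the longest 3'-terminal match against
    the adaptor prefix (mismatch-tolerant from ``min_adaptor_overlap`` bases
    up, exact-only below that).

    Returns :class:`TrimmedFlank` or :class:`Rejection` with reason
    ``no_ltr`` / ``short_flank``.
    """
    ltr = protocol.ltr_nested_primer
    seq = read.sequence
    hit = None
    for off in range(0, max_offset + 1):
        if off + len(ltr) > len(seq):
            break
        mm = hamming(seq[off : off + len(ltr)], ltr)
        if mm <= max_mismatches:
            hit = (off, mm)
            break
    if hit is None:
        return Rejection(read.read_id, "no_ltr")
    off, mm = hit
    flank = seq[off + len(ltr) :]

    adaptor = revcomp(protocol.adaptor_nested_primer)
    adaptor_found = False
    cut = None
    for i in range(0, len(flank) - len(adaptor) + 1):
        if hamming(flank[i : i + len(adaptor)], adaptor) <= adaptor_mismatches:
            cut = i
            break
    if cut is None:
        # read may have been truncated inside the adaptor, leaving any-length
        # remnant; trim the longest 3'-terminal match against the adaptor
        # prefix.  Below min_adaptor_overlap only exact matches count — and
        # a spuriously trimmed genomic suffix is harmless anyway, since the
        # junction sits at the flank start.
        for length in range(min(len(adaptor) - 1, len(flank)), 0, -1):
            allowed = adaptor_mismatches if length >= min_adaptor_overlap else 0
            if hamming(flank[len(flank) - length :], adaptor[:length]) <= allowed:
                cut = len(flank) - length
                break
    if cut is not None:
        flank = flank[:cut]
        adaptor_found = True
    if len(flank) < min_flank:
        return Rejection(read.read_id, "short_flank")
    return TrimmedFlank(read.read_id, flank, off, mm, adaptor_found)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_flank(flank: TrimmedFlank, genome: Genome):
    """Exact-match the flank (and its reverse complement) genome-wide.

    A unique hit yields a :class:`MappedSite`; its position is the junction
    base.  On the plus strand that is the match start; on the minus strand the
    read ran leftwards, so the junction is the match end minus one.

    Returns :class:`Rejection` with reason ``unmapped`` or ``multimapped``
    otherwise.
    """
    if not genome.has_sequence:
        raise ValueError("mapping needs a genome with sequence")
    query, query_rc = flank.flank, revcomp(flank.flank)
    hits = []
    for chrom in genome.names:
        seq = genome.sequences[chrom]
        for i in _find_all(seq, query):
            hits.append((chrom, i, "+"))
        for i in _find_all(seq, query_rc):
            hits.append((chrom, i + len(query_rc) - 1, "-"))
    if not hits:
        return Rejection(flank.read_id, "unmapped")
    if len(hits) > 1:
        return Rejection(flank.read_id, "multimapped")
    chrom, pos, strand = hits[0]
    assert 0 <= pos < genome.lengths[chrom]
    return MappedSite(flank.read_id, chrom, pos, strand, unique=True)


def default_id_parser(read_id: str):
    """Tumor/specimen from the ``tumor|specimen|...`` read-id convention."""
    parts = read_id.split("|")
    if len(parts) >= 2:
        return parts[0], parts[1]
    return None, None


def process_reads(
    reads: Iterable[RawRead],
    genome: Genome,
    protocol: ProtocolParams = ProtocolParams(),
    min_flank: int = 20,
    max_mismatches: int = 2,
    id_parser=default_id_parser,
):
    """Trim + map a read stream.  Returns ``(sites, rejections)``."""
    sites, rejections = [], []
    for read in reads:
        trimmed = trim_read(read, protocol, min_flank=min_flank, max_mismatches=max_mismatches)
        if isinstance(trimmed, Rejection):
            rejections.append(trimmed)
            continue
        mapped = map_flank(trimmed, genome)
        if isinstance(mapped, Rejection):
            rejections.append(mapped)
            continue
        mapped.tumor_id, mapped.specimen_id = id_parser(read.read_id)
        sites.append(mapped)
    return sites, rejections


# ---------------------------------------------------------------------------
# BED interchange (0-based half-open; name = tumor ID, score = read support)


def export_bed(sites: Iterable[MappedSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            name = s.tumor_id if s.tumor_id is not None else "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{name}\t{s.read_support}\t{s.strand}\n")


def import_mapped_bed(path) -> list[MappedSite]:
    """Read junction sites from 6-column BED (tumor ID in the name field).

    BED start (0-based) is taken as the junction position; strand preserved.
    Malformed lines raise with their line number.
    """
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end_i <= start_i or strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: malformed interval or strand")
            try:
                support = int(float(score))
            except ValueError:
                support = 1
            sites.append(
                MappedSite(
                    read_id=f"bed:{lineno}",
                    chrom=chrom,
                    pos=start_i,
                    strand=strand,
                    tumor_id=None if name == "." else name,
                    read_support=support,
                )
            )
    return sites


def write_rejections(rejections: Iterable[Rejection], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["read_id", "reason"])
        for r in rejections:
            w.writerow([r.read_id, r.reason])
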