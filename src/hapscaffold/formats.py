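"""Readers and writers for every external format the scaffolder touches.

Supported formats: FASTA contigs (in/out), paired-read alignments in three
dialects (SAM via pysam, legacy Bowtie tabular, BLAST tabular -outfmt 6),
the SOAPdenovo-style library configuration ("reads info") file, a
two-column contig depth table, the per-pair PairStatus metafile, and DOT
graph export.

All coordinates are normalized at parse time to 0-based, half-open
intervals on the contig forward strand, regardless of dialect.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_MATE_SUFFIX = re.compile(r"^(?P<pair>.*?)[/_](?P<mate>[12])$")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Contigs


@dataclass(frozen=True, slots=True)
class ContigRecord:
    """A named DNA sequence; characters restricted to A/C/G/T/N (uppercased)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path):
    """Open a possibly gzip-compressed text file transparently."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _locate_bad_base(path: str | Path, contig_id: str) -> str:
    """Rescan the raw FASTA to name the line holding an invalid character."""
    in_target = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_target = line[1:].split()[0] == contig_id if line[1:].strip() else False
                continue
            if in_target:
                bad = set(line.strip().upper()) - VALID_BASES
                if bad:
                    return f"line {lineno} (character {sorted(bad)[0]!r})"
    return "unknown line"


def parse_fasta(path: str | Path) -> dict[str, ContigRecord]:
    """Parse a FASTA file into an ordered mapping of contig id -> record.

    Duplicate ids and non-IUPAC (non-ACGTN) characters are hard errors;
    multi-line sequence bodies are concatenated and uppercased.
    """
    contigs: dict[str, ContigRecord] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
            seq = str(rec.seq).upper()
            if set(seq) - VALID_BASES:
                raise FormatError(
                    f"{path}: contig {rec.id!r} has a non-ACGTN character at "
                    f"{_locate_bad_base(path, rec.id)}"
                )
            contigs[rec.id] = ContigRecord(id=rec.id, sequence=seq)
    return contigs


def write_fasta(records: Iterable[ContigRecord | tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write records (ContigRecord or (id, sequence) pairs) as wrapped FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, ContigRecord):
            rid, seq = rec.id, rec.sequence
        else:
            rid, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# Alignments


class AlnFormat(str, Enum):
    SAM = "SAM"
    BOWTIE = "BOWTIE"
    BLAST = "BLAST"


@dataclass(slots=True)
class ReadAlignment:
    """One aligned read end, normalized to 0-based half-open forward-strand
    coordinates. ``read_id`` is always ``<pair>/<mate>`` with mate 1 or 2."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    multiplicity: int = 1

    @property
    def pair_id(self) -> str:
        return self.read_id.rsplit("/", 1)[0]

    @property
    def mate(self) -> int:
        return int(self.read_id.rsplit("/", 1)[1])


class AlignmentSet(Sequence):
    """A collection of ReadAlignment plus the ids of reads reported unmapped.

    Behaves as a sequence of alignments; ``unmapped_read_ids`` preserves
    pairs whose ends the aligner reported but could not place (only SAM
    carries such records)."""

    def __init__(self, alignments: list[ReadAlignment], unmapped_read_ids: set[str] | None = None):
        self.alignments = alignments
        self.unmapped_read_ids = unmapped_read_ids or set()
        self._annotate_multiplicity()

    def _annotate_multiplicity(self) -> None:
        counts: dict[str, int] = {}
        for aln in self.alignments:
            counts[aln.read_id] = counts.get(aln.read_id, 0) + 1
        for aln in self.alignments:
            aln.multiplicity = counts[aln.read_id]

    def __len__(self) -> int:
        return len(self.alignments)

    def __getitem__(self, idx):
        return self.alignments[idx]

    def __iter__(self) -> Iterator[ReadAlignment]:
        return iter(self.alignments)


def split_mate(read_id: str) -> tuple[str, int] | None:
    """Split a read id into (pair id, mate index) via a /1 /2 _1 _2 suffix."""
    m = _MATE_SUFFIX.match(read_id)
    if m is None:
        return None
    return m.group("pair"), int(m.group("mate"))


def _normalize_read_id(raw: str, mate: int | None) -> str:
    split = split_mate(raw)
    if mate is not None:
        pair = split[0] if split is not None else raw
        return f"{pair}/{mate}"
    if split is None:
        raise FormatError(f"cannot determine mate index for read id {raw!r}")
    return f"{split[0]}/{split[1]}"


def _check_span(aln: ReadAlignment, contig_set: dict[str, ContigRecord], where: str) -> None:
    if aln.contig_id not in contig_set:
        raise FormatError(f"{where}: unknown contig id {aln.contig_id!r}")
    clen = contig_set[aln.contig_id].length
    if not (0 <= aln.start < aln.end <= clen):
        raise FormatError(
            f"{where}: alignment interval [{aln.start},{aln.end}) outside contig "
            f"{aln.contig_id!r} of length {clen}"
        )


def _parse_sam(path: str | Path, contig_set: dict[str, ContigRecord]) -> AlignmentSet:
    alignments: list[ReadAlignment] = []
    unmapped: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            mate = None
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            read_id = _normalize_read_id(rec.query_name, mate)
            if rec.is_unmapped:
                unmapped.add(read_id)
                continue
            aln = ReadAlignment(
                read_id=read_id,
                contig_id=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
            )
            _check_span(aln, contig_set, f"{path} (read {rec.query_name})")
            alignments.append(aln)
    return AlignmentSet(alignments, unmapped)


def _parse_bowtie(path: str | Path, contig_set: dict[str, ContigRecord]) -> AlignmentSet:
    # Legacy (pre-Bowtie2) default tab output:
    # read, strand, reference, 0-based offset, sequence, quals, ...
    alignments: list[ReadAlignment] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: malformed Bowtie line ({len(fields)} fields)")
            name, strand, ref, offset, seq = fields[:5]
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                start = int(offset)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad offset {offset!r}") from None
            aln = ReadAlignment(
                read_id=_normalize_read_id(name, None),
                contig_id=ref,
                start=start,
                end=start + len(seq),
                strand=strand,
            )
            _check_span(aln, contig_set, f"{path}:{lineno}")
            alignments.append(aln)
    return AlignmentSet(alignments)


def _parse_blast(path: str | Path, contig_set: dict[str, ContigRecord]) -> AlignmentSet:
    # BLAST tabular (-outfmt 6): qseqid sseqid pident length mismatch gapopen
    # qstart qend sstart send evalue bitscore. Subject coordinates are 1-based
    # inclusive; sstart > send encodes a minus-strand hit.
    alignments: list[ReadAlignment] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}:{lineno}: malformed BLAST line ({len(fields)} fields)")
            try:
                sstart, send = int(fields[8]), int(fields[9])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad subject coordinates") from None
            if sstart <= send:
                strand, start, end = "+", sstart - 1, send
            else:
                strand, start, end = "-", send - 1, sstart
            aln = ReadAlignment(
                read_id=_normalize_read_id(fields[0], None),
                contig_id=fields[1],
                start=start,
                end=end,
                strand=strand,
            )
            _check_span(aln, contig_set, f"{path}:{lineno}")
            alignments.append(aln)
    return AlignmentSet(alignments)


def parse_alignments(
    path: str | Path, format_tag: AlnFormat | str, contig_set: dict[str, ContigRecord]
) -> AlignmentSet:
    """Parse an alignment file in one of the three dialects.

    Unmapped records are excluded from the alignment list (SAM keeps their
    ids in ``unmapped_read_ids``); strand and coordinates are normalized to
    a dialect-independent internal convention."""
    fmt = AlnFormat(format_tag)
    if fmt is AlnFormat.SAM:
        return _parse_sam(path, contig_set)
    if fmt is AlnFormat.BOWTIE:
        return _parse_bowtie(path, contig_set)
    return _parse_blast(path, contig_set)


# ---------------------------------------------------------------------------
# Library configuration ("reads info" file)


@dataclass(slots=True)
class LibrarySpec:
    """One paired-read library: mean insert size, scaffolding rank, files."""

    name: str
    mean_insert: int
    rank: int
    files: list[str] = field(default_factory=list)
    format_tag: AlnFormat | None = None


_FILE_KEYS = {"f", "q", "f1", "f2", "q1", "q2", "map_file", "aln", "aln_file", "b"}


def _infer_format(files: Sequence[str]) -> AlnFormat | None:
    for f in files:
        lower = f.lower()
        if lower.endswith(".sam"):
            return AlnFormat.SAM
        if lower.endswith((".bowtie", ".bwt", ".map")):
            return AlnFormat.BOWTIE
        if lower.endswith((".blast", ".b6", ".tab", ".outfmt6")):
            return AlnFormat.BLAST
    return None


def parse_reads_info(path: str | Path) -> list[LibrarySpec]:
    """Parse a SOAPdenovo-configuration-style library file.

    Stanzas begin with a ``[LIB]`` line followed by ``key=value`` lines;
    ``avg_ins`` and ``rank`` are required per stanza. Ranks need not be
    contiguous; libraries are returned in file order."""
    libs: list[LibrarySpec] = []
    stanza: dict[str, str] | None = None
    stanza_files: list[str] = []
    stanza_line = 0

    def close_stanza() -> None:
        nonlocal stanza, stanza_files
        if stanza is None:
            return
        if "avg_ins" not in stanza:
            raise FormatError(f"{path}: [LIB] stanza at line {stanza_line} missing avg_ins")
        if "rank" not in stanza:
            raise FormatError(f"{path}: [LIB] stanza at line {stanza_line} missing rank")
        fmt = stanza.get("format")
        libs.append(
            LibrarySpec(
                name=stanza.get("name", f"LIB{len(libs) + 1}"),
                mean_insert=int(stanza["avg_ins"]),
                rank=int(stanza["rank"]),
                files=list(stanza_files),
                format_tag=AlnFormat(fmt.upper()) if fmt else _infer_format(stanza_files),
            )
        )
        stanza, stanza_files = None, []

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper().startswith("[LIB]"):
                close_stanza()
                stanza, stanza_line = {}, lineno
                continue
            if "=" not in line:
                continue  # tolerate global keys such as max_rd_len
            key, value = (tok.strip() for tok in line.split("=", 1))
            if stanza is None:
                continue
            if key in _FILE_KEYS:
                stanza_files.append(value)
            else:
                stanza[key] = value
    close_stanza()
    if not libs:
        warnings.warn(f"{path}: no [LIB] stanzas found; empty library list", stacklevel=2)
    return libs


# ---------------------------------------------------------------------------
# Depth table


def parse_depth_table(
    path: str | Path, contig_set: dict[str, ContigRecord] | None = None
) -> dict[str, float]:
    """Parse a two-column TSV of contig id and mean fold coverage."""
    depths: dict[str, float] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            cid, value = fields[0], fields[1]
            try:
                depth = float(value)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad depth value {value!r}") from None
            if depth <= 0:
                raise FormatError(f"{path}:{lineno}: depth must be > 0")
            if contig_set is not None and cid not in contig_set:
                raise FormatError(f"{path}:{lineno}: unknown contig id {cid!r}")
            depths[cid] = depth
    return depths


def write_depth_table(depths: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, depth in depths.items():
            fh.write(f"{cid}\t{depth:.6g}\n")


# ---------------------------------------------------------------------------
# PairStatus metafile


class PairStatus(str, Enum):
    LINK = "LINK"
    SAME_CONTIG = "SAME_CONTIG"
    ONE_END_UNMAPPED = "ONE_END_UNMAPPED"
    BOTH_UNMAPPED = "BOTH_UNMAPPED"
    MULTIPLY_MAPPED_SUPPRESSED = "MULTIPLY_MAPPED_SUPPRESSED"
    REPEAT_EXCLUDED = "REPEAT_EXCLUDED"
    ORIENTATION_REJECTED = "ORIENTATION_REJECTED"


@dataclass(frozen=True, slots=True)
class PairStatusRecord:
    pair_id: str
    status: PairStatus
    detail: tuple[str, ...] = ()


def write_pair_status(records: Iterable[PairStatusRecord], path: str | Path) -> None:
    """Write one tab-delimited line per pair, in input order."""
    with open(path, "w") as fh:
        for rec in records:
            fields = [rec.pair_id, rec.status.value, *rec.detail]
            fh.write("\t".join(fields) + "\n")


def read_pair_status(path: str | Path) -> list[PairStatusRecord]:
    records = []
    with _open_text(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            records.append(
                PairStatusRecord(fields[0], PairStatus(fields[1]), tuple(fields[2:]))
            )
    return records


# ---------------------------------------------------------------------------
# DOT export


def write_dot(
    graph,
    path: str | Path,
    show_excluded: bool = False,
    highlight_edges: set | None = None,
) -> None:
    """Write the scaffold graph as Graphviz DOT.

    Active edges are solid; below-support (excluded) edges are rendered
    dashed when ``show_excluded`` is set. ``highlight_edges`` (a set of edge
    keys, e.g. those inside bubbles) are drawn bold. Output is deterministic
    (sorted node and edge order)."""
    highlight = highlight_edges or set()

    def edge_line(edge, style: str | None) -> str:
        (c1, e1), (c2, e2) = edge.key
        attrs = [f'label="{e1.value}-{e2.value} w={edge.weight} gap={edge.gap_estimate:.0f}"']
        if style:
            attrs.append(f"style={style}")
        if edge.key in highlight:
            attrs.append("penwidth=2")
        return f'  "{c1}" -- "{c2}" [{", ".join(attrs)}];\n'

    with open(path, "w") as fh:
        fh.write("graph scaffold {\n")
        for cid in sorted(graph.contig_lengths):
            shape = "box" if cid in graph.repeat_flags else "ellipse"
            fh.write(f'  "{cid}" [shape={shape}, label="{cid} ({graph.contig_lengths[cid]})"];\n')
        for edge in sorted(graph.active_edges(), key=lambda e: e.key):
            fh.write(edge_line(edge, None))
        if show_excluded:
            for edge in sorted(graph.excluded_edges(), key=lambda e: e.key):
                fh.write(edge_line(edge, "dashed"))
        fh.write("}\n")
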