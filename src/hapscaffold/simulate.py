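"""Synthetic diploid benchmark universe with per-read truth labels.

Everything the scaffolder consumes — a diploid genome pair, error-free
paired reads, a stringent assembler's contig set, alignments, and a depth
table — is generated here with full provenance, so phasing accuracy can be
measured without external data.

The assembler itself is *simulated, not implemented*: a stringent
overlap-consensus assembler separates haplotypes wherever they differ, and
can extend a haplotype-specific contig into shared sequence by at most one
read length of context. Contigs are therefore derived directly from
variant-block geometry: each variant is padded by ``pad`` bases (default
74 = read length - 1) on both sides; overlapping padded blocks merge into
one heterozygous block realized as a heterotig pair (one contig per
haplotype); the remaining homozygous runs become homotigs, with runs
shorter than ``min_homozygous_run`` absorbed into the flanking blocks (too
short to anchor a separate contig). Reads whose alignment interval spans a
contig boundary are dropped from contig membership and reported unmapped,
mimicking assembler clipping at junctions.

Variant placement is clustered by default: heterozygosity in real diploid
genomes is strongly overdispersed, and a bubble-rich contig set (many
alternating homotigs and heterotig pairs) only arises when heterozygous
tracts alternate with conserved tracts. ``placement="uniform"`` places
variant sites uniformly at random instead; at high rates this merges
essentially the whole genome into a single heterozygous block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .formats import AlnFormat, ContigRecord, LibrarySpec
from .phasing import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

HOMOTIG = "HOMOTIG"
HETEROTIG = "HETEROTIG"


# ---------------------------------------------------------------------------
# Diploid genome


@dataclass(frozen=True, slots=True)
class Variant:
    """One heterozygous site, VCF-style anchored on haplotype A.

    SNP: ref and alt are single differing bases. INS: alt = ref base plus
    the inserted sequence (present only on B). DEL: ref = anchor base plus
    the deleted run (absent from B)."""

    pos_a: int
    kind: str  # SNP | INS | DEL
    ref: str
    alt: str

    @property
    def delta(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(slots=True)
class DiploidGenome:
    hap_a: str
    hap_b: str
    variants: list[Variant]
    het_rate: float
    seed: int

    @property
    def length_a(self) -> int:
        return len(self.hap_a)

    @property
    def length_b(self) -> int:
        return len(self.hap_b)

    def map_a_to_b(self, pos: int) -> int:
        """Lift a haplotype-A coordinate lying outside every variant
        footprint onto haplotype B."""
        delta = 0
        for v in self.variants:
            if v.pos_a + len(v.ref) <= pos:
                delta += v.delta
            else:
                break
        return pos + delta


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def apply_variants(hap_a: str, variants: Sequence[Variant]) -> str:
    """Reconstruct haplotype B from haplotype A plus the variant list."""
    parts: list[str] = []
    prev = 0
    for v in variants:
        parts.append(hap_a[prev : v.pos_a])
        parts.append(v.alt)
        prev = v.pos_a + len(v.ref)
    parts.append(hap_a[prev:])
    return "".join(parts)


def _draw_sites_uniform(rng: np.random.Generator, length: int, het_rate: float) -> np.ndarray:
    n = rng.binomial(length, het_rate)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.choice(length, size=n, replace=False))


def _draw_sites_clustered(
    rng: np.random.Generator,
    length: int,
    het_rate: float,
    hom_tract_mean: float,
    het_tract_mean: float,
) -> np.ndarray:
    local_rate = het_rate * (hom_tract_mean + het_tract_mean) / het_tract_mean
    if local_rate >= 1.0:
        raise ValueError("tract means incompatible with het_rate (local rate >= 1)")
    sites: list[np.ndarray] = []
    pos = 0
    in_hom = True
    while pos < length:
        mean = hom_tract_mean if in_hom else het_tract_mean
        tract = max(1, int(round(rng.exponential(mean))))
        end = min(length, pos + tract)
        if not in_hom:
            hits = np.nonzero(rng.random(end - pos) < local_rate)[0]
            if hits.size:
                sites.append(pos + hits)
        pos = end
        in_hom = not in_hom
    if not sites:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(sites)


def generate_diploid(
    length: int,
    het_rate: float = 0.04,
    indel_fraction: float = 0.1,
    seed: int = 0,
    placement: str = "clustered",
    hap_a: str | None = None,
    hom_tract_mean: float = 400.0,
    het_tract_mean: float = 400.0,
) -> DiploidGenome:
    """A diploid genome pair at the requested heterozygosity rate.

    Haplotype A is seeded random DNA (or a user-supplied sequence);
    haplotype B differs at variant sites, each an indel (1-5 bp, uniform,
    insertion or deletion equally likely) with probability
    ``indel_fraction`` and otherwise a SNP. Variants whose footprint would
    overlap the previous variant are dropped."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0 <= het_rate < 0.5):
        raise ValueError("het_rate must be in [0, 0.5)")
    if not (0 <= indel_fraction <= 0.5):
        raise ValueError("indel_fraction must be in [0, 0.5]")
    if placement not in ("clustered", "uniform"):
        raise ValueError("placement must be 'clustered' or 'uniform'")
    rng = np.random.default_rng(seed)
    if hap_a is None:
        hap_a = _random_dna(rng, length)
    elif len(hap_a) != length:
        raise ValueError("supplied hap_a does not match length")

    if placement == "uniform":
        sites = _draw_sites_uniform(rng, length, het_rate)
    else:
        sites = _draw_sites_clustered(rng, length, het_rate, hom_tract_mean, het_tract_mean)

    variants: list[Variant] = []
    prev_end = -1
    base_order = "ACGT"
    for pos in sites.tolist():
        if pos <= prev_end:
            continue
        ref_base = hap_a[pos]
        if rng.random() < indel_fraction:
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5 and pos + 1 + size <= length:  # deletion from B
                ref = hap_a[pos : pos + 1 + size]
                variants.append(Variant(pos, "DEL", ref, ref[0]))
                prev_end = pos + size
                continue
            ins = _random_dna(rng, size)
            variants.append(Variant(pos, "INS", ref_base, ref_base + ins))
            prev_end = pos
        else:
            alt = base_order[(base_order.index(ref_base) + int(rng.integers(1, 4))) % 4]
            variants.append(Variant(pos, "SNP", ref_base, alt))
            prev_end = pos
    hap_b = apply_variants(hap_a, variants)
    return DiploidGenome(hap_a, hap_b, variants, het_rate, seed)


# ---------------------------------------------------------------------------
# Paired reads


@dataclass(slots=True)
class SimRead:
    """One error-free read pair: a fragment on one haplotype sequenced from
    both ends in innie orientation."""

    id: str
    haplotype: str  # "A" | "B"
    start: int  # fragment start on the origin haplotype
    insert: int
    read_len: int

    def mate_interval(self, mate: int) -> tuple[int, int]:
        if mate == 1:
            return self.start, self.start + self.read_len
        return self.start + self.insert - self.read_len, self.start + self.insert

    def mate_strand(self, mate: int) -> str:
        return "+" if mate == 1 else "-"

    def mate_seq(self, genome: DiploidGenome, mate: int) -> str:
        """The sequence as sequenced (reverse mate is reverse-complemented)."""
        hap = genome.hap_a if self.haplotype == "A" else genome.hap_b
        s, e = self.mate_interval(mate)
        return hap[s:e] if mate == 1 else revcomp(hap[s:e])


def simulate_paired_reads(
    genome: DiploidGenome,
    read_len: int = 75,
    insert_mean: int = 400,
    insert_sd: float = 50.0,
    coverage: float = 40.0,
    seed: int = 0,
    library: str = "lib",
) -> list[SimRead]:
    """Error-free innie pairs at ``coverage``-fold per haplotype.

    Insert sizes are rounded normal(insert_mean, insert_sd) truncated to
    [2*read_len, 2*insert_mean]; fragment starts are uniform."""
    if insert_mean < 2 * read_len:
        raise ValueError("insert_mean must be >= 2 * read_len")
    rng = np.random.default_rng(seed)
    reads: list[SimRead] = []
    for hap_tag, hap in (("A", genome.hap_a), ("B", genome.hap_b)):
        L = len(hap)
        n = int(round(coverage * L / (2 * read_len)))
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=n)),
            2 * read_len,
            2 * insert_mean,
        ).astype(np.int64)
        inserts = np.minimum(inserts, L)
        starts = rng.integers(0, L - inserts + 1)
        for i in range(n):
            reads.append(
                SimRead(
                    id=f"{library}:{hap_tag}:{i:07d}",
                    haplotype=hap_tag,
                    start=int(starts[i]),
                    insert=int(inserts[i]),
                    read_len=read_len,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Truth contigs


@dataclass(slots=True)
class TruthContig:
    id: str
    cls: str  # HOMOTIG | HETEROTIG
    source: str  # "A" | "B" | "BOTH"
    interval_a: Optional[tuple[int, int]]
    interval_b: Optional[tuple[int, int]]
    partner_id: Optional[str]
    sequence: str
    member_read_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class TruthAssembly:
    contigs: dict[str, TruthContig]
    # per-haplotype tiling: (tile start array, tile end array, contig id list)
    tiling_a: tuple[np.ndarray, np.ndarray, list[str]]
    tiling_b: tuple[np.ndarray, np.ndarray, list[str]]
    genome: DiploidGenome

    def contig_set(self) -> dict[str, ContigRecord]:
        return {c.id: ContigRecord(c.id, c.sequence) for c in self.contigs.values()}

    @property
    def homolotig_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for c in self.contigs.values():
            if c.cls == HETEROTIG and c.source == "A":
                pairs.append(tuple(sorted((c.id, c.partner_id))))
        return sorted(pairs)

    @property
    def heterotig_ids(self) -> set[str]:
        return {c.id for c in self.contigs.values() if c.cls == HETEROTIG}


def _merge_blocks(blocks: list[list[int]]) -> list[list[int]]:
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def simulate_truth_contigs(
    genome: DiploidGenome,
    pad: int = 74,
    min_homozygous_run: int = 150,
) -> TruthAssembly:
    """Derive the stringent-assembly contig set from variant-block geometry.

    Returns alternating homotigs (homozygous runs, one contig serving both
    haplotypes) and heterotig pairs (merged heterozygous blocks, one contig
    per haplotype with partner links); the tilings partition each haplotype
    exactly."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if min_homozygous_run <= 2 * pad:
        raise ValueError("min_homozygous_run must exceed 2 * pad")
    LA = genome.length_a
    blocks = [
        [max(0, v.pos_a - pad), min(LA, v.pos_a + len(v.ref) + pad)] for v in genome.variants
    ]
    blocks = _merge_blocks(blocks)
    # absorb homozygous runs too short to anchor a contig
    absorbed: list[list[int]] = []
    for blk in blocks:
        if absorbed and blk[0] - absorbed[-1][1] < min_homozygous_run:
            absorbed[-1][1] = blk[1]
        else:
            absorbed.append(list(blk))
    if absorbed:
        if absorbed[0][0] < min_homozygous_run:
            absorbed[0][0] = 0
        if LA - absorbed[-1][1] < min_homozygous_run:
            absorbed[-1][1] = LA

    contigs: dict[str, TruthContig] = {}
    tiles_a: list[tuple[int, int, str]] = []
    tiles_b: list[tuple[int, int, str]] = []
    n_hom = n_het = 0

    def add_homotig(s: int, e: int) -> None:
        nonlocal n_hom
        if e <= s:
            return
        n_hom += 1
        cid = f"h{n_hom:05d}"
        sb, eb = genome.map_a_to_b(s), genome.map_a_to_b(e)
        contigs[cid] = TruthContig(
            cid, HOMOTIG, "BOTH", (s, e), (sb, eb), None, genome.hap_a[s:e]
        )
        tiles_a.append((s, e, cid))
        tiles_b.append((sb, eb, cid))

    def add_heterotig_pair(s: int, e: int) -> None:
        nonlocal n_het
        n_het += 1
        ida, idb = f"t{n_het:05d}a", f"t{n_het:05d}b"
        sb, eb = genome.map_a_to_b(s), genome.map_a_to_b(e)
        contigs[ida] = TruthContig(
            ida, HETEROTIG, "A", (s, e), None, idb, genome.hap_a[s:e]
        )
        contigs[idb] = TruthContig(
            idb, HETEROTIG, "B", None, (sb, eb), ida, genome.hap_b[sb:eb]
        )
        tiles_a.append((s, e, ida))
        tiles_b.append((sb, eb, idb))

    prev = 0
    for s, e in absorbed:
        add_homotig(prev, s)
        add_heterotig_pair(s, e)
        prev = e
    add_homotig(prev, LA)
    if not contigs:  # zero variants: one homotig spans the genome
        add_homotig(0, LA)

    def tiling(tiles: list[tuple[int, int, str]]):
        tiles = sorted(tiles)
        starts = np.array([t[0] for t in tiles], dtype=np.int64)
        ends = np.array([t[1] for t in tiles], dtype=np.int64)
        ids = [t[2] for t in tiles]
        return starts, ends, ids

    return TruthAssembly(contigs, tiling(tiles_a), tiling(tiles_b), genome)


# ---------------------------------------------------------------------------
# Read-to-contig assignment (exact coordinate transfer)


@dataclass(slots=True)
class Placement:
    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str


@dataclass(slots=True)
class Placements:
    placed: dict[str, Placement]
    unmapped: set[str]
    membership: dict[str, list[str]]  # contig -> read ids
    provenance: dict[str, str]  # read id -> "A" | "B"


def assign_reads(truth: TruthAssembly, reads: Sequence[SimRead]) -> Placements:
    """Lift every read end onto the unique contig containing its full
    alignment interval; boundary-spanning reads are unmapped (clipped)."""
    placed: dict[str, Placement] = {}
    unmapped: set[str] = set()
    membership: dict[str, list[str]] = {c: [] for c in truth.contigs}
    provenance: dict[str, str] = {}

    for hap_tag, tiling in (("A", truth.tiling_a), ("B", truth.tiling_b)):
        starts_arr, ends_arr, ids = tiling
        hap_reads = [r for r in reads if r.haplotype == hap_tag]
        if not hap_reads:
            continue
        n = len(hap_reads)
        r_starts = np.empty(2 * n, dtype=np.int64)
        r_ends = np.empty(2 * n, dtype=np.int64)
        for i, r in enumerate(hap_reads):
            s1, e1 = r.mate_interval(1)
            s2, e2 = r.mate_interval(2)
            r_starts[2 * i], r_ends[2 * i] = s1, e1
            r_starts[2 * i + 1], r_ends[2 * i + 1] = s2, e2
        idx = np.searchsorted(starts_arr, r_starts, side="right") - 1
        idx = np.clip(idx, 0, len(ids) - 1)
        contained = (r_starts >= starts_arr[idx]) & (r_ends <= ends_arr[idx])
        for i, r in enumerate(hap_reads):
            for mate in (1, 2):
                k = 2 * i + (mate - 1)
                rid = f"{r.id}/{mate}"
                provenance[rid] = hap_tag
                if not contained[k]:
                    unmapped.add(rid)
                    continue
                cid = ids[idx[k]]
                tile_start = int(starts_arr[idx[k]])
                placed[rid] = Placement(
                    rid,
                    cid,
                    int(r_starts[k]) - tile_start,
                    int(r_ends[k]) - tile_start,
                    r.mate_strand(mate),
                )
                membership[cid].append(rid)
    return Placements(placed, unmapped, membership, provenance)


def depth_table_from_placements(truth: TruthAssembly, placements: Placements) -> dict[str, float]:
    """Mean fold coverage per contig from actual member reads."""
    table: dict[str, float] = {}
    for cid, contig in truth.contigs.items():
        members = placements.membership.get(cid, ())
        total = sum(
            placements.placed[rid].end - placements.placed[rid].start for rid in members
        )
        depth = total / contig.length if contig.length else 0.0
        if depth > 0:
            table[cid] = depth
    return table


# ---------------------------------------------------------------------------
# Alignment emission


def emit_alignments(
    truth: TruthAssembly,
    reads: Sequence[SimRead],
    placements: Placements,
    path: str | Path,
    format_tag: AlnFormat | str = AlnFormat.SAM,
) -> None:
    """Write the lifted placements in the requested dialect.

    SAM carries proper pair flags and unmapped records; the Bowtie and
    BLAST dialects list mapped ends only (their real producers report no
    unmapped reads)."""
    fmt = AlnFormat(format_tag)
    reads = sorted(reads, key=lambda r: r.id)
    if fmt is AlnFormat.SAM:
        _emit_sam(truth, reads, placements, path)
    elif fmt is AlnFormat.BOWTIE:
        _emit_bowtie(truth, reads, placements, path)
    else:
        _emit_blast(truth, reads, placements, path)


def _emit_sam(truth, reads, placements, path) -> None:
    genome = truth.genome
    lines: list[str] = ["@HD\tVN:1.6\tSO:unknown"]
    for cid, contig in truth.contigs.items():
        lines.append(f"@SQ\tSN:{cid}\tLN:{contig.length}")
    for r in reads:
        p = {m: placements.placed.get(f"{r.id}/{m}") for m in (1, 2)}
        for mate in (1, 2):
            other = 2 if mate == 1 else 1
            flag = 0x1 | (0x40 if mate == 1 else 0x80)
            pl, po = p[mate], p[other]
            if pl is None:
                flag |= 0x4
            elif pl.strand == "-":
                flag |= 0x10
            if po is None:
                flag |= 0x8
            elif po.strand == "-":
                flag |= 0x20
            hap = genome.hap_a if r.haplotype == "A" else genome.hap_b
            s, e = r.mate_interval(mate)
            fwd_seq = hap[s:e]  # forward-reference-strand representation
            if pl is None:
                seq = fwd_seq if mate == 1 else revcomp(fwd_seq)
                lines.append(f"{r.id}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*")
                continue
            rnext, pnext = "*", 0
            if po is not None:
                rnext = "=" if po.contig_id == pl.contig_id else po.contig_id
                pnext = po.start + 1
            lines.append(
                f"{r.id}\t{flag}\t{pl.contig_id}\t{pl.start + 1}\t42\t"
                f"{pl.end - pl.start}M\t{rnext}\t{pnext}\t0\t{fwd_seq}\t*"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _emit_bowtie(truth, reads, placements, path) -> None:
    genome = truth.genome
    lines: list[str] = []
    for r in reads:
        hap = genome.hap_a if r.haplotype == "A" else genome.hap_b
        for mate in (1, 2):
            pl = placements.placed.get(f"{r.id}/{mate}")
            if pl is None:
                continue
            s, e = r.mate_interval(mate)
            fwd_seq = hap[s:e]
            quals = "I" * (e - s)
            lines.append(
                f"{r.id}/{mate}\t{pl.strand}\t{pl.contig_id}\t{pl.start}\t{fwd_seq}\t{quals}\t0\t"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _emit_blast(truth, reads, placements, path) -> None:
    lines: list[str] = []
    for r in reads:
        for mate in (1, 2):
            pl = placements.placed.get(f"{r.id}/{mate}")
            if pl is None:
                continue
            length = pl.end - pl.start
            if pl.strand == "+":
                sstart, send = pl.start + 1, pl.end
            else:
                sstart, send = pl.end, pl.start + 1
            lines.append(
                f"{r.id}/{mate}\t{pl.contig_id}\t100.000\t{length}\t0\t0\t1\t{length}\t"
                f"{sstart}\t{send}\t0.0\t{2 * length}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Whole-universe convenience


@dataclass(slots=True)
class SimLibrary:
    spec: LibrarySpec
    reads: list[SimRead]
    placements: Placements


@dataclass(slots=True)
class SyntheticUniverse:
    genome: DiploidGenome
    truth: TruthAssembly
    libraries: list[SimLibrary]
    depth_table: dict[str, float]
    provenance: dict[str, str]
    read_len: int
    seed: int

    def contig_set(self) -> dict[str, ContigRecord]:
        return self.truth.contig_set()


def build_universe(
    length: int = 500_000,
    het_rate: float = 0.04,
    indel_fraction: float = 0.1,
    coverage: float = 40.0,
    read_len: int = 75,
    inserts: Sequence[tuple[int, float]] = ((400, 50.0), (1000, 100.0)),
    seed: int = 0,
    placement: str = "clustered",
    pad: int = 74,
    min_homozygous_run: int = 150,
) -> SyntheticUniverse:
    """Generate the full benchmark: genome, truth contigs, one read library
    per insert size (ranked in the given order), lifted placements, and a
    depth table computed from the rank-1 library's member reads."""
    genome = generate_diploid(length, het_rate, indel_fraction, seed, placement)
    truth = simulate_truth_contigs(genome, pad, min_homozygous_run)
    libraries: list[SimLibrary] = []
    provenance: dict[str, str] = {}
    for i, (insert_mean, insert_sd) in enumerate(inserts):
        lib_name = f"lib{insert_mean}"
        reads = simulate_paired_reads(
            genome,
            read_len=read_len,
            insert_mean=insert_mean,
            insert_sd=insert_sd,
            coverage=coverage,
            seed=seed + 1_000_003 * (i + 1),
            library=lib_name,
        )
        placements = assign_reads(truth, reads)
        provenance.update(placements.provenance)
        spec = LibrarySpec(
            name=lib_name,
            mean_insert=insert_mean,
            rank=i + 1,
            files=[],
            format_tag=AlnFormat.SAM,
        )
        libraries.append(SimLibrary(spec, reads, placements))
    depth_table = depth_table_from_placements(truth, libraries[0].placements)
    for cid, members in libraries[0].placements.membership.items():
        truth.contigs[cid].member_read_ids = list(members)
    return SyntheticUniverse(genome, truth, libraries, depth_table, provenance, read_len, seed)


def write_universe(universe: SyntheticUniverse, outdir: str | Path) -> dict[str, Path]:
    """Write contigs, per-library SAM, depth table, truth tables and the
    reads-info config into a directory; returns the paths."""
    from .formats import write_depth_table, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["contigs"] = outdir / "contigs.fasta"
    write_fasta(universe.contig_set().values(), paths["contigs"])

    paths["depth"] = outdir / "depth.tsv"
    write_depth_table(universe.depth_table, paths["depth"])

    config_lines = ["max_rd_len=%d" % universe.read_len]
    for lib in universe.libraries:
        sam_path = outdir / f"{lib.spec.name}.sam"
        emit_alignments(universe.truth, lib.reads, lib.placements, sam_path, AlnFormat.SAM)
        paths[lib.spec.name] = sam_path
        config_lines += [
            "[LIB]",
            f"name={lib.spec.name}",
            f"avg_ins={lib.spec.mean_insert}",
            f"rank={lib.spec.rank}",
            f"map_file={sam_path.name}",
            "format=SAM",
        ]
    paths["reads_info"] = outdir / "reads_info.txt"
    paths["reads_info"].write_text("\n".join(config_lines) + "\n")

    paths["truth_contigs"] = outdir / "truth_contigs.tsv"
    with open(paths["truth_contigs"], "w") as fh:
        fh.write("contig\tclass\tsource\tlength\tpartner\n")
        for c in universe.truth.contigs.values():
            fh.write(f"{c.id}\t{c.cls}\t{c.source}\t{c.length}\t{c.partner_id or '-'}\n")

    paths["provenance"] = outdir / "read_provenance.tsv"
    with open(paths["provenance"], "w") as fh:
        for rid in sorted(universe.provenance):
            fh.write(f"{rid}\t{universe.provenance[rid]}\n")
    return paths
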