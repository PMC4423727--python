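"""End-to-end scaffolding pipeline.

Stages, by library rank (ascending; the smallest-insert library should be
rank 1 so local scaffoldings are resolved first):

rank 1   build scaffold graph -> support filter -> repeat flagging ->
         perfect bubbles -> train classifier -> classify imperfect
         bubbles -> accept bubbles -> greedy linking
rank >=2 build that rank's graph -> greedy linking of chains/scaffolds
finally  assemble chains, tally cross-bubble read-pair links (all
         libraries), phase by majority-vote 2-coloring, emit two linear
         haploid scaffolds per chain plus metadata files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import bubbles as bub
from . import classify as cls
from . import formats, graph as gr, phasing as ph

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class PipelineConfig:
    min_support: int = 2
    allow_multimapped: bool = False
    degree_factor: float = 5.0
    depth_factor: float = 3.0
    learner: str = "logistic"
    negative_ratio: float = 1.0
    threshold: float = 0.5
    min_training: int = 10
    min_score: int = 20
    bin_width: float = 1.0
    gap_floor: int = 10
    min_present_edges: int = 2
    allow_partial_flank: bool = True
    seed: int = 0


@dataclass(slots=True)
class LoadedLibrary:
    spec: formats.LibrarySpec
    alignments: formats.AlignmentSet


@dataclass(slots=True)
class PipelineResult:
    config: PipelineConfig
    contig_set: dict[str, formats.ContigRecord]
    depth_table: Optional[dict[str, float]]
    modal_depth: Optional[float]
    rank_graphs: dict[int, gr.ScaffoldGraph]
    statuses: dict[str, list[formats.PairStatusRecord]]
    repeat_flags: set[str]
    perfect_bubbles: list[bub.Bubble]
    candidates: list[tuple[bub.Bubble, bub.PerfectnessScore]]
    classified: list[tuple[bub.Bubble, bub.PerfectnessScore, float]]  # positives
    classification_skipped: bool
    training_set: Optional[cls.TrainingSet]
    model: Optional[cls.ClassifierModel]
    accepted_bubbles: list[bub.Bubble]
    rejected_bubbles: list[bub.Bubble]
    included: ph.IncludedEdgeSet
    chains: list[ph.Chain]
    het_links: dict[frozenset, int]
    phase_groups: list[ph.PhaseGroup]
    coloring: dict[str, int]
    phase_conflicts: int
    singletons: list[str]
    hap1: list[tuple[str, str]]
    hap2: list[tuple[str, str]]
    agp: list[tuple]

    @property
    def trained_heterotigs(self) -> set[str]:
        return {h for b in self.perfect_bubbles for h in b.heterotigs}

    @property
    def classified_heterotigs(self) -> set[str]:
        return {h for b, _, _ in self.classified for h in b.heterotigs}

    @property
    def n_scaffolds(self) -> int:
        return len(self.hap1)


def _build_rank_graph(
    libs: Sequence[LoadedLibrary],
    contig_set: Mapping[str, formats.ContigRecord],
    config: PipelineConfig,
    repeat_contigs: frozenset[str] | set[str] = frozenset(),
) -> tuple[gr.ScaffoldGraph, dict[str, list[formats.PairStatusRecord]]]:
    """One merged graph over all libraries of a rank (edges pooled)."""
    lengths = {cid: rec.length for cid, rec in contig_set.items()}
    merged = gr.ScaffoldGraph(lengths)
    statuses: dict[str, list[formats.PairStatusRecord]] = {}
    for lib in libs:
        g, st = gr.build_graph(
            lib.alignments,
            lib.spec.mean_insert,
            lengths,
            allow_multimapped=config.allow_multimapped,
            repeat_contigs=repeat_contigs,
        )
        statuses[lib.spec.name] = st
        for edge in g.all_edges():
            for gap in edge.gap_samples:
                merged.add_gap_sample(edge.end_a, edge.end_b, gap)
    gr.apply_min_support(merged, config.min_support)
    return merged, statuses


def _classify_candidates(
    candidates: Sequence[tuple[bub.Bubble, bub.PerfectnessScore]],
    model: cls.ClassifierModel,
    contig_set: Mapping[str, formats.ContigRecord],
    depth_table: Optional[dict[str, float]],
    modal_depth: Optional[float],
    min_score: int,
) -> list[tuple[bub.Bubble, bub.PerfectnessScore, float]]:
    positives = []
    fv_cache: dict[frozenset, cls.FeatureVector] = {}
    for bubble, score in candidates:
        pair = frozenset(bubble.heterotigs)
        fv = fv_cache.get(pair)
        if fv is None:
            fv = cls.compute_feature_vector(
                contig_set[bubble.a],
                contig_set[bubble.b],
                depth_table,
                modal_depth,
                min_score,
            )
            fv_cache[pair] = fv
        is_pos, prob = cls.classify_pair(model, fv)
        if is_pos:
            positives.append((bubble, score, prob))
    return positives


def _tally_het_links(
    libraries: Sequence[LoadedLibrary], heterotigs: set[str]
) -> dict[frozenset, int]:
    """Read pairs whose two uniquely mapped ends sit in two different
    heterotigs: the phasing evidence."""
    links: dict[frozenset, int] = {}
    for lib in libraries:
        for pair_id, (p1, p2) in gr.group_pairs(lib.alignments).items():
            if len(p1) != 1 or len(p2) != 1:
                continue
            c1, c2 = p1[0].contig_id, p2[0].contig_id
            if c1 == c2 or c1 not in heterotigs or c2 not in heterotigs:
                continue
            key = frozenset((c1, c2))
            links[key] = links.get(key, 0) + 1
    return links


def run_pipeline(
    contig_set: dict[str, formats.ContigRecord],
    libraries: Sequence[LoadedLibrary],
    depth_table: Optional[dict[str, float]] = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full diploid scaffolding pipeline in memory."""
    config = config or PipelineConfig()
    libraries = sorted(libraries, key=lambda l: (l.spec.rank, l.spec.name))
    ranks = sorted({l.spec.rank for l in libraries})
    if not ranks:
        raise ValueError("no libraries supplied")
    by_rank = {r: [l for l in libraries if l.spec.rank == r] for r in ranks}
    lengths = {cid: rec.length for cid, rec in contig_set.items()}

    # --- rank 1: graph, repeats, bubbles, classification -----------------
    rank1 = ranks[0]
    g1, statuses = _build_rank_graph(by_rank[rank1], contig_set, config)
    repeat_flags = gr.flag_repeats(
        g1,
        depth_table,
        degree_factor=config.degree_factor,
        depth_factor=config.depth_factor,
        bin_width=config.bin_width,
    )
    if repeat_flags:
        logger.info("flagged %d repeat-like contigs; rebuilding rank-%d graph", len(repeat_flags), rank1)
        g1, statuses = _build_rank_graph(
            by_rank[rank1], contig_set, config, repeat_contigs=repeat_flags
        )
        g1.repeat_flags |= repeat_flags

    modal_depth = None
    if depth_table:
        modal_depth = cls.depth_mode(
            depth_table, bin_width=config.bin_width, contig_lengths=lengths
        )

    perfect = bub.find_perfect_bubbles(g1)
    candidates = bub.enumerate_imperfect_bubbles(
        g1,
        perfect,
        min_present_edges=config.min_present_edges,
        allow_partial_flank=config.allow_partial_flank,
    )

    training_set = None
    model = None
    classified: list[tuple[bub.Bubble, bub.PerfectnessScore, float]] = []
    classification_skipped = False
    try:
        training_set = cls.build_training_set(
            perfect,
            g1,
            contig_set,
            depth_table,
            modal_depth,
            negative_ratio=config.negative_ratio,
            seed=config.seed,
            min_training=config.min_training,
            min_score=config.min_score,
        )
        model = cls.train_classifier(
            training_set, config.learner, seed=config.seed, threshold=config.threshold
        )
        classified = _classify_candidates(
            candidates, model, contig_set, depth_table, modal_depth, config.min_score
        )
    except cls.TrainingSetError as exc:
        classification_skipped = True
        logger.warning("classification skipped: %s", exc)

    # --- acceptance and linking ------------------------------------------
    included = ph.IncludedEdgeSet()
    accepted, rejected = ph.accept_bubbles(
        perfect, [b for b, _, _ in classified], included
    )
    included.assert_bubble_purity()

    gaps: dict[gr.EdgeKey, float] = {e.key: e.gap_estimate for e in g1.active_edges()}
    ph.greedy_link(g1, included)
    rank_graphs = {rank1: g1}

    for rank in ranks[1:]:
        g_r, st_r = _build_rank_graph(
            by_rank[rank], contig_set, config, repeat_contigs=repeat_flags
        )
        g_r.repeat_flags |= repeat_flags
        for name, st in st_r.items():
            statuses[name] = st
        for e in g_r.active_edges():
            gaps.setdefault(e.key, e.gap_estimate)
        ph.greedy_link(g_r, included)
        rank_graphs[rank] = g_r

    # --- chains, phasing, output -----------------------------------------
    chains = ph.build_chains(included, gaps)
    accepted_hets = {h for b in accepted for h in b.heterotigs}
    het_links = _tally_het_links(libraries, accepted_hets)
    phase_groups, coloring, conflicts = ph.phase_chains(chains, het_links)

    in_chain = {c for chain in chains for c in chain.contigs}
    singletons = sorted(set(contig_set) - in_chain - repeat_flags)
    hap1, hap2, agp = ph.emit_haplotypes(
        chains, coloring, contig_set, gap_floor=config.gap_floor, singletons=singletons
    )

    return PipelineResult(
        config=config,
        contig_set=contig_set,
        depth_table=depth_table,
        modal_depth=modal_depth,
        rank_graphs=rank_graphs,
        statuses=statuses,
        repeat_flags=repeat_flags,
        perfect_bubbles=perfect,
        candidates=candidates,
        classified=classified,
        classification_skipped=classification_skipped,
        training_set=training_set,
        model=model,
        accepted_bubbles=accepted,
        rejected_bubbles=rejected,
        included=included,
        chains=chains,
        het_links=het_links,
        phase_groups=phase_groups,
        coloring=coloring,
        phase_conflicts=conflicts,
        singletons=singletons,
        hap1=hap1,
        hap2=hap2,
        agp=agp,
    )


# ---------------------------------------------------------------------------
# File-level entry points


def load_libraries(
    reads_info_path: str | Path,
    contig_set: dict[str, formats.ContigRecord],
    base_dir: str | Path | None = None,
) -> list[LoadedLibrary]:
    """Parse the reads-info config and load each library's alignment files."""
    base = Path(base_dir) if base_dir else Path(reads_info_path).parent
    loaded: list[LoadedLibrary] = []
    for spec in formats.parse_reads_info(reads_info_path):
        if not spec.files:
            raise formats.FormatError(f"library {spec.name} lists no alignment files")
        if spec.format_tag is None:
            raise formats.FormatError(
                f"library {spec.name}: cannot infer alignment format; add format="
            )
        alignments: list[formats.ReadAlignment] = []
        unmapped: set[str] = set()
        for f in spec.files:
            fpath = Path(f)
            if not fpath.is_absolute():
                fpath = base / fpath
            aln_set = formats.parse_alignments(fpath, spec.format_tag, contig_set)
            alignments.extend(aln_set.alignments)
            unmapped |= aln_set.unmapped_read_ids
        loaded.append(LoadedLibrary(spec, formats.AlignmentSet(alignments, unmapped)))
    return loaded


def write_outputs(
    result: PipelineResult, outdir: str | Path, show_excluded: bool = True
) -> dict[str, Path]:
    """Write all pipeline outputs (deterministic content for fixed inputs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["hap1"] = outdir / "haplotype1.fasta"
    paths["hap2"] = outdir / "haplotype2.fasta"
    formats.write_fasta(result.hap1, paths["hap1"])
    formats.write_fasta(result.hap2, paths["hap2"])

    paths["agp"] = outdir / "scaffolds.tsv"
    with open(paths["agp"], "w") as fh:
        fh.write("scaffold\thap\tposition\tcomponent\torient_or_len\n")
        for row in result.agp:
            fh.write("\t".join(str(x) for x in row) + "\n")

    paths["phase_groups"] = outdir / "phase_groups.tsv"
    with open(paths["phase_groups"], "w") as fh:
        fh.write("group\tcomplement\tchain\tmembers\n")
        for g in result.phase_groups:
            fh.write(f"{g.id}\t{g.complement_id}\t{g.chain_id}\t{','.join(g.members)}\n")

    paths["bubbles"] = outdir / "bubbles.tsv"
    with open(paths["bubbles"], "w") as fh:
        fh.write("c1\ta\tb\tc2\tkind\tmissing\tconflicts\tsupport\n")
        for b in result.perfect_bubbles:
            fh.write(f"{b.c1}\t{b.a}\t{b.b}\t{b.c2}\tperfect\t0\t0\t-\n")
        for b, s, prob in result.classified:
            fh.write(
                f"{b.c1 or '-'}\t{b.a}\t{b.b}\t{b.c2 or '-'}\tclassified\t"
                f"{s.missing_edges}\t{s.conflict_count}\t{s.total_support}\n"
            )

    for name, st in result.statuses.items():
        p = outdir / f"pair_status.{name}.tsv"
        formats.write_pair_status(st, p)
        paths[f"pair_status.{name}"] = p

    first_rank = min(result.rank_graphs)
    paths["dot"] = outdir / "scaffold_graph.dot"
    formats.write_dot(
        result.rank_graphs[first_rank],
        paths["dot"],
        show_excluded=show_excluded,
        highlight_edges={k for b in result.accepted_bubbles for k in b.edges},
    )

    if result.training_set is not None:
        paths["training"] = outdir / "training_set.tsv"
        cls.write_training_tsv(result.training_set, paths["training"])
    return paths


def run_from_files(
    contig_fasta: str | Path,
    reads_info: str | Path,
    depth_table_path: str | Path | None = None,
    outdir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """File-level convenience wrapper: parse inputs, run, optionally write."""
    contig_set = formats.parse_fasta(contig_fasta)
    libraries = load_libraries(reads_info, contig_set)
    depth_table = (
        formats.parse_depth_table(depth_table_path, contig_set)
        if depth_table_path
        else None
    )
    result = run_pipeline(contig_set, libraries, depth_table, config)
    if outdir is not None:
        write_outputs(result, outdir)
    return result
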