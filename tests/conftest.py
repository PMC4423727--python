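"""Shared fixtures: in-memory library adapters and the session-scoped
synthetic benchmark (500 kb diploid, het 0.04, two 40x libraries) that the
end-to-end tests share."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

import hapscaffold as hs
from hapscaffold import formats, pipeline, simulate

BENCH_SEED = 11
BENCH_LENGTH = 500_000
BENCH_COVERAGE = 40.0
BENCH_INSERTS = ((400, 50.0), (1000, 100.0))


def universe_to_libraries(universe: simulate.SyntheticUniverse) -> list[pipeline.LoadedLibrary]:
    """Adapt a simulated universe's placements into in-memory alignment sets
    (bypassing file I/O where a test doesn't exercise it)."""
    libs = []
    for lib in universe.libraries:
        alns = [
            formats.ReadAlignment(p.read_id, p.contig_id, p.start, p.end, p.strand)
            for p in sorted(lib.placements.placed.values(), key=lambda p: p.read_id)
        ]
        libs.append(
            pipeline.LoadedLibrary(
                lib.spec, formats.AlignmentSet(alns, set(lib.placements.unmapped))
            )
        )
    return libs


@pytest.fixture(scope="session")
def small_universe():
    """A quick 60 kb universe for unit-level end-to-end checks."""
    return simulate.build_universe(length=60_000, coverage=20, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench_universe():
    """The full benchmark universe: 500 kb diploid at het 0.04 with 40x
    400-bp and 40x 1000-bp error-free 75-bp paired-read libraries."""
    return simulate.build_universe(
        length=BENCH_LENGTH,
        het_rate=0.04,
        indel_fraction=0.1,
        coverage=BENCH_COVERAGE,
        inserts=BENCH_INSERTS,
        seed=BENCH_SEED,
    )


@pytest.fixture(scope="session")
def bench_pipeline(bench_universe, tmp_path_factory):
    """The full pipeline on the benchmark universe, run through real files
    (FASTA + SAM round trip) exactly as a user would."""
    outdir = tmp_path_factory.mktemp("bench")
    paths = simulate.write_universe(bench_universe, outdir / "universe")
    contigs = formats.parse_fasta(paths["contigs"])
    libs = pipeline.load_libraries(paths["reads_info"], contigs)
    depth = formats.parse_depth_table(paths["depth"], contigs)
    result = pipeline.run_pipeline(
        contigs, libs, depth, pipeline.PipelineConfig(seed=BENCH_SEED)
    )
    pipeline.write_outputs(result, outdir / "scaffolds")
    return result
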