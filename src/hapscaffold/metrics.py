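"""Diploid scaffolding quality metrics computed from truth labels.

Four metrics, all derived from knowing which synthetic haplotype (A or B)
each read came from:

* contig sequencing depth — mean reads per position; homotigs should sit at
  diploid depth, heterotigs at haploid depth;
* contig homogeneity — the fraction of a contig's member reads deriving
  from haplotype A; heterotigs should peak at 0 and 1, homotigs at 0.5;
* phase-group homogeneity — the read-weighted haplotype-A fraction over all
  contigs phased together; accurate groups cluster at 0 and 1;
* heterogeneity between complementary phase groups — the absolute
  difference of the two groups' homogeneities; accurate phasing clusters
  at 1. (The absolute value makes the metric invariant to which group is
  labelled first.)

All analyses consider only contigs longer than 100 bases. A
precision/recall-style summary of heterotig classification against a depth
cutoff (default 1.5x the modal depth) mirrors the headline check that
classified heterotigs should have haploid, not diploid, depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .phasing import PhaseGroup

MIN_CONTIG_LEN = 100  # metrics ignore contigs of <= this many bases


def contig_depth(contig_length: int, aligned_lengths: Iterable[int]) -> float:
    """Mean fold coverage: summed aligned bases over contig length."""
    if contig_length <= 0:
        raise ValueError("contig length must be > 0")
    return sum(aligned_lengths) / contig_length


def contig_homogeneity(member_reads: Sequence[str], provenance: Mapping[str, str]) -> float:
    """Fraction of a contig's member reads deriving from haplotype A."""
    if not member_reads:
        raise ValueError("contig has no member reads")
    n_a = sum(1 for rid in member_reads if provenance[rid] == "A")
    return n_a / len(member_reads)


def phase_group_homogeneity(
    group_members: Iterable[str],
    membership: Mapping[str, Sequence[str]],
    provenance: Mapping[str, str],
) -> float:
    """Read-weighted haplotype-A fraction across a group of phased contigs."""
    n_a = n_total = 0
    for cid in group_members:
        for rid in membership.get(cid, ()):
            n_total += 1
            if provenance[rid] == "A":
                n_a += 1
    if n_total == 0:
        raise ValueError("phase group has no member reads")
    return n_a / n_total


def phase_pair_heterogeneity(
    group_m: PhaseGroup,
    group_n: PhaseGroup,
    membership: Mapping[str, Sequence[str]],
    provenance: Mapping[str, str],
) -> float:
    """|hom_phase(m) - hom_phase(n)| for a complementary group pair."""
    if group_m.complement_id != group_n.id or group_n.complement_id != group_m.id:
        raise ValueError(f"groups {group_m.id} and {group_n.id} are not complementary")
    hm = phase_group_homogeneity(group_m.members, membership, provenance)
    hn = phase_group_homogeneity(group_n.members, membership, provenance)
    return abs(hm - hn)


@dataclass(frozen=True, slots=True)
class ClassificationSummary:
    precision_fraction: Optional[float]  # classified heterotigs below the cutoff
    recall_fraction: Optional[float]  # below-cutoff contigs that were classified
    n_classified: int
    n_classified_below: int
    n_below: int
    depth_threshold: float


def classification_summary(
    depths: Mapping[str, float],
    contig_lengths: Mapping[str, int],
    classified_heterotigs: Iterable[str],
    depth_threshold: float,
) -> ClassificationSummary:
    """Heterotig-classification quality against a depth cutoff.

    Precision-like: the fraction of classified heterotigs whose depth lies
    below the cutoff (true heterotigs have haploid depth). Recall-like: the
    fraction of below-cutoff contigs that were classified. Contigs of
    <= 100 bases are excluded; degenerate denominators yield None."""
    eligible = {
        cid
        for cid, ln in contig_lengths.items()
        if ln > MIN_CONTIG_LEN and cid in depths
    }
    classified = {c for c in classified_heterotigs if c in eligible}
    below = {c for c in eligible if depths[c] < depth_threshold}
    classified_below = classified & below
    precision = len(classified_below) / len(classified) if classified else None
    recall = len(classified_below) / len(below) if below else None
    return ClassificationSummary(
        precision,
        recall,
        len(classified),
        len(classified_below),
        len(below),
        depth_threshold,
    )


# ---------------------------------------------------------------------------
# Report assembly and density export


@dataclass(slots=True)
class MetricsReport:
    contig_rows: list[tuple]  # (contig, length, depth, homogeneity, label)
    group_homogeneity: dict[str, float]
    pair_heterogeneity: dict[tuple[str, str], float]
    summary: ClassificationSummary


def build_report(
    contig_lengths: Mapping[str, int],
    depths: Mapping[str, float],
    membership: Mapping[str, Sequence[str]],
    provenance: Mapping[str, str],
    phase_groups: Sequence[PhaseGroup],
    trained_heterotigs: Iterable[str] = (),
    classified_heterotigs: Iterable[str] = (),
    depth_threshold: float | None = None,
) -> MetricsReport:
    """All four metrics plus the classification summary in one pass.

    ``depth_threshold`` defaults to 1.5x the modal depth of eligible
    contigs. Each contig row is labelled trained / classified / other."""
    trained = set(trained_heterotigs)
    classified = set(classified_heterotigs)

    if depth_threshold is None:
        from .classify import depth_mode

        eligible_depths = {
            c: d
            for c, d in depths.items()
            if contig_lengths.get(c, 0) > MIN_CONTIG_LEN
        }
        depth_threshold = 1.5 * depth_mode(eligible_depths)

    rows: list[tuple] = []
    for cid in sorted(contig_lengths):
        ln = contig_lengths[cid]
        if ln <= MIN_CONTIG_LEN:
            continue
        members = membership.get(cid, ())
        if not members:
            continue
        label = "trained" if cid in trained else "classified" if cid in classified else "other"
        rows.append(
            (cid, ln, depths.get(cid, 0.0), contig_homogeneity(members, provenance), label)
        )

    group_hom: dict[str, float] = {}
    pair_het: dict[tuple[str, str], float] = {}
    by_id = {g.id: g for g in phase_groups}
    for g in phase_groups:
        try:
            group_hom[g.id] = phase_group_homogeneity(g.members, membership, provenance)
        except ValueError:
            continue
    for g in phase_groups:
        comp = by_id.get(g.complement_id)
        if comp is None or g.id > comp.id:
            continue
        if g.id in group_hom and comp.id in group_hom:
            pair_het[(g.id, comp.id)] = abs(group_hom[g.id] - group_hom[comp.id])

    summary = classification_summary(
        depths, contig_lengths, trained | classified, depth_threshold
    )
    return MetricsReport(rows, group_hom, pair_het, summary)


def density_histogram(values: Sequence[float], bin_width: float) -> list[tuple[float, int]]:
    """(bin center, count) pairs; bins centered on multiples of bin_width."""
    import math

    counts: dict[int, int] = {}
    for v in values:
        k = math.floor(v / bin_width + 0.5)
        counts[k] = counts.get(k, 0) + 1
    return [(k * bin_width, counts[k]) for k in sorted(counts)]


def write_report(report: MetricsReport, outdir, bin_width_depth: float = 2.0) -> None:
    """Export the report as TSVs (per-contig table plus density histograms)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "contig_metrics.tsv", "w") as fh:
        fh.write("contig\tlength\tdepth\thomogeneity\tlabel\n")
        for row in report.contig_rows:
            fh.write("%s\t%d\t%.4f\t%.4f\t%s\n" % row)
    with open(outdir / "phase_group_homogeneity.tsv", "w") as fh:
        fh.write("group\thomogeneity\n")
        for gid, hom in sorted(report.group_homogeneity.items()):
            fh.write(f"{gid}\t{hom:.4f}\n")
    with open(outdir / "phase_pair_heterogeneity.tsv", "w") as fh:
        fh.write("group_m\tgroup_n\theterogeneity\n")
        for (gm, gn), het in sorted(report.pair_heterogeneity.items()):
            fh.write(f"{gm}\t{gn}\t{het:.4f}\n")
    for name, values, width in (
        ("depth_density", [r[2] for r in report.contig_rows], bin_width_depth),
        ("homogeneity_density", [r[3] for r in report.contig_rows], 0.05),
        ("group_homogeneity_density", list(report.group_homogeneity.values()), 0.05),
        ("heterogeneity_density", list(report.pair_heterogeneity.values()), 0.05),
    ):
        with open(outdir / f"{name}.tsv", "w") as fh:
            fh.write("value\tcount\n")
            for center, count in density_histogram(values, width):
                fh.write(f"{center:.4f}\t{count}\n")


def plot_report(report: MetricsReport, outdir, fmt: str = "png") -> None:
    """Render the four density plots (depth, contig homogeneity, phase-group
    homogeneity, heterogeneity) as image files."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panels = [
        ("contig_depth", [r[2] for r in report.contig_rows], "sequencing depth (x)"),
        ("contig_homogeneity", [r[3] for r in report.contig_rows], "haplotype-A read fraction"),
        (
            "phase_group_homogeneity",
            list(report.group_homogeneity.values()),
            "haplotype-A read fraction",
        ),
        (
            "phase_pair_heterogeneity",
            list(report.pair_heterogeneity.values()),
            "|hom(m) - hom(n)|",
        ),
    ]
    for name, values, xlabel in panels:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        if values:
            ax.hist(values, bins=40)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("contigs" if name.startswith("contig") else "groups")
        fig.tight_layout()
        fig.savefig(outdir / f"{name}.{fmt}", dpi=120)
        plt.close(fig)
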