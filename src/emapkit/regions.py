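"""Genome-order analytics: linkage masking and suppressor-region detection.

Two deletions close together on the same chromosome rarely yield viable
double mutants for purely meiotic reasons, so nearby pairs (< 100 kb by
default) are masked rather than scored. Conversely, an *undeclared
suppressor* in one screen strain produces the opposite artifact: a block of
consecutive genes around the suppressor locus all show strong negative S
scores with that one distant strain, because selecting their linked array
marker evicts the suppressor. This module masks linked pairs, orders the
matrix along the genome, scans for such uniformly interacting regions, and
calibrates the scan against a gene-to-locus permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    GeneLocus,
    InteractionMatrix,
    Thresholds,
    ValidationError,
    get_logger,
    locus_index,
)

__all__ = [
    "SuppressorRegionCall",
    "chromosome_order",
    "order_by_genome",
    "mask_linked_pairs",
    "detect_regions",
    "region_null_rate",
    "genome_heatmap",
]

logger = get_logger("emapkit.regions")


@dataclass(frozen=True)
class SuppressorRegionCall:
    """A contiguous chromosomal region uniformly interacting with one distant gene."""

    distant_gene: str
    chromosome: str
    region_start_bp: int
    region_end_bp: int
    member_genes: tuple[str, ...]
    n_below_cut: int
    min_S: float
    median_S: float

    @property
    def run_length(self) -> int:
        return len(self.member_genes)


def chromosome_order(loci: Sequence[GeneLocus]) -> list[str]:
    """Chromosome labels in order of first appearance in the locus table."""
    return list(dict.fromkeys(l.chromosome for l in loci))


def _genome_sorted(genes: Sequence[str], loci: Sequence[GeneLocus]) -> list[str]:
    by_id = locus_index(loci)
    missing = [g for g in genes if g not in by_id]
    if missing:
        raise ValidationError(f"genes without locus: {missing[:5]}")
    chrom_rank = {c: k for k, c in enumerate(chromosome_order(loci))}
    return sorted(genes, key=lambda g: (chrom_rank[by_id[g].chromosome], by_id[g].start_bp, g))


def order_by_genome(m: InteractionMatrix, loci: Sequence[GeneLocus]) -> InteractionMatrix:
    """Permute the matrix into genome order (chromosome by chromosome,
    left arm to right arm by start coordinate)."""
    target = _genome_sorted(m.genes, loci)
    return m.reordered([m.index_of(g) for g in target])


def mask_linked_pairs(
    m: InteractionMatrix, loci: Sequence[GeneLocus], linkage_bp: int = 100_000
) -> InteractionMatrix:
    """Flag same-chromosome pairs closer than ``linkage_bp`` as MASKED_LINKED.

    Distance is between start coordinates; the bound is strict (< linkage_bp
    masks, exactly linkage_bp does not). Pairs on different chromosomes are
    never masked. Masked pairs are excluded from significance counts,
    correlations and region calls downstream.
    """
    by_id = locus_index(loci)
    out = m.copy()
    chrom = np.array([by_id[g].chromosome for g in m.genes], dtype=object)
    start = np.array([by_id[g].start_bp for g in m.genes], dtype=np.int64)
    same = chrom[:, None] == chrom[None, :]
    close = np.abs(start[:, None] - start[None, :]) < linkage_bp
    mask = same & close
    np.fill_diagonal(mask, False)
    out.flags["MASKED_LINKED"] |= mask
    logger.debug("mask_linked_pairs: masked %d pair(s)", int(mask.sum()) // 2)
    return out


def detect_regions(
    m: InteractionMatrix,
    loci: Sequence[GeneLocus],
    th: Thresholds,
    exclude_hyper: set[str] | None = None,
    missing_breaks_run: bool = False,
) -> list[SuppressorRegionCall]:
    """Scan every distant gene for chromosomal runs of strong negative S.

    For each candidate distant gene g (hyper-interactors excluded), each
    chromosome is traversed in genome order; maximal runs of consecutive
    genes whose unmasked S[g, ·] falls below ``th.region_s_cut`` are
    collected, and runs of at least ``th.region_min_run`` genes become calls.
    Missing/masked cells do not break a run by default (a failed cross should
    not split a real region) but also do not count toward its length; set
    ``missing_breaks_run`` to make them break. Runs that touch g's own
    linkage neighborhood (within ``th.linkage_bp`` of g on its chromosome)
    are discarded — those are linkage, not suppressor, signal. The matrix is
    re-ordered internally, so input row order is irrelevant.
    """
    exclude_hyper = exclude_hyper or set()
    mo = order_by_genome(m, loci)
    by_id = locus_index(loci)
    genes = mo.genes
    chroms = [by_id[g].chromosome for g in genes]
    starts = [by_id[g].start_bp for g in genes]
    usable = mo.usable

    calls: list[SuppressorRegionCall] = []
    for gi, g in enumerate(genes):
        if g in exclude_hyper:
            continue
        g_chrom, g_start = chroms[gi], starts[gi]
        # walk each chromosome collecting runs of qualifying genes
        run: list[int] = []

        def flush() -> None:
            if len(run) >= th.region_min_run:
                members = [genes[k] for k in run]
                in_linkage = any(
                    chroms[k] == g_chrom and abs(starts[k] - g_start) < th.linkage_bp
                    for k in run
                )
                if not in_linkage:
                    svals = np.array([mo.S[gi, k] for k in run])
                    calls.append(
                        SuppressorRegionCall(
                            distant_gene=g,
                            chromosome=chroms[run[0]],
                            region_start_bp=starts[run[0]],
                            region_end_bp=int(by_id[members[-1]].end_bp),
                            member_genes=tuple(members),
                            n_below_cut=len(run),
                            min_S=float(svals.min()),
                            median_S=float(np.median(svals)),
                        )
                    )
            run.clear()

        prev_chrom = None
        for k in range(len(genes)):
            if chroms[k] != prev_chrom:
                flush()
                prev_chrom = chroms[k]
            if k == gi:
                # the distant gene itself is not data on its own chromosome
                if missing_breaks_run:
                    flush()
                continue
            if not usable[gi, k]:
                if missing_breaks_run:
                    flush()
                continue
            if mo.S[gi, k] < th.region_s_cut:
                run.append(k)
            else:
                flush()
        flush()

    calls.sort(key=lambda c: (-c.run_length, c.min_S, c.distant_gene))
    if calls:
        logger.debug("detect_regions: %d call(s)", len(calls))
    return calls


def region_null_rate(
    m: InteractionMatrix,
    loci: Sequence[GeneLocus],
    th: Thresholds,
    permutations: int = 200,
    seed: int = 0,
    exclude_hyper: set[str] | None = None,
) -> dict:
    """Positional-chance calibration of the region scan.

    Permutes the gene-to-locus assignment ``permutations`` times, re-runs
    detection on each permuted genome, and reports the mean and 95th
    percentile of call counts — how many calls pure chromosome geometry
    would produce with these S scores. Deterministic for a fixed seed.
    """
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")
    rng = np.random.default_rng(seed)
    by_id = locus_index(loci)
    base = [by_id[g] for g in m.genes]
    counts = []
    for _ in range(permutations):
        perm = rng.permutation(len(base))
        permuted = [
            GeneLocus(
                gene_id=m.genes[i],
                chromosome=base[perm[i]].chromosome,
                start_bp=base[perm[i]].start_bp,
                end_bp=base[perm[i]].end_bp,
            )
            for i in range(len(base))
        ]
        # re-derive the linkage mask for the permuted genome
        m_perm = m.copy()
        m_perm.flags["MASKED_LINKED"][:] = False
        m_perm = mask_linked_pairs(m_perm, permuted, th.linkage_bp)
        counts.append(len(detect_regions(m_perm, permuted, th, exclude_hyper)))
    counts_arr = np.array(counts)
    return {
        "mean": float(counts_arr.mean()),
        "p95": float(np.percentile(counts_arr, 95)),
        "max": int(counts_arr.max()),
        "counts": counts,
    }


def genome_heatmap(
    m: InteractionMatrix,
    loci: Sequence[GeneLocus],
    path: str | Path,
    vmax: float = 6.0,
) -> InteractionMatrix:
    """Write the genome-ordered matrix as TSV + PNG heat map.

    Masked-linked cells are drawn in neutral grey (they cluster along the
    diagonal in same-chromosome blocks whose size tracks the number of genes
    per chromosome); chromosome boundaries are drawn as black lines. Returns
    the ordered matrix (whose TSV is written next to the image).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    from .core_io import write_matrix

    path = Path(path)
    mo = order_by_genome(m, loci)
    write_matrix(mo, path.with_suffix(".tsv"))

    by_id = locus_index(loci)
    chroms = [by_id[g].chromosome for g in mo.genes]
    bounds = [k for k in range(1, len(chroms)) if chroms[k] != chroms[k - 1]]

    cmap = LinearSegmentedColormap.from_list("emap", ["#00a000", "#000000", "#ff2020"])
    cmap.set_bad("#bbbbbb")
    shown = np.ma.masked_where(
        mo.flags["MASKED_LINKED"] | ~np.isfinite(mo.S), mo.S
    )
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(shown, cmap=cmap, vmin=-vmax, vmax=vmax, interpolation="nearest")
    for b in bounds:
        ax.axhline(b - 0.5, color="black", lw=0.6)
        ax.axvline(b - 0.5, color="black", lw=0.6)
    ax.set_title("S scores in genome order (grey = linkage-masked)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return mo
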