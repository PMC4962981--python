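"""Profile correlations, significance classes, clustering and curve analytics.

Two genes that interact with the same partners in the same way likely act in
the same process; the Pearson correlation of their S-score profiles is the
screen's similarity measure. This module computes the correlation matrix,
partitions pairs into the significance classes of the S-vs-correlation
scatter (significant S only, significant correlation only, both, neither),
builds the windowed summary curves along the correlation axis, clusters the
correlation matrix, and provides the descriptive utilities (hyper-interactor
detection, class-by-class frequency cross-tabs, set-overlap accounting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import GeneLocus, InteractionMatrix, Thresholds, ValidationError, get_logger

__all__ = [
    "CorrelationMatrix",
    "PairClass",
    "profile_correlations",
    "classify_pairs",
    "high_correlation_pairs",
    "s_vs_correlation_curve",
    "pos_neg_ratio_curve",
    "hierarchical_cluster",
    "hyper_interactors",
    "class_crosstab",
    "set_overlap",
]

logger = get_logger("emapkit.network")

CATEGORIES = ("S_ONLY", "CORR_ONLY", "BOTH", "NEITHER")


class CorrelationMatrix:
    """Pairwise profile-similarity scores with P values.

    ``r`` holds Pearson correlations (NaN diagonal and wherever fewer than 3
    shared profile positions exist), ``P`` their two-sided t-transform P
    values, ``n_used`` the profile length behind each correlation.
    """

    def __init__(self, genes: Sequence[str], r: np.ndarray, P: np.ndarray, n_used: np.ndarray) -> None:
        self.genes = list(genes)
        n = len(self.genes)
        self.r = np.asarray(r, dtype=float)
        self.P = np.asarray(P, dtype=float)
        self.n_used = np.asarray(n_used, dtype=int)
        for mat in (self.r, self.P):
            if mat.shape != (n, n):
                raise ValidationError("correlation tables must be square over the gene list")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.r), initial=0.0) > 1 + 1e-9:
                raise ValidationError("|r| must not exceed 1")
        np.fill_diagonal(self.r, np.nan)
        np.fill_diagonal(self.P, np.nan)

    @property
    def n(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        return self.genes.index(gene)


@dataclass(frozen=True)
class PairClass:
    """One gene pair's significance category in the S-vs-correlation plane."""

    pair: tuple[str, str]
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


def profile_correlations(m: InteractionMatrix) -> CorrelationMatrix:
    """Pearson correlation of every two genes' interaction profiles.

    The profile of gene i is its row of S scores over partners k; for the
    pair (i, j) the positions k ∈ {i, j} and any flagged cells are excluded,
    so a single strong mutual interaction cannot inflate its own profile
    correlation. Missing values are handled pairwise-complete. P values come
    from the t transform with ``n_used − 2`` degrees of freedom.
    """
    n = m.n
    S = np.where(m.usable, m.S, np.nan)
    r = np.full((n, n), np.nan)
    P = np.full((n, n), np.nan)
    n_used = np.zeros((n, n), dtype=int)
    for i in range(n):
        xi = S[i]
        for j in range(i + 1, n):
            yj = S[j]
            ok = np.isfinite(xi) & np.isfinite(yj)
            ok[i] = ok[j] = False
            k = int(ok.sum())
            n_used[i, j] = n_used[j, i] = k
            if k < 3:
                continue
            x, y = xi[ok], yj[ok]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            rv = float(np.dot(x - x.mean(), y - y.mean()) / (k * sx * sy))
            rv = min(1.0, max(-1.0, rv))
            r[i, j] = r[j, i] = rv
            # t transform: t = r sqrt((k-2)/(1-r^2))
            if abs(rv) >= 1.0:
                pv = 0.0
            else:
                t = rv * np.sqrt((k - 2) / (1 - rv**2))
                pv = float(2 * stats.t.sf(abs(t), df=k - 2))
            P[i, j] = P[j, i] = pv
    return CorrelationMatrix(m.genes, r, P, n_used)


def classify_pairs(
    m: InteractionMatrix, c: CorrelationMatrix, th: Thresholds
) -> list[PairClass]:
    """Assign each scored pair to the 2×2 significance grid.

    S significant iff P_s ≤ th.p_s; correlation significant iff
    P_corr ≤ th.p_corr (boundary values are significant). Pairs flagged in
    the interaction matrix are skipped.
    """
    if list(m.genes) != list(c.genes):
        raise ValidationError("matrices must share gene order")
    out = []
    iu = zip(*np.triu_indices(m.n, k=1))
    for i, j in iu:
        if not m.usable[i, j]:
            continue
        s_sig = np.isfinite(m.P[i, j]) and m.P[i, j] <= th.p_s
        c_sig = np.isfinite(c.P[i, j]) and c.P[i, j] <= th.p_corr
        cat = ("BOTH" if c_sig else "S_ONLY") if s_sig else ("CORR_ONLY" if c_sig else "NEITHER")
        out.append(PairClass((m.genes[i], m.genes[j]), cat))
    return out


def high_correlation_pairs(
    c: CorrelationMatrix, cut: float = 0.5
) -> list[tuple[tuple[str, str], float]]:
    """Pairs with r strictly above ``cut``, sorted by r descending."""
    iu = np.triu_indices(c.n, k=1)
    out = [
        ((c.genes[i], c.genes[j]), float(c.r[i, j]))
        for i, j in zip(*iu)
        if np.isfinite(c.r[i, j]) and c.r[i, j] > cut
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def _qualifying_pairs(
    m: InteractionMatrix, c: CorrelationMatrix, th: Thresholds
) -> tuple[np.ndarray, np.ndarray]:
    """(r, S) of pairs with finite correlation and significant S, sorted by r."""
    iu = np.triu_indices(m.n, k=1)
    ok = (
        m.usable[iu]
        & np.isfinite(c.r[iu])
        & np.isfinite(m.P[iu])
        & (m.P[iu] <= th.p_s)
    )
    r, s = c.r[iu][ok], m.S[iu][ok]
    order = np.argsort(r, kind="stable")
    return r[order], s[order]


@dataclass(frozen=True)
class CurvePoint:
    mean_r: float
    value: float
    n: int
    partial: bool = False


def _windows(n: int, size: int, mode: str) -> Iterable[tuple[int, int, bool]]:
    if mode == "chunk":
        for lo in range(0, n, size):
            hi = min(lo + size, n)
            yield lo, hi, hi - lo < size
    elif mode == "rolling":
        if n < size:
            yield 0, n, True
        else:
            for lo in range(0, n - size + 1):
                yield lo, lo + size, False
    else:
        raise ValidationError(f"unknown window mode {mode!r}")


def s_vs_correlation_curve(
    m: InteractionMatrix, c: CorrelationMatrix, th: Thresholds, mode: str = "chunk"
) -> list[CurvePoint]:
    """Mean significant S as a function of profile correlation.

    Qualifying pairs (finite r, S significant at ``th.p_s``) are sorted by r
    and summarized in windows of ``th.window`` values — consecutive
    non-overlapping chunks by default, or sliding windows (``mode="rolling"``).
    A trailing window shorter than ``th.window`` is flagged partial.
    """
    r, s = _qualifying_pairs(m, c, th)
    if r.size == 0:
        return []
    return [
        CurvePoint(float(r[lo:hi].mean()), float(s[lo:hi].mean()), hi - lo, part)
        for lo, hi, part in _windows(r.size, th.window, mode)
    ]


def pos_neg_ratio_curve(
    m: InteractionMatrix, c: CorrelationMatrix, th: Thresholds, mode: str = "chunk"
) -> list[CurvePoint]:
    """Per window, (# significant positive S) / (# significant negative S).

    The ratio is NaN (not infinity) for windows without negative scores.
    """
    r, s = _qualifying_pairs(m, c, th)
    if r.size == 0:
        return []
    out = []
    for lo, hi, part in _windows(r.size, th.window, mode):
        w = s[lo:hi]
        n_pos, n_neg = int((w > 0).sum()), int((w < 0).sum())
        ratio = n_pos / n_neg if n_neg else float("nan")
        out.append(CurvePoint(float(r[lo:hi].mean()), ratio, hi - lo, part))
    return out


def hierarchical_cluster(c: CorrelationMatrix) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering on distance 1 − r.

    Missing correlations are treated as r = 0 (no evidence of similarity).
    Genes are presorted by gene_id before linkage so the leaf order is a
    deterministic function of the correlation values alone. Returns
    ``(leaf_order, linkage_matrix)`` (scipy linkage format over the presorted
    gene list).
    """
    if c.n < 3 or not np.isfinite(c.r).any():
        raise ValidationError("need >= 3 genes with correlations to cluster")
    order = sorted(range(c.n), key=lambda i: c.genes[i])
    genes = [c.genes[i] for i in order]
    r = c.r[np.ix_(order, order)]
    d = 1.0 - np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return [genes[i] for i in leaves], Z


def hyper_interactors(
    m: InteractionMatrix, th: Thresholds
) -> tuple[set[str], dict[str, int]]:
    """Genes with far more significant interactions than the average gene.

    Counts significant (P ≤ th.p_s) unflagged pairs per gene. A gene is
    flagged when its count exceeds mean + ``th.hyper_sd`` standard
    deviations of the per-gene counts AND covers at least
    ``th.hyper_min_frac`` of its possible partners. The fraction condition
    encodes what a hyper-interactor is — a strain interacting throughout the
    map (a third or more of its partners), as opposed to ordinary count
    fluctuations or one compact chromosomal artifact block (at most a
    linkage window plus the screen's base interaction rate), which the
    regional analysis must still see.
    """
    sig = m.usable & (np.nan_to_num(m.P, nan=1.0) <= th.p_s)
    counts = {g: int(sig[i].sum()) for i, g in enumerate(m.genes)}
    vals = np.array(list(counts.values()), dtype=float)
    if vals.size == 0 or vals.std() == 0:
        return set(), counts
    cut = max(vals.mean() + th.hyper_sd * vals.std(), th.hyper_min_frac * (m.n - 1))
    flagged = {g for g, k in counts.items() if k > cut}
    if flagged:
        logger.info("hyper_interactors: %d gene(s) above mean + %.1f SD", len(flagged), th.hyper_sd)
    return flagged, counts


def class_crosstab(
    m: InteractionMatrix,
    loci: Sequence[GeneLocus],
    th: Thresholds,
    c: CorrelationMatrix | None = None,
) -> pd.DataFrame:
    """Frequency of significant interactions per functional-class pair.

    For each unordered class pair (A, B): significant tested pairs between A
    and B divided by all tested pairs between A and B. Genes without a
    functional class are grouped under ``"unannotated"``. When a correlation
    matrix is supplied, a second column block reports the frequency of
    significant correlations the same way. Returned as a tidy DataFrame with
    columns class_a, class_b, n_tested, n_sig_s, freq_s [, n_sig_corr,
    freq_corr].
    """
    klass = {l.gene_id: (l.functional_class or "unannotated") for l in loci}
    missing = [g for g in m.genes if g not in klass]
    if missing:
        raise ValidationError(f"genes without locus entry: {missing[:5]}")
    sig_s = m.usable & (np.nan_to_num(m.P, nan=1.0) <= th.p_s)
    rows: dict[tuple[str, str], list[int]] = {}
    iu = zip(*np.triu_indices(m.n, k=1))
    for i, j in iu:
        if not m.usable[i, j]:
            continue
        a, b = sorted((klass[m.genes[i]], klass[m.genes[j]]))
        rec = rows.setdefault((a, b), [0, 0, 0])
        rec[0] += 1
        rec[1] += int(sig_s[i, j])
        if c is not None and np.isfinite(c.P[i, j]) and c.P[i, j] <= th.p_corr:
            rec[2] += 1
    data = []
    for (a, b), (n_tested, n_sig, n_corr) in sorted(rows.items()):
        row = {
            "class_a": a,
            "class_b": b,
            "n_tested": n_tested,
            "n_sig_s": n_sig,
            "freq_s": n_sig / n_tested,
        }
        if c is not None:
            row["n_sig_corr"] = n_corr
            row["freq_corr"] = n_corr / n_tested
        data.append(row)
    return pd.DataFrame(data)


def set_overlap(
    tested_pairs: set, reference_sets: Mapping[str, set]
) -> dict[frozenset, int]:
    """Venn-region counts of a tested pair set against named reference sets.

    Pair sets must use canonical unordered keys. Each element of the union is
    assigned to the frozenset of set names containing it; returns counts per
    region (regions with zero members are reported too).
    """
    from itertools import combinations

    named: dict[str, set] = {"tested": set(tested_pairs)}
    named.update({k: set(v) for k, v in reference_sets.items()})
    names = list(named)
    counts: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            combo_set = frozenset(combo)
            inside = set.intersection(*(named[n] for n in combo))
            outside = set.union(set(), *(named[n] for n in names if n not in combo_set))
            counts[combo_set] = len(inside - outside)
    return counts
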