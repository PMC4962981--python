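"""From replicate colony sizes to a symmetrized, significance-annotated matrix.

The S score is the modified t-statistic of the E-MAP tradition::

    S = (mean_obs - expected) / sqrt(spread^2 / n_ctrl + var_obs / n_obs)

where ``expected`` and ``spread`` are robust per-array-gene control
statistics (median and scaled MAD across queries) and both variance terms
are floored at a screen-wide level so that pairs measured with accidentally
tiny replicate scatter cannot reach absurd significance. Negative S =
smaller colonies than expected (synthetic sick/lethal); positive S =
larger (alleviation/suppression).

Stages: plate normalization -> control statistics -> per-direction scores ->
reciprocal symmetrization -> empirical-null (or permutation) P values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import (
    ControlStats,
    CrossGrid,
    InteractionMatrix,
    ValidationError,
    get_logger,
)

__all__ = [
    "RawScorePair",
    "normalize_grid",
    "fit_control_stats",
    "compute_s_score",
    "score_grid",
    "pairs_from_directional",
    "symmetrize",
    "s_pvalues",
    "bonferroni_cut",
]

logger = get_logger("emapkit.scoring")

MAD_SCALE = 1.4826  # MAD -> SD for a normal distribution
_FLOOR_EPS = 1e-9  # relative floor keeping S finite on degenerate (noise-free) screens


@dataclass
class RawScorePair:
    """Unaveraged scores of one gene pair from its two reciprocal crosses.

    ``s_qa`` comes from [query A × array B], ``s_aq`` from the reciprocal
    [query B × array A]; either may be NaN when that direction failed.
    """

    gene_a: str
    gene_b: str
    s_qa: float
    s_aq: float
    n_obs_qa: int = 0
    n_obs_aq: int = 0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def both_present(self) -> bool:
        return np.isfinite(self.s_qa) and np.isfinite(self.s_aq)

    @property
    def mean_s(self) -> float:
        vals = [v for v in (self.s_qa, self.s_aq) if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_grid(grid: CrossGrid, polish: bool = False) -> CrossGrid:
    """Scale each plate so its median colony size equals the global median.

    With ``polish`` enabled, a subsequent row/column median polish in log
    space removes residual linear gradients (e.g. an uneven array plate);
    the global median is restored afterwards. Plates with no finite sizes
    are left untouched (flagged by a log message, not scaled).
    """
    out = grid.copy()
    sizes = out.sizes
    if not np.isfinite(sizes).any():
        raise ValidationError("grid has no positive colony sizes to normalize")
    global_median = float(np.nanmedian(sizes))
    if not np.isfinite(global_median) or global_median <= 0:
        raise ValidationError("grid has no positive colony sizes to normalize")

    plate_ids = {p for p in out.plate_of.ravel() if p is not None}
    n_empty = 0
    for plate in plate_ids:
        mask = out.plate_of == plate
        vals = sizes[mask]
        med = float(np.nanmedian(vals)) if np.isfinite(vals).any() else np.nan
        if not np.isfinite(med) or med <= 0:
            n_empty += 1
            continue
        sizes[mask] *= global_median / med
    if n_empty:
        logger.warning("normalize_grid: %d plate(s) had no usable sizes; left unscaled", n_empty)

    if polish:
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(sizes > 0, np.log(sizes), np.nan)
        for _ in range(2):  # two sweeps of median polish are ample for linear trends
            row_med = np.nanmedian(logs, axis=(1, 2), keepdims=True)
            logs = logs - np.where(np.isfinite(row_med), row_med, 0.0)
            col_med = np.nanmedian(logs, axis=(0, 2), keepdims=True)
            logs = logs - np.where(np.isfinite(col_med), col_med, 0.0)
        polished = np.exp(logs)
        polished *= global_median / np.nanmedian(polished)
        keep = ~(sizes > 0)  # zeros/missing pass through untouched
        sizes[...] = np.where(keep, sizes, polished)
    return out


# ---------------------------------------------------------------------------
# control statistics and the S score
# ---------------------------------------------------------------------------


def fit_control_stats(
    grid: CrossGrid, n_ctrl: int | None = None, min_crosses: int = 4
) -> ControlStats:
    """Robust per-array-gene expectation and spread from a normalized grid.

    Expected size is the median of all replicate measurements of that array
    gene across queries; spread is the scaled MAD of the same values, floored
    at the screen-wide median spread (true interactions are rare, so medians
    across queries estimate the non-interacting control). Array genes with
    fewer than ``min_crosses`` usable crosses are flagged missing (NaN).
    """
    sizes = grid.sizes
    na = len(grid.arrays)
    expected = np.full(na, np.nan)
    spread_raw = np.full(na, np.nan)
    for j in range(na):
        col = sizes[:, j, :]
        usable_crosses = int(np.isfinite(col).any(axis=1).sum())
        vals = col[np.isfinite(col)]
        if usable_crosses < min_crosses or vals.size == 0:
            continue
        med = float(np.median(vals))
        expected[j] = med
        spread_raw[j] = MAD_SCALE * float(np.median(np.abs(vals - med)))
    finite = np.isfinite(spread_raw)
    if not finite.any():
        raise ValidationError("no array gene has enough usable crosses")
    global_median = float(np.nanmedian(sizes))
    floor = max(float(np.median(spread_raw[finite])), _FLOOR_EPS * global_median)
    spread = np.where(finite, np.maximum(spread_raw, floor), np.nan)
    n_missing = int((~finite).sum())
    if n_missing:
        logger.info("fit_control_stats: %d array gene(s) flagged MISSING", n_missing)
    return ControlStats(
        arrays=list(grid.arrays),
        expected=expected,
        spread=spread,
        n_ctrl=n_ctrl if n_ctrl is not None else grid.n_replicates,
        variance_floor=floor,
    )


def compute_s_score(observed, expected: float, spread: float, n_ctrl: int, variance_floor: float) -> float:
    """S score of one cross from its replicate sizes and the array-gene null.

    Returns NaN when fewer than 2 finite replicates are available or the
    control statistics are missing.
    """
    obs = np.asarray(observed, dtype=float)
    obs = obs[np.isfinite(obs)]
    if obs.size < 2 or not (np.isfinite(expected) and np.isfinite(spread)):
        return float("nan")
    var_obs = float(np.var(obs, ddof=1))
    var_obs = max(var_obs, variance_floor**2)
    denom = np.sqrt(spread**2 / n_ctrl + var_obs / obs.size)
    return float((obs.mean() - expected) / denom)


def score_grid(grid: CrossGrid, ctrl: ControlStats) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-direction S scores.

    Returns ``(S_dir, n_obs)`` of shape ``(n_queries, n_arrays)``; ``S_dir``
    is NaN where fewer than 2 replicates or no control statistics exist.
    """
    if list(grid.arrays) != list(ctrl.arrays):
        raise ValidationError("control statistics were fitted on a different array list")
    sizes = grid.sizes
    finite = np.isfinite(sizes)
    n_obs = finite.sum(axis=2)
    filled = np.where(finite, sizes, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_obs = filled.sum(axis=2) / n_obs
        ss = (np.where(finite, sizes - mean_obs[..., None], 0.0) ** 2).sum(axis=2)
        var_obs = ss / np.maximum(n_obs - 1, 1)
    var_obs = np.maximum(var_obs, ctrl.variance_floor**2)
    denom = np.sqrt(ctrl.spread[None, :] ** 2 / ctrl.n_ctrl + var_obs / np.maximum(n_obs, 1))
    S = (mean_obs - ctrl.expected[None, :]) / denom
    S[n_obs < 2] = np.nan
    return S, n_obs


def pairs_from_directional(
    genes: list[str], S_dir: np.ndarray, n_obs: np.ndarray
) -> list[RawScorePair]:
    """Collect reciprocal score pairs from a square directional matrix."""
    n = len(genes)
    if S_dir.shape != (n, n):
        raise ValidationError("directional matrix must be square over the gene list")
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            s_qa, s_aq = float(S_dir[i, j]), float(S_dir[j, i])
            if np.isfinite(s_qa) or np.isfinite(s_aq):
                pairs.append(
                    RawScorePair(genes[i], genes[j], s_qa, s_aq, int(n_obs[i, j]), int(n_obs[j, i]))
                )
    return pairs


def symmetrize(pairs: list[RawScorePair], genes: list[str]) -> InteractionMatrix:
    """Average reciprocal directions into a symmetric matrix.

    Pairs observed in only one direction keep that score and are flagged
    ``ONE_DIRECTION_ONLY``.
    """
    n = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    S = np.full((n, n), np.nan)
    one_dir = np.zeros((n, n), dtype=bool)
    for p in pairs:
        i, j = gi[p.gene_a], gi[p.gene_b]
        S[i, j] = S[j, i] = p.mean_s
        if not p.both_present:
            one_dir[i, j] = one_dir[j, i] = True
    return InteractionMatrix(genes, S, flags={"ONE_DIRECTION_ONLY": one_dir})


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def empirical_null_params(m: InteractionMatrix) -> tuple[float, float]:
    """Median and scaled MAD of the usable S distribution (the empirical null).

    Assumes the bulk of pairs are non-interacting, so robust location/scale
    of the whole S distribution estimate the null.
    """
    iu = np.triu_indices(m.n, k=1)
    vals = m.S[iu][m.usable[iu]]
    if vals.size < 50:
        raise ValidationError(
            f"only {vals.size} finite S values; empirical null needs >= 50 "
            "(use the permutation null for small screens)"
        )
    med = float(np.median(vals))
    mad = MAD_SCALE * float(np.median(np.abs(vals - med)))
    if mad == 0:
        mad = _FLOOR_EPS  # degenerate noise-free screen; P values then saturate
    return med, mad


def s_pvalues(
    m: InteractionMatrix,
    null: str = "empirical",
    grid: CrossGrid | None = None,
    ctrl: ControlStats | None = None,
    permutations: int = 2000,
    seed: int = 0,
) -> InteractionMatrix:
    """Attach two-sided P values to every finite S score.

    ``null="empirical"``: robust-standardize the S distribution (median /
    scaled MAD over unflagged pairs) and evaluate against the standard
    normal. ``null="permute"``: shuffle which query each cross's replicate
    set belongs to within every array column (breaking any query-array
    association while preserving the column's marginal), rescore, and use the
    pooled permuted |S| distribution as the null.
    """
    out = m.copy()
    if null == "empirical":
        med, mad = empirical_null_params(out)
        with np.errstate(invalid="ignore"):
            z = np.abs(out.S - med) / mad
        out.P = np.where(np.isfinite(out.S), 2.0 * stats.norm.sf(z), np.nan)
    elif null == "permute":
        if grid is None or ctrl is None:
            raise ValidationError("permutation null needs the normalized grid and control stats")
        rng = np.random.default_rng(seed)
        if permutations < 1:
            raise ValidationError("permutations must be >= 1")
        nq = len(grid.queries)
        pooled = []
        for _ in range(permutations):
            perm_sizes = np.empty_like(grid.sizes)
            for j in range(len(grid.arrays)):
                perm = rng.permutation(nq)
                perm_sizes[:, j, :] = grid.sizes[perm, j, :]
            g2 = CrossGrid(grid.condition, grid.queries, grid.arrays, perm_sizes, grid.plate_of)
            S_perm, _ = score_grid(g2, ctrl)
            pooled.append(np.abs(S_perm[np.isfinite(S_perm)]))
        null_abs = np.sort(np.concatenate(pooled))
        k = null_abs.size - np.searchsorted(null_abs, np.abs(out.S), side="left")
        out.P = np.where(np.isfinite(out.S), (1.0 + k) / (1.0 + null_abs.size), np.nan)
    else:
        raise ValidationError(f"unknown null {null!r}")
    np.fill_diagonal(out.P, np.nan)
    return out


def bonferroni_cut(m: InteractionMatrix, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold alpha / (number of tested pairs)."""
    iu = np.triu_indices(m.n, k=1)
    n_tested = int(m.usable[iu].sum())
    if n_tested == 0:
        raise ValidationError("no tested pairs; cannot form a Bonferroni threshold")
    return alpha / n_tested
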