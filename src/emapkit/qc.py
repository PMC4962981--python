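"""Strain-level quality control: reciprocal concordance and noisy strains.

A well-behaved screen measures each gene pair twice — [query A × array B]
and [query B × array A] — and the two S scores should agree. Strains whose
crosses systematically disagree with their reciprocals (mating defects,
secondary mutations, slow growers) are flagged and removed before any
downstream analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core_io import InteractionMatrix, ValidationError, get_logger
from .scoring import RawScorePair

__all__ = [
    "reciprocal_concordance",
    "detect_noisy_strains",
    "apply_noisy_flags",
    "replicate_concordance",
]

logger = get_logger("emapkit.qc")


def reciprocal_concordance(
    pairs: list[RawScorePair],
    significant_only: bool = False,
    p_cut: float = 0.005,
    pvalues: dict[tuple[str, str], float] | None = None,
) -> float:
    """Pearson correlation of the two reciprocal score directions.

    With ``significant_only``, restrict to pairs whose averaged P value
    (supplied via ``pvalues``, keyed by the pair tuple) is below ``p_cut``.
    Returns NaN when fewer than 3 qualifying pairs exist.
    """
    qa, aq = [], []
    for p in pairs:
        if not p.both_present:
            continue
        if significant_only:
            if pvalues is None:
                raise ValidationError("significant_only requires per-pair P values")
            pv = pvalues.get(p.pair, np.nan)
            if not (np.isfinite(pv) and pv < p_cut):
                continue
        qa.append(p.s_qa)
        aq.append(p.s_aq)
    if len(qa) < 3:
        return float("nan")
    return float(stats.pearsonr(qa, aq)[0])


def _per_strain_discordance(pairs: list[RawScorePair], skip: set[str]) -> tuple[dict[str, float], float]:
    """Median |s_qa - s_aq| per strain over its partners, plus the screen median."""
    disc: dict[str, list[float]] = {}
    all_d: list[float] = []
    for p in pairs:
        if not p.both_present or p.gene_a in skip or p.gene_b in skip:
            continue
        d = abs(p.s_qa - p.s_aq)
        disc.setdefault(p.gene_a, []).append(d)
        disc.setdefault(p.gene_b, []).append(d)
        all_d.append(d)
    if not all_d:
        return {}, float("nan")
    return {g: float(np.median(v)) for g, v in disc.items()}, float(np.median(all_d))


def detect_noisy_strains(pairs: list[RawScorePair], k_noisy: float = 3.0) -> set[str]:
    """Strains whose reciprocal discordance is an outlier.

    A strain is flagged when its median |s_qa − s_aq| over partners exceeds
    ``k_noisy`` times the screen-wide median discordance. After the first
    pass the screen statistics are recomputed without the flagged strains and
    the criterion applied once more (one iteration only, so the procedure is
    deterministic and order-independent).
    """
    flagged: set[str] = set()
    for _ in range(2):
        per_strain, screen_med = _per_strain_discordance(pairs, flagged)
        if not per_strain or not np.isfinite(screen_med) or screen_med == 0:
            break
        new = {g for g, d in per_strain.items() if d > k_noisy * screen_med}
        if not new:
            break
        flagged |= new
    if flagged:
        logger.info("detect_noisy_strains: flagged %d strain(s): %s", len(flagged), sorted(flagged))
    return flagged


def apply_noisy_flags(m: InteractionMatrix, noisy: set[str]) -> InteractionMatrix:
    """Flag every pair involving a noisy strain; S values are kept but excluded."""
    out = m.copy()
    idx = [out.index_of(g) for g in noisy if g in out.genes]
    for i in idx:
        out.flags["NOISY_STRAIN"][i, :] = True
        out.flags["NOISY_STRAIN"][:, i] = True
    np.fill_diagonal(out.flags["NOISY_STRAIN"], False)
    return out


def replicate_concordance(
    m1: InteractionMatrix,
    m2: InteractionMatrix,
    significant_only: bool = False,
    p_cut: float = 0.005,
) -> tuple[float, int]:
    """Between-experiment concordance of S scores over shared gene pairs.

    Returns ``(pearson_r, n_pairs)``. With ``significant_only``, restricts
    to pairs significant (P < p_cut) in either experiment — the comparison
    the screen's repeat-experiment scatter plots make.
    """
    shared = [g for g in m1.genes if g in set(m2.genes)]
    if len(shared) < 2:
        raise ValidationError("matrices share no gene pairs")
    i1 = [m1.index_of(g) for g in shared]
    i2 = [m2.index_of(g) for g in shared]
    S1 = m1.S[np.ix_(i1, i1)]
    S2 = m2.S[np.ix_(i2, i2)]
    U1 = m1.usable[np.ix_(i1, i1)]
    U2 = m2.usable[np.ix_(i2, i2)]
    iu = np.triu_indices(len(shared), k=1)
    ok = U1[iu] & U2[iu]
    if significant_only:
        P1 = m1.P[np.ix_(i1, i1)][iu]
        P2 = m2.P[np.ix_(i2, i2)][iu]
        ok &= (np.nan_to_num(P1, nan=1.0) < p_cut) | (np.nan_to_num(P2, nan=1.0) < p_cut)
    x, y = S1[iu][ok], S2[iu][ok]
    if x.size < 3:
        raise ValidationError("fewer than 3 shared finite pairs")
    return float(stats.pearsonr(x, y)[0]), int(x.size)
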