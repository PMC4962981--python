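"""Two-condition (chemogenetic) comparison of interaction matrices.

The drug arm of the screen repeats every cross under a compound; an
interaction is *aggravated* when the double mutant becomes sicker on drug
(ΔS = S_drug − S_control strongly negative) and *alleviated* when it
recovers (ΔS strongly positive). Because single S scores carry replicate
noise, a call requires both a minimum |ΔS| and significance of the
interaction in the condition that anchors the call (drug for aggravation,
control for alleviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import InteractionMatrix, ValidationError, get_logger
from .scoring import RawScorePair, empirical_null_params

__all__ = ["DifferentialCall", "compare_conditions", "axis_artifact_scan"]

logger = get_logger("emapkit.differential")


@dataclass(frozen=True)
class DifferentialCall:
    """One pair's control/drug scores and its category."""

    pair: tuple[str, str]
    s_control: float
    s_drug: float
    delta: float  # s_drug - s_control
    category: str  # AGGRAVATED | ALLEVIATED | UNCHANGED


def compare_conditions(
    m_ctrl: InteractionMatrix,
    m_drug: InteractionMatrix,
    min_delta: float = 2.0,
    p_cut: float = 0.005,
) -> list[DifferentialCall]:
    """Call aggravated/alleviated interactions between two conditions.

    AGGRAVATED: ΔS ≤ −min_delta, the pair is significant on drug, and the
    drug-condition interaction is negative (the double mutant is genuinely
    sicker than expected). ALLEVIATED: ΔS ≥ +min_delta, the pair is
    significant in control, and the control interaction is negative (an
    existing synthetic-sick interaction is relieved). The sign conditions
    keep changes among *positive* interactions — a different phenomenon —
    out of the aggravated/alleviated vocabulary.
    Pairs flagged (noisy, masked, missing) in either condition are excluded;
    pairs present in only one condition are not silently dropped — they are
    logged and left out of the returned list.
    """
    shared = [g for g in m_ctrl.genes if g in set(m_drug.genes)]
    if len(shared) < 2:
        raise ValidationError("conditions share no gene pairs")
    ic = [m_ctrl.index_of(g) for g in shared]
    idr = [m_drug.index_of(g) for g in shared]
    Sc = m_ctrl.S[np.ix_(ic, ic)]
    Sd = m_drug.S[np.ix_(idr, idr)]
    Pc = m_ctrl.P[np.ix_(ic, ic)]
    Pd = m_drug.P[np.ix_(idr, idr)]
    ok = m_ctrl.usable[np.ix_(ic, ic)] & m_drug.usable[np.ix_(idr, idr)]
    one_sided = (m_ctrl.usable[np.ix_(ic, ic)] ^ m_drug.usable[np.ix_(idr, idr)]).sum() // 2
    if one_sided:
        logger.info("compare_conditions: %d pair(s) measured in only one condition (excluded)", one_sided)

    calls = []
    for i, j in zip(*np.triu_indices(len(shared), k=1)):
        if not ok[i, j]:
            continue
        delta = float(Sd[i, j] - Sc[i, j])
        drug_sig = np.isfinite(Pd[i, j]) and Pd[i, j] <= p_cut
        ctrl_sig = np.isfinite(Pc[i, j]) and Pc[i, j] <= p_cut
        if delta <= -min_delta and drug_sig and Sd[i, j] < 0:
            cat = "AGGRAVATED"
        elif delta >= min_delta and ctrl_sig and Sc[i, j] < 0:
            cat = "ALLEVIATED"
        else:
            cat = "UNCHANGED"
        calls.append(
            DifferentialCall((shared[i], shared[j]), float(Sc[i, j]), float(Sd[i, j]), delta, cat)
        )
    calls.sort(key=lambda c: (-abs(c.delta), c.pair))
    return calls


def axis_artifact_scan(
    pairs_ctrl: list[RawScorePair],
    pairs_drug: list[RawScorePair],
    m_ctrl: InteractionMatrix,
    m_drug: InteractionMatrix,
    p_cut: float = 0.005,
) -> dict:
    """Pairs significant in exactly one cross direction, per condition.

    In the scatter of reciprocal scores these pairs hug the x- or y-axis:
    one direction clears the significance bound while the reciprocal sits in
    the null bulk. The per-direction bound is the |S| value whose two-sided
    empirical-null P equals ``p_cut`` (null location/scale taken from each
    condition's symmetrized matrix). Returns per-condition pair sets and the
    drug/control excess ratio (NaN when the control set is empty).
    """
    z_cut = float(stats.norm.isf(p_cut / 2.0))

    def scan(pairs: list[RawScorePair], m: InteractionMatrix) -> set[tuple[str, str]]:
        med, mad = empirical_null_params(m)
        bound = med + z_cut * mad, med - z_cut * mad
        hi, lo = max(bound), min(bound)
        found = set()
        for p in pairs:
            if not p.both_present:
                continue
            sig_qa = p.s_qa > hi or p.s_qa < lo
            sig_aq = p.s_aq > hi or p.s_aq < lo
            if sig_qa != sig_aq:
                found.add(p.pair)
        return found

    ctrl_set = scan(pairs_ctrl, m_ctrl)
    drug_set = scan(pairs_drug, m_drug)
    ratio = len(drug_set) / len(ctrl_set) if ctrl_set else float("nan")
    return {"control": ctrl_set, "drug": drug_set, "drug_excess_ratio": ratio}
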