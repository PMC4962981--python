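"""Model-style front end: ``EMapScreen`` fits a screen, ``EMapResults`` holds it.

Typical use::

    from emapkit import EMapScreen, SimConfig, simulate_screen

    truth, grids = simulate_screen(SimConfig(), seed=1)
    model = EMapScreen(grids, truth.loci)
    res = model.fit()
    print(res.summary())
    calls = res.detect_regions("control")
    diffs = res.compare_conditions()

``fit()`` runs the full raw-to-matrix pipeline per condition — plate
normalization, robust control statistics, per-direction S scores, noisy-
strain removal, reciprocal symmetrization, linkage masking, empirical-null
P values — and returns a results object from which the correlation,
classification, curve, clustering, differential and region analyses hang.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import differential as _diff
from . import network as _net
from . import qc as _qc
from . import regions as _reg
from . import scoring as _sc
from .core_io import (
    ControlStats,
    CrossGrid,
    GeneLocus,
    InteractionMatrix,
    Thresholds,
    ValidationError,
    get_logger,
    read_cross_grid,
    read_locus_table,
)

__all__ = ["EMapScreen", "EMapResults", "ConditionFit"]

logger = get_logger("emapkit.model")


@dataclass
class ConditionFit:
    """Everything the pipeline produced for one condition."""

    condition: str
    grid: CrossGrid  # normalized
    control_stats: ControlStats
    raw_pairs: list[_sc.RawScorePair]
    interactions: InteractionMatrix
    noisy_strains: set[str]


class EMapScreen:
    """An E-MAP screen ready to fit.

    Parameters
    ----------
    grids
        One :class:`CrossGrid` per condition (mapping condition -> grid), or
        a single grid for a one-condition screen.
    loci
        Locus table covering every screened gene.
    thresholds
        Pipeline cutoffs; defaults to the published settings.
    """

    def __init__(
        self,
        grids: Mapping[str, CrossGrid] | CrossGrid,
        loci: Sequence[GeneLocus],
        thresholds: Thresholds | None = None,
    ) -> None:
        if isinstance(grids, CrossGrid):
            grids = {grids.condition: grids}
        if not grids:
            raise ValidationError("need at least one condition grid")
        self.grids = dict(grids)
        self.loci = list(loci)
        self.thresholds = thresholds or Thresholds()
        for g in self.grids.values():
            g.validate_against(self.loci)

    @classmethod
    def from_tsv(
        cls,
        loci_path: str | Path,
        control_path: str | Path,
        drug_path: str | Path | None = None,
        thresholds: Thresholds | None = None,
        n_replicates: int = 4,
    ) -> "EMapScreen":
        """Build a screen from the on-disk long-format TSVs."""
        loci = read_locus_table(loci_path)
        grids = {"control": read_cross_grid(control_path, "control", n_replicates)}
        if drug_path is not None:
            grids["drug"] = read_cross_grid(drug_path, "drug", n_replicates)
        return cls(grids, loci, thresholds)

    def fit(
        self,
        null: str = "empirical",
        remove_noisy: bool = True,
        mask_linkage: bool = True,
        polish: bool = False,
        permutations: int = 2000,
        seed: int = 0,
    ) -> "EMapResults":
        """Run the full scoring pipeline and return the results object."""
        th = self.thresholds
        fits: dict[str, ConditionFit] = {}
        for cond, grid in self.grids.items():
            if set(grid.queries) != set(grid.arrays):
                raise ValidationError(
                    f"{cond}: reciprocal analysis needs a square grid (queries == arrays)"
                )
            if list(grid.queries) != list(grid.arrays):
                # align the array axis to query order (file readers list
                # arrays by first occurrence)
                perm = [grid.arrays.index(g) for g in grid.queries]
                grid = CrossGrid(
                    grid.condition,
                    list(grid.queries),
                    [grid.arrays[k] for k in perm],
                    grid.sizes[:, perm, :],
                    grid.plate_of[:, perm],
                )
            norm = _sc.normalize_grid(grid, polish=polish)
            ctrl = _sc.fit_control_stats(norm)
            S_dir, n_obs = _sc.score_grid(norm, ctrl)
            pairs = _sc.pairs_from_directional(list(norm.queries), S_dir, n_obs)
            noisy = _qc.detect_noisy_strains(pairs, th.k_noisy) if remove_noisy else set()
            m = _sc.symmetrize(pairs, list(norm.queries))
            if noisy:
                m = _qc.apply_noisy_flags(m, noisy)
            if mask_linkage:
                m = _reg.mask_linked_pairs(m, self.loci, th.linkage_bp)
            m = _sc.s_pvalues(m, null=null, grid=norm, ctrl=ctrl, permutations=permutations, seed=seed)
            fits[cond] = ConditionFit(cond, norm, ctrl, pairs, m, noisy)
            logger.info(
                "fit[%s]: %d genes, %d scored pairs, %d noisy strain(s)",
                cond, len(norm.queries), len(pairs), len(noisy),
            )
        return EMapResults(self, fits)


class EMapResults:
    """Fitted screen: matrices, diagnostics and downstream analyses."""

    def __init__(self, model: EMapScreen, fits: dict[str, ConditionFit]) -> None:
        self.model = model
        self.fits = fits
        self.thresholds = model.thresholds
        self.loci = model.loci
        self._correlations: dict[str, _net.CorrelationMatrix] = {}

    # -- access -------------------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        return list(self.fits)

    def _fit(self, condition: str | None) -> ConditionFit:
        if condition is None:
            condition = self.conditions[0]
        try:
            return self.fits[condition]
        except KeyError:
            raise ValidationError(f"no condition {condition!r} in this fit") from None

    def interactions(self, condition: str | None = None) -> InteractionMatrix:
        return self._fit(condition).interactions

    def raw_pairs(self, condition: str | None = None) -> list[_sc.RawScorePair]:
        return self._fit(condition).raw_pairs

    def noisy_strains(self, condition: str | None = None) -> set[str]:
        return self._fit(condition).noisy_strains

    def correlations(self, condition: str | None = None) -> _net.CorrelationMatrix:
        cond = self._fit(condition).condition
        if cond not in self._correlations:
            self._correlations[cond] = _net.profile_correlations(self.fits[cond].interactions)
        return self._correlations[cond]

    # -- per-condition analyses --------------------------------------------

    def significant_counts(self, condition: str | None = None) -> dict[str, int]:
        m = self.interactions(condition)
        iu = np.triu_indices(m.n, k=1)
        sig = m.usable[iu] & (np.nan_to_num(m.P, nan=1.0)[iu] <= self.thresholds.p_s)
        s = m.S[iu]
        return {
            "tested": int(m.usable[iu].sum()),
            "negative": int((sig & (s < 0)).sum()),
            "positive": int((sig & (s > 0)).sum()),
            "masked_linked": int(m.flags["MASKED_LINKED"][iu].sum()),
        }

    def bonferroni_cut(self, condition: str | None = None) -> float:
        return _sc.bonferroni_cut(self.interactions(condition), self.thresholds.bonferroni_alpha)

    def classify_pairs(self, condition: str | None = None) -> list[_net.PairClass]:
        return _net.classify_pairs(
            self.interactions(condition), self.correlations(condition), self.thresholds
        )

    def high_correlation_pairs(self, condition: str | None = None):
        return _net.high_correlation_pairs(self.correlations(condition), self.thresholds.corr_high)

    def s_vs_correlation_curve(self, condition: str | None = None, mode: str = "chunk"):
        return _net.s_vs_correlation_curve(
            self.interactions(condition), self.correlations(condition), self.thresholds, mode
        )

    def pos_neg_ratio_curve(self, condition: str | None = None, mode: str = "chunk"):
        return _net.pos_neg_ratio_curve(
            self.interactions(condition), self.correlations(condition), self.thresholds, mode
        )

    def hierarchical_cluster(self, condition: str | None = None):
        return _net.hierarchical_cluster(self.correlations(condition))

    def hyper_interactors(self, condition: str | None = None):
        return _net.hyper_interactors(self.interactions(condition), self.thresholds)

    def class_crosstab(self, condition: str | None = None, with_correlations: bool = False):
        return _net.class_crosstab(
            self.interactions(condition),
            self.loci,
            self.thresholds,
            self.correlations(condition) if with_correlations else None,
        )

    def reciprocal_concordance(self, condition: str | None = None, significant_only: bool = False) -> float:
        fit = self._fit(condition)
        pvals = None
        if significant_only:
            m = fit.interactions
            pvals = {}
            for p in fit.raw_pairs:
                i, j = m.index_of(p.gene_a), m.index_of(p.gene_b)
                pvals[p.pair] = float(m.P[i, j])
        return _qc.reciprocal_concordance(
            fit.raw_pairs, significant_only, self.thresholds.p_s, pvals
        )

    # -- cross-condition / genome analyses ----------------------------------

    def compare_conditions(
        self, control: str = "control", drug: str = "drug"
    ) -> list[_diff.DifferentialCall]:
        return _diff.compare_conditions(
            self.interactions(control),
            self.interactions(drug),
            self.thresholds.min_delta,
            self.thresholds.p_s,
        )

    def axis_artifact_scan(self, control: str = "control", drug: str = "drug") -> dict:
        return _diff.axis_artifact_scan(
            self.raw_pairs(control),
            self.raw_pairs(drug),
            self.interactions(control),
            self.interactions(drug),
            self.thresholds.p_s,
        )

    def detect_regions(
        self, condition: str | None = None, exclude_hyper: bool = True
    ) -> list[_reg.SuppressorRegionCall]:
        hyper = self.hyper_interactors(condition)[0] if exclude_hyper else set()
        return _reg.detect_regions(
            self.interactions(condition), self.loci, self.thresholds, hyper
        )

    def region_null_rate(
        self, condition: str | None = None, permutations: int = 200, seed: int = 0
    ) -> dict:
        return _reg.region_null_rate(
            self.interactions(condition), self.loci, self.thresholds, permutations, seed
        )

    def genome_heatmap(self, path: str | Path, condition: str | None = None):
        return _reg.genome_heatmap(self.interactions(condition), self.loci, path)

    # -- summary ------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary across conditions."""
        th = self.thresholds
        lines = [
            "E-MAP screen fit",
            "================",
            f"genes: {len(self._fit(None).grid.queries)}   conditions: {', '.join(self.conditions)}",
            f"thresholds: P(S) <= {th.p_s}, P(corr) <= {th.p_corr}, "
            f"linkage < {th.linkage_bp / 1000:g} kb, region cut S < {th.region_s_cut}",
            "",
            f"{'condition':<10} {'tested':>8} {'neg':>6} {'pos':>6} {'masked':>7} "
            f"{'noisy':>6} {'recip_r':>8} {'bonferroni':>11}",
        ]
        for cond in self.conditions:
            counts = self.significant_counts(cond)
            r = self.reciprocal_concordance(cond)
            lines.append(
                f"{cond:<10} {counts['tested']:>8} {counts['negative']:>6} "
                f"{counts['positive']:>6} {counts['masked_linked']:>7} "
                f"{len(self.noisy_strains(cond)):>6} {r:>8.3f} "
                f"{self.bonferroni_cut(cond):>11.3e}"
            )
        if len(self.conditions) >= 2:
            calls = self.compare_conditions(self.conditions[0], self.conditions[1])
            n_agg = sum(c.category == "AGGRAVATED" for c in calls)
            n_all = sum(c.category == "ALLEVIATED" for c in calls)
            lines += ["", f"differential: {n_agg} aggravated, {n_all} alleviated "
                          f"(|ΔS| >= {th.min_delta}, gated at P <= {th.p_s})"]
        return "\n".join(lines)
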