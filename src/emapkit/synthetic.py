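"""Synthetic E-MAP screens with known ground truth.

The generator emulates the statistical structure a colony-size screen hands
to the scoring pipeline:

* a multiplicative neutral model — the expected double-mutant colony size is
  ``plate_scale × f_q × f_a``, with genetic interactions entering as a
  multiplicative deviation ``(1 + ε)`` (negative ε = synthetic sick);
* lognormal replicate noise parameterized by a coefficient of variation,
  inflated for designated noisy strains;
* per-plate scale factors (one plate per query row per condition);
* condition-specific interaction shifts ``Δε`` applied only in the "drug"
  condition;
* undeclared suppressor mutations: a carrier strain with a fitness defect is
  rescued by a suppressor at a known locus, EXCEPT in crosses whose partner
  gene lies within ``linkage_bp`` of the suppressor locus on the same
  chromosome — there, selection for the partner's linked marker evicts the
  suppressor and the cross collapses back to the unrescued fitness, faking a
  contiguous block of negative interactions.

Everything planted is recorded in :class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .core_io import CrossGrid, GeneLocus, ValidationError, get_logger

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_truth",
    "simulate_colonies",
    "simulate_screen",
    "expected_size",
]

logger = get_logger("emapkit.synthetic")

_PAIR = tuple[str, str]


def pair_key(a: str, b: str) -> _PAIR:
    """Canonical unordered pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated screen.

    The defaults describe the package's reference world: 120 genes on 4
    chromosomes spaced 20 kb apart, quadruplicate crosses, 2% of pairs
    genuinely interacting with |ε| in 0.3–0.6, 15% replicate noise, mild
    plate-scale variation, and one suppressor-carrier strain whose rescue is
    lost across a 10-gene linked region (<100 kb around the suppressor
    locus). Small enough for seconds-scale tests, structured enough to
    exercise every downstream stage.
    """

    n_genes: int = 120
    n_chromosomes: int = 4
    gene_spacing_bp: int = 20_000
    gene_length_bp: int = 1_500
    replicates: int = 4
    interaction_fraction: float = 0.02
    effect_size_range: tuple[float, float] = (0.3, 0.6)
    negative_fraction: float = 0.5
    noise_cv: float = 0.15
    fitness_range: tuple[float, float] = (0.7, 1.0)
    fitness_sd: float | None = None  # None = draw from fitness_range; 0 = all equal
    plate_scale_sd: float = 0.1
    n_noisy_strains: int = 0
    noisy_multiplier: float = 10.0
    n_drug_shifts: int = 20
    drug_shift_size: float = 0.45
    n_suppressors: int = 1
    rescue_factor: float = 6.0
    linkage_bp: int = 100_000
    column_gradient: float = 0.0  # optional linear array-position gradient

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise ValidationError("need at least 4 genes")
        if self.n_chromosomes < 1:
            raise ValidationError("need at least 1 chromosome")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.rescue_factor <= 1:
            raise ValidationError("rescue_factor must exceed 1")
        if self.n_suppressors > self.n_genes:
            raise ValidationError("more suppressors than strains")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValidationError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("effect_size_range", "fitness_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Suppressor:
    """An undeclared suppressor carried by one strain."""

    carrier: str
    chromosome: str
    locus_bp: int
    rescue_factor: float

    def rescues(self, partner: GeneLocus, linkage_bp: int) -> bool:
        """True if the suppressor survives a cross with ``partner``.

        The suppressor is evicted (no rescue) when the partner gene lies
        within ``linkage_bp`` of the suppressor locus on the same chromosome.
        """
        if partner.chromosome != self.chromosome:
            return True
        return abs(partner.start_bp - self.locus_bp) >= linkage_bp


@dataclass
class SyntheticTruth:
    """Every planted parameter of one simulated screen."""

    config: SimConfig
    seed: int
    loci: list[GeneLocus]
    single_fitness: dict[str, float]
    interactions: dict[_PAIR, float]
    drug_shifts: dict[_PAIR, float]
    noisy_strains: set[str]
    suppressors: list[Suppressor]
    plate_scales: dict[str, float]

    def __post_init__(self) -> None:
        for g, f in self.single_fitness.items():
            if not 0 < f <= 1:
                raise ValidationError(f"single fitness of {g} outside (0, 1]")

    @property
    def genes(self) -> list[str]:
        return [l.gene_id for l in self.loci]

    def suppressor_region(self, sup: Suppressor) -> list[str]:
        """Genes whose array marker is linked to the suppressor (genome order)."""
        members = [
            l
            for l in self.loci
            if l.chromosome == sup.chromosome
            and abs(l.start_bp - sup.locus_bp) < self.config.linkage_bp
        ]
        members.sort(key=lambda l: l.start_bp)
        return [l.gene_id for l in members]


def _layout_loci(cfg: SimConfig) -> list[GeneLocus]:
    """Evenly spaced genes across chromosomes, genome order chr1..chrK."""
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    loci = []
    for idx in range(cfg.n_genes):
        c, k = divmod(idx, per_chrom)
        start = k * cfg.gene_spacing_bp
        loci.append(
            GeneLocus(
                gene_id=f"g{idx:03d}",
                chromosome=f"chr{c + 1}",
                start_bp=start,
                end_bp=start + cfg.gene_length_bp,
            )
        )
    return loci


def generate_truth(cfg: SimConfig, seed: int) -> SyntheticTruth:
    """Draw one fully specified synthetic screen. Deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    loci = _layout_loci(cfg)
    genes = [l.gene_id for l in loci]
    by_id = {l.gene_id: l for l in loci}

    if cfg.fitness_sd is None:
        fitness = rng.uniform(*cfg.fitness_range, size=cfg.n_genes)
    elif cfg.fitness_sd == 0:
        fitness = np.full(cfg.n_genes, 0.85)
    else:
        fitness = np.clip(rng.normal(0.85, cfg.fitness_sd, cfg.n_genes), 0.05, 1.0)
    single_fitness = dict(zip(genes, fitness))

    all_pairs = [(genes[i], genes[j]) for i in range(cfg.n_genes) for j in range(i + 1, cfg.n_genes)]
    n_int = int(round(cfg.interaction_fraction * len(all_pairs)))
    chosen = rng.choice(len(all_pairs), size=n_int, replace=False) if n_int else []
    interactions: dict[_PAIR, float] = {}
    lo, hi = cfg.effect_size_range
    for k in chosen:
        mag = rng.uniform(lo, hi)
        sign = -1.0 if rng.random() < cfg.negative_fraction else 1.0
        interactions[pair_key(*all_pairs[k])] = sign * mag

    # drug shifts come in two kinds, mirroring what a compound can do:
    # aggravations create new synthetic sickness on otherwise neutral pairs
    # (Δε < 0); alleviations relieve an existing negative interaction
    # (Δε = −ε on a planted synthetic-sick pair), since "alleviated" only
    # means something for an interaction that exists without the drug.
    # Shifts are planted on unlinked pairs only — linkage-masked pairs are
    # never scored in a screen of this design, so a shift there is
    # unobservable in principle.
    def unlinked(p: _PAIR) -> bool:
        a, b = by_id[p[0]], by_id[p[1]]
        return a.chromosome != b.chromosome or abs(a.start_bp - b.start_bp) >= cfg.linkage_bp

    drug_shifts: dict[_PAIR, float] = {}
    n_shift = cfg.n_drug_shifts
    if n_shift:
        n_allev = n_shift // 2
        relievable = [
            p for p, e in interactions.items()
            if e <= -cfg.drug_shift_size and unlinked(p)
        ]
        n_allev = min(n_allev, len(relievable))
        if n_allev:
            for k in rng.choice(len(relievable), size=n_allev, replace=False):
                drug_shifts[relievable[k]] = -interactions[relievable[k]]
        free = [
            p
            for i, p in enumerate(all_pairs)
            if i not in set(np.atleast_1d(chosen)) and unlinked(pair_key(*p))
        ]
        n_aggr = min(n_shift - n_allev, len(free))
        for k in rng.choice(len(free), size=n_aggr, replace=False):
            drug_shifts[pair_key(*free[k])] = -cfg.drug_shift_size

    noisy = set(rng.choice(genes, size=cfg.n_noisy_strains, replace=False)) if cfg.n_noisy_strains else set()

    # suppressors: locus midway between two genes on a chromosome, carrier on
    # a different chromosome. The suppressor restores the carrier to its
    # originally drawn (typical) fitness: carrier fitness = draw / rescue, so
    # rescued crosses look like any other strain's and rescue-loss crosses
    # collapse by the full factor.
    suppressors: list[Suppressor] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    for s in range(cfg.n_suppressors):
        sup_chrom = f"chr{(s % cfg.n_chromosomes) + 1}"
        on_chrom = [l for l in loci if l.chromosome == sup_chrom]
        mid = on_chrom[len(on_chrom) // 2]
        locus_bp = mid.start_bp + cfg.gene_spacing_bp // 2
        candidates = [g for g in genes if by_id[g].chromosome != sup_chrom and g not in {x.carrier for x in suppressors}]
        carrier = str(rng.choice(candidates))
        single_fitness[carrier] = single_fitness[carrier] / cfg.rescue_factor
        suppressors.append(Suppressor(carrier, sup_chrom, locus_bp, cfg.rescue_factor))

    # one plate per query row per condition
    plate_scales: dict[str, float] = {}
    for cond in ("control", "drug"):
        for g in genes:
            plate_scales[f"{cond}:{g}"] = float(
                np.exp(rng.normal(0.0, cfg.plate_scale_sd))
            ) if cfg.plate_scale_sd > 0 else 1.0

    return SyntheticTruth(
        config=cfg,
        seed=seed,
        loci=loci,
        single_fitness=single_fitness,
        interactions=interactions,
        drug_shifts=drug_shifts,
        noisy_strains=noisy,
        suppressors=suppressors,
        plate_scales=plate_scales,
    )


def expected_size(truth: SyntheticTruth, query: str, array: str, condition: str) -> float:
    """Closed-form expected colony size of one cross (the simulator's mean)."""
    if condition not in ("control", "drug"):
        raise ValidationError(f"unknown condition {condition!r}")
    cfg = truth.config
    by_id = {l.gene_id: l for l in truth.loci}
    key = pair_key(query, array)
    eps = truth.interactions.get(key, 0.0)
    if condition == "drug":
        eps += truth.drug_shifts.get(key, 0.0)
    size = (
        truth.plate_scales[f"{condition}:{query}"]
        * truth.single_fitness[query]
        * truth.single_fitness[array]
        * max(0.0, 1.0 + eps)
    )
    # suppressor acts whenever the carrier strain is on either side of the
    # cross; rescue is lost when the partner marker is linked to the locus
    for sup in truth.suppressors:
        if query == sup.carrier and sup.rescues(by_id[array], cfg.linkage_bp):
            size *= sup.rescue_factor
        elif array == sup.carrier and sup.rescues(by_id[query], cfg.linkage_bp):
            size *= sup.rescue_factor
    if cfg.column_gradient:
        j = truth.genes.index(array)
        size *= 1.0 + cfg.column_gradient * (j / max(1, len(truth.genes) - 1) - 0.5)
    return 100.0 * size


def simulate_colonies(
    truth: SyntheticTruth,
    condition: str,
    replicates: int | None = None,
    rng: np.random.Generator | None = None,
) -> CrossGrid:
    """Draw a full square [gene × gene × replicate] colony-size grid.

    Both orientations of every pair are generated (the grid is square), so
    reciprocal-cross analyses are exercised. Replicate sizes are lognormal
    around the closed-form expectation with ``noise_cv``; diagonal
    self-crosses are missing. Noisy strains additionally carry a per-cross
    multiplicative bias (lognormal, CV = ``noisy_multiplier × noise_cv``,
    shared by all replicates of a cross) on their query side — replicates of
    a bad strain agree with each other while the cross itself is off, which
    is what makes its scores unreliable; iid replicate noise alone would be
    absorbed by the score's own variance term. ``rng`` defaults to a
    generator seeded from the truth's seed and the condition, so the two
    conditions get independent noise.
    """
    if condition not in ("control", "drug"):
        raise ValidationError(f"unknown condition {condition!r}")
    cfg = truth.config
    reps = replicates if replicates is not None else cfg.replicates
    genes = truth.genes
    n = len(genes)
    if rng is None:
        rng = np.random.default_rng([truth.seed, 0 if condition == "control" else 1])

    mean = np.empty((n, n))
    for i, q in enumerate(genes):
        for j, a in enumerate(genes):
            mean[i, j] = expected_size(truth, q, a, condition)

    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=(n, n, reps))
    else:
        noise = np.ones((n, n, reps))
    sizes = mean[..., None] * noise
    if truth.noisy_strains:
        cv_bias = cfg.noisy_multiplier * max(cfg.noise_cv, 0.05)
        sb = np.sqrt(np.log1p(cv_bias**2))
        for g in truth.noisy_strains:
            i = genes.index(g)
            bias = rng.lognormal(mean=-(sb**2) / 2, sigma=sb, size=n)
            sizes[i, :, :] *= bias[:, None]
    idx = np.arange(n)
    sizes[idx, idx, :] = np.nan  # self-crosses are controls, not data

    plates = np.empty((n, n), dtype=object)
    for i, q in enumerate(genes):
        plates[i, :] = f"{condition}:{q}"
    return CrossGrid(condition, list(genes), list(genes), sizes, plates)


def simulate_screen(
    cfg: SimConfig, seed: int, conditions: Iterable[str] = ("control", "drug")
) -> tuple[SyntheticTruth, dict[str, CrossGrid]]:
    """Convenience: truth plus one grid per condition."""
    truth = generate_truth(cfg, seed)
    grids = {c: simulate_colonies(truth, c) for c in conditions}
    logger.info(
        "simulated screen: %d genes, %d planted interactions, %d drug shifts, "
        "%d noisy strains, %d suppressors",
        cfg.n_genes, len(truth.interactions), len(truth.drug_shifts),
        len(truth.noisy_strains), len(truth.suppressors),
    )
    return truth, grids


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Dump planted parameters as a plain TSV (one record type per block)."""
    with open(path, "w") as fh:
        fh.write(f"#seed\t{truth.seed}\n")
        for g, f in truth.single_fitness.items():
            fh.write(f"fitness\t{g}\t{float(f)!r}\n")
        for (a, b), e in truth.interactions.items():
            fh.write(f"interaction\t{a}\t{b}\t{float(e)!r}\n")
        for (a, b), d in truth.drug_shifts.items():
            fh.write(f"drug_shift\t{a}\t{b}\t{float(d)!r}\n")
        for g in sorted(truth.noisy_strains):
            fh.write(f"noisy\t{g}\n")
        for s in truth.suppressors:
            fh.write(
                f"suppressor\t{s.carrier}\t{s.chromosome}\t{s.locus_bp}\t{float(s.rescue_factor)!r}\n"
            )
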