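"""Domain types, readers/writers, configuration and logging for E-MAP pipelines.

The central objects are:

* :class:`GeneLocus` — a screened gene with chromosomal coordinates and
  optional functional-class / subcellular-location labels.
* :class:`CrossGrid` — replicate colony sizes for every [query × array] cross
  of one condition, plus the plate each cross grew on.
* :class:`InteractionMatrix` — symmetrized S scores with two-sided P values
  and per-cell status flags.
* :class:`Thresholds` — every tunable cutoff of the pipeline, with the
  screen's published defaults.

Coordinates are 0-based half-open (BED convention); the representative
position of a gene for all distance computations is its ``start_bp``.
Missing data is explicit (NaN plus a ``MISSING`` flag), never imputed here.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_NAMES",
    "GeneLocus",
    "CrossGrid",
    "ControlStats",
    "InteractionMatrix",
    "Thresholds",
    "read_locus_table",
    "write_locus_table",
    "read_cross_grid",
    "write_cross_grid",
    "write_matrix",
    "read_matrix",
    "load_config",
    "get_logger",
]

#: Status flags an InteractionMatrix cell may carry.
FLAG_NAMES = ("MASKED_LINKED", "NOISY_STRAIN", "MISSING", "ONE_DIRECTION_ONLY")

_LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "emapkit") -> logging.Logger:
    """Timestamped, leveled logger writing to standard error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    """A screened gene and where it sits in the genome.

    ``functional_class`` and ``location_label`` are free-text annotation
    labels (e.g. ``"transporter"``, ``"ER"``); multi-location genes may use a
    comma-joined label.
    """

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    functional_class: str | None = None
    location_label: str | None = None

    def __post_init__(self) -> None:
        if self.start_bp < 0:
            raise ValidationError(f"{self.gene_id}: start_bp must be >= 0")
        if self.end_bp <= self.start_bp:
            raise ValidationError(
                f"{self.gene_id}: end_bp ({self.end_bp}) must exceed start_bp ({self.start_bp})"
            )


def locus_index(loci: Sequence[GeneLocus]) -> dict[str, GeneLocus]:
    """Map gene_id -> locus, enforcing uniqueness."""
    index: dict[str, GeneLocus] = {}
    for locus in loci:
        if locus.gene_id in index:
            raise ValidationError(f"duplicate gene_id {locus.gene_id!r} in locus table")
        index[locus.gene_id] = locus
    return index


@dataclass
class CrossGrid:
    """Replicate colony sizes for all [query × array] crosses of one condition.

    ``sizes`` is a ``(n_queries, n_arrays, n_replicates)`` float array with
    NaN marking missing replicates; ``plate_of`` is a ``(n_queries,
    n_arrays)`` object array of plate identifiers (None for absent crosses).
    """

    condition: str
    queries: list[str]
    arrays: list[str]
    sizes: np.ndarray
    plate_of: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.ndim != 3:
            raise ValidationError("sizes must be a 3-way [query × array × replicate] table")
        nq, na, _ = self.sizes.shape
        if nq != len(self.queries) or na != len(self.arrays):
            raise ValidationError("sizes shape does not match query/array lists")
        if np.nanmin(self.sizes, initial=0.0) < 0:
            raise ValidationError("colony sizes must be non-negative")
        self.plate_of = np.asarray(self.plate_of, dtype=object)
        if self.plate_of.shape != (nq, na):
            raise ValidationError("plate_of shape does not match query/array lists")

    @property
    def n_replicates(self) -> int:
        return self.sizes.shape[2]

    def validate_against(self, loci: Sequence[GeneLocus]) -> None:
        """Fail fast if any grid gene does not resolve in the locus table."""
        known = {l.gene_id for l in loci}
        unknown = (set(self.queries) | set(self.arrays)) - known
        if unknown:
            raise ValidationError(
                f"grid genes missing from locus table: {sorted(unknown)[:5]}"
                + ("..." if len(unknown) > 5 else "")
            )

    def copy(self) -> "CrossGrid":
        return CrossGrid(
            condition=self.condition,
            queries=list(self.queries),
            arrays=list(self.arrays),
            sizes=self.sizes.copy(),
            plate_of=self.plate_of.copy(),
        )


@dataclass
class ControlStats:
    """Per-array-gene null statistics the S score compares against.

    ``expected`` and ``spread`` are per-array-gene (median colony size and a
    MAD-based standard-deviation estimate, floored at ``variance_floor``);
    ``n_ctrl`` is the effective control replicate count entering the S-score
    denominator.
    """

    arrays: list[str]
    expected: np.ndarray
    spread: np.ndarray
    n_ctrl: int
    variance_floor: float

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        finite = np.isfinite(self.spread)
        if np.any(self.spread[finite] < self.variance_floor - 1e-12):
            raise ValidationError("spread below variance_floor after flooring")
        if np.any(self.expected[np.isfinite(self.expected)] <= 0):
            raise ValidationError("expected colony size must be positive")


class InteractionMatrix:
    """Symmetric per-pair S scores, P values and status flags.

    Parameters
    ----------
    genes
        Ordered gene ids (rows == columns).
    S, P
        ``(n, n)`` float arrays, NaN for missing; symmetric with NaN diagonal.
    flags
        Mapping flag name -> ``(n, n)`` boolean array. Only names from
        :data:`FLAG_NAMES` are allowed.
    """

    def __init__(
        self,
        genes: Sequence[str],
        S: np.ndarray,
        P: np.ndarray | None = None,
        flags: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.genes = list(genes)
        n = len(self.genes)
        self.S = np.asarray(S, dtype=float)
        if self.S.shape != (n, n):
            raise ValidationError("S must be square over the gene list")
        self.P = (
            np.full((n, n), np.nan) if P is None else np.asarray(P, dtype=float)
        )
        if self.P.shape != (n, n):
            raise ValidationError("P must be square over the gene list")
        self.flags: dict[str, np.ndarray] = {
            name: np.zeros((n, n), dtype=bool) for name in FLAG_NAMES
        }
        if flags:
            for name, mat in flags.items():
                if name not in FLAG_NAMES:
                    raise ValidationError(f"unknown flag {name!r}")
                self.flags[name] = np.asarray(mat, dtype=bool)
        np.fill_diagonal(self.S, np.nan)
        np.fill_diagonal(self.P, np.nan)
        self.flags["MISSING"] |= ~np.isfinite(self.S)
        np.fill_diagonal(self.flags["MISSING"], True)

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def flag_set(self, i: int, j: int) -> frozenset[str]:
        return frozenset(name for name, mat in self.flags.items() if mat[i, j])

    @property
    def excluded(self) -> np.ndarray:
        """Cells excluded from downstream analysis (any flag set)."""
        out = np.zeros((self.n, self.n), dtype=bool)
        for mat in self.flags.values():
            out |= mat
        return out

    @property
    def usable(self) -> np.ndarray:
        """Finite, unflagged cells."""
        return np.isfinite(self.S) & ~self.excluded

    def check_symmetric(self) -> None:
        S, P = self.S, self.P
        if not np.array_equal(np.isfinite(S), np.isfinite(S.T)) or np.nanmax(
            np.abs(S - S.T), initial=0.0
        ) > 1e-9:
            raise ValidationError("S is not symmetric")
        if np.isnan(P[np.isfinite(S)]).any():
            raise ValidationError("P missing where S present")

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(
            self.genes,
            self.S.copy(),
            self.P.copy(),
            {k: v.copy() for k, v in self.flags.items()},
        )

    def reordered(self, order: Sequence[int]) -> "InteractionMatrix":
        """Return a copy with rows/columns permuted consistently."""
        order = np.asarray(order)
        return InteractionMatrix(
            [self.genes[i] for i in order],
            self.S[np.ix_(order, order)],
            self.P[np.ix_(order, order)],
            {k: v[np.ix_(order, order)] for k, v in self.flags.items()},
        )


@dataclass(frozen=True)
class Thresholds:
    """All pipeline cutoffs, defaulting to the screen's published settings.

    ``p_s`` / ``p_corr`` are the unadjusted significance cuts for S scores
    and profile correlations; ``linkage_bp`` is the same-chromosome masking
    distance; ``region_s_cut`` / ``region_min_run`` parameterize the
    suppressor-region scan; ``window`` is the curve window size.
    """

    p_s: float = 0.005
    p_corr: float = 0.05
    bonferroni_alpha: float = 0.05
    corr_high: float = 0.5
    corr_knee: float = 0.4
    window: int = 10
    linkage_bp: int = 100_000
    region_s_cut: float = -3.0
    region_min_run: int = 5
    k_noisy: float = 3.0
    min_delta: float = 2.0
    hyper_sd: float = 2.0
    hyper_min_frac: float = 0.25

    def __post_init__(self) -> None:
        for name in ("p_s", "p_corr", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.window < 2:
            raise ValidationError("window must be >= 2")
        if self.linkage_bp <= 0:
            raise ValidationError("linkage_bp must be positive")
        if self.region_s_cut >= 0:
            raise ValidationError("region_s_cut must be negative")
        if self.region_min_run < 2:
            raise ValidationError("region_min_run must be >= 2")

    def with_(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a BED-like TSV: chrom, start, end, gene_id [, class, location].

    Lines starting with ``#`` are comments. Duplicate gene ids and
    ``end <= start`` are rejected.
    """
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 tab-separated columns")
            chrom, start_s, end_s, gene_id = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            fclass = parts[4] if len(parts) > 4 and parts[4] not in ("", ".") else None
            loc = parts[5] if len(parts) > 5 and parts[5] not in ("", ".") else None
            loci.append(GeneLocus(gene_id, chrom, start, end, fclass, loc))
    return loci


def write_locus_table(loci: Sequence[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chromosome}\t{l.start_bp}\t{l.end_bp}\t{l.gene_id}\t"
                f"{l.functional_class or '.'}\t{l.location_label or '.'}\n"
            )


def read_cross_grid(
    path: str | Path, condition: str, n_replicates: int = 4
) -> CrossGrid:
    """Read long-format colony data: query_id, array_id, replicate_index, size, plate_id.

    Replicate indices are 1-based in the file and must not exceed
    ``n_replicates``. Absent crosses are marked missing (NaN).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["query", "array", "replicate", "size", "plate"],
        comment="#",
        dtype={"query": str, "array": str, "plate": str},
    )
    if df["size"].lt(0).any():
        bad = df.index[df["size"].lt(0)][0] + 1
        raise ValidationError(f"{path}: negative colony size at data row {bad}")
    if df["replicate"].lt(1).any() or df["replicate"].gt(n_replicates).any():
        raise ValidationError(
            f"{path}: replicate index outside declared range 1..{n_replicates}"
        )
    queries = list(dict.fromkeys(df["query"]))
    arrays = list(dict.fromkeys(df["array"]))
    qi = {g: i for i, g in enumerate(queries)}
    ai = {g: i for i, g in enumerate(arrays)}
    sizes = np.full((len(queries), len(arrays), n_replicates), np.nan)
    plates = np.full((len(queries), len(arrays)), None, dtype=object)
    rows_q = df["query"].map(qi).to_numpy()
    rows_a = df["array"].map(ai).to_numpy()
    rows_r = df["replicate"].to_numpy() - 1
    sizes[rows_q, rows_a, rows_r] = df["size"].to_numpy(dtype=float)
    plates[rows_q, rows_a] = df["plate"].to_numpy()
    return CrossGrid(condition, queries, arrays, sizes, plates)


def write_cross_grid(grid: CrossGrid, path: str | Path) -> None:
    """Write a grid back to long format, skipping missing replicates."""
    with open(path, "w") as fh:
        for i, q in enumerate(grid.queries):
            for j, a in enumerate(grid.arrays):
                plate = grid.plate_of[i, j]
                for r in range(grid.n_replicates):
                    v = grid.sizes[i, j, r]
                    if np.isfinite(v):
                        fh.write(f"{q}\t{a}\t{r + 1}\t{float(v)!r}\t{plate}\n")


def write_matrix(m: "InteractionMatrix | object", path: str | Path) -> None:
    """Write a square matrix as TSV (gene ids as first row/column, NA missing).

    For an :class:`InteractionMatrix`, three files are produced:
    ``<path>`` (S), ``<path>`` with ``.pvalues.tsv`` suffix (P) and a sidecar
    ``.flags.tsv`` with comma-joined flag names per cell. Correlation
    matrices (anything exposing ``genes``/``r``/``P``) get value + P files.
    """
    path = Path(path)
    genes = list(m.genes)

    def _dump(mat: np.ndarray, p: Path) -> None:
        df = pd.DataFrame(mat, index=genes, columns=genes)
        df.to_csv(p, sep="\t", na_rep="NA", float_format="%.10g")

    if isinstance(m, InteractionMatrix):
        _dump(m.S, path)
        _dump(m.P, path.with_suffix(".pvalues.tsv"))
        n = m.n
        cells = np.empty((n, n), dtype=object)
        cells[:] = ""
        for name, mat in m.flags.items():
            idx = np.nonzero(mat)
            for i, j in zip(*idx):
                cells[i, j] = f"{cells[i, j]},{name}" if cells[i, j] else name
        pd.DataFrame(cells, index=genes, columns=genes).to_csv(
            path.with_suffix(".flags.tsv"), sep="\t"
        )
    else:  # CorrelationMatrix-like
        _dump(np.asarray(m.r, dtype=float), path)
        _dump(np.asarray(m.P, dtype=float), path.with_suffix(".pvalues.tsv"))


def read_matrix(path: str | Path) -> "InteractionMatrix":
    """Read an S-score TSV written by :func:`write_matrix` (plus sidecars if present)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    genes = [str(g) for g in df.index]
    S = df.to_numpy(dtype=float)
    P = None
    ppath = path.with_suffix(".pvalues.tsv")
    if ppath.exists():
        P = pd.read_csv(ppath, sep="\t", index_col=0, na_values="NA").to_numpy(dtype=float)
    flags: dict[str, np.ndarray] = {}
    fpath = path.with_suffix(".flags.tsv")
    if fpath.exists():
        cells = pd.read_csv(fpath, sep="\t", index_col=0, keep_default_na=False).to_numpy(
            dtype=object
        )
        for name in FLAG_NAMES:
            flags[name] = np.array(
                [[name in str(c).split(",") for c in row] for row in cells], dtype=bool
            )
    return InteractionMatrix(genes, S, P, flags)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a TOML run configuration.

    Recognised tables: ``[thresholds]`` (any :class:`Thresholds` field) and
    ``[simulation]`` (any :class:`emapkit.synthetic.SimConfig` field).
    Returns ``{"thresholds": Thresholds, "simulation": dict}``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    th_kwargs = raw.get("thresholds", {})
    valid = {f.name for f in fields(Thresholds)}
    unknown = set(th_kwargs) - valid
    if unknown:
        raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
    return {
        "thresholds": Thresholds(**th_kwargs),
        "simulation": raw.get("simulation", {}),
    }
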