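"""Single-sample gene set enrichment analysis (ssGSEA).

One sample at a time, genes are ranked from high to low expression and the
ranks turned into correlation values r_g (plain ECDF ranks or their
z-scores). For a gene set G the running enrichment score walks the ranked
list accumulating the difference between the weighted empirical CDF of
in-set genes (weights |r_g|^α) and the unweighted ECDF of out-of-set
genes; the enrichment score is the area under that running curve (the
"area under RES" statistic) or, optionally, its signed Kolmogorov–Smirnov
extremum. Significance comes from a gene-label permutation null of
size-matched random sets: NES is the z-statistic of ES against the null,
the p-value an add-one two-sided permutation tail, and FDR is
Benjamini–Hochberg within each sample.

Defaults follow common ssGSEA practice: weight exponent α = 0.75, z-score
correlation type, area-under-RES statistic, 1000 permutations, minimum set
size 3, |NES| >= 1.96 flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

logger = logging.getLogger(__name__)

AREA_UNDER_RES = "area_under_RES"
KOLMOGOROV_SMIRNOV = "kolmogorov_smirnov"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (genes × samples): unique gene ids,
    finite values."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return matrix


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Genes × samples TSV with a gene-id first column."""
    return validate_expression(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: map set-name -> (description, member gene ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def all_genes(self) -> set[str]:
        return {g for _, genes in self.sets.values() for g in genes}

    def rename_genes(self, mapping: Mapping[str, str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {
                name: (desc, tuple(mapping.get(g, g) for g in genes))
                for name, (desc, genes) in self.sets.items()
            }
        )


@dataclass(frozen=True)
class SsgseaConfig:
    """Parameters of the ssGSEA run; defaults are the package's standard
    operating point (see module docstring)."""

    weight_exponent: float = 0.75
    correlation_type: str = "z-score"  # or "rank"
    statistic: str = AREA_UNDER_RES  # or "kolmogorov_smirnov"
    n_permutations: int = 1000
    min_set_size: int = 3
    z_cutoff: float = 1.96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight exponent must be >= 0")
        if self.correlation_type not in ("rank", "z-score"):
            raise ValueError(f"unknown correlation type {self.correlation_type!r}")
        if self.statistic not in (AREA_UNDER_RES, KOLMOGOROV_SMIRNOV):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.n_permutations < 1:
            raise ValueError("need >= 1 permutation")
        if self.min_set_size < 1:
            raise ValueError("minimum set size must be >= 1")
        if self.z_cutoff < 0:
            raise ValueError("z cutoff must be >= 0")


@dataclass(frozen=True)
class RankedProfile:
    """One sample's genes ordered from high to low expression with their
    correlation values r_g (transformed ranks)."""

    genes: tuple[str, ...]
    correlations: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass(frozen=True)
class RunningScore:
    """Running enrichment score RES(i) = P_in(i) − P_out(i) along the
    ranked list; both ECDFs rise from 0 to 1, so RES(N) = 0."""

    res: np.ndarray
    p_in: np.ndarray
    p_out: np.ndarray
    set_size_used: int


@dataclass
class EnrichmentResult:
    """Long-format ssGSEA output: one row per (gene set, sample)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["set", "sample", "es", "nes", "p_value", "fdr", "size", "significant"]
        )
    )

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.table[self.table["sample"] == sample]

    def to_tsv(self, path: str | None = None) -> str | None:
        return self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT parsing
# ---------------------------------------------------------------------------


def read_gmt(path: str) -> GeneSetCollection:
    """Read gene sets from GMT: per line, set name, description, then
    member genes, tab-separated. Duplicate genes within a line are dropped;
    a duplicate set name or a line with fewer than 3 fields is an error."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and >= 1 gene "
                    f"(got {len(fields)} fields)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = (description, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as handle:
        for name in collection:
            genes = "\t".join(collection.genes(name))
            handle.write(f"{name}\t{collection.description(name)}\t{genes}\n")


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------


def rank_transform(
    values: pd.Series | Mapping[str, float],
    config: SsgseaConfig = SsgseaConfig(),
) -> RankedProfile:
    """Order genes from high to low expression and attach correlation
    values.

    Ranks run 1..N from the bottom of the list, so the top gene carries
    rank N. "rank" mode sets r_g = rank/N (the descending ECDF value);
    "z-score" mode standardizes the rank vector to mean 0, sd 1. Ties are
    broken by a seeded shuffle of the gene order, recorded via the config
    seed, so results are reproducible yet not alphabetically biased.
    """
    series = pd.Series(values, dtype=float)
    if len(series) < 2:
        raise ValueError("need >= 2 genes to rank")
    if series.nunique() == 1:
        raise ValueError("all expression values are equal; ranking undefined")
    rng = np.random.default_rng(config.seed)
    tiebreak = {g: i for i, g in enumerate(rng.permutation(series.index.to_numpy()))}
    order = sorted(series.index, key=lambda g: (-series[g], tiebreak[g]))
    n = len(order)
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene -> N
    if config.correlation_type == "rank":
        correlations = ranks / n
    else:
        correlations = (ranks - ranks.mean()) / ranks.std()
    return RankedProfile(genes=tuple(order), correlations=correlations)


def _batch_running_stats(
    correlations: np.ndarray,
    membership: np.ndarray,
    alpha: float,
    statistic: str,
) -> np.ndarray:
    """Enrichment scores for a batch of sets over one ranked profile.

    ``membership`` is a (batch, N) boolean matrix in ranked order. Fully
    vectorized; used by the permutation null and by brute-force-style
    batch scoring in calibration runs.
    """
    weights = np.abs(correlations) ** alpha
    in_weights = membership * weights
    denom = in_weights.sum(axis=1, keepdims=True)
    # Degenerate all-zero-weight sets: fall back to unweighted membership.
    zero = denom[:, 0] == 0
    if zero.any():
        in_weights[zero] = membership[zero].astype(float)
        denom = in_weights.sum(axis=1, keepdims=True)
    p_in = np.cumsum(in_weights, axis=1) / denom
    set_sizes = membership.sum(axis=1, keepdims=True)
    p_out = np.cumsum(~membership, axis=1) / (membership.shape[1] - set_sizes)
    res = p_in - p_out
    if statistic == AREA_UNDER_RES:
        return res.sum(axis=1)
    extremum_idx = np.argmax(np.abs(res), axis=1)
    return res[np.arange(res.shape[0]), extremum_idx]


def running_score(
    profile: RankedProfile, gene_set: Iterable[str], alpha: float = 0.75
) -> RunningScore:
    """Running enrichment score of one gene set along the ranked list.

    Walking positions i = 1..N, P_in is the |r_g|^α-weighted ECDF over
    in-set genes, P_out the plain ECDF over out-of-set genes, and
    RES(i) = P_in(i) − P_out(i).
    """
    members = set(gene_set) & set(profile.genes)
    n = profile.n_genes
    n_in = len(members)
    if n_in == 0:
        raise ValueError("gene set shares no genes with the profile")
    if n_in == n:
        raise ValueError("gene set covers the whole profile; P_out undefined")
    membership = np.fromiter(
        (g in members for g in profile.genes), dtype=bool, count=n
    )[None, :]
    weights = np.abs(profile.correlations) ** alpha
    in_weights = membership[0] * weights
    denom = in_weights.sum()
    if denom == 0:
        in_weights = membership[0].astype(float)
        denom = in_weights.sum()
    p_in = np.cumsum(in_weights) / denom
    p_out = np.cumsum(~membership[0]) / (n - n_in)
    return RunningScore(res=p_in - p_out, p_in=p_in, p_out=p_out, set_size_used=n_in)


def enrichment_score(rs: RunningScore, statistic: str = AREA_UNDER_RES) -> float:
    """Collapse a running score into one ES: the area under RES (sum over
    positions) or the signed Kolmogorov–Smirnov extremum."""
    if statistic == AREA_UNDER_RES:
        return float(rs.res.sum())
    if statistic == KOLMOGOROV_SMIRNOV:
        return float(rs.res[int(np.argmax(np.abs(rs.res)))])
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_null(
    profile: RankedProfile,
    set_size: int,
    config: SsgseaConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null ES distribution from uniformly random gene sets of matched size.

    ssGSEA has no phenotype labels to permute, so the null resamples
    gene labels: each of ``n_permutations`` draws scores a random subset of
    ``set_size`` profile genes.
    """
    n = profile.n_genes
    if not 1 <= set_size < n:
        raise ValueError(f"set size must be in [1, {n - 1}], got {set_size}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    membership = np.zeros((config.n_permutations, n), dtype=bool)
    for row in membership:
        row[rng.choice(n, size=set_size, replace=False)] = True
    return _batch_running_stats(
        profile.correlations, membership, config.weight_exponent, config.statistic
    )


def normalize_scores(es: float, null: np.ndarray) -> tuple[float, float]:
    """NES and permutation p-value of an ES against its null.

    NES = (ES − mean(null)) / sd(null), so a z-style cutoff such as 1.96
    reads as a two-sided 5% normal bound; p is the add-one two-sided tail
    (1 + #{|null| >= |ES|}) / (1 + n_permutations).
    """
    null = np.asarray(null, dtype=float)
    if len(null) < 2:
        raise ValueError("need >= 2 null values")
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance null; NES undefined")
    nes = (es - null.mean()) / sd
    p = (1 + int((np.abs(null) >= abs(es)).sum())) / (1 + len(null))
    return float(nes), float(p)


def ssgsea(
    matrix: pd.DataFrame,
    sets: GeneSetCollection,
    config: SsgseaConfig = SsgseaConfig(),
) -> EnrichmentResult:
    """Full ssGSEA over an expression matrix (genes × samples).

    Per sample: rank-transform once, score every gene set with at least
    ``min_set_size`` genes present (smaller sets are dropped and logged),
    calibrate against a size-matched permutation null (cached per set
    size), then BH-adjust p-values across the sets of that sample. A set is
    flagged significant when |NES| >= ``z_cutoff``.
    """
    validate_expression(matrix)
    shared = set(matrix.index) & sets.all_genes()
    if not shared:
        raise ValueError("expression matrix and gene sets share no genes")
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    for sample in matrix.columns:
        profile = rank_transform(matrix[sample], config)
        null_cache: dict[int, np.ndarray] = {}
        sample_rows: list[dict] = []
        for name in sets:
            present = set(sets.genes(name)) & set(profile.genes)
            if len(present) < config.min_set_size:
                logger.info(
                    "sample %s: set %s dropped (%d < %d genes present)",
                    sample, name, len(present), config.min_set_size,
                )
                continue
            rs = running_score(profile, present, config.weight_exponent)
            es = enrichment_score(rs, config.statistic)
            size = rs.set_size_used
            if size not in null_cache:
                null_cache[size] = permutation_null(profile, size, config, rng)
            nes, p = normalize_scores(es, null_cache[size])
            sample_rows.append(
                {
                    "set": name,
                    "sample": sample,
                    "es": es,
                    "nes": nes,
                    "p_value": p,
                    "size": size,
                    "significant": abs(nes) >= config.z_cutoff,
                }
            )
        if sample_rows:
            p_values = np.array([r["p_value"] for r in sample_rows])
            for row, fdr in zip(sample_rows, false_discovery_control(p_values)):
                row["fdr"] = float(fdr)
        rows.extend(sample_rows)
    if not rows:
        logger.warning("no gene set passed the size filter; empty result")
        return EnrichmentResult()
    table = pd.DataFrame(rows)[
        ["set", "sample", "es", "nes", "p_value", "fdr", "size", "significant"]
    ]
    return EnrichmentResult(table=table)
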