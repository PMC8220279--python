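"""Per-species signature measures: consistency and entropy-based distinctiveness.

Each egg is a point in a 10-dimensional phenotypic space (MDPS) and pairs of
eggs are compared by Euclidean distance. Three species-level defence measures
are computed:

* **intraclutch consistency** — 1 minus the species' mean within-clutch
  distance, computed on *effective clutches* (two randomly chosen eggs per
  multi-egg clutch, singleton clutches removed) so clutch sizes are comparable;
* **absolute distinctiveness** — the variance component of the Gaussian
  differential entropy of the across-clutch phenotype distribution,
  ``Σᵢ ½ ln(2πe σᵢ²)``, i.e. summed per-metric variation;
* **combinatorial distinctiveness** — the correlation component,
  ``½ ln det R`` for correlation matrix R, which is ≤ 0 (Hadamard) and closer
  to 0 the less predictable one metric is from the others.

Entropy = variance component + correlation component exactly; all entropies are
in nats (natural log). Distinctiveness uses one randomly selected egg per
clutch to avoid pseudoreplication. Species whose eggs are immaculate have
zero-variance pattern metrics; their entropy is undefined and is propagated as
missing values rather than an error. An MDPS-based distinctiveness (mean
pairwise interclutch distance) is also provided.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import METRIC_COLUMNS, substream

LN_2PIE = float(np.log(2.0 * np.pi * np.e))

#: cone channel dropped before the correlation determinant: the four catches
#: sum to one, so one channel is linearly redundant and R would be singular.
REDUNDANT_METRIC = "q_lw"


# ---------------------------------------------------------------------------
# effective clutches and consistency
# ---------------------------------------------------------------------------


def make_effective_clutches(
    eggs: pd.DataFrame, seed: int, metric_columns: list[str] | None = None
) -> pd.DataFrame:
    """Reduce every multi-egg clutch to two randomly selected eggs.

    One-egg clutches are eliminated (within-clutch distance is undefined for
    them); from each remaining clutch exactly two eggs are sampled uniformly
    without replacement. Deterministic given ``seed``.
    """
    rng = substream(seed, "effective-clutches")
    counts = eggs.groupby("clutch_id", sort=False)["egg_id"].transform("count")
    multi = eggs[counts >= 2]
    if multi.empty:
        raise ValueError("no effective clutches: every clutch has a single egg")
    keep_idx: list = []
    for _, idx in multi.groupby("clutch_id", sort=False).indices.items():
        chosen = rng.choice(len(idx), size=2, replace=False)
        keep_idx.extend(multi.index[idx[np.sort(chosen)]])
    return multi.loc[keep_idx]


def mdps_distance(a, b) -> float:
    """Euclidean distance between two eggs in 10-metric phenotypic space."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("phenotype vectors must be 1-d and of equal length")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("phenotype vector has missing metrics")
    return float(np.linalg.norm(a - b))


def consistency_index(
    effective_clutches: pd.DataFrame, metric_columns: list[str] | None = None
) -> float:
    """1 − mean within-clutch pairwise distance over effective clutches.

    Each effective clutch contributes its single within-pair distance; the
    index is 1 at perfect within-clutch identity and is deliberately not
    clamped below (10-d distances can exceed 1 for very dissimilar eggs).
    """
    cols = metric_columns or METRIC_COLUMNS
    if effective_clutches.empty:
        raise ValueError("no effective clutches supplied")
    dists = []
    for _, grp in effective_clutches.groupby("clutch_id", sort=False):
        x = grp[cols].to_numpy(dtype=float)
        if x.shape[0] != 2:
            raise ValueError("effective clutches must contain exactly two eggs")
        dists.append(mdps_distance(x[0], x[1]))
    return 1.0 - float(np.mean(dists))


def sample_one_egg_per_clutch(
    eggs: pd.DataFrame, seed: int, metric_columns: list[str] | None = None
) -> np.ndarray:
    """One uniformly chosen egg per clutch, as a (clutches × metrics) matrix."""
    cols = metric_columns or METRIC_COLUMNS
    groups = eggs.groupby("clutch_id", sort=False).indices
    if len(groups) < 2:
        raise ValueError("need at least 2 clutches")
    rng = substream(seed, "one-egg-per-clutch")
    rows = []
    for _, idx in groups.items():
        rows.append(eggs.index[idx[int(rng.integers(len(idx)))]])
    return eggs.loc[rows, cols].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Gaussian differential entropy and its decomposition
# ---------------------------------------------------------------------------


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy ½ ln((2πe)^k det Σ) of a Gaussian, in nats."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0:
        raise ValueError(f"covariance not positive definite (eigenvalue {eigvals[0]:.3g})")
    k = cov.shape[0]
    return 0.5 * (k * LN_2PIE + float(np.sum(np.log(eigvals))))


def decompose_covariance(cov: np.ndarray) -> tuple[float, float, float]:
    """Split Gaussian entropy into variance and correlation components.

    Returns ``(entropy, variance_component, correlation_component)`` with
    variance component ``Σᵢ ½ ln(2πe σᵢ²)`` and correlation component
    ``½ ln det R``; their sum equals the entropy exactly because
    ``det Σ = det R · Πᵢ σᵢ²``.
    """
    cov = np.asarray(cov, dtype=float)
    var = np.diag(cov)
    if np.any(var <= 0):
        raise ValueError("zero or negative variance on the diagonal")
    sd = np.sqrt(var)
    corr = cov / np.outer(sd, sd)
    sign, logdet_r = np.linalg.slogdet(corr)
    if sign <= 0:
        raise ValueError("correlation matrix is singular or indefinite")
    variance_component = float(0.5 * np.sum(LN_2PIE + np.log(var)))
    correlation_component = float(0.5 * logdet_r)
    return variance_component + correlation_component, variance_component, correlation_component


@dataclass
class EntropyDecomposition:
    entropy: float
    absolute: float  # variance component
    combinatorial: float  # correlation component, ≤ 0
    undefined: bool
    dropped_metric: str | None = None


def entropy_decomposition(
    data: np.ndarray,
    metric_columns: list[str] | None = None,
    drop_redundant: str | None = REDUNDANT_METRIC,
) -> EntropyDecomposition:
    """Plug-in entropy decomposition of a (clutches × metrics) data matrix.

    The sample covariance (ddof = 1) supplies per-metric variances for the
    variance component (summed over every metric with nonzero variance) and,
    after dropping the linearly redundant cone channel (the four catches sum
    to one), the correlation determinant for the correlation component. Any
    zero-variance metric — immaculate species — yields an undefined
    decomposition flagged rather than raised, so whole-dataset runs skip those
    species as missing values.
    """
    x = np.asarray(data, dtype=float)
    cols = metric_columns or METRIC_COLUMNS
    if x.ndim != 2 or x.shape[1] != len(cols):
        raise ValueError("data must be (observations × metrics)")
    if x.shape[0] < x.shape[1] + 2:
        raise ValueError(
            f"need at least k+2 = {x.shape[1] + 2} observations for a stable decomposition"
        )
    var = x.var(axis=0, ddof=1)
    if np.any(var <= 1e-300):
        return EntropyDecomposition(np.nan, np.nan, np.nan, undefined=True)

    variance_component = float(0.5 * np.sum(LN_2PIE + np.log(var)))

    keep = [i for i, c in enumerate(cols) if c != drop_redundant]
    corr = np.corrcoef(x[:, keep], rowvar=False)
    sign, logdet_r = np.linalg.slogdet(corr)
    if sign <= 0 or not np.isfinite(logdet_r):
        return EntropyDecomposition(np.nan, variance_component, np.nan, undefined=True)
    correlation_component = float(0.5 * logdet_r)
    return EntropyDecomposition(
        entropy=variance_component + correlation_component,
        absolute=variance_component,
        combinatorial=correlation_component,
        undefined=False,
        dropped_metric=drop_redundant if drop_redundant in cols else None,
    )


# ---------------------------------------------------------------------------
# MDPS distinctiveness and resampling
# ---------------------------------------------------------------------------


def mdps_distinctiveness(
    eggs: pd.DataFrame, seed: int, metric_columns: list[str] | None = None
) -> float:
    """Mean pairwise MDPS distance among one-egg-per-clutch representatives."""
    x = sample_one_egg_per_clutch(eggs, seed, metric_columns)
    from scipy.spatial.distance import pdist

    return float(pdist(x, metric="euclidean").mean())


def resample_species(eggs: pd.DataFrame, n_clutches: int, seed: int) -> pd.DataFrame:
    """Uniform subsample of ``n_clutches`` clutches without replacement.

    Used to recompute consistency at the minimum observed sample size so that
    unequal sampling effort across species cannot drive comparative results.
    """
    clutches = list(dict.fromkeys(eggs["clutch_id"]))
    if len(clutches) < n_clutches:
        raise ValueError(f"species has {len(clutches)} clutches, fewer than {n_clutches}")
    rng = substream(seed, "resample-species")
    chosen = set(
        np.asarray(clutches, dtype=object)[
            rng.choice(len(clutches), size=n_clutches, replace=False)
        ].tolist()
    )
    return eggs[eggs["clutch_id"].isin(chosen)]


# ---------------------------------------------------------------------------
# per-species orchestration
# ---------------------------------------------------------------------------


def species_signatures(
    eggs: pd.DataFrame,
    seed: int,
    resample_to: int | None = None,
    metric_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Compute the full signature table, one row per species.

    Consistency uses effective clutches; distinctiveness uses one egg per
    clutch; the two draws come from separate named substreams, so each is
    independently reproducible. ``resample_to`` first subsamples every species
    to that many clutches (species below the floor are kept whole only if
    exactly at it — others raise, mirroring a fixed minimum sample size).
    """
    rows = []
    for species, grp in eggs.groupby("species", sort=False):
        if resample_to is not None:
            grp = resample_species(
                grp, resample_to, seed=seed + zlib.crc32(str(species).encode()) % 100000
            )
        try:
            eff = make_effective_clutches(grp, seed=seed)
            consistency = consistency_index(eff, metric_columns)
            n_used = eff["clutch_id"].nunique()
        except ValueError:
            consistency, n_used = np.nan, 0
        try:
            x = sample_one_egg_per_clutch(grp, seed=seed, metric_columns=metric_columns)
            decomp = entropy_decomposition(x, metric_columns)
        except ValueError:
            decomp = EntropyDecomposition(np.nan, np.nan, np.nan, undefined=True)
        try:
            mdps = mdps_distinctiveness(grp, seed=seed, metric_columns=metric_columns)
        except ValueError:
            mdps = np.nan
        rows.append(
            {
                "species": species,
                "family": grp["family"].iloc[0],
                "consistency": consistency,
                "entropy": decomp.entropy,
                "absolute_distinctiveness": decomp.absolute,
                "combinatorial_distinctiveness": decomp.combinatorial,
                "mdps_distinctiveness": mdps,
                "n_clutches_used": int(grp["clutch_id"].nunique()),
                "undefined_entropy": bool(decomp.undefined),
            }
        )
    return pd.DataFrame(rows)
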