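"""Synthetic inputs with known ground truth for every pipeline stage.

This module simulates the kind of data the downstream stages consume, at the scale
of the motivating study system (two passerine families — warblers and weavers —
with species laying clutches of one to five eggs, a subset of species parasitized
by mimetic brood parasites):

* hierarchical egg-phenotype tables — species means, between-clutch covariance
  ``Σ_b``, within-clutch covariance ``Σ_w``, clutch-level Bernoulli parasitism;
* pure-birth (Yule) phylogenies and tip traits with known Pagel's λ;
* grayscale egg images with known spot size, coverage and polar bias;
* smooth reflectance spectra on a 300–700 nm grid;
* species-level "strategy-blocking" scenario tables with known group-specific
  consistency–distinctiveness slopes, for end-to-end recovery experiments.

Every generator is a pure function of its configuration and seed: the global seed
spawns one named substream per component (see :func:`eggsig.schema.substream`),
so adding a generator never perturbs the output of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from PIL import Image

from .schema import (
    CLUTCH_SIZE_MAX,
    CLUTCH_SIZE_MIN,
    METRIC_COLUMNS,
    PATTERN_COLUMNS,
    substream,
)

N_METRICS = len(METRIC_COLUMNS)

# ---------------------------------------------------------------------------
# covariance helpers
# ---------------------------------------------------------------------------


def check_psd(matrix: np.ndarray, name: str = "covariance", tol: float = 1e-8) -> np.ndarray:
    """Validate that ``matrix`` is a symmetric positive-semidefinite covariance."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eigmin = float(np.linalg.eigvalsh(m)[0])
    if eigmin < -tol * max(1.0, float(np.abs(m).max())):
        raise ValueError(f"{name} is not positive-semidefinite (min eigenvalue {eigmin:.3g})")
    return m


def psd_factor(matrix: np.ndarray) -> np.ndarray:
    """A factor L with L Lᵀ = matrix, valid for singular PSD matrices.

    Uses the symmetric eigendecomposition with negative round-off eigenvalues
    clamped to zero, so a zero covariance yields an exactly zero factor.
    """
    vals, vecs = np.linalg.eigh(np.asarray(matrix, dtype=float))
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def random_correlation(k: int, rng: np.random.Generator, concentration: float = 2.0) -> np.ndarray:
    """Draw a random full-rank correlation matrix (vine/onion-free shortcut).

    A random Wishart-like matrix ``A Aᵀ`` with ``k + concentration`` columns is
    normalized to unit diagonal; larger ``concentration`` gives correlations
    closer to zero.
    """
    a = rng.standard_normal((k, k + max(1, int(round(concentration * k)))))
    s = a @ a.T
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


def covariance_from(variances: Sequence[float], correlation: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.asarray(variances, dtype=float))
    return correlation * np.outer(sd, sd)


# ---------------------------------------------------------------------------
# hierarchical phenotype tables
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Conditions for the hierarchical egg-phenotype generator.

    Defaults emulate the motivating dataset: 11 + 14 species in two families,
    ~32 clutches per species (≈800 clutches in total), clutch sizes 1–5 with
    mean ≈ 2.4 eggs and ≈13% singletons, 60% of species parasitized with
    clutch-level parasitism rates in 2–43%, and three immaculate species in the
    second family whose five pattern metrics are identically zero.
    """

    n_species_per_family: tuple[int, int] = (11, 14)
    parasitized_fraction: float = 0.6
    clutch_count_per_species: tuple[int, int] = (15, 60)
    clutch_size_weights: tuple[float, ...] = (0.13, 0.45, 0.31, 0.09, 0.02)
    parasitism_rate_range: tuple[float, float] = (0.02, 0.43)
    n_immaculate_species: int = 3
    #: scale of between-clutch standard deviations (per metric)
    between_sd_range: tuple[float, float] = (0.08, 0.20)
    #: scale of within-clutch standard deviations (eggs of one female are similar)
    within_sd_range: tuple[float, float] = (0.02, 0.06)
    #: optional overrides: one matrix shared by all species
    between_clutch_cov: np.ndarray | None = None
    within_clutch_cov: np.ndarray | None = None
    species_means: np.ndarray | None = None  # (n_species, 10)
    clip_to_valid_ranges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.clutch_size_weights, dtype=float)
        if w.size != CLUTCH_SIZE_MAX - CLUTCH_SIZE_MIN + 1 or np.any(w < 0):
            raise ValueError("clutch_size_weights must be 5 non-negative weights for sizes 1..5")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("clutch_size_weights must sum to 1")
        if self.between_clutch_cov is not None:
            self.between_clutch_cov = check_psd(self.between_clutch_cov, "between_clutch_cov")
        if self.within_clutch_cov is not None:
            self.within_clutch_cov = check_psd(self.within_clutch_cov, "within_clutch_cov")


@dataclass
class SyntheticDataset:
    """A generated egg table plus the ground truth that produced it."""

    eggs: pd.DataFrame
    truth: dict

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.eggs["species"]))


def _default_species_mean(rng: np.random.Generator) -> np.ndarray:
    """Plausible raw-scale species mean: cone catches near 1/4, bounded metrics mid-range."""
    mean = np.empty(N_METRICS)
    q = rng.dirichlet(np.full(4, 20.0))
    mean[:4] = q
    mean[4:] = rng.uniform(0.3, 0.8, size=N_METRICS - 4)
    return mean


def generate_species_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a two-family, multi-species egg-phenotype table.

    For each species a clutch mean is drawn from ``Normal(species mean, Σ_b)``
    and each egg from ``Normal(clutch mean, Σ_w)``; clutch sizes follow the
    configured distribution over 1–5; each clutch carries an independent
    Bernoulli(parasitism rate) parasitism indicator. Metrics are unconstrained
    Gaussians by default (the covariance ground truth stays exact); with
    ``clip_to_valid_ranges`` cone catches are renormalized to sum to one and
    bounded metrics are clipped to [0, 1].
    """
    cfg = config
    rng_struct = substream(cfg.seed, "dataset-structure")
    rng_pheno = substream(cfg.seed, "dataset-phenotypes")
    rng_par = substream(cfg.seed, "dataset-parasitism")

    n1, n2 = cfg.n_species_per_family
    families = ["warbler"] * n1 + ["weaver"] * n2
    n_species = n1 + n2
    species_names = [f"sp{idx:02d}" for idx in range(n_species)]

    # parasitized species and their local rates
    n_par = int(round(cfg.parasitized_fraction * n_species))
    par_species = set(rng_par.choice(n_species, size=n_par, replace=False).tolist())
    rates = {
        s: (float(rng_par.uniform(*cfg.parasitism_rate_range)) if s in par_species else 0.0)
        for s in range(n_species)
    }
    # species with parasitism records elsewhere in their range (a few unparasitized ones)
    unpar = [s for s in range(n_species) if s not in par_species]
    n_elsewhere = min(5, len(unpar))
    elsewhere = set(rng_par.choice(unpar, size=n_elsewhere, replace=False).tolist()) if n_elsewhere else set()

    # immaculate species: last ones of the second family
    immaculate = set(range(n_species - cfg.n_immaculate_species, n_species)) if cfg.n_immaculate_species else set()
    pattern_idx = [METRIC_COLUMNS.index(c) for c in PATTERN_COLUMNS]

    sizes = np.arange(CLUTCH_SIZE_MIN, CLUTCH_SIZE_MAX + 1)
    weights = np.asarray(cfg.clutch_size_weights, dtype=float)

    rows: list[dict] = []
    truth: dict = {"config_seed": cfg.seed, "species": {}}
    for s in range(n_species):
        name = species_names[s]
        mean = (
            np.asarray(cfg.species_means[s], dtype=float)
            if cfg.species_means is not None
            else _default_species_mean(rng_pheno)
        )
        if cfg.between_clutch_cov is not None:
            sigma_b = cfg.between_clutch_cov
        else:
            var_b = rng_pheno.uniform(*cfg.between_sd_range, size=N_METRICS) ** 2
            sigma_b = covariance_from(var_b, random_correlation(N_METRICS, rng_pheno))
        if cfg.within_clutch_cov is not None:
            sigma_w = cfg.within_clutch_cov
        else:
            var_w = rng_pheno.uniform(*cfg.within_sd_range, size=N_METRICS) ** 2
            sigma_w = covariance_from(var_w, random_correlation(N_METRICS, rng_pheno))
        if s in immaculate:
            mean = mean.copy()
            mean[pattern_idx] = 0.0
            sigma_b = sigma_b.copy()
            sigma_w = sigma_w.copy()
            for m in (sigma_b, sigma_w):
                m[pattern_idx, :] = 0.0
                m[:, pattern_idx] = 0.0

        lo, hi = cfg.clutch_count_per_species
        n_clutches = int(rng_struct.integers(lo, hi + 1)) if hi > lo else int(lo)
        clutch_sizes = rng_struct.choice(sizes, size=n_clutches, p=weights)

        lb = psd_factor(sigma_b)
        lw = psd_factor(sigma_w)
        for c in range(n_clutches):
            clutch_mean = mean + lb @ rng_pheno.standard_normal(N_METRICS)
            parasitized = bool(rng_par.random() < rates[s])
            for e in range(int(clutch_sizes[c])):
                egg = clutch_mean + lw @ rng_pheno.standard_normal(N_METRICS)
                if s in immaculate:
                    egg[pattern_idx] = 0.0
                if cfg.clip_to_valid_ranges:
                    egg = _map_to_valid_ranges(egg)
                row = {
                    "species": name,
                    "family": families[s],
                    "clutch_id": f"{name}_c{c:03d}",
                    "egg_id": f"{name}_c{c:03d}_e{e}",
                    "parasitized": parasitized,
                    "parasitized_elsewhere": s in elsewhere,
                }
                row.update(dict(zip(METRIC_COLUMNS, egg)))
                rows.append(row)
        truth["species"][name] = {
            "family": families[s],
            "mean": mean.tolist(),
            "sigma_b": sigma_b.tolist(),
            "sigma_w": sigma_w.tolist(),
            "parasitism_rate": rates[s],
            "parasitized_elsewhere": s in elsewhere,
            "immaculate": s in immaculate,
            "n_clutches": int(n_clutches),
        }

    eggs = pd.DataFrame(rows)
    return SyntheticDataset(eggs=eggs, truth=truth)


def _map_to_valid_ranges(egg: np.ndarray) -> np.ndarray:
    """Post-hoc constraint mapping: cone catches to the simplex, the rest to [0, 1]."""
    out = egg.copy()
    q = np.clip(out[:4], 1e-6, None)
    out[:4] = q / q.sum()
    out[4:] = np.clip(out[4:], 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# phylogenies and traits
# ---------------------------------------------------------------------------


def generate_tree(
    n_tips: int,
    seed: int,
    birth_rate: float = 1.0,
    taxon_labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    Lineages split after exponential waiting times with total rate
    ``birth_rate × (number of lineages)``; after the last split the clock runs
    for one further exponential waiting time, and all tips terminate at that
    final time, so the tree is exactly ultrametric.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    rng = substream(seed, "yule-tree")

    labels = list(taxon_labels) if taxon_labels is not None else [f"t{i}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("taxon_labels length must equal n_tips")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.edge.length = t - birth if node.parent_node is not None else None
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.extend([(left, t), (right, t)])
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    order = rng.permutation(len(active))
    for k, idx in enumerate(order):
        node, birth = active[idx]
        node.edge.length = t - birth
        node.taxon = taxa.get_taxon(labels[k])
    tree.seed_node.edge.length = None
    return tree


def simulate_trait_with_lambda(
    tree: dendropy.Tree, lambda_true: float, seed: int, sigma2: float = 1.0
) -> pd.Series:
    """Draw one tip trait vector with covariance = λ-scaled Brownian covariance.

    The Brownian covariance entry for tips i, j is their shared root-to-tip
    branch length; λ multiplies the off-diagonal entries only (λ = 0: i.i.d.
    tips; λ = 1: plain Brownian motion). Returns a Series indexed by tip label.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    from .comparative_models import phylo_covariance

    labels, vcv = phylo_covariance(tree, lambda_true)
    rng = substream(seed, "lambda-trait")
    chol = psd_factor(sigma2 * vcv)
    values = chol @ rng.standard_normal(len(labels))
    return pd.Series(values, index=labels, name="trait")


# ---------------------------------------------------------------------------
# egg images
# ---------------------------------------------------------------------------


@dataclass
class ImageGroundTruth:
    """Known pattern ground truth for one generated egg image.

    Either ``coverage_true`` (spots placed until the target fraction of masked
    pixels is covered) or ``spot_count`` drives spot placement; ``polar_bias``
    is the probability that a spot falls in the blunt (top) half of the egg.
    """

    spot_radius_px: float = 4.0
    spot_count: int | None = None
    coverage_true: float | None = 0.2
    polar_bias: float = 0.5
    background_level: float = 0.75
    spot_level: float = 0.25

    def __post_init__(self) -> None:
        if self.coverage_true is not None and not 0.0 <= self.coverage_true <= 1.0:
            raise ValueError("coverage_true must lie in [0, 1]")
        if not 0.0 <= self.polar_bias <= 1.0:
            raise ValueError("polar_bias must lie in [0, 1]")
        for lvl in (self.background_level, self.spot_level):
            if not 0.0 <= lvl <= 1.0:
                raise ValueError("grayscale levels must lie in [0, 1]")
        if self.coverage_true is None and self.spot_count is None:
            raise ValueError("one of coverage_true or spot_count is required")


def generate_egg_image(
    truth: ImageGroundTruth,
    size_px: tuple[int, int] = (160, 128),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a grayscale egg image with circular spots on an elliptical mask.

    Returns ``(image, mask, realized)`` where ``image`` is float in [0, 1],
    ``mask`` is the boolean egg region (major axis vertical, blunt pole at the
    top) and ``realized`` records the realized coverage, spot count and the
    boolean spot mask.
    """
    h, w = size_px
    if truth.spot_radius_px >= min(h, w) / 2:
        raise ValueError("spot radius must be smaller than the image")
    rng = substream(seed, "egg-image")

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.45 * h, 0.42 * w
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    n_mask = int(mask.sum())

    image = np.zeros((h, w), dtype=float)
    image[mask] = truth.background_level
    spots = np.zeros((h, w), dtype=bool)

    r = truth.spot_radius_px
    dy, dx = np.mgrid[-int(np.ceil(r)) : int(np.ceil(r)) + 1, -int(np.ceil(r)) : int(np.ceil(r)) + 1]
    disk = dy**2 + dx**2 <= r**2

    target_cov = truth.coverage_true
    target_count = truth.spot_count
    centers: list[tuple[int, int]] = []
    placed = 0
    attempts = 0
    max_attempts = 20000
    while True:
        if target_cov is not None:
            if spots[mask].sum() / n_mask >= target_cov:
                break
        elif placed >= (target_count or 0):
            break
        if attempts > max_attempts:
            raise ValueError(
                "infeasible coverage: could not place enough non-overlapping spots "
                f"(placed {placed}, realized coverage {spots[mask].sum() / n_mask:.3f})"
            )
        attempts += 1
        top = rng.random() < truth.polar_bias
        # the whole disk stays inside the chosen half, so extreme bias is exact
        y = rng.uniform(0, cy - r - 1) if top else rng.uniform(cy + r + 1, h - 1)
        x = rng.uniform(0, w - 1)
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < h and 0 <= ix < w) or not mask[iy, ix]:
            continue
        # keep spots disjoint so realized coverage is a clean sum of disk areas
        if any((iy - py) ** 2 + (ix - px) ** 2 < (2 * r) ** 2 for py, px in centers):
            continue
        ys, xs = np.nonzero(disk)
        ys, xs = ys + iy - disk.shape[0] // 2, xs + ix - disk.shape[1] // 2
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ys, xs = ys[ok], xs[ok]
        inside = mask[ys, xs]
        spots[ys[inside], xs[inside]] = True
        centers.append((iy, ix))
        placed += 1

    image[spots] = truth.spot_level
    realized = {
        "coverage_realized": float(spots[mask].sum() / n_mask),
        "spot_count_realized": placed,
        "spot_mask": spots,
        "centers": centers,
        "blunt_half_spot_pixels": int(spots[: int(np.floor(cy)) + 1, :].sum()),
        "pointed_half_spot_pixels": int(spots[int(np.floor(cy)) + 1 :, :].sum()),
    }
    return image, mask, realized


# ---------------------------------------------------------------------------
# reflectance spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectrumShape:
    """Shape parameters for a smooth synthetic reflectance spectrum."""

    baseline: float = 0.3
    bumps: tuple[tuple[float, float, float], ...] = ()  # (center nm, width nm, amplitude)
    n_random_bumps: int = 0
    amplitude_range: tuple[float, float] = (0.05, 0.3)
    width_range: tuple[float, float] = (20.0, 80.0)


def generate_spectrum(
    shape: SpectrumShape,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
):
    """Generate a smooth reflectance spectrum in [0, 1] on a 300–700 nm grid.

    The curve is a baseline plus Gaussian bumps (fixed and/or randomly drawn),
    squashed through a logistic map only if it would leave [0, 1].
    """
    from .visual_phenotype import ReflectanceSpectrum

    wl = np.arange(300.0, 701.0, 2.0) if wavelengths is None else np.asarray(wavelengths, float)
    if wl.size == 0:
        raise ValueError("wavelength grid is empty")
    if wl.size > 1 and np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    rng = substream(seed, "spectrum")
    refl = np.full_like(wl, shape.baseline)
    bumps = list(shape.bumps)
    for _ in range(shape.n_random_bumps):
        bumps.append(
            (
                float(rng.uniform(wl[0], wl[-1])),
                float(rng.uniform(*shape.width_range)),
                float(rng.uniform(*shape.amplitude_range)),
            )
        )
    for center, width, amp in bumps:
        refl = refl + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if refl.min() < 0.0 or refl.max() > 1.0:
        refl = 1.0 / (1.0 + np.exp(-(refl - 0.5) * 4.0))
    return ReflectanceSpectrum(wavelengths=wl, reflectance=refl)


# ---------------------------------------------------------------------------
# species-level scenario tables (strategy-blocking and null)
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Species-level generative model for recovery experiments.

    Consistency is generated as a linear function of combinatorial
    distinctiveness with a group-specific slope:
    ``consistency = intercept + slope[status] · combinatorial + ε``. Default
    slopes are −0.18 (parasitized) and −0.03 (unparasitized) — the
    strategy-blocking scenario in which only parasitized species trade
    consistency against combinatorial distinctiveness; equal slopes give the
    no-effect null. The predictor spread (s.d. 0.5 nats) and residual noise
    (s.d. 0.12) are chosen so that group-slope standard errors at this sample
    size are ≈ 0.07, the precision regime the method is meant to operate in.
    """

    n_species_per_family: tuple[int, int] = (11, 14)
    parasitized_fraction: float = 0.6
    slope_parasitized: float = -0.18
    slope_unparasitized: float = -0.03
    intercept: float = 0.75
    combinatorial_mean: float = -1.0
    combinatorial_sd: float = 0.5
    residual_sd: float = 0.12
    seed: int = 0


def generate_scenario_table(config: ScenarioConfig) -> pd.DataFrame:
    """Generate a per-species signature + status table with known group slopes."""
    cfg = config
    rng = substream(cfg.seed, "scenario")
    n1, n2 = cfg.n_species_per_family
    n = n1 + n2
    families = ["warbler"] * n1 + ["weaver"] * n2
    n_par = int(round(cfg.parasitized_fraction * n))
    parasitized = np.zeros(n, dtype=bool)
    parasitized[rng.choice(n, size=n_par, replace=False)] = True

    comb = rng.normal(cfg.combinatorial_mean, cfg.combinatorial_sd, size=n)
    slopes = np.where(parasitized, cfg.slope_parasitized, cfg.slope_unparasitized)
    consistency = cfg.intercept + slopes * comb + rng.normal(0.0, cfg.residual_sd, size=n)
    absolute = rng.normal(5.0, 1.0, size=n)
    n_clutches = rng.integers(5, 60, size=n)

    return pd.DataFrame(
        {
            "species": [f"sp{i:02d}" for i in range(n)],
            "family": families,
            "consistency": consistency,
            "absolute_distinctiveness": absolute,
            "combinatorial_distinctiveness": comb,
            "status_local": np.where(parasitized, "parasitized", "unparasitized"),
            "status_restrictive": np.where(parasitized, "parasitized", "unparasitized"),
            "n_clutches_used": n_clutches,
            "undefined_entropy": False,
        }
    )


# ---------------------------------------------------------------------------
# writers (CSV / Newick / PNG / JSON sidecar)
# ---------------------------------------------------------------------------


def save_bundle(
    outdir: str | Path,
    dataset: SyntheticDataset | None = None,
    trees: Sequence[dendropy.Tree] | None = None,
    images: Sequence[tuple[str, np.ndarray, np.ndarray, dict]] | None = None,
    spectra: Sequence[tuple[str, "object"]] | None = None,
) -> dict:
    """Write generated artefacts to disk and return a ground-truth sidecar dict.

    Phenotype tables go to ``eggs.csv``, trees to ``trees.nwk``, each image to
    ``<name>.png`` with mask ``<name>_mask.png`` (8-bit grayscale), spectra to
    2-column CSVs, and all ground truth to ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {}
    if dataset is not None:
        dataset.eggs.to_csv(outdir / "eggs.csv", index=False)
        sidecar["dataset"] = dataset.truth
    if trees:
        tl = dendropy.TreeList(trees, taxon_namespace=trees[0].taxon_namespace)
        tl.write(path=str(outdir / "trees.nwk"), schema="newick")
    if images:
        sidecar["images"] = {}
        for name, image, mask, realized in images:
            Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8)).save(outdir / f"{name}.png")
            Image.fromarray((mask.astype(np.uint8)) * 255).save(outdir / f"{name}_mask.png")
            sidecar["images"][name] = {
                k: v for k, v in realized.items() if k not in ("spot_mask", "centers")
            }
    if spectra:
        for name, spec in spectra:
            pd.DataFrame(
                {"wavelength_nm": spec.wavelengths, "reflectance": spec.reflectance}
            ).to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return sidecar


def config_to_dict(config) -> dict:
    """JSON-serializable snapshot of a generator config (arrays become lists)."""
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
    return out
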