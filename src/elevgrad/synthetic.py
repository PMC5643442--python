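"""Seeded synthetic two-slope trapping surveys.

Generates capture records, species traits and band covariates with the
statistical structure the downstream analysis assumes, so the whole
pipeline is testable without field data.  The generative model is
deliberately minimal:

* each species on each slope occupies a contiguous interval of bands
  whose size is drawn from a categorical distribution and whose position
  is either uniform over the feasible placements (the mid-domain null)
  or biased toward a per-species environmental optimum;
* abundance in each occupied band and season is Poisson; each individual
  is detected with probability ``1 - (1 - q)^T`` where ``q`` is the
  per-individual per-trap-night detection probability and ``T`` the
  season's trap-nights — binomial thinning of the Poisson count;
* covariates follow linear trends in elevation (temperature falls,
  humidity rises), NDVI responds linearly to both, and plant richness
  tracks temperature, with Gaussian noise on each — reproducing the
  sign structure of the field correlations (MAT-NDVI strongly negative,
  MAH-NDVI strongly positive).

Covariates are produced on the natural scale; log transforms are the
analysis stage's job.  Everything is reproducible from a single seed via
``numpy.random.SeedSequence`` stream splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .community import CaptureRecord, SpeciesTraits

__all__ = [
    "CovariateCoefs",
    "GradientSimConfig",
    "SyntheticDataset",
    "default_config",
    "generate_dataset",
    "generate_richness_from_model",
]


@dataclass(frozen=True)
class CovariateCoefs:
    """Linear generators for the band covariates (natural scale).

    Temperature follows a lapse rate from its value at the lowest band;
    humidity rises with elevation; NDVI = intercept + a*MAT + b*MAH; plant
    richness tracks temperature.  ``area_profile`` is one value per band
    per slope (km^2); the default gives the second slope a plateau-like
    bulge at the top of the gradient.
    """

    mat_at_base: float = 14.5          # deg C at the lowest band
    mat_lapse_per_m: float = -0.0055   # deg C per meter
    mah_at_base: float = 76.0          # % at the lowest band
    mah_slope_per_m: float = 0.006     # % per meter
    ndvi_intercept: float = 0.35
    ndvi_mat_coef: float = -0.020
    ndvi_mah_coef: float = 0.005
    psr_intercept: float = -20.0
    psr_mat_coef: float = 4.0
    area_profile: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "west": (30.0, 26.0, 22.0, 18.0, 14.0, 10.0),
            "east": (36.0, 34.0, 32.0, 31.0, 36.0, 46.0),
        }
    )


@dataclass(frozen=True)
class GradientSimConfig:
    """Settings for one synthetic survey.

    Defaults emulate a two-slope, six-band (1,800-2,800 m at 200-m steps)
    small-mammal survey with 27 and 33 species per slope (23 shared),
    roughly 1,100 trap-nights per season per band, and imperfect
    detection tuned so overall trap success lands near 8 captures per
    100 trap-nights.
    """

    n_bands: int = 6
    band_step: int = 200
    base_elevation: int = 1800
    slopes: tuple[str, str] = ("west", "east")
    n_species: Mapping[str, int] | int = field(
        default_factory=lambda: {"west": 27, "east": 33}
    )
    shared_species: int | None = 23
    range_size_dist: tuple[float, ...] = (0.16, 0.20, 0.20, 0.16, 0.14, 0.14)
    placement_mode: str = "mde_null"
    env_optimum_band: Mapping[str, float] | float | None = None
    env_breadth: float = 1.0
    detection_prob: float = 0.001       # per individual per trap-night
    trap_nights_per_band: int = 2200    # both seasons combined
    seasons: tuple[str, str] = ("dry", "wet")
    abundance_mean: float = 12.0        # individuals per occupied band (both seasons)
    covariate_coefs: CovariateCoefs = field(default_factory=CovariateCoefs)
    mat_sd: float = 0.3
    mah_sd: float = 1.0
    ndvi_sd: float = 0.03
    psr_sd: float = 7.0
    area_sd: float = 0.0
    endemic_prob: float = 0.5
    insectivore_prob: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        p = np.asarray(self.range_size_dist, dtype=float)
        if p.size != self.n_bands:
            raise ValueError(
                f"range_size_dist has {p.size} entries for {self.n_bands} bands"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("range_size_dist must be a probability vector")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in (0, 1]")
        if min(self.species_counts().values()) < 1:
            raise ValueError("each slope needs at least one species")
        for sd in (self.mat_sd, self.mah_sd, self.ndvi_sd, self.psr_sd, self.area_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")
        if self.placement_mode not in ("mde_null", "environmental"):
            raise ValueError(f"unknown placement_mode {self.placement_mode!r}")
        if not 0.0 <= self.endemic_prob <= 1.0:
            raise ValueError("endemic_prob must be in [0, 1]")
        if not 0.0 <= self.insectivore_prob <= 1.0:
            raise ValueError("insectivore_prob must be in [0, 1]")

    def species_counts(self) -> dict[str, int]:
        if isinstance(self.n_species, int):
            return {s: self.n_species for s in self.slopes}
        return {s: int(self.n_species[s]) for s in self.slopes}

    @property
    def bands(self) -> tuple[int, ...]:
        return tuple(
            self.base_elevation + i * self.band_step for i in range(self.n_bands)
        )


def default_config(seed: int = 0) -> GradientSimConfig:
    """The packaged two-slope default survey configuration."""
    return GradientSimConfig(seed=seed)


def wide_survey_config(
    n_bands: int, n_species: int = 40, seed: int = 0, **overrides
) -> GradientSimConfig:
    """A two-slope configuration on an ``n_bands``-band domain.

    Used for parameter-recovery experiments that need more band units
    than the six-band default (e.g. 2 x 30 bands).  Range sizes are
    uniform over 1..n_bands and the area profiles interpolate the
    default shapes (one slope tapering, the other bulging at the top).
    """
    west = tuple(np.linspace(30.0, 10.0, n_bands))
    east = tuple(36.0 - 5.0 * t + 15.0 * t**4 for t in np.linspace(0, 1, n_bands))
    cc = CovariateCoefs(area_profile={"west": west, "east": east})
    kwargs = dict(
        n_bands=n_bands,
        # keep the gradient's elevational span near 1,000 m regardless of
        # band count, so the covariate trends stay in a realistic regime
        band_step=max(1, round(1000 / (n_bands - 1))),
        n_species=n_species,
        shared_species=0,
        range_size_dist=tuple([1.0 / n_bands] * n_bands),
        covariate_coefs=cc,
        seed=seed,
    )
    kwargs.update(overrides)
    return GradientSimConfig(**kwargs)


@dataclass(frozen=True)
class SyntheticDataset:
    """One generated survey: captures, traits, covariates, and the truth.

    ``truth`` records the generating ranges (band-index intervals per
    species x slope), the covariate coefficients, and the seed, so
    recovery tests can compare the analysis output against it.
    """

    captures: tuple[CaptureRecord, ...]
    traits: dict[str, SpeciesTraits]
    covariates: pd.DataFrame
    truth: dict
    config: GradientSimConfig

    def captures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": c.species,
                    "slope": c.slope,
                    "elevation": c.elevation,
                    "season": c.season,
                    "count": c.count,
                }
                for c in self.captures
            ]
        )

    def traits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": t.species,
                    "taxon_group": t.taxon_group,
                    "endemic": t.endemic,
                }
                for t in sorted(self.traits.values(), key=lambda t: t.species)
            ]
        )


def _species_pools(config: GradientSimConfig) -> dict[str, list[str]]:
    """Per-slope species code lists drawn from one global pool with overlap."""
    counts = config.species_counts()
    s1, s2 = config.slopes
    shared = config.shared_species
    if shared is None:
        shared = round(0.7 * min(counts.values()))
    shared = min(shared, min(counts.values()))
    pool_size = counts[s1] + counts[s2] - shared
    codes = [f"sp{i + 1:03d}" for i in range(pool_size)]
    return {
        s1: codes[: counts[s1]],
        s2: codes[counts[s1] - shared: counts[s1] - shared + counts[s2]],
    }


def _draw_range(
    rng: np.random.Generator, config: GradientSimConfig, slope: str
) -> tuple[int, int]:
    """(start band index, size) for one species range."""
    m = config.n_bands
    size = int(rng.choice(np.arange(1, m + 1), p=config.range_size_dist))
    n_pos = m - size + 1
    if config.placement_mode == "mde_null":
        start = int(rng.integers(0, n_pos))
    else:
        opt = config.env_optimum_band
        if isinstance(opt, Mapping):
            opt = opt[slope]
        if opt is None:
            opt = float(rng.uniform(0, m - 1))
        centers = np.arange(n_pos) + (size - 1) / 2.0
        w = np.exp(-0.5 * ((centers - opt) / config.env_breadth) ** 2)
        start = int(rng.choice(np.arange(n_pos), p=w / w.sum()))
    return start, size


def _generate_covariates(
    rng: np.random.Generator, config: GradientSimConfig
) -> pd.DataFrame:
    cc = config.covariate_coefs
    rows = []
    for slope in config.slopes:
        profile = np.asarray(cc.area_profile[slope], dtype=float)
        if profile.size != config.n_bands:
            raise ValueError(
                f"area profile for {slope!r} has {profile.size} entries "
                f"for {config.n_bands} bands"
            )
        for i, elev in enumerate(config.bands):
            dz = elev - config.base_elevation
            mat = cc.mat_at_base + cc.mat_lapse_per_m * dz + rng.normal(0, config.mat_sd)
            mah = cc.mah_at_base + cc.mah_slope_per_m * dz + rng.normal(0, config.mah_sd)
            ndvi = (
                cc.ndvi_intercept + cc.ndvi_mat_coef * mat + cc.ndvi_mah_coef * mah
                + rng.normal(0, config.ndvi_sd)
            )
            psr = cc.psr_intercept + cc.psr_mat_coef * mat + rng.normal(0, config.psr_sd)
            area = profile[i] * float(np.exp(rng.normal(0, config.area_sd)))
            rows.append(
                {
                    "slope": slope,
                    "elevation": elev,
                    "area": area,
                    "MAT": mat,
                    "MAH": mah,
                    "NDVI": float(np.clip(ndvi, -1.0, 1.0)),
                    "PSR": max(psr, 1.0),
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(config: GradientSimConfig) -> SyntheticDataset:
    """Generate one fully reproducible synthetic survey from ``config``."""
    ss = np.random.SeedSequence(config.seed)
    rng_ranges, rng_counts, rng_cov, rng_traits = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    pools = _species_pools(config)
    bands = config.bands

    # traits once per species (shared across slopes)
    all_species = sorted({sp for pool in pools.values() for sp in pool})
    traits = {
        sp: SpeciesTraits(
            species=sp,
            taxon_group="insectivore"
            if rng_traits.random() < config.insectivore_prob
            else "rodent",
            endemic=bool(rng_traits.random() < config.endemic_prob),
        )
        for sp in all_species
    }

    # true ranges, then detections
    tn_per_season = config.trap_nights_per_band / len(config.seasons)
    p_detect = 1.0 - (1.0 - config.detection_prob) ** tn_per_season
    mean_per_season = config.abundance_mean / len(config.seasons)
    truth_ranges: dict[str, dict[str, list[int]]] = {s: {} for s in config.slopes}
    captures: list[CaptureRecord] = []
    for slope in config.slopes:
        for sp in pools[slope]:
            start, size = _draw_range(rng_ranges, config, slope)
            truth_ranges[slope][sp] = [start, start + size - 1]
            for b in range(start, start + size):
                for season in config.seasons:
                    n_ind = int(rng_counts.poisson(mean_per_season))
                    caught = int(rng_counts.binomial(n_ind, p_detect)) if n_ind else 0
                    if caught > 0:
                        captures.append(
                            CaptureRecord(
                                species=sp,
                                slope=slope,
                                elevation=bands[b],
                                season=season,
                                count=caught,
                            )
                        )

    covariates = _generate_covariates(rng_cov, config)
    truth = {
        "seed": config.seed,
        "bands": list(bands),
        "ranges": truth_ranges,
        "detection_prob": config.detection_prob,
        "abundance_mean": config.abundance_mean,
        "covariate_coefs": asdict(config.covariate_coefs),
    }
    return SyntheticDataset(
        captures=tuple(captures),
        traits=traits,
        covariates=covariates,
        truth=truth,
        config=config,
    )


def generate_richness_from_model(
    design: pd.DataFrame,
    coefficients: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    integer_output: bool = False,
) -> np.ndarray:
    """Richness from a known linear model on an analysis-scale design.

    ``richness_i = sum_t coef_t * x_it + N(0, noise_sd)``; the key
    ``"intercept"`` maps to a constant column.  Coefficient keys must
    match design columns (after any log transforms the caller applied).
    Used for parameter-recovery tests of the model-selection machinery.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = len(design)
    y = np.zeros(n, dtype=float)
    for term, coef in coefficients.items():
        if term == "intercept":
            y += float(coef)
        elif term in design.columns:
            y += float(coef) * np.asarray(design[term], dtype=float)
        else:
            raise KeyError(f"unknown term {term!r}; design has {list(design.columns)}")
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    if integer_output:
        y = np.maximum(np.rint(y), 0.0)
    return y
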