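"""Community assembly along an elevational gradient.

Turns trapping records into per-species elevational ranges on a discrete
band domain, applies the interpolation rule (a species detected at two
elevations is assumed present at every band in between), partitions the
species pool into ecological groups, and computes per-band richness
vectors plus a few classical survey summary statistics (Sorensen
similarity, trap success, NDVI, richness-abundance correlation).

Bands are the sampling unit throughout: a band is identified by its index
``0..n_bands-1`` into the sorted vector of design elevations, and range
size is measured in occupied band count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

GROUP_LABELS = (
    "total",
    "insectivores",
    "rodents",
    "large_ranged",
    "small_ranged",
    "endemic",
    "non_endemic",
)

TAXON_GROUPS = ("insectivore", "rodent")


@dataclass(frozen=True)
class CaptureRecord:
    """One trapping (or sighting) observation at a design band."""

    species: str
    slope: str
    elevation: int
    season: str = ""
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative count for {self.species}: {self.count}")


@dataclass(frozen=True)
class SpeciesTraits:
    """Taxonomic group and endemism flag for one species."""

    species: str
    taxon_group: str
    endemic: bool

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"unknown taxon_group {self.taxon_group!r} for {self.species}; "
                f"expected one of {TAXON_GROUPS}"
            )


@dataclass(frozen=True)
class ElevationalRange:
    """Occupied band set for one species on one slope.

    ``observed_bands`` holds band indices with at least one detection;
    ``interpolated_bands`` is the full integer interval between the lowest
    and highest observed band.
    """

    species: str
    slope: str
    observed_bands: frozenset[int]
    band_step: int = 200

    def __post_init__(self) -> None:
        if not self.observed_bands:
            raise ValueError(f"empty range for {self.species}/{self.slope}")

    @property
    def interpolated_bands(self) -> frozenset[int]:
        lo, hi = min(self.observed_bands), max(self.observed_bands)
        return frozenset(range(lo, hi + 1))

    @property
    def range_size(self) -> int:
        """Number of bands in the interpolated range."""
        return max(self.observed_bands) - min(self.observed_bands) + 1

    @property
    def range_extent(self) -> int:
        """Range extent in meters, counting each occupied band as one step."""
        return self.range_size * self.band_step

    def bands(self, mode: str = "interpolated") -> frozenset[int]:
        if mode == "observed":
            return self.observed_bands
        if mode == "interpolated":
            return self.interpolated_bands
        raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class RichnessProfile:
    """Per-band species richness of one group on one slope."""

    group_label: str
    slope: str
    richness: tuple[int, ...]
    mode: str = "observed"

    def as_array(self) -> np.ndarray:
        return np.asarray(self.richness, dtype=float)


def band_index(elevation: float, bands: Sequence[int]) -> int:
    """Index of ``elevation`` in the design band vector; exact match required."""
    try:
        return list(bands).index(int(elevation))
    except ValueError:
        raise ValueError(
            f"elevation {elevation} is not a design band (bands: {list(bands)})"
        ) from None


def build_ranges(
    captures: Iterable[CaptureRecord],
    bands: Sequence[int],
    band_step: int | None = None,
) -> list[ElevationalRange]:
    """Build one :class:`ElevationalRange` per species x slope with presence.

    Rows with ``count == 0`` carry no presence; a species whose records are
    all zero-count is absent from the output.  A capture at an elevation
    outside the design raises, naming the offending record.
    """
    bands = sorted(int(b) for b in bands)
    if band_step is None:
        band_step = int(bands[1] - bands[0]) if len(bands) > 1 else 200
    occupied: dict[tuple[str, str], set[int]] = {}
    for i, rec in enumerate(captures):
        if rec.elevation not in bands:
            raise ValueError(
                f"record {i} ({rec.species}, {rec.slope}): elevation "
                f"{rec.elevation} is not one of the design bands {bands}"
            )
        if rec.count > 0:
            occupied.setdefault((rec.species, rec.slope), set()).add(
                bands.index(rec.elevation)
            )
    return [
        ElevationalRange(species=sp, slope=sl, observed_bands=frozenset(bset),
                         band_step=band_step)
        for (sp, sl), bset in sorted(occupied.items())
    ]


def interpolate_presence(rng: ElevationalRange) -> ElevationalRange:
    """Fill gaps between the lowest and highest observed band (idempotent)."""
    return ElevationalRange(
        species=rng.species,
        slope=rng.slope,
        observed_bands=rng.interpolated_bands,
        band_step=rng.band_step,
    )


def classify_range_size(
    ranges: Iterable[ElevationalRange],
) -> dict[str, str]:
    """Median split of range sizes into ``large`` / ``small``.

    Large-ranged species are those whose range size strictly exceeds the
    median size of the supplied pool; ties at the median are small.  Pass
    a single slope's ranges for the per-slope split, or a pooled
    collection for a pooled split.
    """
    ranges = list(ranges)
    if not ranges:
        raise ValueError("cannot classify an empty species pool")
    sizes = {r.species: r.range_size for r in ranges}
    med = float(np.median(list(sizes.values())))
    return {sp: ("large" if sz > med else "small") for sp, sz in sizes.items()}


def group_members(
    ranges: Sequence[ElevationalRange],
    traits: Mapping[str, SpeciesTraits],
    group_label: str,
) -> list[ElevationalRange]:
    """Subset of ``ranges`` belonging to ``group_label``.

    The range-size split is computed over the species in ``ranges``
    (i.e. per slope when a single slope's ranges are passed).
    """
    if group_label == "total":
        return list(ranges)
    if group_label in ("large_ranged", "small_ranged"):
        split = classify_range_size(ranges)
        want = "large" if group_label == "large_ranged" else "small"
        return [r for r in ranges if split[r.species] == want]
    missing = sorted({r.species for r in ranges} - set(traits))
    if missing:
        raise KeyError(f"species missing from traits: {missing}")
    if group_label == "insectivores":
        return [r for r in ranges if traits[r.species].taxon_group == "insectivore"]
    if group_label == "rodents":
        return [r for r in ranges if traits[r.species].taxon_group == "rodent"]
    if group_label == "endemic":
        return [r for r in ranges if traits[r.species].endemic]
    if group_label == "non_endemic":
        return [r for r in ranges if not traits[r.species].endemic]
    raise ValueError(f"unknown group {group_label!r}; expected one of {GROUP_LABELS}")


def group_richness(
    ranges: Sequence[ElevationalRange],
    traits: Mapping[str, SpeciesTraits],
    group_label: str,
    n_bands: int,
    mode: str = "observed",
) -> RichnessProfile:
    """Per-band richness of one species group on one slope.

    ``ranges`` must all belong to a single slope; richness at band *j* is
    the number of group members whose (observed or interpolated) band set
    contains *j*.
    """
    slopes = {r.slope for r in ranges}
    if len(slopes) > 1:
        raise ValueError(f"ranges span multiple slopes: {sorted(slopes)}")
    members = group_members(ranges, traits, group_label)
    rich = np.zeros(n_bands, dtype=int)
    for r in members:
        for b in r.bands(mode):
            rich[b] += 1
    return RichnessProfile(
        group_label=group_label,
        slope=slopes.pop() if slopes else "",
        richness=tuple(int(x) for x in rich),
        mode=mode,
    )


def sorensen_index(s1: int, s2: int, shared: int) -> float:
    """Sorensen similarity 100 * 2c / (S1 + S2), in percent."""
    if shared > min(s1, s2):
        raise ValueError(f"shared ({shared}) exceeds min richness ({min(s1, s2)})")
    if s1 + s2 <= 0:
        raise ValueError("both assemblages are empty")
    if min(s1, s2, shared) < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * 2.0 * shared / (s1 + s2)


def trap_success(total_captures: int, total_trap_nights: int) -> float:
    """Captures per 100 trap-nights."""
    if total_trap_nights <= 0:
        raise ValueError("trap-nights must be positive")
    if total_captures < 0:
        raise ValueError("captures must be non-negative")
    return 100.0 * total_captures / total_trap_nights


def compute_ndvi(nir_reflectance, red_reflectance):
    """NDVI = (nir - red) / (nir + red); NaN where the denominator is zero."""
    nir = np.asarray(nir_reflectance, dtype=float)
    red = np.asarray(red_reflectance, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0.0, (nir - red) / denom, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def richness_abundance_correlation(
    richness: Sequence[float], abundance: Sequence[float]
) -> tuple[float, float]:
    """Pearson r between per-band richness and abundance, with t-based p."""
    x = np.asarray(richness, dtype=float)
    y = np.asarray(abundance, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
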