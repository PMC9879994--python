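"""Core record types for specimen and belt-transect data.

Units are fixed package-wide: diameters and lengths in cm, weights in g,
transect dimensions in m, biomass densities in g·m⁻².  All records validate
on construction; invalid field combinations raise :class:`RecordError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: The six harvested large-polyp stony (LPS) species the package is
#: calibrated for.  The enumeration is extensible: validation accepts any
#: label when an explicit ``species`` vocabulary is passed.
STUDY_SPECIES: tuple[str, ...] = (
    "Catalaphyllia jardinei",
    "Duncanopsammia axifuga",
    "Euphyllia glabrescens",
    "Homophyllia cf. australis",
    "Micromussa lordhowensis",
    "Trachyphyllia geoffroyi",
)

#: Australian states with active coral harvest fisheries.
STATES: tuple[str, ...] = ("QLD", "WA", "NT")


class RecordError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One weighed and measured coral piece (whole colony or fragment).

    Parameters
    ----------
    species : str
        Species label; one of :data:`STUDY_SPECIES` unless a custom
        vocabulary is supplied at read time.
    state : str
        Collection state, one of :data:`STATES`.
    max_diameter_cm : float
        Maximum colony diameter in cm (> 0); the size covariate of the
        size-weight model.
    weight_g : float
        Drained wet weight in g (> 0).
    perp_diameter_cm : float, optional
        Diameter perpendicular to the maximum; must not exceed it.
    is_fragment : bool
        Whether the piece is a fragment rather than a whole colony.  Carried
        through but does not alter fitting (fragments pool with colonies).
    """

    species: str
    state: str
    max_diameter_cm: float
    weight_g: float
    perp_diameter_cm: float | None = None
    site: str | None = None
    region: str | None = None
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.max_diameter_cm > 0:
            raise RecordError(f"max_diameter_cm must be > 0, got {self.max_diameter_cm}")
        if not self.weight_g > 0:
            raise RecordError(f"weight_g must be > 0, got {self.weight_g}")
        if self.perp_diameter_cm is not None:
            if not self.perp_diameter_cm > 0:
                raise RecordError("perp_diameter_cm must be > 0 when present")
            if self.perp_diameter_cm > self.max_diameter_cm:
                raise RecordError(
                    "perp_diameter_cm exceeds max_diameter_cm "
                    f"({self.perp_diameter_cm} > {self.max_diameter_cm})"
                )

    def validate_vocab(self, species: Sequence[str], states: Sequence[str] = STATES) -> None:
        if self.species not in species:
            raise RecordError(f"unknown species label {self.species!r}")
        if self.state not in states:
            raise RecordError(f"unknown state label {self.state!r}")


@dataclass(frozen=True)
class CoralMeasurement:
    """A single coral measured on a video-transect frame."""

    species: str
    max_length_cm: float
    width_cm: float | None = None
    partially_visible: bool = False

    def __post_init__(self) -> None:
        if not self.max_length_cm > 0:
            raise RecordError(f"max_length_cm must be > 0, got {self.max_length_cm}")
        if self.width_cm is not None and self.width_cm > self.max_length_cm:
            raise RecordError("width_cm exceeds max_length_cm")


@dataclass(frozen=True)
class TransectRecord:
    """A belt transect (default 50 × 1 m) with its measured corals."""

    transect_id: str
    state: str
    corals: tuple[CoralMeasurement, ...] = ()
    location: str | None = None
    reef: str | None = None
    site: str | None = None
    depth_m: float = 0.0
    length_m: float = 50.0
    width_m: float = 1.0

    def __post_init__(self) -> None:
        if not (self.length_m > 0 and self.width_m > 0):
            raise RecordError("transect length_m and width_m must be > 0")
        if self.depth_m < 0:
            raise RecordError("depth_m must be >= 0")
        object.__setattr__(self, "corals", tuple(self.corals))

    @property
    def area_m2(self) -> float:
        return self.length_m * self.width_m


@dataclass(frozen=True)
class FrameScale:
    """Scale reference for a captured video frame.

    A jig bar of known length (``reference_length_m``, the 1 m conduit) spans
    ``reference_pixels`` pixels in the frame, fixing the cm-per-pixel factor.
    """

    reference_length_m: float
    reference_pixels: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        if not self.reference_pixels > 0:
            raise RecordError("reference_pixels must be > 0")
        if not self.reference_length_m > 0:
            raise RecordError("reference_length_m must be > 0")

    @property
    def cm_per_pixel(self) -> float:
        return 100.0 * self.reference_length_m / self.reference_pixels


@dataclass(frozen=True)
class DensityEstimate:
    """Per-transect, per-species biomass per unit area.

    Emitted only for transects where the species occurred (occupied-transect
    convention), so ``n_corals >= 1``.  Conservation holds by construction:
    ``density_g_per_m2`` is exactly ``total_biomass_g / area_m2`` (one
    floating-point rounding; the product reconstructs the total to 1 ulp).
    """

    species: str
    transect_id: str
    state: str
    total_biomass_g: float
    area_m2: float
    n_corals: int
    n_skipped: int = 0
    n_extrapolated: int = 0
    density_g_per_m2: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise RecordError("area_m2 must be > 0")
        if self.n_corals < 1:
            raise RecordError("DensityEstimate requires at least one coral")
        object.__setattr__(self, "density_g_per_m2", self.total_biomass_g / self.area_m2)
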