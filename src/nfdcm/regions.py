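"""Canonical region set for the self-regulation network.

The analysis operates on four regions of interest in a fixed order:

``F``
    Frontal node (superior and middle frontal gyrus).
``ACC``
    Anterior cingulate cortex (subgenual, pregenual and supracallosal parts).
``S``
    Striatum (putamen and nucleus accumbens).
``SMA``
    Supplementary motor area — the neurofeedback target region.

Anatomical codes are AAL3 atlas label numbers and are carried as metadata
only; the simulator and estimator never touch voxel data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["RegionSet", "DEFAULT_REGIONS", "REGION_LABELS", "F", "ACC", "S", "SMA"]

#: Canonical region order used by every matrix in the package.
REGION_LABELS: tuple[str, ...] = ("F", "ACC", "S", "SMA")

# Indices, for readable mask construction elsewhere.
F, ACC, S, SMA = 0, 1, 2, 3

_DEFAULT_CODES: dict[str, tuple[int, ...]] = {
    "F": (3, 4, 5, 6),
    "ACC": (151, 152, 153, 154, 155, 156),
    "S": (78, 80, 157, 158),
    "SMA": (16,),
}


@dataclass(frozen=True)
class RegionSet:
    """Ordered set of the four network regions with AAL3 atlas codes."""

    labels: tuple[str, ...] = REGION_LABELS
    anatomical_codes: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CODES)
    )

    def __post_init__(self) -> None:
        if tuple(self.labels) != REGION_LABELS:
            raise ValueError(
                f"regions must be exactly {REGION_LABELS} in canonical order, "
                f"got {tuple(self.labels)}"
            )
        if set(self.anatomical_codes) != set(REGION_LABELS):
            raise ValueError("anatomical_codes must cover exactly the four regions")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


#: Shared default instance.
DEFAULT_REGIONS = RegionSet()
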