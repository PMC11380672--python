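"""Assay measurements to community scores.

Community function is pollutant degradation, measured as chemical oxygen
demand (COD) remaining after four days of growth relative to an abiotic
control.  Communities are additionally penalized for driving their own members
extinct: the degradation percent is scaled by the fraction ``f`` of inoculated
species still detectable on selective plates at disassembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .community import InputError

__all__ = [
    "AssayMeasurement",
    "SurvivalRecord",
    "CommunityScore",
    "DEFAULT_DETECTION_LIMIT",
    "degradation_percent",
    "detect_survival",
    "community_score",
]

#: Default plate-count detection floor, CFU/ml.  Stands in for the plating
#: dilution floor of the disassembly protocol; configurable per run.
DEFAULT_DETECTION_LIMIT = 1e3


@dataclass(frozen=True)
class AssayMeasurement:
    """One COD tube-test reading pair (sample and abiotic control), g/l."""

    cod_sample: float
    cod_control: float
    day: int = 4

    def __post_init__(self) -> None:
        if self.cod_control <= 0:
            raise InputError(f"cod_control must be positive, got {self.cod_control}")
        if self.cod_sample < 0:
            raise InputError(f"cod_sample must be non-negative, got {self.cod_sample}")


@dataclass(frozen=True)
class SurvivalRecord:
    """Outcome of plating one community on the full bank of selective media.

    ``survivors`` are inoculated species detected at disassembly; ``extinctions``
    inoculated but undetected; ``contaminants`` detected but never inoculated.
    Contaminants do not enter the survival fraction ``f``.
    """

    inoculated: frozenset[str]
    detected: frozenset[str]

    @property
    def survivors(self) -> frozenset[str]:
        return self.detected & self.inoculated

    @property
    def extinctions(self) -> frozenset[str]:
        return self.inoculated - self.detected

    @property
    def contaminants(self) -> frozenset[str]:
        return self.detected - self.inoculated

    @property
    def f(self) -> float:
        """Fraction of inoculated species surviving, in [0, 1]."""
        if not self.inoculated:
            return 1.0
        return len(self.survivors) / len(self.inoculated)


@dataclass(frozen=True)
class CommunityScore:
    """Degradation percent, survival fraction, and their product (the fitness)."""

    degradation_percent: float
    f: float
    penalized_score: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise InputError(f"survival fraction f must be in [0, 1], got {self.f}")
        object.__setattr__(self, "penalized_score", self.degradation_percent * self.f)


def degradation_percent(m: AssayMeasurement) -> float:
    """Percent of pollutant degraded: ``(1 - COD_sample/COD_control) * 100``.

    Negative when the sample's COD exceeds the abiotic control's; the raw value
    is preserved (flooring happens only when scores are turned into sampling
    probabilities).
    """
    return (1.0 - m.cod_sample / m.cod_control) * 100.0


def detect_survival(
    inoculated: frozenset[str] | set[str],
    counts: Mapping[str, float],
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> SurvivalRecord:
    """Classify plate counts into survivors, extinctions and contaminants.

    A species is detected iff its CFU/ml count is at or above ``detection_limit``.
    """
    if detection_limit <= 0:
        raise InputError(f"detection_limit must be positive, got {detection_limit}")
    for sp, c in counts.items():
        if c < 0:
            raise InputError(f"negative CFU count for {sp!r}: {c}")
    detected = frozenset(sp for sp, c in counts.items() if c >= detection_limit)
    return SurvivalRecord(inoculated=frozenset(inoculated), detected=detected)


def community_score(degradation: float, record: SurvivalRecord) -> CommunityScore:
    """The extinction-penalized community score: degradation percent times ``f``."""
    return CommunityScore(degradation_percent=degradation, f=record.f)
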