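"""Species response parameters for the ecoclimatic-index engine.

The parameter set follows the CLIMEX convention: a four-point temperature
response (DV0..DV3), a four-point soil-moisture response (SM0..SM3), a
thermal constant (PDD, degree days above DV0 per generation), diapause
induction/termination settings, and threshold/rate pairs for the five
stress accumulators (cold, heat, dry, wet and the hot-wet interaction).

Default values are the published fit for the brown marmorated stink bug
*Halyomorpha halys* (e.g. 595 degree days above 12 degC per generation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "SpeciesParameters",
    "ParameterError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]


class ParameterError(ValueError):
    """Invalid, missing or non-monotone species parameter values."""


@dataclass(frozen=True)
class SpeciesParameters:
    """Full species response parameter set.

    Temperature response (degC): DV0 limiting low, DV1 lower optimal,
    DV2 upper optimal, DV3 limiting high.  PDD is the thermal constant
    (degC days above DV0 per generation).  Soil moisture response
    (fraction of bucket capacity): SM0..SM3, analogous four points.

    Diapause: DPD0 induction day length (h), DPT0 induction temperature
    (degC), DPT1 termination temperature (degC), DPD development days,
    DPSW 0 for winter diapause / 1 for summer diapause.

    Stress thresholds and weekly accumulation rates: TTCS/THCS cold,
    TTHS/THHS heat, SMDS/HDS dry, SMWS/HWS wet, TTHW (degC) + MTHW
    (moisture) / PHW hot-wet interaction.  Negative printed rates (THCS,
    HDS) are stored as printed; the engine uses their absolute value as
    the accumulation magnitude.
    """

    DV0: float = 12.0
    DV1: float = 27.0
    DV2: float = 30.0
    DV3: float = 33.0
    PDD: float = 595.0
    SM0: float = 0.1
    SM1: float = 0.5
    SM2: float = 1.0
    SM3: float = 1.5
    DPD0: float = 12.0
    DPT0: float = 5.0
    DPT1: float = 5.0
    DPD: float = 0.0
    DPSW: int = 0
    TTCS: float = -18.0
    THCS: float = -0.01
    TTHS: float = 33.0
    THHS: float = 0.01
    SMDS: float = 0.1
    HDS: float = -0.01
    SMWS: float = 1.5
    HWS: float = 0.002
    TTHW: float = 28.0
    MTHW: float = 1.5
    PHW: float = 0.007

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check ordering and range invariants; raise ParameterError."""
        if not (self.DV0 < self.DV1 <= self.DV2 < self.DV3):
            raise ParameterError(
                "temperature response must satisfy DV0 < DV1 <= DV2 < DV3, "
                f"got {self.DV0}, {self.DV1}, {self.DV2}, {self.DV3}"
            )
        if not (self.SM0 < self.SM1 <= self.SM2 < self.SM3):
            raise ParameterError(
                "moisture response must satisfy SM0 < SM1 <= SM2 < SM3, "
                f"got {self.SM0}, {self.SM1}, {self.SM2}, {self.SM3}"
            )
        if not self.PDD > 0:
            raise ParameterError(f"PDD must be positive, got {self.PDD}")
        for name in ("THCS", "THHS", "HDS", "HWS", "PHW"):
            rate = getattr(self, name)
            if not abs(rate) < 1.0:
                raise ParameterError(f"|{name}| must be < 1, got {rate}")
        if self.DPSW not in (0, 1):
            raise ParameterError(f"DPSW must be 0 or 1, got {self.DPSW}")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: Field names in canonical order, as printed in the published table.
FIELD_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(SpeciesParameters)
)


def default_parameters() -> SpeciesParameters:
    """Published parameter fit for *H. halys* (all defaults)."""
    return SpeciesParameters()


def load_parameters(
    source: Mapping[str, Any] | str | Path,
    *,
    use_defaults: bool = True,
) -> SpeciesParameters:
    """Load parameters from a mapping or a flat YAML/JSON key-value file.

    Keys are the standard abbreviations (DV0, PDD, ...).  With
    ``use_defaults`` (the default) unspecified fields fall back to the
    published values; otherwise every field must be present.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            doc = {}
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise ParameterError(f"parameter document must be a mapping, got {type(doc)}")
    unknown = set(doc) - set(FIELD_NAMES)
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    if not use_defaults:
        missing = set(FIELD_NAMES) - set(doc)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
    kwargs = {k: (int(v) if k == "DPSW" else float(v)) for k, v in doc.items()}
    return SpeciesParameters(**kwargs)


def save_parameters(params: SpeciesParameters, path: str | Path) -> None:
    """Write parameters as a flat YAML key-value document (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
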