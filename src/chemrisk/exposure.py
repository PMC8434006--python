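"""Occupational chemical-exposure indices for multi-substance emissions.

For a mixture of ``r`` substances with shift-weighted exposure indices
``Ps_1..Ps_r`` and permissible limits (threshold limit values) ``NDS_1..NDS_r``
the combined index is the ratio of sums

    Ps = (Ps_1 + ... + Ps_r) / (NDS_1 + ... + NDS_r)

The conventional occupational-hygiene additive rule ``sum(Ps_r / NDS_r)`` is
available as an alternative convention.  The index maps to a risk level
through a configurable two-threshold ladder.
"""

from __future__ import annotations

from dataclasses import dataclass

MIXTURE_RULES = ("printed", "conventional")

#: index <= 0.5 -> low, <= 1.0 -> medium, above -> high; the standard
#: convention of keeping exposure below half the permissible limit.
DEFAULT_THRESHOLDS = (0.5, 1.0)
RISK_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class ExposureRecord:
    """Per-substance exposure indices and permissible limit.

    ``Ps`` is the shift-weighted exposure index; ``Pch`` and ``Pp`` assess
    instantaneous and ceiling concentrations; ``Cw`` is the weighted mean
    shift concentration and ``GGw`` the upper confidence bound of that mean
    (both mg/m3); ``NDS`` is the permissible limit (mg/m3).
    """

    substance: str
    Ps: float
    NDS: float
    Pch: float | None = None
    Pp: float | None = None
    Cw: float | None = None
    GGw: float | None = None

    def __post_init__(self) -> None:
        if self.Ps < 0:
            raise ValueError(f"{self.substance}: Ps must be >= 0")
        if self.NDS <= 0:
            raise ValueError(f"{self.substance}: NDS must be > 0")
        for name in ("Pch", "Pp", "Cw", "GGw"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.substance}: {name} must be >= 0")


def mixture_exposure_index(
    records: list[ExposureRecord], rule: str = "printed"
) -> float:
    """Combined exposure index of a substance mixture.

    ``printed`` is the ratio-of-sums form above; ``conventional`` is the
    additive rule ``sum(Ps_r / NDS_r)``.  Requires at least one record and
    strictly positive limits.
    """
    if rule not in MIXTURE_RULES:
        raise ValueError(f"unknown mixture rule: {rule!r}")
    if not records:
        raise ValueError("mixture_exposure_index needs at least one record")
    if rule == "printed":
        return sum(r.Ps for r in records) / sum(r.NDS for r in records)
    return sum(r.Ps / r.NDS for r in records)


def combined_exposure_index(
    records: list[ExposureRecord], rule: str = "printed"
) -> float:
    """Worst-case index over the shift, instantaneous and ceiling channels.

    Takes the maximum of the mixture index computed from ``Ps`` and the
    largest per-substance ``Pch``/``Pp``.  How the three channels enter the
    final risk call is not standardized; this max-combination is a
    construction of this package.
    """
    idx = mixture_exposure_index(records, rule)
    extremes = [
        v for r in records for v in (r.Pch, r.Pp) if v is not None
    ]
    return max([idx, *extremes]) if extremes else idx


def risk_level(
    index: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Map an exposure index to low / medium / high.

    Boundary values belong to the lower band; thresholds must be strictly
    increasing.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")
    if index < 0:
        raise ValueError("exposure index must be >= 0")
    if index <= lo:
        return "low"
    if index <= hi:
        return "medium"
    return "high"
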