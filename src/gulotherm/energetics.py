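"""Thermal-gradient energy-saving calculation.

For a homeotherm below its thermoneutral zone, heat loss — and hence the
thermoregulatory part of metabolic rate — scales with the gradient between
core body temperature T_b and ambient temperature T_a (Newtonian
conductance). A sustained reduction of T_b from ``tb_ref`` to ``tb_low``
therefore saves a fraction

    (tb_ref - tb_low) / (tb_ref - ta)

of thermoregulatory cost. An alternative Q10 metabolic scaling is provided
behind a flag for comparison; it answers a different question (temperature
sensitivity of tissue metabolism) and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EnergyScenario:
    """Reference and lowered core temperature against an ambient, all deg C."""

    tb_ref: float
    tb_low: float
    ta: float

    def __post_init__(self) -> None:
        if self.tb_low > self.tb_ref:
            raise ValueError("tb_low must not exceed tb_ref")
        if self.ta >= self.tb_low:
            raise ValueError("ambient temperature must be below tb_low "
                             "(heat must flow outward)")


def energy_saving(scenario: EnergyScenario, *, method: str = "gradient",
                  q10: float = 2.5) -> float:
    """Fractional thermoregulatory energy saving in [0, 1).

    method="gradient" (default): Newtonian thermal-gradient proportionality.
    method="q10": metabolic Q10 scaling 1 - q10**((tb_low - tb_ref)/10).
    """
    if method == "gradient":
        return (scenario.tb_ref - scenario.tb_low) / (scenario.tb_ref - scenario.ta)
    if method == "q10":
        return 1.0 - q10 ** ((scenario.tb_low - scenario.tb_ref) / 10.0)
    raise ValueError(f"unknown method {method!r}")
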