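"""Synaptic effect parameters driving the simulator.

Each (circuit, subtype) combination carries a :class:`SynapticEffect`: a
signed EPSP weight (mV of peak subthreshold depolarization per mW of light),
a between-cell coefficient of variation, and a dimensionless spike gain that
maps the subthreshold drive onto the firing decision. A negative weight
models a net-hyperpolarizing (polysynaptic inhibition dominated) circuit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .exceptions import CalibrationError
from .regions import SUBTYPES, CircuitSpec, enumerate_circuits


@dataclass(frozen=True)
class SynapticEffect:
    weight: float = 0.0  # mV / mW peak EPSP scaling, signed
    weight_cv: float = 0.3  # between-cell variability of |weight|
    spike_gain: float = 0.0  # scales the drive that is compared to spike threshold
    burst_drive_ratio: float = 1.0  # drive multiple of threshold that triggers a full burst

    def __post_init__(self) -> None:
        if self.weight_cv < 0:
            raise CalibrationError("weight_cv must be >= 0")
        if self.spike_gain < 0:
            raise CalibrationError("spike_gain must be >= 0")
        if self.burst_drive_ratio < 1.0:
            raise CalibrationError("burst_drive_ratio must be >= 1")


class EffectTable:
    """Complete mapping (circuit, subtype) -> SynapticEffect.

    The default circuit space has 35 circuits x 2 subtypes = 70 entries; the
    table refuses to be constructed with any combination missing.
    """

    def __init__(
        self,
        effects: dict[tuple[CircuitSpec, str], SynapticEffect],
        circuits: list[CircuitSpec] | None = None,
    ) -> None:
        circuits = circuits if circuits is not None else enumerate_circuits()
        required = {(c, s) for c in circuits for s in SUBTYPES}
        missing = required - set(effects)
        if missing:
            labels = sorted(f"{c.label} [{s}]" for c, s in missing)
            raise CalibrationError(f"effect table incomplete, missing {len(missing)} combinations: {labels[:6]}...")
        extra = set(effects) - required
        if extra:
            raise CalibrationError(f"effect table has {len(extra)} entries outside the circuit space")
        for (circuit, _), eff in effects.items():
            if circuit.input_region == "aINS" and eff.weight != 0.0:
                raise CalibrationError("aINS-input circuits must have weight 0 (no observable responses)")
        self._effects = dict(effects)
        self.circuits = list(circuits)

    def __getitem__(self, key: tuple[CircuitSpec, str]) -> SynapticEffect:
        return self._effects[key]

    def __iter__(self) -> Iterator[tuple[CircuitSpec, str]]:
        return iter(self._effects)

    def __len__(self) -> int:
        return len(self._effects)

    def items(self):
        return self._effects.items()


def null_effect_table(weight_cv: float = 0.3) -> EffectTable:
    """All-zero table: every circuit silent (global null)."""
    eff = SynapticEffect(0.0, weight_cv, 0.0)
    return EffectTable({(c, s): eff for c in enumerate_circuits() for s in SUBTYPES})
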