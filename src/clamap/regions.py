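"""Cortical region sets and the cortico-claustro-cortical circuit space.

A circuit is an (input cortex, output cortex) pair relayed through claustrum
projection neurons. Five frontal regions provide input; the anterior insula
sends no claustrum projection back out, so it never appears as an output.
Circuits that return to the originating region (contralaterally) are termed
"homoloquial"; all others are "heteroloquial".
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import LabelingError

INPUT_REGIONS: tuple[str, ...] = ("ACC", "plPFC", "ilPFC", "OFC", "aINS")
OUTPUT_REGIONS: tuple[str, ...] = ("ACC", "plPFC", "ilPFC", "OFC", "RSC", "V1/V2", "PtA")

HOMOLOQUIAL = "homoloquial"
HETEROLOQUIAL = "heteroloquial"

SUBTYPES: tuple[str, str] = ("I", "II")


@dataclass(frozen=True, order=True)
class CircuitSpec:
    """One input -> claustrum -> output pathway."""

    input_region: str
    output_region: str

    @property
    def loquial_class(self) -> str:
        return HOMOLOQUIAL if self.input_region == self.output_region else HETEROLOQUIAL

    @property
    def label(self) -> str:
        """Field notation, e.g. ``"ACC > CL > plPFC"``."""
        return f"{self.input_region} > CL > {self.output_region}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def enumerate_circuits(
    inputs: tuple[str, ...] = INPUT_REGIONS,
    outputs: tuple[str, ...] = OUTPUT_REGIONS,
) -> list[CircuitSpec]:
    """Enumerate every (input, output) circuit.

    With the default region sets this yields the 35 mapped circuits: 4
    homoloquial (ACC, plPFC, ilPFC, OFC; aINS is excluded because the
    claustrum sends no projection to aINS) and 31 heteroloquial.
    """
    if "aINS" in outputs:
        raise LabelingError("aINS is not a valid output region: no claustrum neurons project to aINS")
    unknown_in = set(inputs) - set(INPUT_REGIONS)
    unknown_out = set(outputs) - set(OUTPUT_REGIONS)
    if unknown_in or unknown_out:
        raise LabelingError(f"unknown regions: {sorted(unknown_in | unknown_out)}")
    return [CircuitSpec(i, o) for i in inputs for o in outputs]


def validate_circuit(circuit: CircuitSpec) -> None:
    if circuit.input_region not in INPUT_REGIONS:
        raise LabelingError(f"unknown input region {circuit.input_region!r}")
    if circuit.output_region not in OUTPUT_REGIONS:
        raise LabelingError(f"unknown output region {circuit.output_region!r}")
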