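"""The four cephalic (CEP) dopaminergic neurons scored in the worm head."""

from __future__ import annotations

import enum


class Neuron(str, enum.Enum):
    """One of the four cephalic neurons, dorsal/ventral x left/right.

    The string value is the standard cell name (e.g. ``CEPVL`` = cephalic,
    ventral, left), so members serialize naturally as CSV column headers.
    """

    CEPDL = "CEPDL"
    CEPDR = "CEPDR"
    CEPVL = "CEPVL"
    CEPVR = "CEPVR"

    @property
    def position(self) -> str:
        """``"dorsal"`` or ``"ventral"``."""
        return "dorsal" if self.value[3] == "D" else "ventral"

    @property
    def side(self) -> str:
        """``"left"`` or ``"right"``."""
        return "left" if self.value[4] == "L" else "right"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed scoring order used in CSV files and reports.
NEURONS: tuple[Neuron, ...] = (
    Neuron.CEPDL,
    Neuron.CEPDR,
    Neuron.CEPVL,
    Neuron.CEPVR,
)

DORSAL: tuple[Neuron, ...] = (Neuron.CEPDL, Neuron.CEPDR)
VENTRAL: tuple[Neuron, ...] = (Neuron.CEPVL, Neuron.CEPVR)
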