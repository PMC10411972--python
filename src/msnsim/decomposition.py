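"""Attribution of GABA supply to its three sources.

Vesicular GABA in striatal neurons can be synthesized de novo from
glutamine, or from glutamate taken up across the plasma membrane either by
the neuronal transporter EAAC1 or by glial transporters (whose transmitter
reaches neurons via the glutamine cycle).  Blocking all glutamate
transporters with T-TBOA removes the uptake-dependent supply; comparing the
percent reduction of the IPSC amplitude in wild-type and EAAC1-knockout
tissue therefore splits the supply exactly:

* EAAC1 share      = reduction(WT) − reduction(KO)
* glial share      = reduction(KO)
* de novo share    = 100 − reduction(WT)

The three shares close to 100% by construction.  A knockout reduction larger
than the wild-type one would imply a negative EAAC1 share; that is surfaced
as an error rather than clamped, because it means the measurement resolves
no EAAC1 contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import percent_reduction

__all__ = [
    "UptakeDecomposition",
    "DecompositionError",
    "decompose_gaba_sources",
    "decomposition_from_amplitudes",
]


class DecompositionError(ValueError):
    pass


@dataclass(frozen=True)
class UptakeDecomposition:
    """Three-way percentage split of GABA supply for one synapse context."""

    eaac1_pct: float
    glial_pct: float
    denovo_pct: float
    context: str = ""

    def __post_init__(self):
        for name in ("eaac1_pct", "glial_pct", "denovo_pct"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise DecompositionError(f"{name} = {value} outside [0, 100]")

    def as_dict(self) -> dict:
        return {
            "context": self.context,
            "eaac1_pct": self.eaac1_pct,
            "glial_pct": self.glial_pct,
            "denovo_pct": self.denovo_pct,
        }


def decompose_gaba_sources(
    reduction_wt_pct: float, reduction_ko_pct: float, context: str = ""
) -> UptakeDecomposition:
    """Split GABA supply from T-TBOA percent reductions in WT and KO.

    Requires ``0 <= reduction_ko <= reduction_wt <= 100``.
    """
    for name, value in (
        ("reduction_wt_pct", reduction_wt_pct),
        ("reduction_ko_pct", reduction_ko_pct),
    ):
        if not -1e-9 <= value <= 100.0 + 1e-9:
            raise DecompositionError(f"{name} = {value} outside [0, 100]")
    reduction_wt_pct = float(np.clip(reduction_wt_pct, 0.0, 100.0))
    reduction_ko_pct = float(np.clip(reduction_ko_pct, 0.0, 100.0))
    if reduction_ko_pct > reduction_wt_pct + 1e-9:
        raise DecompositionError(
            "knockout reduction exceeds wild-type reduction: "
            "no resolvable EAAC1 contribution (negative share)"
        )
    return UptakeDecomposition(
        eaac1_pct=max(0.0, reduction_wt_pct - reduction_ko_pct),
        glial_pct=reduction_ko_pct,
        denovo_pct=100.0 - reduction_wt_pct,
        context=context,
    )


def decomposition_from_amplitudes(
    amp_ctrl_wt: float,
    amp_tboa_wt: float,
    amp_ctrl_ko: float,
    amp_tboa_ko: float,
    context: str = "",
) -> UptakeDecomposition:
    """Split GABA supply from raw IPSC amplitudes before/after T-TBOA."""
    return decompose_gaba_sources(
        percent_reduction(amp_ctrl_wt, amp_tboa_wt),
        percent_reduction(amp_ctrl_ko, amp_tboa_ko),
        context=context,
    )
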