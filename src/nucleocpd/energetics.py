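"""Transition-state free-energy differences from rate (or yield) ratios.

For two first-order processes with rate constants ``k_fast`` and
``k_slow``, transition-state theory gives the difference in activation
free energy as ``ddG = R*T*ln(k_fast/k_slow)``.  Photoproduct yields can
be used as rate proxies for the formation step; that approximation is
discussed in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEAMINATION_T_K",
    "IRRADIATION_T_K",
    "DdgResult",
    "ddg_from_rates",
    "ddg_profile",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Default temperature for deamination comparisons (assay run at 37 degC).
DEAMINATION_T_K = 310.15

#: Default temperature for photoproduct-formation comparisons
#: (irradiation at 4 degC).
IRRADIATION_T_K = 277.15


@dataclass(frozen=True)
class DdgResult:
    """A free-energy difference and the ratio/temperature that produced it."""

    ddg_kcal_mol: float
    ratio: float
    temperature_K: float
    label: str = ""


def ddg_from_rates(
    k_fast: float, k_slow: float, temperature_K: float = DEAMINATION_T_K
) -> DdgResult:
    """``R*T*ln(k_fast/k_slow)`` in kcal/mol.

    Negative when ``k_fast < k_slow``; the sign carries which process is
    actually faster.
    """
    if k_fast <= 0 or k_slow <= 0:
        raise ValueError("rate constants must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    ratio = k_fast / k_slow
    return DdgResult(
        ddg_kcal_mol=GAS_CONSTANT_KCAL * temperature_K * math.log(ratio),
        ratio=ratio,
        temperature_K=temperature_K,
    )


def ddg_profile(
    values: Sequence[float],
    reference: float,
    temperature_K: float = DEAMINATION_T_K,
    labels: Sequence[str] | None = None,
) -> list[DdgResult]:
    """Per-position free-energy differences relative to a reference value.

    ``values`` may be rate constants or yields (used as rate proxies);
    each entry is compared against ``reference`` (free DNA by default in
    the pipeline).
    """
    if len(values) == 0:
        raise ValueError("empty value list")
    if reference <= 0:
        raise ValueError("reference must be positive")
    labels = labels if labels is not None else [""] * len(values)
    if len(labels) != len(values):
        raise ValueError("labels and values must have equal length")
    out = []
    for v, lab in zip(values, labels):
        r = ddg_from_rates(v, reference, temperature_K)
        out.append(DdgResult(r.ddg_kcal_mol, r.ratio, r.temperature_K, label=lab))
    return out
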