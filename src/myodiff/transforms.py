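"""Scale conversions between raw intensities (RFU) and display/density space.

Flow-cytometry fluorescence spans several decades, so density estimation and
display happen on a log-like scale.  Three transforms are provided:

``linear``
    Identity.
``log10``
    ``log10(max(v, floor))`` — a floored decadic log for strictly positive
    display; invertible only above the floor.
``biexponential``
    ``asinh(v / cofactor) / ln(10)`` — log-like for ``|v| >> cofactor`` (one
    unit per decade) but linear through zero, so it is defined for the
    negative and zero intensities that linear ("HLin") channels can contain.
    Closed-form invertible everywhere.

All transforms are strictly monotone on their domain, which is the only
property gating correctness relies on: a threshold found in transformed space
maps back to a unique threshold in RFU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, TransformDomainError

_KINDS = ("linear", "log10", "biexponential")

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class TransformSpec:
    """A named scale with its parameters.

    Parameters
    ----------
    kind
        One of ``linear``, ``log10``, ``biexponential``.
    cofactor
        Width (RFU) of the quasi-linear region of the biexponential; default
        5 RFU, appropriate for channels whose background sits near 10 RFU.
    floor
        Positive clamp (RFU) applied before ``log10``; default 0.1 RFU.
    """

    kind: str = "biexponential"
    cofactor: float = 5.0
    floor: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown transform kind {self.kind!r}; expected one of {_KINDS}")
        if not self.cofactor > 0:
            raise ConfigurationError("transform cofactor must be > 0")
        if not self.floor > 0:
            raise ConfigurationError("log10 floor must be > 0")


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Map raw intensities (RFU) into transformed space.

    Total on finite input; monotone non-decreasing (strictly monotone except
    for ``log10`` below its floor, where values are clamped).
    """
    v = np.asarray(values, dtype=np.float64)
    if spec.kind == "linear":
        return v.copy()
    if spec.kind == "log10":
        return np.log10(np.maximum(v, spec.floor))
    return np.arcsinh(v / spec.cofactor) / _LN10


def invert_transform(values, spec: TransformSpec) -> np.ndarray:
    """Map transformed coordinates back to RFU.

    Raises
    ------
    TransformDomainError
        For ``log10`` when any value lies below the image of the floor (the
        forward map is not injective there).
    """
    t = np.asarray(values, dtype=np.float64)
    if spec.kind == "linear":
        return t.copy()
    if spec.kind == "log10":
        lo = math.log10(spec.floor)
        if np.any(t < lo - 1e-12):
            raise TransformDomainError(
                f"log10 inversion below floor image (min input {t.min():g} < log10(floor) = {lo:g})"
            )
        return np.power(10.0, t)
    return spec.cofactor * np.sinh(t * _LN10)
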