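"""The signed logistic transfer function used by every connection.

Every connection in the model — the preset subregion and output sigmoids of
the monocular front end and the evolvable lines feeding binocular units —
applies the same three-parameter logistic with a discrete sign::

    post = sign * gain / (1 + exp(-slope * pre + offset))

``gain`` bounds the output magnitude, ``slope`` sets the steepness, ``offset``
shifts the half-activation point to ``pre = offset / slope``, and ``sign``
(+1 or -1) makes the connection excitatory or inhibitory.  Carrying the sign
as a discrete field (rather than allowing negative gains) keeps the
excitatory/inhibitory classification of evolved connections well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of one signed logistic connection."""

    gain: float
    slope: float
    offset: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    def to_dict(self) -> dict:
        return {
            "gain": self.gain,
            "slope": self.slope,
            "offset": self.offset,
            "sign": self.sign,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SigmoidParams":
        return cls(
            gain=float(d["gain"]),
            slope=float(d["slope"]),
            offset=float(d["offset"]),
            sign=int(d["sign"]),
        )


def logistic(pre, params: SigmoidParams):
    """Apply the signed logistic to a scalar or array drive.

    Bounded in ``[-gain, gain]``; monotone in ``pre`` for positive slope.
    Non-finite inputs are rejected.
    """
    pre = np.asarray(pre, dtype=float)
    if not np.all(np.isfinite(pre)):
        raise ValueError("logistic input must be finite")
    out = params.sign * params.gain / (1.0 + np.exp(-params.slope * pre + params.offset))
    if pre.ndim == 0:
        return float(out)
    return out
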