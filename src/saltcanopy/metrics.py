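"""Model-evaluation statistics: RMSD, bias and accuracy.

accuracy = 100 * (1 - RMSD / mean(obs)), floored at 0. The literature
the evaluation convention descends from does not pin down a single
accuracy formula; this normalised-RMSD definition is the package's
declared choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalStats", "evaluate"]


@dataclass(frozen=True)
class EvalStats:
    rmsd: float
    bias: float
    accuracy: float
    n: int


def evaluate(sim, obs) -> EvalStats:
    """Compare aligned simulated and observed series.

    rmsd = sqrt(mean((sim-obs)^2)); bias = mean(sim-obs);
    accuracy = 100 (1 - rmsd/mean(obs)), floored at 0 and undefined
    (raises) when the observed mean is zero.
    """
    s = np.asarray(sim, dtype=float)
    o = np.asarray(obs, dtype=float)
    if s.shape != o.shape:
        raise ValueError(f"series are not aligned: {s.shape} vs {o.shape}")
    if s.size < 1:
        raise ValueError("need at least one point")
    d = s - o
    rmsd = float(np.sqrt(np.mean(d * d)))
    bias = float(np.mean(d))
    o_mean = float(np.mean(o))
    if o_mean == 0.0:
        raise ValueError("accuracy undefined: observed mean is zero")
    accuracy = max(0.0, 100.0 * (1.0 - rmsd / abs(o_mean)))
    return EvalStats(rmsd=rmsd, bias=bias, accuracy=accuracy, n=int(s.size))
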