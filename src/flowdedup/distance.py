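"""Pairwise flowgram distance over trimmed, overlapping flows.

The distance between two flowgrams is one minus the geometric mean of
the per-flow equal-homopolymer probabilities over the comparison window:
``d = 1 - (prod p_i)^(1/n)``.  The window starts at the first informative
flow shared by both reads (duplicates share a template start, so no
offset search is performed) and ends at the lowest trim point, capped at
``max_flows`` compared flows.  The product is accumulated as a sum of
logarithms to avoid underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow_model import FlowModel, default_parametric_model
from .flowgram_io import Flowgram

__all__ = ["DistanceConfig", "EmptyWindowError", "flowgram_distance"]


class EmptyWindowError(ValueError):
    """Raised when two flowgrams share no informative flows."""


@dataclass
class DistanceConfig:
    """Parameters of the flowgram distance."""

    model: FlowModel = field(default_factory=default_parametric_model)
    max_flows: int = 400
    cycle_length: int = 4

    def __post_init__(self) -> None:
        if self.max_flows < 1:
            raise ValueError("max_flows must be >= 1")


def comparison_window(
    fg_a: Flowgram, fg_b: Flowgram, max_flows: int
) -> tuple[int, int]:
    """Shared informative flow range of a pair, 0-based half-open."""
    start_a, end_a = fg_a.flow_window()
    start_b, end_b = fg_b.flow_window()
    start = max(start_a, start_b)
    end = min(end_a, end_b, start + max_flows)
    return start, end


def flowgram_distance(
    fg_a: Flowgram, fg_b: Flowgram, cfg: DistanceConfig
) -> float:
    """Distance in [0, 1] between two flowgrams; 0 iff every p_i is 1."""
    if fg_a.flow_order != fg_b.flow_order:
        raise ValueError(
            f"flow orders differ between reads {fg_a.read_id!r} and "
            f"{fg_b.read_id!r}"
        )
    start, end = comparison_window(fg_a, fg_b, cfg.max_flows)
    if end <= start:
        raise EmptyWindowError(
            f"no overlapping informative flows between reads "
            f"{fg_a.read_id!r} and {fg_b.read_id!r}"
        )
    indices = np.arange(start, end)
    cycles = indices // cfg.cycle_length + 1
    p = cfg.model.pair_probabilities(
        fg_a.flow_values[start:end], fg_b.flow_values[start:end], cycles
    )
    if np.any(p <= 0.0):
        return 1.0
    mean_log = float(np.mean(np.log(p)))
    return float(min(max(1.0 - np.exp(mean_log), 0.0), 1.0))
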