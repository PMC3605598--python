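"""Flow-sign preclustering.

Flowgrams are binned by the sign pattern of their first seed flows
(positive meaning a flow value >= 0.5, i.e. at least one called base)
together with the called length of the first positive flow.  Bins larger
than ``max_bin_size`` are recursively split by extending the seed, one
flow at a time, until they fit or the seed reaches the shortest member's
informative flow count.  Reads in different bins are never compared
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Sequence

from .flowgram_io import Flowgram, round_half_up

logger = logging.getLogger(__name__)

__all__ = ["PreclusterConfig", "seed_key", "precluster"]

POSITIVE_THRESHOLD = 0.5  # a flow value >= 0.5 calls at least one base


@dataclass
class PreclusterConfig:
    min_seed_flows: int = 8
    max_bin_size: int = 2000
    seed_step: int = 1

    def __post_init__(self) -> None:
        if self.min_seed_flows < 1:
            raise ValueError("min_seed_flows must be >= 1")
        if self.max_bin_size < 2:
            raise ValueError("max_bin_size must be >= 2")
        if self.seed_step < 1:
            raise ValueError("seed_step must be >= 1")


def seed_key(fg: Flowgram, seed_len: int) -> Hashable:
    """Bin key: sign pattern of the first seed flows + first homopolymer.

    Reads with fewer informative flows than ``seed_len`` contribute the
    flows they have; the shorter sign tuple marks the key as short.
    """
    if seed_len < 1:
        raise ValueError("seed_len must be >= 1")
    start, end = fg.flow_window()
    window = fg.flow_values[start : min(end, start + seed_len)]
    signs = tuple(bool(v >= POSITIVE_THRESHOLD) for v in window)
    informative = fg.flow_values[start:end]
    first_hp = 0
    for value in informative:
        if value >= POSITIVE_THRESHOLD:
            first_hp = int(round_half_up(value))
            break
    return (first_hp, signs)


def precluster(
    flowgrams: Sequence[Flowgram], cfg: PreclusterConfig | None = None
) -> list[list[int]]:
    """Partition flowgram indices into bins; deterministic key order."""
    cfg = cfg or PreclusterConfig()
    bins: list[list[int]] = []
    _split(flowgrams, list(range(len(flowgrams))), cfg.min_seed_flows, cfg, bins)
    return bins


def _informative_length(fg: Flowgram) -> int:
    start, end = fg.flow_window()
    return end - start


def _split(
    flowgrams: Sequence[Flowgram],
    indices: list[int],
    seed_len: int,
    cfg: PreclusterConfig,
    bins: list[list[int]],
) -> None:
    groups: dict[Hashable, list[int]] = {}
    for idx in indices:
        groups.setdefault(seed_key(flowgrams[idx], seed_len), []).append(idx)
    for key in sorted(groups, key=repr):
        members = groups[key]
        if len(members) > cfg.max_bin_size:
            shortest = min(_informative_length(flowgrams[i]) for i in members)
            if seed_len < shortest:
                _split(flowgrams, members, seed_len + cfg.seed_step, cfg, bins)
                continue
            logger.warning(
                "precluster bin of %d reads exceeds max_bin_size=%d but the "
                "seed is exhausted at %d flows; passing through whole",
                len(members), cfg.max_bin_size, seed_len,
            )
        bins.append(members)
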