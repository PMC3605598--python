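"""Cluster representatives: longest, best or consensus.

``longest`` picks the member with the most called bases in its trimmed
region.  ``best`` picks the member minimizing the squared deviation of
its trimmed flow values from the nearest integers, normalized by the
number of trimmed flows (values near integers are the most accurately
resolved).  ``consensus`` emits the cluster's median consensus flowgram,
which for multi-member clusters need not equal any input read.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

import numpy as np

from .cluster import ClusterSet, consensus_flowgram
from .flowgram_io import Flowgram

__all__ = ["OutputMode", "select_representative", "representatives"]


class OutputMode(str, Enum):
    LONGEST = "longest"
    BEST = "best"
    CONSENSUS = "consensus"


def called_length(fg: Flowgram) -> int:
    """Number of called bases in the trimmed region."""
    start, end = fg.flow_window()
    return int(fg.base_calls()[start:end].sum())


def integrality_score(fg: Flowgram) -> float:
    """Mean squared deviation of trimmed flow values from integers."""
    values = fg.trimmed_values()
    if len(values) == 0:
        return float("inf")
    return float(np.sum((values - np.round(values)) ** 2) / len(values))


def select_representative(
    members: Sequence[Flowgram],
    consensus: Flowgram | None,
    mode: OutputMode | str = OutputMode.LONGEST,
) -> Flowgram:
    """Pick one output flowgram for a cluster.

    Ties are broken by longest called length, then input order.
    """
    if not members:
        raise ValueError("cannot select a representative of an empty cluster")
    mode = OutputMode(mode)
    if mode is OutputMode.CONSENSUS:
        return consensus if consensus is not None else consensus_flowgram(members)
    if mode is OutputMode.LONGEST:
        ranked = [(-called_length(fg), i) for i, fg in enumerate(members)]
    else:
        ranked = [
            (integrality_score(fg), -called_length(fg), i)
            for i, fg in enumerate(members)
        ]
    return members[min(ranked)[-1]]


def representatives(
    cs: ClusterSet,
    flowgrams: Sequence[Flowgram],
    mode: OutputMode | str = OutputMode.LONGEST,
) -> list[Flowgram]:
    """One representative per cluster, in cluster order."""
    by_id = {fg.read_id: fg for fg in flowgrams}
    out = []
    for cid, member_ids in cs.clusters.items():
        members = [by_id[r] for r in member_ids]
        out.append(select_representative(members, cs.consensus.get(cid), mode))
    return out
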