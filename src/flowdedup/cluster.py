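"""Agglomerative flowgram clustering with per-flow-median consensus.

Within each precluster bin, clustering starts from singletons and
repeatedly merges the pair of clusters with the smallest consensus
distance.  After every merge the new cluster's consensus flowgram (the
per-flow median over members covering each flow) is recomputed, as are
its distances to all remaining clusters.  Clustering stops once the
minimum inter-cluster distance exceeds the stringency threshold.  Ties
on the minimum distance are broken by the lowest (first, second) cluster
index pair, so results are deterministic given the input order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .distance import DistanceConfig, flowgram_distance
from .flowgram_io import Flowgram
from .precluster import PreclusterConfig, precluster

logger = logging.getLogger(__name__)

__all__ = ["ClusterSet", "consensus_flowgram", "agglomerate", "dedupe"]


@dataclass
class ClusterSet:
    """A partition of read ids into duplicate clusters.

    ``clusters`` maps cluster id -> member read ids (input order);
    ``consensus`` maps cluster id -> consensus flowgram.
    """

    clusters: dict[str, list[str]]
    consensus: dict[str, Flowgram] = field(default_factory=dict)
    threshold: float | None = None

    @property
    def n_reads(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def size_histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(len(m) for m in self.clusters.values()).items()))


def consensus_flowgram(members: Sequence[Flowgram]) -> Flowgram:
    """Per-flow median of the members' quality-trimmed flow values.

    Flow i is the median over members whose trimmed region covers i (the
    midpoint of the two central values for even counts).  The consensus
    window runs to the shortest member trim; a singleton's consensus is
    the member itself.
    """
    if not members:
        raise ValueError("consensus of an empty cluster is undefined")
    if len(members) == 1:
        return members[0]
    windows = [fg.flow_window() for fg in members]
    start = min(w[0] for w in windows)
    end = min(w[1] for w in windows)
    n_flows = members[0].n_flows
    values = np.zeros(n_flows)
    for i in range(start, end):
        covering = [
            fg.flow_values[i]
            for fg, (s, e) in zip(members, windows)
            if s <= i < e
        ]
        values[i] = float(np.median(covering))
    # keep the hundredths quantization invariant of flow values
    values = np.round(values, 2)
    return Flowgram(
        read_id=f"{members[0].read_id}|consensus",
        flow_values=values,
        flow_order=members[0].flow_order,
        key_sequence=members[0].key_sequence,
        trim_flow_start=start,
        trim_flow_end=end,
    )


def agglomerate(
    flowgrams: Sequence[Flowgram],
    threshold: float,
    cfg: DistanceConfig | None = None,
) -> ClusterSet:
    """Cluster one precluster bin; merges while min distance <= threshold."""
    cfg = cfg or DistanceConfig()
    n = len(flowgrams)
    members: list[list[int] | None] = [[i] for i in range(n)]
    consensus: list[Flowgram | None] = list(flowgrams)
    dist = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = flowgram_distance(consensus[i], consensus[j], cfg)

    while n > 1:
        flat = int(np.argmin(dist))
        i, j = divmod(flat, dist.shape[1])
        if dist[i, j] > threshold:
            break
        members[i] = members[i] + members[j]
        members[j] = None
        consensus[j] = None
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        consensus[i] = consensus_flowgram([flowgrams[k] for k in members[i]])
        for k in range(dist.shape[0]):
            if k == i or members[k] is None:
                continue
            d = flowgram_distance(consensus[i], consensus[k], cfg)
            if k < i:
                dist[k, i] = d
            else:
                dist[i, k] = d
        n -= 1

    clusters: dict[str, list[str]] = {}
    consensus_map: dict[str, Flowgram] = {}
    for i, mem in enumerate(members):
        if mem is None:
            continue
        cid = f"c{i}"
        clusters[cid] = [flowgrams[k].read_id for k in mem]
        consensus_map[cid] = consensus[i]
    return ClusterSet(clusters=clusters, consensus=consensus_map, threshold=threshold)


def dedupe(
    flowgrams: Sequence[Flowgram],
    threshold: float = 0.05,
    cfg: DistanceConfig | None = None,
    precluster_cfg: PreclusterConfig | None = None,
) -> ClusterSet:
    """Full pipeline on one dataset: precluster, then agglomerate per bin."""
    cfg = cfg or DistanceConfig()
    bins = precluster(flowgrams, precluster_cfg)
    clusters: dict[str, list[str]] = {}
    consensus_map: dict[str, Flowgram] = {}
    for bin_no, bin_indices in enumerate(bins):
        bin_fgs = [flowgrams[i] for i in bin_indices]
        sub = agglomerate(bin_fgs, threshold, cfg)
        for cid, mem in sub.clusters.items():
            gid = f"b{bin_no}_{cid}"
            clusters[gid] = mem
            consensus_map[gid] = sub.consensus[cid]
    result = ClusterSet(clusters=clusters, consensus=consensus_map, threshold=threshold)
    if flowgrams:
        from .evaluate import duplicate_rate

        logger.info(
            "dedupe: %d reads, %d precluster bins, %d clusters, "
            "estimated duplicate rate %.2f%%, size histogram %s",
            len(flowgrams), len(bins), result.n_clusters,
            duplicate_rate(result, len(flowgrams)), result.size_histogram(),
        )
    return result
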