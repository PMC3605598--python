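"""Ground-truth construction and clustering evaluation.

Truth clusters come from alignments (same reference, strand-resolved
start and 16-base read prefix) or from the simulator.  Clusterings are
compared with a pair-counting Jaccard index J = a / (a + b + c) over
unordered read pairs, where a counts pairs clustered together in both
partitions, b pairs together only in the truth and c pairs together only
in the prediction.  Pair counts use exact size-based combinatorics, so
no O(n^2) enumeration is performed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "TruthSet",
    "truth_from_sam",
    "duplicate_rate",
    "pair_counts",
    "jaccard",
    "threshold_sweep",
    "read_membership",
    "write_membership",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class TruthSet:
    """Ground-truth partition of read ids into duplicate clusters."""

    clusters: dict[str, list[str]]
    source: str = "simulated"

    @property
    def n_reads(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def truth_from_sam(sam_path, prefix_len: int = 16) -> TruthSet:
    """Truth clusters from a SAM file.

    Reads are grouped by (reference, strand, strand-aware start, first
    ``prefix_len`` bases of the read as sequenced).  Reverse-strand
    records are canonicalized to their alignment end on the forward axis
    and their prefix taken from the reverse complement, equivalent to
    mapping against the reverse-complemented reference and keeping
    forward matches.  Alignments whose read-start side is hard-clipped
    are discarded; soft-clipped starts are kept and counted in the log.
    """
    groups: dict[tuple, list[str]] = {}
    n_soft = n_hard = 0
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cigar = aln.cigartuples or []
            # read-start side is the last CIGAR element for reverse strand
            start_op = cigar[-1][0] if aln.is_reverse else cigar[0][0]
            if start_op == 5:  # H
                n_hard += 1
                continue
            if start_op == 4:  # S
                n_soft += 1
            seq = aln.query_sequence or ""
            if aln.is_reverse:
                key_pos = aln.reference_end
                prefix = seq.translate(_COMPLEMENT)[::-1][:prefix_len]
                strand = "-"
            else:
                key_pos = aln.reference_start
                prefix = seq[:prefix_len]
                strand = "+"
            key = (aln.reference_name, strand, key_pos, prefix.upper())
            groups.setdefault(key, []).append(aln.query_name)
    if n_soft:
        logger.info("truth_from_sam: kept %d soft-clipped read starts", n_soft)
    if n_hard:
        logger.info("truth_from_sam: discarded %d hard-clipped read starts", n_hard)
    clusters = {
        f"t{i}": names for i, (_, names) in enumerate(sorted(groups.items()))
    }
    return TruthSet(clusters=clusters, source="alignment-derived")


def duplicate_rate(cs, n_reads: int) -> float:
    """Percent of reads removed keeping one representative per cluster."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    return 100.0 * (n_reads - len(cs.clusters)) / n_reads


def _pairs(n: int) -> int:
    return n * (n - 1) // 2


def pair_counts(truth, predicted) -> tuple[int, int, int]:
    """Exact (a, b, c) pair counts between two partitions.

    a: pairs together in both; b: together only in the truth; c: together
    only in the prediction.  Raises if the two partitions do not cover the
    same read ids.
    """
    truth_of: dict[str, str] = {}
    for cid, members in truth.clusters.items():
        for rid in members:
            truth_of[rid] = cid
    predicted_ids = {r for m in predicted.clusters.values() for r in m}
    if set(truth_of) != predicted_ids:
        missing = sorted(set(truth_of) ^ predicted_ids)[:10]
        raise ValueError(
            f"partitions cover different read ids; first differences: {missing}"
        )
    a = 0
    for members in predicted.clusters.values():
        overlap = Counter(truth_of[r] for r in members)
        a += sum(_pairs(n) for n in overlap.values())
    within_truth = sum(_pairs(len(m)) for m in truth.clusters.values())
    within_pred = sum(_pairs(len(m)) for m in predicted.clusters.values())
    return a, within_truth - a, within_pred - a


def jaccard(truth, predicted) -> float:
    """Pair-counting Jaccard index a / (a + b + c).

    When neither partition contains any pair (all singletons on both
    sides) the partitions are identical and J is defined as 1.
    """
    a, b, c = pair_counts(truth, predicted)
    if a + b + c == 0:
        return 1.0
    return a / (a + b + c)


def threshold_sweep(
    flowgrams: Sequence,
    thresholds: Sequence[float],
    truth: TruthSet | None = None,
    cfg=None,
    precluster_cfg=None,
) -> pd.DataFrame:
    """Cluster at each stringency threshold and tabulate rate and Jaccard."""
    from .cluster import dedupe

    rows = []
    for threshold in thresholds:
        cs = dedupe(flowgrams, threshold, cfg, precluster_cfg)
        row = {
            "threshold": threshold,
            "n_clusters": cs.n_clusters,
            "duplicate_rate": duplicate_rate(cs, len(flowgrams)),
        }
        if truth is not None:
            row["jaccard"] = jaccard(truth, cs)
        rows.append(row)
    return pd.DataFrame(rows)


def write_membership(cs, path) -> None:
    """Write a read_id TAB cluster_id membership table."""
    with open(path, "w") as handle:
        for cid, members in cs.clusters.items():
            for rid in members:
                handle.write(f"{rid}\t{cid}\n")


def read_membership(path, source: str = "file") -> TruthSet:
    """Read a membership table back into a partition."""
    clusters: dict[str, list[str]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                rid, cid = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: expected two columns") from exc
            clusters.setdefault(cid, []).append(rid)
    return TruthSet(clusters=clusters, source=source)
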