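"""Synthetic 454-like flowgram datasets with known duplicate structure.

A random genome is generated, templates are drawn at unique random
starts, and duplicate clusters share a template start while receiving
independent per-flow noise and independent length truncation.  Noise is
drawn from the same parametric family as the default flow model (normal
around the homopolymer length, widening with length and flow cycle;
half-normal around zero for empty flows) so that model-matched
clustering is well-posed; passing different noise parameters gives a
mismatched-noise mode for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import TruthSet
from .flowgram_io import Flowgram, round_half_up

__all__ = ["SimConfig", "simulate_run", "ideal_flows"]

_CYCLE = "TACG"


@dataclass
class SimConfig:
    """Parameters of the synthetic flowgram generator."""

    n_templates: int = 100
    duplicate_rate: float = 0.2
    cluster_size_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.75, 3: 0.18, 4: 0.05, 5: 0.02}
    )
    read_length_flows: tuple[float, float] = (150.0, 25.0)
    min_length_flows: int = 40
    n_flows: int = 200
    genome_length: int = 200_000
    noise_scale: float = 1.0
    degradation_rate: float = 0.002
    base_sigma: float = 0.11
    sigma_slope: float = 0.02
    zero_sigma: float = 0.10
    key_sequence: str = "TCAG"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        total = sum(self.cluster_size_probs.values())
        if total <= 0 or min(self.cluster_size_probs) < 2:
            raise ValueError("cluster sizes must be >= 2 with positive mass")
        if self.genome_length < 4 * self.n_flows:
            raise ValueError("genome_length too small for the flow count")
        if self.n_flows % len(_CYCLE) != 0:
            raise ValueError("n_flows must be a multiple of the flow cycle")

    @property
    def flow_order(self) -> str:
        return _CYCLE * (self.n_flows // len(_CYCLE))


def ideal_flows(sequence: str, flow_order: str) -> np.ndarray:
    """Noise-free integer flow values of a sequence under a flow order."""
    values = np.zeros(len(flow_order), dtype=int)
    pos = 0
    for i, ch in enumerate(flow_order):
        if pos >= len(sequence):
            break
        run = 0
        while pos + run < len(sequence) and sequence[pos + run] == ch:
            run += 1
        values[i] = run
        pos += run
    return values


def _noisy_flows(ideal: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    cycles = np.arange(len(ideal)) // len(_CYCLE) + 1
    widen = 1.0 + cfg.degradation_rate * cycles
    sd = np.where(
        ideal == 0, cfg.zero_sigma, cfg.base_sigma + cfg.sigma_slope * ideal
    ) * widen * cfg.noise_scale
    if cfg.noise_scale == 0:
        return ideal.astype(float)
    # reflection at zero approximates the truncated-normal model family
    values = np.abs(rng.normal(ideal.astype(float), sd))
    return np.round(values, 2)


def _cluster_sizes(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    """One cluster size per template, spending the duplicate budget."""
    budget = int(round(cfg.duplicate_rate / (1.0 - cfg.duplicate_rate) * cfg.n_templates))
    sizes_avail = sorted(cfg.cluster_size_probs)
    probs = np.array([cfg.cluster_size_probs[s] for s in sizes_avail], dtype=float)
    probs /= probs.sum()
    max_size = max(sizes_avail)
    if budget > cfg.n_templates * (max_size - 1):
        raise ValueError(
            "infeasible config: duplicate budget exceeds what the "
            "templates and cluster sizes can absorb"
        )
    sizes = [1] * cfg.n_templates
    for t in range(cfg.n_templates):
        if budget <= 0:
            break
        size = int(rng.choice(sizes_avail, p=probs))
        size = min(size, budget + 1)
        sizes[t] = size
        budget -= size - 1
    # spend any leftover budget by growing clusters up to max_size
    t = 0
    while budget > 0:
        if sizes[t] < max_size:
            sizes[t] += 1
            budget -= 1
        t = (t + 1) % cfg.n_templates
    return sizes


def simulate_run(cfg: SimConfig) -> tuple[list[Flowgram], TruthSet]:
    """Generate flowgrams and the exact truth partition.

    Deterministic for a fixed config (the seed fixes all randomness).
    Read order is a random permutation so cluster members are not
    adjacent in the output.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = "".join(rng.choice(list("ACGT"), size=cfg.genome_length))
    span = 2 * cfg.n_flows
    candidates = np.array(
        [
            p
            for p in range(cfg.genome_length - span)
            if genome[p] != cfg.key_sequence[-1]
        ]
    )
    if len(candidates) < cfg.n_templates:
        raise ValueError("infeasible config: not enough distinct template starts")
    starts = rng.choice(candidates, size=cfg.n_templates, replace=False)
    sizes = _cluster_sizes(cfg, rng)

    key_len = len(cfg.key_sequence)
    mean_len, sd_len = cfg.read_length_flows
    flow_order = cfg.flow_order

    flowgrams: list[Flowgram] = []
    clusters: dict[str, list[str]] = {}
    counter = 0
    for t, (start, size) in enumerate(zip(starts, sizes)):
        template = cfg.key_sequence + genome[start : start + span]
        ideal = ideal_flows(template, flow_order)
        calls_ideal = np.cumsum(ideal)
        key_end_flow = int(np.searchsorted(calls_ideal, key_len)) + 1
        cid = f"t{t:05d}"
        clusters[cid] = []
        max_informative = cfg.n_flows - key_end_flow
        for _ in range(size):
            rid = f"r{counter:06d}"
            counter += 1
            length = int(round(rng.normal(mean_len, sd_len)))
            length = max(cfg.min_length_flows, min(length, max_informative))
            values = _noisy_flows(ideal, cfg, rng)
            calls = round_half_up(values)
            trim_end_flow = key_end_flow + length
            clip_right = int(calls[:trim_end_flow].sum())
            fg = Flowgram(
                read_id=rid,
                flow_values=values,
                flow_order=flow_order,
                key_sequence=cfg.key_sequence,
                clip_left=key_len + 1,
                clip_right=clip_right,
            )
            flowgrams.append(fg)
            clusters[cid].append(rid)

    order = rng.permutation(len(flowgrams))
    flowgrams = [flowgrams[i] for i in order]
    return flowgrams, TruthSet(clusters=clusters, source="simulated")
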