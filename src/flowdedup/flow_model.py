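"""Probability model for flow values.

Houses the homopolymer-length prior P(h), the position-dependent
likelihood P(f|h), the Bayesian posterior P(h|f) and the probability
that two flow values arise from equal homopolymer lengths, with the
fixed-score capping rules (any value above 5.5, or both values above
2.5, scores exactly 1).

Two interchangeable backends exist: a clearly-labelled parametric
stand-in (:func:`default_parametric_model`) and empirical lookup tables
loaded from a tab-separated file (:func:`load_lookup_model`).  Posteriors
are precomputed per flow cycle on a hundredths grid so that distance
computation is a table lookup; flow values are hundredths-quantized, so
the grid is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "FlowModel",
    "default_parametric_model",
    "load_lookup_model",
    "export_lookup_table",
    "posterior_h",
    "prob_equal",
]

# Capping thresholds for the equal-length probability.
CAP_HIGH_SINGLE = 5.5
CAP_HIGH_BOTH = 2.5
EQUAL_SUM_MAX = 5

_GRID_MAX_HUNDREDTHS = 550  # grid covers f in [0, 5.50]; larger f always caps


@dataclass
class FlowModel:
    """Prior, likelihood and capping parameters behind one interface.

    ``log_likelihood`` maps (flow values array, flow cycle) to an array of
    shape (len(values), h_max + 1) of log densities P(f|h).
    """

    prior: np.ndarray
    log_likelihood: Callable[[np.ndarray, int], np.ndarray]
    h_max: int = 11
    cap_high_single: float = CAP_HIGH_SINGLE
    cap_high_both: float = CAP_HIGH_BOTH
    equal_sum_max: int = EQUAL_SUM_MAX
    _posterior_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        if self.prior.shape != (self.h_max + 1,):
            raise ValueError("prior must cover h = 0..h_max")
        if not np.isclose(self.prior.sum(), 1.0, atol=1e-9):
            raise ValueError("prior must sum to 1")

    def posterior_matrix(self, f: np.ndarray, cycle: int) -> np.ndarray:
        """Posterior P(h|f) for an array of flow values at one cycle.

        Rows sum to 1; computed in log space for stability at large f.
        """
        f = np.asarray(f, dtype=float)
        log_joint = self.log_likelihood(f, cycle) + np.log(self.prior)
        return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))

    def posterior_grid(self, cycle: int) -> np.ndarray:
        """Cached posterior over the hundredths grid f = 0.00..5.50."""
        if cycle not in self._posterior_cache:
            grid = np.arange(_GRID_MAX_HUNDREDTHS + 1) / 100.0
            self._posterior_cache[cycle] = self.posterior_matrix(grid, cycle)
        return self._posterior_cache[cycle]

    def pair_probabilities(
        self, f_a: np.ndarray, f_b: np.ndarray, cycles: np.ndarray
    ) -> np.ndarray:
        """Vectorized equal-homopolymer probability for aligned flow pairs."""
        f_a = np.asarray(f_a, dtype=float)
        f_b = np.asarray(f_b, dtype=float)
        cycles = np.asarray(cycles)
        if np.any(f_a < 0) or np.any(f_b < 0):
            raise ValueError("flow values must be non-negative")
        out = np.empty(len(f_a))
        capped = (
            (f_a > self.cap_high_single)
            | (f_b > self.cap_high_single)
            | ((f_a > self.cap_high_both) & (f_b > self.cap_high_both))
        )
        out[capped] = 1.0
        todo = ~capped
        if np.any(todo):
            ia = np.round(f_a[todo] * 100).astype(int)
            ib = np.round(f_b[todo] * 100).astype(int)
            vals = np.empty(int(todo.sum()))
            sub_cycles = cycles[todo]
            for cycle in np.unique(sub_cycles):
                grid = self.posterior_grid(int(cycle))[:, : self.equal_sum_max + 1]
                sel = sub_cycles == cycle
                vals[sel] = np.einsum(
                    "ij,ij->i", grid[ia[sel]], grid[ib[sel]]
                )
            out[todo] = np.minimum(vals, 1.0)
        return out


def posterior_h(model: FlowModel, f: float, cycle: int = 1) -> np.ndarray:
    """Posterior probability vector over h = 0..h_max for one flow value."""
    if f < 0:
        raise ValueError(f"flow value must be non-negative, got {f}")
    return model.posterior_matrix(np.array([f]), cycle)[0]


def prob_equal(model: FlowModel, f_a: float, f_b: float, cycle: int = 1) -> float:
    """Probability that two flow values share one homopolymer length.

    Returns exactly 1 when either value exceeds 5.5 or both exceed 2.5;
    otherwise sums the posterior products over h = 0..equal_sum_max,
    treating the two flowgrams as independent.
    """
    if f_a < 0 or f_b < 0:
        raise ValueError("flow values must be non-negative")
    if f_a > model.cap_high_single or f_b > model.cap_high_single:
        return 1.0
    if f_a > model.cap_high_both and f_b > model.cap_high_both:
        return 1.0
    p_a = posterior_h(model, f_a, cycle)[: model.equal_sum_max + 1]
    p_b = posterior_h(model, f_b, cycle)[: model.equal_sum_max + 1]
    return float(min(np.dot(p_a, p_b), 1.0))


def _geometric_prior(decay: float, h_max: int) -> np.ndarray:
    weights = decay ** np.arange(h_max + 1)
    return weights / weights.sum()


def default_parametric_model(
    degradation_rate: float = 0.002,
    base_sigma: float = 0.11,
    sigma_slope: float = 0.02,
    *,
    zero_sigma: float = 0.10,
    prior_decay: float = 0.25,
    h_max: int = 11,
) -> FlowModel:
    """Parametric stand-in for the downloadable empirical tables.

    The likelihood for h >= 1 is a normal density centred at h, truncated
    at 0, with standard deviation (base_sigma + sigma_slope*h) widened by
    a factor (1 + degradation_rate*cycle); h = 0 uses a half-normal
    concentrated below 0.5.  The prior decays geometrically.  Parameter
    values are this package's own defaults, not published distributions.
    """
    if base_sigma <= 0 or zero_sigma <= 0:
        raise ValueError("sigma parameters must be positive")
    if sigma_slope < 0 or degradation_rate < 0:
        raise ValueError("sigma_slope and degradation_rate must be >= 0")

    h_values = np.arange(h_max + 1)
    base_sd = np.where(
        h_values == 0, zero_sigma, base_sigma + sigma_slope * h_values
    )

    def log_likelihood(f: np.ndarray, cycle: int) -> np.ndarray:
        sd = base_sd * (1.0 + degradation_rate * cycle)
        f = np.asarray(f, dtype=float)[:, None]
        logpdf = norm.logpdf(f, loc=h_values[None, :], scale=sd[None, :])
        # renormalize for the truncation of mass below 0
        log_norm = norm.logsf(-h_values / sd)
        return logpdf - log_norm[None, :]

    return FlowModel(
        prior=_geometric_prior(prior_decay, h_max),
        log_likelihood=log_likelihood,
        h_max=h_max,
    )


def export_lookup_table(
    model: FlowModel,
    path,
    *,
    cycle_bins: tuple[int, ...] = (1, 25, 50, 75, 100, 150, 200),
    f_max: float = 8.0,
    bin_width: float = 0.01,
) -> None:
    """Write a model's prior and likelihood as a tab-separated table.

    Format: ``prior<TAB>h<TAB>probability`` rows followed by
    ``likelihood<TAB>cycle_bin<TAB>h<TAB>f_low<TAB>f_high<TAB>density``
    rows, densities piecewise-constant per flow-value bin.
    """
    edges = np.arange(0.0, f_max + bin_width / 2, bin_width)
    mids = (edges[:-1] + edges[1:]) / 2.0
    with open(path, "w") as handle:
        handle.write("# flowdedup lookup table\n")
        for h, p in enumerate(model.prior):
            handle.write(f"prior\t{h}\t{p:.10g}\n")
        for cycle in cycle_bins:
            density = np.exp(model.log_likelihood(mids, cycle))
            # renormalize the discretized rows so they integrate to one
            density = density / (density.sum(axis=0) * bin_width)[None, :]
            for h in range(model.h_max + 1):
                for low, high, d in zip(edges[:-1], edges[1:], density[:, h]):
                    if d < 1e-12:
                        continue
                    handle.write(
                        f"likelihood\t{cycle}\t{h}\t{low:.4f}\t{high:.4f}"
                        f"\t{d:.10g}\n"
                    )


class LookupTableError(ValueError):
    """Raised for malformed or non-normalizing lookup tables."""


def load_lookup_model(path) -> FlowModel:
    """Build a :class:`FlowModel` from an empirical lookup table file.

    Densities are piecewise-constant over the stored flow-value bins;
    cycles outside the tabulated bins fall back to the nearest bin.  Rows
    must integrate to 1 within 1e-3 and cover at least h = 0..1; a table
    truncated below the default h_max simply truncates posterior support.
    """
    path = Path(path)
    prior: dict[int, float] = {}
    tables: dict[tuple[int, int], list[tuple[float, float, float]]] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if parts[0] == "prior":
                    prior[int(parts[1])] = float(parts[2])
                elif parts[0] == "likelihood":
                    cycle, h = int(parts[1]), int(parts[2])
                    tables.setdefault((cycle, h), []).append(
                        (float(parts[3]), float(parts[4]), float(parts[5]))
                    )
                else:
                    raise ValueError(f"unknown row type {parts[0]!r}")
            except (IndexError, ValueError) as exc:
                raise LookupTableError(f"{path}:{line_no}: {exc}") from exc
    if not prior or not tables:
        raise LookupTableError(f"{path}: empty or missing prior/likelihood")

    h_levels = sorted({h for _, h in tables})
    if h_levels != list(range(len(h_levels))):
        raise LookupTableError(
            f"{path}: missing h rows, found h = {h_levels}"
        )
    h_max = max(h_levels)
    if h_max < EQUAL_SUM_MAX:
        import logging

        logging.getLogger(__name__).warning(
            "lookup table covers h <= %d only; posterior support truncated",
            h_max,
        )
    if sorted(prior) != list(range(max(prior) + 1)):
        raise LookupTableError(f"{path}: prior rows must cover h = 0..max")
    prior_vec = np.array([prior[h] for h in range(h_max + 1)])
    prior_vec = prior_vec / prior_vec.sum()

    cycle_bins = sorted({c for c, _ in tables})
    # per (cycle, h): sorted bin edges + densities for searchsorted lookup
    compiled: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (cycle, h), rows in tables.items():
        rows.sort()
        lows = np.array([r[0] for r in rows])
        highs = np.array([r[1] for r in rows])
        dens = np.array([r[2] for r in rows])
        mass = float(np.sum(dens * (highs - lows)))
        if abs(mass - 1.0) > 1e-3:
            raise LookupTableError(
                f"{path}: density for cycle {cycle}, h {h} integrates to "
                f"{mass:.6f}, not 1"
            )
        compiled[(cycle, h)] = (lows, highs, dens)

    bins_arr = np.asarray(cycle_bins)

    def log_likelihood(f: np.ndarray, cycle: int) -> np.ndarray:
        nearest = int(bins_arr[np.argmin(np.abs(bins_arr - cycle))])
        f = np.asarray(f, dtype=float)
        out = np.full((len(f), h_max + 1), -np.inf)
        for h in range(h_max + 1):
            lows, highs, dens = compiled[(nearest, h)]
            idx = np.searchsorted(lows, f, side="right") - 1
            idx_clip = np.clip(idx, 0, len(lows) - 1)
            inside = (idx >= 0) & (f <= highs[idx_clip] + 1e-12)
            vals = np.where(inside, dens[idx_clip], 0.0)
            with np.errstate(divide="ignore"):
                out[:, h] = np.log(vals)
        # guard rows where every density underflows (f beyond the table):
        # fall back to the nearest populated bin per h
        empty = ~np.isfinite(out).any(axis=1)
        if np.any(empty):
            for h in range(h_max + 1):
                lows, highs, dens = compiled[(nearest, h)]
                idx = np.clip(
                    np.searchsorted(lows, f[empty]) - 1, 0, len(lows) - 1
                )
                out[empty, h] = np.log(dens[idx])
        return out

    return FlowModel(prior=prior_vec, log_likelihood=log_likelihood, h_max=h_max)
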