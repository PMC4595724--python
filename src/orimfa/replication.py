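"""Population-level model of multi-origin replication on a circular chromosome.

Marker-frequency analysis (MFA) measures the relative abundance of genomic
loci in an asynchronously growing population: loci replicated early (near
fired origins) are present in more copies than loci replicated late, so
origins appear as peaks in the abundance profile.

The forward model here assumes:

* A fraction ``f`` of cells is actively cycling; the rest carry exactly one
  genome equivalent per locus.
* In a cycling cell, each origin ``i`` fires independently with efficiency
  ``e_i`` at the start of the round; cells in which no origin fires are not
  viable, so the firing-subset distribution is renormalized over non-empty
  subsets.
* Replication forks proceed bidirectionally from every fired origin at
  constant speed ``v``, so the locus at ``x`` is replicated at time
  ``t_S(x) = min_{i in S} d_circ(x, o_i) / v`` where ``d_circ`` is the
  shortest arc on the circle.
* Cell ages follow the exponential (asynchronous steady-state) distribution
  with density ``(2 ln 2 / T) 2^{-a/T}`` on ``[0, T]``, giving an expected
  copy number ``M_S(x) = 2^{1 - t_S(x)/T}`` for the locus at ``x``.

The population marker frequency is then

    MF(x) = f * E_S[ M_S(x) ] + (1 - f) * 1      in [1, 1 + f].

Replication rounds longer than a doubling time (``t_S(x) > T``) are excluded
by a validated precondition rather than modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genome import Chromosome

MAX_ORIGINS_FOR_ENUMERATION = 12


@dataclass(frozen=True)
class OriginSpec:
    """A replication origin: chromosomal position plus firing efficiency.

    ``efficiency`` is the probability the origin fires in a given
    replication round; 0 encodes a strictly dormant origin that is only
    replicated passively by forks from elsewhere.
    """

    id: str
    position: int
    efficiency: float

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(
                f"origin {self.id}: efficiency {self.efficiency} outside [0, 1]"
            )
        if self.position < 0:
            raise ValueError(f"origin {self.id}: negative position {self.position}")


@dataclass(frozen=True)
class ReplicationParams:
    """Kinetic parameters of the replication model.

    fork_speed : bp per minute (v)
    doubling_time : minutes (T)
    cycling_fraction : probability that a sampled cell is replicating (f)
    """

    fork_speed: float
    doubling_time: float
    cycling_fraction: float = 0.5

    def __post_init__(self):
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be positive")
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be positive")
        if not 0.0 <= self.cycling_fraction <= 1.0:
            raise ValueError("cycling_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ProbeDesign:
    """Tiling-array probe layout: ordered probe start coordinates."""

    positions: np.ndarray
    probe_length: int = 50
    density: float = 34.0  # probes per kb, nominal

    def __post_init__(self):
        pos = np.asarray(self.positions)
        if pos.ndim != 1 or len(pos) == 0:
            raise ValueError("probe positions must be a non-empty 1-D array")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("probe positions must be strictly increasing")
        object.__setattr__(self, "positions", pos.astype(np.int64))

    @classmethod
    def tile(cls, length: int, density: float = 34.0, probe_length: int = 50) -> "ProbeDesign":
        """Evenly tile a chromosome at ``density`` probes per kb."""
        n = int(round(density * length / 1000.0))
        positions = np.floor(np.arange(n) * (length / n)).astype(np.int64)
        positions = np.unique(positions)
        realized = len(positions) / (length / 1000.0)
        if abs(realized - density) / density > 0.05:
            raise ValueError(
                f"realized density {realized:.2f}/kb deviates >5% from nominal {density}/kb"
            )
        return cls(positions=positions, probe_length=probe_length, density=density)


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel multiplicative log-normal noise (natural-log sd)."""

    channel_log_sd: float = 0.07
    seed: int = 0

    def __post_init__(self):
        if self.channel_log_sd < 0:
            raise ValueError("channel_log_sd must be >= 0")


def _active(origins: list[OriginSpec]) -> list[OriginSpec]:
    act = [o for o in origins if o.efficiency > 0]
    if not act:
        raise ValueError("all origin efficiencies are 0: no replication possible")
    return act


def max_replication_time(chrom: Chromosome, origins: list[OriginSpec],
                         params: ReplicationParams) -> float:
    """Worst-case locus replication time over reachable firing subsets (min).

    Origins with efficiency 1 are present in every firing subset, so if any
    exist the worst case is the farthest locus from the *always-firing* set;
    otherwise any single origin can be the lone firer and the worst case is
    half the circle (or the far end, if linear) from it.
    """
    act = _active(origins)
    certain = [o for o in act if o.efficiency == 1.0]
    if certain:
        # only subsets containing every certain origin are reachable; the
        # farthest locus from the always-firing set sits mid-gap
        pos = np.sort([o.position for o in certain])
        if chrom.circular:
            gaps = np.diff(np.append(pos, pos[0] + chrom.length))
            worst = float(gaps.max()) / 2.0
        else:
            internal = np.diff(pos) / 2.0 if len(pos) > 1 else np.array([0.0])
            worst = float(max(pos[0], chrom.length - 1 - pos[-1], internal.max()))
    elif chrom.circular:
        worst = chrom.length / 2.0  # lone-origin subset, antipodal locus
    else:
        worst = max(
            float(max(o.position, chrom.length - 1 - o.position)) for o in act
        )
    return worst / params.fork_speed


def _check_c_period(chrom, origins, params):
    tmax = max_replication_time(chrom, origins, params)
    if tmax > params.doubling_time * (1 + 1e-9):
        raise ValueError(
            f"C period {tmax:.1f} min exceeds the doubling time "
            f"{params.doubling_time:.1f} min; raise fork_speed or doubling_time"
        )


def expected_marker_frequency(
    chrom: Chromosome,
    origins: list[OriginSpec],
    params: ReplicationParams,
    positions,
):
    """Exact population marker frequency MF(x) by firing-subset enumeration.

    Enumerates every non-empty subset ``S`` of origins with non-zero
    efficiency, weights it by ``prod_{i in S} e_i * prod_{i not in S}
    (1 - e_i)`` renormalized over non-empty subsets, and averages the
    per-subset copy number ``2^{1 - t_S(x)/T}``.

    ``positions`` may be a scalar or array; the return matches its shape.
    Values lie in ``[1, 1 + f]``.
    """
    act = _active(origins)
    if len(act) > MAX_ORIGINS_FOR_ENUMERATION:
        raise ValueError(
            f"{len(act)} active origins exceed the enumeration limit "
            f"({MAX_ORIGINS_FOR_ENUMERATION})"
        )
    scalar = np.isscalar(positions)
    x = np.atleast_1d(np.asarray(positions, dtype=float))
    if np.any((x < 0) | (x >= chrom.length)):
        raise ValueError("position out of range [0, chromosome length)")
    _check_c_period(chrom, origins, params)

    T = params.doubling_time
    f = params.cycling_fraction
    # replication time from each active origin alone: (n, k)
    t = np.stack(
        [chrom.circular_distance(x, o.position) / params.fork_speed for o in act],
        axis=1,
    )
    eff = np.array([o.efficiency for o in act])

    em = np.zeros(len(x))
    total_p = 0.0
    idx = range(len(act))
    for r in range(1, len(act) + 1):
        for subset in combinations(idx, r):
            s = np.array(subset)
            p = np.prod(eff[s]) * np.prod(1 - np.delete(eff, s))
            if p == 0.0:
                continue
            t_s = t[:, s].min(axis=1)
            em += p * np.power(2.0, 1.0 - t_s / T)
            total_p += p
    em /= total_p
    mf = f * em + (1.0 - f)
    return float(mf[0]) if scalar else mf


def sample_marker_frequency(
    chrom: Chromosome,
    origins: list[OriginSpec],
    params: ReplicationParams,
    positions,
    n_cells: int,
    seed: int,
):
    """Monte-Carlo estimate of MF(x) with per-position standard errors.

    Samples ``n_cells`` cycling cells (firing subsets resampled until
    non-empty), computes each cell's expected copy number at every position,
    and mixes with the non-cycling fraction.  Returns ``(mf, se)``.

    Serves as the stochastic cross-check of the closed-form enumeration in
    :func:`expected_marker_frequency`; the two must agree within Monte-Carlo
    error.
    """
    act = _active(origins)
    x = np.atleast_1d(np.asarray(positions, dtype=float))
    _check_c_period(chrom, origins, params)
    rng = np.random.default_rng(seed)
    eff = np.array([o.efficiency for o in act])
    fired = rng.random((n_cells, len(act))) < eff
    empty = ~fired.any(axis=1)
    while empty.any():
        fired[empty] = rng.random((int(empty.sum()), len(act))) < eff
        empty = ~fired.any(axis=1)

    t = np.stack(
        [chrom.circular_distance(x, o.position) / params.fork_speed for o in act],
        axis=1,
    )  # (n_pos, k)
    T = params.doubling_time
    f = params.cycling_fraction
    # per-cell replication time at each position: mask unfired origins
    t_cells = np.where(fired[:, None, :], t[None, :, :], np.inf).min(axis=2)
    m = np.power(2.0, 1.0 - t_cells / T)  # (n_cells, n_pos)
    mf = f * m.mean(axis=0) + (1 - f)
    se = f * m.std(axis=0, ddof=1) / np.sqrt(n_cells)
    return mf, se


def simulate_microarray(
    chrom: Chromosome,
    origins: list[OriginSpec],
    params: ReplicationParams,
    design: ProbeDesign,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Simulate a two-channel exponential-vs-stationary tiling array.

    The exponential-phase channel measures MF(x) and the stationary-phase
    channel measures the fully replicated (copy number 1) genome; each
    channel carries independent multiplicative log-normal noise.  Returns a
    probe table with columns ``probe_pos, exp_signal, stat_signal, ratio``.
    """
    if design.positions[-1] >= chrom.length:
        raise ValueError("probe design extends beyond the chromosome")
    mf = expected_marker_frequency(chrom, origins, params, design.positions)
    rng = np.random.default_rng(noise.seed)
    exp_noise = rng.normal(0.0, noise.channel_log_sd, size=len(design.positions))
    stat_noise = rng.normal(0.0, noise.channel_log_sd, size=len(design.positions))
    exp_signal = mf * np.exp(exp_noise)
    stat_signal = np.exp(stat_noise)
    return pd.DataFrame(
        {
            "probe_pos": design.positions,
            "exp_signal": exp_signal,
            "stat_signal": stat_signal,
            "ratio": exp_signal / stat_signal,
        }
    )


def simulate_reads(
    chrom: Chromosome,
    origins: list[OriginSpec],
    params: ReplicationParams,
    n_reads: int,
    read_length: int,
    seed: int,
    grid_bp: int = 100,
) -> pd.DataFrame:
    """Draw read start positions with density proportional to MF(x).

    Sequencing depth of an exponential-phase library tracks locus copy
    number, so read starts are sampled from the normalized MF profile
    (piecewise-constant on a ``grid_bp`` lattice, uniform within a cell).
    Returns sorted 0-based half-open BED records as a DataFrame with columns
    ``chrom, start, end``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    centers = np.arange(grid_bp // 2, chrom.length, grid_bp, dtype=float)
    mf = expected_marker_frequency(chrom, origins, params, centers)
    p = mf / mf.sum()
    rng = np.random.default_rng(seed)
    cells = rng.choice(len(centers), size=n_reads, p=p)
    offsets = rng.integers(0, grid_bp, size=n_reads)
    starts = np.minimum(cells * grid_bp + offsets, chrom.length - 1)
    starts.sort()
    ends = np.minimum(starts + read_length, chrom.length)
    return pd.DataFrame({"chrom": chrom.name, "start": starts, "end": ends})
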