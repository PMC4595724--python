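"""Marker-frequency-analysis processing chain.

The chain mirrors the standard tiling-array MFA workflow for archaeal
replication profiling:

1. per-probe ratio of the exponential-phase channel to the
   stationary-phase channel (:func:`compute_ratios`);
2. exclusion of outlier probes with ratio > 2 or < 0.5
   (:func:`filter_outliers`; boundary values are retained — the
   inequalities are strict);
3. averaging of consecutive groups of 30 retained probes into one point
   located at the group's first probe (:func:`bin_probes`);
4. a centered 5-point moving average with 1-point slide
   (:func:`smooth`), wrapping around circular chromosomes.

For sequencing-based profiling, read starts are counted in non-overlapping
1-kb windows instead (:func:`window_read_counts`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

RETAINED = "retained"
EXCLUDED = "excluded_outlier"

#: outlier bounds on the exp/stat ratio, exclusion strictly outside
RATIO_UPPER = 2.0
RATIO_LOWER = 0.5

DEFAULT_BIN_PROBES = 30
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_READ_WINDOW_BP = 1000


@dataclass
class MFAProfile:
    """A binned (optionally smoothed) marker-frequency track.

    positions : bp coordinate of each profile point (strictly increasing)
    values : mean probe ratio (array mode) or read count (sequencing mode)
    """

    positions: np.ndarray
    values: np.ndarray
    chrom_name: str
    chrom_length: int
    circular: bool = True
    source: str = "array"  # "array" | "sequencing"
    bin_size_probes: int | None = None
    window_bp: int | None = None
    smoothed: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values differ in length")
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValueError("profile positions must be strictly increasing")

    def __len__(self):
        return len(self.positions)


def compute_ratios(exp_signals, stat_signals, positions) -> pd.DataFrame:
    """Build the per-probe ratio table (exponential / stationary).

    Returns a DataFrame with columns ``probe_pos, exp_signal, stat_signal,
    ratio, status``; every probe starts out retained.
    """
    exp_signals = np.asarray(exp_signals, dtype=float)
    stat_signals = np.asarray(stat_signals, dtype=float)
    positions = np.asarray(positions)
    if not (len(exp_signals) == len(stat_signals) == len(positions)):
        raise ValueError(
            f"misaligned inputs: {len(exp_signals)} exp, {len(stat_signals)} stat, "
            f"{len(positions)} positions"
        )
    if len(positions) and not np.all(np.diff(positions) > 0):
        raise ValueError("probe positions must be strictly increasing")
    bad = np.flatnonzero(stat_signals <= 0)
    if len(bad):
        raise ValueError(
            f"non-positive stationary signal at probe position {positions[bad[0]]}"
        )
    return pd.DataFrame(
        {
            "probe_pos": positions,
            "exp_signal": exp_signals,
            "stat_signal": stat_signals,
            "ratio": exp_signals / stat_signals,
            "status": RETAINED,
        }
    )


def filter_outliers(
    table: pd.DataFrame,
    upper: float = RATIO_UPPER,
    lower: float = RATIO_LOWER,
) -> tuple[pd.DataFrame, float]:
    """Flag probes with ratio strictly above ``upper`` or below ``lower``.

    Rows with ratio exactly equal to a bound are retained.  Returns the
    flagged table (a copy) and the excluded fraction.  Idempotent.
    """
    table = table.copy()
    outlier = (table["ratio"] > upper) | (table["ratio"] < lower)
    table["status"] = np.where(outlier, EXCLUDED, RETAINED)
    return table, float(outlier.mean())


def bin_probes(
    table: pd.DataFrame,
    bin_size: int = DEFAULT_BIN_PROBES,
    chrom_name: str = "chr",
    chrom_length: int | None = None,
    circular: bool = True,
) -> MFAProfile:
    """Average consecutive groups of ``bin_size`` retained probes.

    Each group becomes one profile point located at its first probe.  A
    trailing partial group is kept if it has at least ``bin_size / 2``
    probes, otherwise dropped.
    """
    kept = table[table["status"] == RETAINED]
    if len(kept) < bin_size / 2:
        raise ValueError(
            f"only {len(kept)} retained probes; need at least {bin_size / 2:g} "
            f"for one bin"
        )
    pos = kept["probe_pos"].to_numpy()
    ratio = kept["ratio"].to_numpy()
    n_full = len(kept) // bin_size
    remainder = len(kept) - n_full * bin_size
    bins = [(i * bin_size, (i + 1) * bin_size) for i in range(n_full)]
    if remainder >= bin_size / 2:
        bins.append((n_full * bin_size, len(kept)))
    out_pos = np.array([pos[s] for s, _ in bins])
    out_val = np.array([ratio[s:e].mean() for s, e in bins])
    if chrom_length is None:
        chrom_length = int(pos[-1]) + 1
    return MFAProfile(
        positions=out_pos,
        values=out_val,
        chrom_name=chrom_name,
        chrom_length=chrom_length,
        circular=circular,
        source="array",
        bin_size_probes=bin_size,
        metadata={"n_probes_retained": len(kept)},
    )


def smooth(
    profile: MFAProfile,
    window: int = DEFAULT_SMOOTH_WINDOW,
    slide: int = 1,
) -> MFAProfile:
    """Centered moving average with 1-point slide; cardinality-preserving.

    On circular profiles the window wraps across the coordinate origin; in
    linear mode edge windows shrink symmetrically (the radius is reduced
    near the ends so the window stays centered).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if slide != 1:
        raise ValueError("only 1-point slide is supported")
    if profile.smoothed:
        raise ValueError("profile is already smoothed")
    n = len(profile)
    if n < window:
        raise ValueError(f"profile has {n} points, fewer than the window ({window})")
    if profile.circular:
        values = uniform_filter1d(profile.values, size=window, mode="wrap")
    else:
        h = window // 2
        values = np.empty(n)
        for i in range(n):
            r = min(h, i, n - 1 - i)
            values[i] = profile.values[i - r : i + r + 1].mean()
    out = replace(profile, values=values, smoothed=True)
    out.metadata = dict(profile.metadata, smooth_window=window, smooth_slide=slide)
    return out


def window_read_counts(
    reads: pd.DataFrame,
    chrom_name: str,
    chrom_length: int,
    window: int = DEFAULT_READ_WINDOW_BP,
    circular: bool = True,
) -> MFAProfile:
    """Count read starts per non-overlapping window of ``window`` bp.

    Points are located at window starts; a final short window keeps its raw
    count.  The sum of counts equals the number of input reads.
    """
    if not {"start"}.issubset(reads.columns):
        raise ValueError("reads must carry a 'start' column (BED)")
    starts = reads["start"].to_numpy()
    if len(starts) and (starts.min() < 0 or starts.max() >= chrom_length):
        raise ValueError("read start outside [0, chromosome length)")
    edges = np.arange(0, chrom_length + window, window)
    edges[-1] = max(edges[-1], chrom_length)  # final short window
    counts, _ = np.histogram(starts, bins=edges)
    return MFAProfile(
        positions=edges[:-1],
        values=counts.astype(float),
        chrom_name=chrom_name,
        chrom_length=chrom_length,
        circular=circular,
        source="sequencing",
        window_bp=window,
        metadata={"n_reads": int(len(starts))},
    )
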