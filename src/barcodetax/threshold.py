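"""Optimum-threshold (OT) selection by minimum cumulative identification error.

A candidate threshold t splits the pooled pairwise K2P distances of a
labelled reference dataset into identification errors:

* Type I  — conspecific pairs with divergence above t (the marker looks too
  variable within a species);
* Type II — heterospecific pairs with divergence below t (the marker fails
  to separate species).

Both are expressed as percentages of all compared pairs (intra- and
interspecific pooled); pairs exactly at t count as neither, following the
strict inequalities of the error definitions.  Their sum is the cumulative
error (CE); the threshold grid is scanned and the Optimum Threshold is read
off where CE attains its minimum (MCE).  When a contiguous run of candidates
ties at the MCE, the default tie rule returns the midpoint of the first such
run, maximising the margin around the chosen cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, split_pair_distances

DEFAULT_STEP_PCT = 0.1


@dataclass(frozen=True)
class ThresholdScan:
    """Type I / Type II / cumulative error (%) over a candidate grid (%)."""

    thresholds_pct: np.ndarray
    type_i_pct: np.ndarray
    type_ii_pct: np.ndarray
    n_intra_pairs: int
    n_inter_pairs: int

    @property
    def cumulative_error_pct(self) -> np.ndarray:
        return self.type_i_pct + self.type_ii_pct

    @property
    def n_total_pairs(self) -> int:
        return self.n_intra_pairs + self.n_inter_pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_pct": self.thresholds_pct,
                "type_I_pct": self.type_i_pct,
                "type_II_pct": self.type_ii_pct,
                "cumulative_error_pct": self.cumulative_error_pct,
            }
        )


@dataclass(frozen=True)
class OTResult:
    """Optimum threshold and its minimum cumulative error (both %)."""

    ot_pct: float
    mce_pct: float
    optimal_interval_pct: tuple[float, float]
    tie_rule: str


def make_grid(
    max_distance_pct: float, step_pct: float = DEFAULT_STEP_PCT
) -> np.ndarray:
    """Candidate thresholds 0, step, 2*step, ... up to ceil(max distance)."""
    top = math.ceil(max(max_distance_pct, step_pct))
    n_steps = int(round(top / step_pct))
    return step_pct * np.arange(n_steps + 1)


def scan_pair_distances(
    intra_pct: np.ndarray,
    inter_pct: np.ndarray,
    grid_pct: np.ndarray | None = None,
    step_pct: float = DEFAULT_STEP_PCT,
) -> ThresholdScan:
    """Scan candidate thresholds over pooled intra/inter pair distances (%)."""
    intra_pct = np.sort(np.asarray(intra_pct, dtype=float))
    inter_pct = np.sort(np.asarray(inter_pct, dtype=float))
    if intra_pct.size == 0:
        raise ValueError(
            "reference dataset needs >= 2 conspecific samples "
            "(no intraspecific pairs)"
        )
    if inter_pct.size == 0:
        raise ValueError("reference dataset has no interspecific pairs")
    if grid_pct is None:
        grid_pct = make_grid(max(intra_pct.max(), inter_pct.max()), step_pct)
    grid_pct = np.asarray(grid_pct, dtype=float)
    n_total = intra_pct.size + inter_pct.size
    # strict inequalities: d > t for Type I, d < t for Type II; d == t neither
    n_type_i = intra_pct.size - np.searchsorted(intra_pct, grid_pct, side="right")
    n_type_ii = np.searchsorted(inter_pct, grid_pct, side="left")
    return ThresholdScan(
        thresholds_pct=grid_pct,
        type_i_pct=100.0 * n_type_i / n_total,
        type_ii_pct=100.0 * n_type_ii / n_total,
        n_intra_pairs=int(intra_pct.size),
        n_inter_pairs=int(inter_pct.size),
    )


def threshold_scan(
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    exclusions: Sequence[str] = (),
    grid_pct: np.ndarray | None = None,
    step_pct: float = DEFAULT_STEP_PCT,
) -> ThresholdScan:
    """Scan thresholds on a labelled reference distance matrix.

    UNKNOWN-labelled samples and excluded species are left out; undefined
    (NaN) pairs are dropped.
    """
    intra, inter, _ = split_pair_distances(matrix, species_labels, exclusions)
    return scan_pair_distances(intra, inter, grid_pct=grid_pct, step_pct=step_pct)


def optimum_threshold(scan: ThresholdScan, tie_rule: str = "midpoint") -> OTResult:
    """Pick the OT at the minimum cumulative error.

    tie_rule:
      * "midpoint" — midpoint of the first contiguous run of optimal
        candidates (default: maximises margin around the cutoff);
      * "smallest" — smallest optimal candidate.
    """
    ce = scan.cumulative_error_pct
    if ce.size == 0:
        raise ValueError("empty threshold scan")
    mce = float(ce.min())
    optimal = np.flatnonzero(ce <= mce + 1e-12)
    # first contiguous run of optimal candidates
    breaks = np.flatnonzero(np.diff(optimal) > 1)
    stop = optimal[breaks[0]] if breaks.size else optimal[-1]
    lo = float(scan.thresholds_pct[optimal[0]])
    hi = float(scan.thresholds_pct[stop])
    if tie_rule == "midpoint":
        ot = (lo + hi) / 2.0
    elif tie_rule == "smallest":
        ot = lo
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return OTResult(
        ot_pct=ot, mce_pct=mce, optimal_interval_pct=(lo, hi), tie_rule=tie_rule
    )


def error_curve_report(
    scan: ThresholdScan, path: str | Path, plot: bool = False
) -> None:
    """Write the scan as TSV (threshold, typeI, typeII, CE); optional PNG plot."""
    path = Path(path)
    scan.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(scan.thresholds_pct, scan.type_i_pct, label="Type I", color="gold")
        ax.plot(scan.thresholds_pct, scan.type_ii_pct, label="Type II", color="red")
        ax.plot(
            scan.thresholds_pct, scan.cumulative_error_pct,
            label="cumulative error", color="black", linestyle="--",
        )
        ax.set_xlabel("threshold (% K2P distance)")
        ax.set_ylabel("error (% of compared pairs)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
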