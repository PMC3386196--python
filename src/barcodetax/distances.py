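"""Kimura 2-parameter distances under pairwise deletion, plus divergence summaries.

The K2P model separates transitions (A<->G, C<->T; proportion P over compared
sites) from transversions (proportion Q) and estimates the per-site number of
substitutions as

    d = -(1/2) * ln(1 - 2P - Q) - (1/4) * ln(1 - 2Q)

Sites where either sequence carries a gap or an IUPAC ambiguity code are
dropped for that pair only (pairwise deletion).  When an argument of a log is
non-positive (saturation) or no comparable sites remain, the distance is
undefined and stored as NaN; summaries skip NaN entries and report how many
there were.

Distances are held in substitutions/site throughout; user-facing reports
multiply by 100 and print percent, matching field convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seq_qc import UNKNOWN, BarcodeAlignment

# Encoding: A,C,G,T -> 0..3; anything else (gap/ambiguity) -> 4 (masked).
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_PURINE = np.array([True, False, True, False, False])  # A,G purines


def encode_alignment(alignment: BarcodeAlignment) -> np.ndarray:
    """Encode an alignment to a (n_records, n_columns) uint8 matrix."""
    raw = np.frombuffer(
        "".join(r.sequence for r in alignment.records).encode("ascii"), dtype=np.uint8
    )
    return _CODE[raw].reshape(len(alignment), alignment.length)


def encode_sequence(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def k2p_from_proportions(p: float, q: float) -> float:
    """Evaluate the K2P formula; NaN where the logs are undefined."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def _pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    comparable = (a < 4) & (b < 4)
    n = int(comparable.sum())
    if n == 0:
        return float("nan")
    ac, bc = a[comparable], b[comparable]
    diff = ac != bc
    transitions = int((diff & (_PURINE[ac] == _PURINE[bc])).sum())
    transversions = int(diff.sum()) - transitions
    return k2p_from_proportions(transitions / n, transversions / n)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance between two equal-length sequences (NaN if undefined)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    return _pair_distance(
        encode_sequence(seq_a.upper()), encode_sequence(seq_b.upper())
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix in substitutions/site."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) float64, zero diagonal, NaN = undefined

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValueError("diagonal must be exactly zero")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def pairwise(self) -> Iterable[tuple[str, str, float]]:
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.labels[i], self.labels[j], float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        frame.to_csv(path, sep="\t", float_format="%.6f", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy(dtype=float)
        np.fill_diagonal(values, 0.0)
        values = (values + values.T) / 2.0
        return cls(tuple(frame.columns), values)


def distance_matrix(alignment: BarcodeAlignment) -> DistanceMatrix:
    """All-pairs K2P distances under pairwise deletion."""
    if len(alignment) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    enc = encode_alignment(alignment)
    n = enc.shape[0]
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_distance(enc[i], enc[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(alignment.sample_ids), values)


def cross_distances(
    queries: BarcodeAlignment, references: BarcodeAlignment
) -> np.ndarray:
    """(n_query, n_reference) K2P distances between two aligned sets."""
    if queries.length != references.length:
        raise ValueError(
            f"alignment length mismatch: {queries.length} vs {references.length}"
        )
    qe, re = encode_alignment(queries), encode_alignment(references)
    out = np.empty((qe.shape[0], re.shape[0]), dtype=float)
    for i in range(qe.shape[0]):
        for j in range(re.shape[0]):
            out[i, j] = _pair_distance(qe[i], re[j])
    return out


# ---------------------------------------------------------------------------
# Intra/interspecific divergence summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceSummary:
    """Within- and between-species K2P divergence statistics (percent scale).

    ``dispersion`` columns are the standard deviation of the pairwise values
    (the field's headline "mean ± x%" figures are of this magnitude, not a
    standard error of the mean).
    """

    per_species: pd.DataFrame     # species, n_samples, n_pairs, mean/disp/min/max %
    per_species_pair: pd.DataFrame  # species_a, species_b, n_pairs, mean/disp %
    intraspecific_mean_pct: float   # NaN if no species has >= 2 samples
    intraspecific_dispersion_pct: float
    intraspecific_range_pct: tuple[float, float]
    interspecific_mean_pct: float
    interspecific_dispersion_pct: float
    interspecific_range_pct: tuple[float, float]
    overall_mean_pct: float
    n_undefined: int


def split_pair_distances(
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    exclusions: Sequence[str] = (),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool pairwise distances (percent) into intra- and interspecific arrays.

    Pairs involving UNKNOWN or excluded species are dropped; NaN (undefined)
    pairs are dropped and counted.
    """
    if len(species_labels) != len(matrix):
        raise ValueError("species_labels length does not match matrix")
    drop = set(exclusions) | {UNKNOWN}
    labels = np.asarray(species_labels)
    keep = ~np.isin(labels, list(drop))
    idx = np.flatnonzero(keep)
    sub = matrix.values[np.ix_(idx, idx)]
    sub_species = labels[idx]
    iu, ju = np.triu_indices(len(idx), k=1)
    vals = sub[iu, ju] * 100.0
    same = sub_species[iu] == sub_species[ju]
    defined = ~np.isnan(vals)
    n_undefined = int((~defined).sum())
    return vals[same & defined], vals[~same & defined], n_undefined


def divergence_summary(
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    exclusions: Sequence[str] = (),
) -> DivergenceSummary:
    """Summarise within- and between-species divergence (percent scale).

    Species with fewer than two samples have no intraspecific pairs and
    appear with NaN statistics (never zero); they still contribute
    interspecific pairs.
    """
    intra, inter, n_undefined = split_pair_distances(
        matrix, species_labels, exclusions
    )
    drop = set(exclusions) | {UNKNOWN}
    labels = np.asarray(species_labels)

    per_species_rows = []
    for sp in sorted(set(labels) - drop):
        idx = np.flatnonzero(labels == sp)
        iu, ju = np.triu_indices(len(idx), k=1)
        vals = matrix.values[np.ix_(idx, idx)][iu, ju] * 100.0
        vals = vals[~np.isnan(vals)]
        row = {"species": sp, "n_samples": len(idx), "n_pairs": len(vals)}
        if len(vals):
            row.update(
                mean_pct=vals.mean(), dispersion_pct=vals.std(ddof=0),
                min_pct=vals.min(), max_pct=vals.max(),
            )
        else:
            row.update(mean_pct=np.nan, dispersion_pct=np.nan,
                       min_pct=np.nan, max_pct=np.nan)
        per_species_rows.append(row)
    per_species = pd.DataFrame(per_species_rows)

    pair_rows = []
    kept = sorted(set(labels) - drop)
    for a_i, sp_a in enumerate(kept):
        for sp_b in kept[a_i + 1 :]:
            ia = np.flatnonzero(labels == sp_a)
            ib = np.flatnonzero(labels == sp_b)
            vals = matrix.values[np.ix_(ia, ib)].ravel() * 100.0
            vals = vals[~np.isnan(vals)]
            if not len(vals):
                continue
            pair_rows.append(
                {
                    "species_a": sp_a, "species_b": sp_b, "n_pairs": len(vals),
                    "mean_pct": vals.mean(), "dispersion_pct": vals.std(ddof=0),
                }
            )
    per_species_pair = pd.DataFrame(pair_rows)

    def _stats(vals: np.ndarray) -> tuple[float, float, tuple[float, float]]:
        if not len(vals):
            return float("nan"), float("nan"), (float("nan"), float("nan"))
        return (
            float(vals.mean()),
            float(vals.std(ddof=0)),
            (float(vals.min()), float(vals.max())),
        )

    intra_mean, intra_disp, intra_range = _stats(intra)
    inter_mean, inter_disp, inter_range = _stats(inter)
    pooled = np.concatenate([intra, inter])
    overall = float(pooled.mean()) if len(pooled) else float("nan")

    return DivergenceSummary(
        per_species=per_species,
        per_species_pair=per_species_pair,
        intraspecific_mean_pct=intra_mean,
        intraspecific_dispersion_pct=intra_disp,
        intraspecific_range_pct=intra_range,
        interspecific_mean_pct=inter_mean,
        interspecific_dispersion_pct=inter_disp,
        interspecific_range_pct=inter_range,
        overall_mean_pct=overall,
        n_undefined=n_undefined,
    )
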