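"""Synthetic barcode datasets with known ground truth.

The generator mirrors the statistical structure a coxI barcode survey of a
well-sorted vertebrate fauna exhibits: a star phylogeny of species whose
ancestors sit ``inter_divergence`` apart in expectation, with conspecific
samples radiating ``intra_divergence`` around their ancestor, sequences
evolving under the Kimura two-parameter substitution process (transition:
transversion rate ratio ``kappa``), and a protein-coding reading frame kept
free of stop codons.  Scenario injections create the structures the rank
classifier must recognise:

* ``MTMotuPair`` — two nominal species drawn from one ancestor (the marker
  cannot separate them -> MT_MOTU);
* ``IotuSplit``  — divergent intraspecific lineages with disjoint locality
  groups (geographic congruence -> IOTU);
* ``UcsSplit``   — divergent lineages whose localities overlap (molecular
  evidence only -> UCS).

A star phylogeny (all species equidistant) is the default because the
downstream analysis consumes only pairwise distances and a star makes the
configured divergences exact in expectation; a random coalescent-style tree
is available for stress testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_qc import (
    UNKNOWN,
    BarcodeAlignment,
    BarcodeRecord,
    write_fasta,
)

_BASES = "ACGT"
#: Transition partner of A,C,G,T (A<->G, C<->T).
_TS_PARTNER = np.array([2, 3, 0, 1])
#: The two transversion partners of each base.
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
#: Vertebrate-mitochondrial stop codons over the 0..3 encoding.
_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (0, 2, 0), (0, 2, 2)}  # TAA TAG AGA AGG

DEFAULT_LOCALITY_POOL = ("NIT", "CIT", "SIT", "SAR")


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MTMotuPair:
    """One ancestral gene pool labelled as two nominal species."""

    species_index: int = 0


@dataclass(frozen=True)
class IotuSplit:
    """Divergent lineages with disjoint locality groups."""

    species_index: int = 0
    n_lineages: int = 2
    lineage_divergence: float = 0.06   # subst/site between sub-ancestors
    localities: tuple[tuple[str, ...], ...] = (("NIT",), ("CIT", "SIT"))


@dataclass(frozen=True)
class UcsSplit:
    """Divergent lineages whose localities overlap (molecular evidence only)."""

    species_index: int = 0
    n_lineages: int = 2
    lineage_divergence: float = 0.025
    localities: tuple[str, ...] = ("NIT", "CIT")  # shared by all lineages


Scenario = MTMotuPair | IotuSplit | UcsSplit


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: ~30 species, 1-22 samples each, 556-bp coding
    alignment, low (~1%) intraspecific and high (~20%) interspecific
    divergence, mammalian-mtDNA-like kappa."""

    n_species: int = 30
    samples_per_species: tuple[int, int] = (1, 22)
    sequence_length: int = 556
    kappa: float = 4.0
    intra_divergence: float = 0.01
    inter_divergence: float = 0.20
    scenarios: tuple[Scenario, ...] = ()
    locality_pool: tuple[str, ...] = DEFAULT_LOCALITY_POOL
    species_tree: str = "star"   # or "coalescent"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intra_divergence < self.inter_divergence:
            raise ValueError("need 0 <= intra_divergence < inter_divergence")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.samples_per_species[0] < 1 or \
                self.samples_per_species[0] > self.samples_per_species[1]:
            raise ValueError("invalid samples_per_species range")
        for sc in self.scenarios:
            if not 0 <= sc.species_index < self.n_species:
                raise ValueError(f"scenario species_index out of range: {sc}")


@dataclass(frozen=True)
class GroundTruth:
    """True species, lineage and locality per sample; expected rank per species."""

    sample_species: dict[str, str]
    sample_lineage: dict[str, str]
    sample_locality: dict[str, str]
    expected_rank: dict[str, str]    # nominal species -> rank


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: BarcodeAlignment
    truth: GroundTruth
    config: SimulationConfig

    def write(self, fasta_path: str | Path, metadata_path: str | Path) -> None:
        write_fasta(self.alignment.records, fasta_path)
        pd.DataFrame(
            {
                "sample_id": self.alignment.sample_ids,
                "species_label": self.alignment.species_labels,
                "locality_group": [
                    l or "" for l in self.alignment.locality_groups
                ],
            }
        ).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequence evolution under the K2P process
# ---------------------------------------------------------------------------

def _substitution_probs(branch_length: float, kappa: float) -> tuple[float, float, float]:
    """(stay, transition, each transversion) probabilities after t subst/site.

    Rates are normalised so the total substitution rate is 1: transition
    rate alpha = kappa/(kappa+2), each transversion beta = 1/(kappa+2).
    """
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    t = branch_length
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * e1                 # each of the two transversions
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_stay = 1.0 - p_ts - 2.0 * p_tv
    return p_stay, p_ts, p_tv


def evolve_encoded(
    ancestor: np.ndarray, branch_length: float, kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a 0..3-encoded sequence for ``branch_length`` expected subst/site."""
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    p_stay, p_ts, p_tv = _substitution_probs(branch_length, kappa)
    u = rng.random(ancestor.shape[0])
    out = ancestor.copy()
    ts_mask = (u >= p_stay) & (u < p_stay + p_ts)
    tv1_mask = (u >= p_stay + p_ts) & (u < p_stay + p_ts + p_tv)
    tv2_mask = u >= p_stay + p_ts + p_tv
    out[ts_mask] = _TS_PARTNER[ancestor[ts_mask]]
    out[tv1_mask] = _TV_PARTNERS[ancestor[tv1_mask], 0]
    out[tv2_mask] = _TV_PARTNERS[ancestor[tv2_mask], 1]
    return out


def evolve_encoded_fixed_events(
    ancestor: np.ndarray, n_events: int, kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve with exactly ``n_events`` substitution events (jump chain).

    Under the K2P process every site carries the same total rate, so the
    embedded jump chain places events uniformly over sites; each event is a
    transition with probability kappa/(kappa+2), otherwise one of the two
    transversions.  Conditioning on the event count makes a configured
    branch divergence exact rather than Poisson-distributed — used for the
    lineage-defining branches of scenario injections, whose divergence IS
    the ground truth.
    """
    out = ancestor.copy()
    length = out.shape[0]
    p_ts = kappa / (kappa + 2.0)
    for _ in range(n_events):
        site = int(rng.integers(0, length))
        u = rng.random()
        base = out[site]
        if u < p_ts:
            out[site] = _TS_PARTNER[base]
        elif u < p_ts + (1.0 - p_ts) / 2.0:
            out[site] = _TV_PARTNERS[base, 0]
        else:
            out[site] = _TV_PARTNERS[base, 1]
    return out


def evolve_sequence(
    ancestor: str, branch_length: float, kappa: float = 4.0,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Evolve an A/C/G/T string under the K2P process (uniform stationary
    base frequencies, transition:transversion rate ratio kappa per
    transversion type).  Reproducible given a seed."""
    enc = np.array([_BASES.index(b) if b in _BASES else -1
                    for b in ancestor.upper()], dtype=int)
    if (enc < 0).any():
        bad = sorted({b for b in ancestor.upper() if b not in _BASES})
        raise ValueError(f"ancestor contains non-ACGT characters: {bad}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    evolved = evolve_encoded(enc.astype(np.intp), branch_length, kappa, rng)
    return "".join(_BASES[i] for i in evolved)


def _scrub_stops(
    seq: np.ndarray, ancestor: np.ndarray | None, branch_length: float,
    kappa: float, rng: np.random.Generator,
) -> np.ndarray:
    """Re-draw frame-0 stop codons until none remain.

    Only complete codons are considered; 1-2 trailing bases of an alignment
    whose length is not a codon multiple (e.g. 556 bp) are unconstrained.
    Root sequences (no ancestor) get fresh uniform codons; evolved sequences
    re-evolve the offending codon from its ancestral codon (rejection
    sampling conditional on a coding sequence).
    """
    seq = seq.copy()
    n_codons = seq.shape[0] // 3
    for _ in range(1000):
        stops = [
            k for k in range(n_codons)
            if tuple(seq[3 * k : 3 * k + 3]) in _STOP_CODONS
        ]
        if not stops:
            return seq
        for k in stops:
            sl = slice(3 * k, 3 * k + 3)
            if ancestor is None:
                seq[sl] = rng.integers(0, 4, size=3)
            else:
                seq[sl] = evolve_encoded(
                    ancestor[sl], branch_length, kappa, rng
                )
    raise RuntimeError("could not obtain a stop-free coding sequence")


def _random_coding_root(length: int, rng: np.random.Generator) -> np.ndarray:
    root = rng.integers(0, 4, size=length).astype(np.intp)
    return _scrub_stops(root, None, 0.0, 1.0, rng)


def _evolve_coding(
    ancestor: np.ndarray, branch_length: float, kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    child = evolve_encoded(ancestor, branch_length, kappa, rng)
    return _scrub_stops(child, ancestor, branch_length, kappa, rng)


def _evolve_coding_fixed(
    ancestor: np.ndarray, branch_length: float, kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Coding, stop-free branch with its substitution count fixed to the
    expectation round(L * t); the whole branch is redrawn on a stop codon so
    the count stays exact."""
    n_events = int(round(ancestor.shape[0] * branch_length))
    n_codons = ancestor.shape[0] // 3
    for _ in range(1000):
        child = evolve_encoded_fixed_events(ancestor, n_events, kappa, rng)
        if not any(
            tuple(child[3 * k : 3 * k + 3]) in _STOP_CODONS
            for k in range(n_codons)
        ):
            return child
    raise RuntimeError("could not obtain a stop-free coding sequence")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[i] for i in seq)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a labelled, coding, stop-free barcode dataset.

    Species ancestors are evolved from a common root by inter_divergence/2
    each (star phylogeny: every ancestor pair sits inter_divergence apart in
    expectation); samples evolve from their ancestor by intra_divergence/2.
    Scenario injections restructure individual species as documented in the
    scenario classes.  Byte-identical output for equal config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    root = _random_coding_root(config.sequence_length, rng)

    scenario_by_species: dict[int, Scenario] = {}
    for sc in config.scenarios:
        if sc.species_index in scenario_by_species:
            raise ValueError(
                f"multiple scenarios target species {sc.species_index}"
            )
        scenario_by_species[sc.species_index] = sc

    half_inter = config.inter_divergence / 2.0
    half_intra = config.intra_divergence / 2.0
    lo, hi = config.samples_per_species

    records: list[BarcodeRecord] = []
    sample_species: dict[str, str] = {}
    sample_lineage: dict[str, str] = {}
    sample_locality: dict[str, str] = {}
    expected_rank: dict[str, str] = {}
    counter = 0

    if config.species_tree == "star":
        depths = [half_inter] * config.n_species
    elif config.species_tree == "coalescent":
        # exchangeable random depths around the star expectation
        depths = list(half_inter * (0.5 + rng.random(config.n_species)))
    else:
        raise ValueError(f"unknown species_tree {config.species_tree!r}")

    for s in range(config.n_species):
        ancestor = _evolve_coding(root, depths[s], config.kappa, rng)
        species_name = f"Species_{s + 1:02d}"
        scenario = scenario_by_species.get(s)
        n_samples = int(rng.integers(lo, hi + 1))

        if isinstance(scenario, MTMotuPair):
            # one gene pool, two nominal labels
            names = (f"{species_name}a", f"{species_name}b")
            n_samples = max(n_samples, 4)
            for name in names:
                expected_rank[name] = "MT_MOTU"
            for k in range(n_samples):
                counter += 1
                sid = f"S{counter:04d}"
                seq = _evolve_coding(ancestor, half_intra, config.kappa, rng)
                label = names[k % 2]
                loc = str(rng.choice(config.locality_pool))
                records.append(BarcodeRecord(sid, _decode(seq), label, loc))
                sample_species[sid] = label
                sample_lineage[sid] = f"{species_name}/L1"
                sample_locality[sid] = loc
        elif isinstance(scenario, (IotuSplit, UcsSplit)):
            n_lin = scenario.n_lineages
            per_lineage = max(2, math.ceil(max(n_samples, 2 * n_lin) / n_lin))
            half_split = scenario.lineage_divergence / 2.0
            expected_rank[species_name] = (
                "IOTU" if isinstance(scenario, IotuSplit) else "UCS"
            )
            if isinstance(scenario, IotuSplit):
                if len(scenario.localities) != n_lin:
                    raise ValueError(
                        "IotuSplit needs one locality tuple per lineage"
                    )
                sets = [set(a) for a in scenario.localities]
                for i, a in enumerate(sets):
                    for b in sets[i + 1 :]:
                        if a & b:
                            raise ValueError(
                                "IotuSplit locality sets must be disjoint"
                            )
                lineage_locs = list(scenario.localities)
            else:
                lineage_locs = [tuple(scenario.localities)] * n_lin
            for li in range(n_lin):
                # lineage-defining branch: substitution count fixed to its
                # expectation so the injected divergence is realised, not
                # merely expected (the split IS the ground truth)
                sub_ancestor = _evolve_coding_fixed(
                    ancestor, half_split, config.kappa, rng
                )
                for k in range(per_lineage):
                    counter += 1
                    sid = f"S{counter:04d}"
                    seq = _evolve_coding(
                        sub_ancestor, half_intra, config.kappa, rng
                    )
                    if isinstance(scenario, UcsSplit):
                        # sympatric lineages: cycle the shared localities so
                        # every lineage realises the whole overlapping set
                        loc = lineage_locs[li][k % len(lineage_locs[li])]
                    else:
                        loc = str(rng.choice(lineage_locs[li]))
                    records.append(
                        BarcodeRecord(sid, _decode(seq), species_name, loc)
                    )
                    sample_species[sid] = species_name
                    sample_lineage[sid] = f"{species_name}/L{li + 1}"
                    sample_locality[sid] = loc
        else:
            expected_rank[species_name] = "SPECIES_MATCH"
            for _ in range(n_samples):
                counter += 1
                sid = f"S{counter:04d}"
                seq = _evolve_coding(ancestor, half_intra, config.kappa, rng)
                loc = str(rng.choice(config.locality_pool))
                records.append(
                    BarcodeRecord(sid, _decode(seq), species_name, loc)
                )
                sample_species[sid] = species_name
                sample_lineage[sid] = f"{species_name}/L1"
                sample_locality[sid] = loc

    alignment = BarcodeAlignment(tuple(records))
    truth = GroundTruth(
        sample_species=sample_species,
        sample_lineage=sample_lineage,
        sample_locality=sample_locality,
        expected_rank=expected_rank,
    )
    return SimulatedDataset(alignment=alignment, truth=truth, config=config)


def relabel_unknown(
    dataset: SimulatedDataset, fraction: float, seed: int
) -> SimulatedDataset:
    """Blank the species label of a random sample fraction (query simulation).

    Ground truth keeps the original labels, so identification accuracy can
    be scored.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(dataset.alignment)
    k = max(1, int(round(fraction * n)))
    hide = set(rng.choice(n, size=k, replace=False).tolist())
    new_records = tuple(
        replace(rec, species_label=UNKNOWN) if i in hide else rec
        for i, rec in enumerate(dataset.alignment.records)
    )
    return SimulatedDataset(
        alignment=BarcodeAlignment(new_records),
        truth=dataset.truth,
        config=dataset.config,
    )
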