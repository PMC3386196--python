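"""Molecular entities at the optimum threshold, taxonomic ranks, identification.

Entities are the single-linkage connected components of the sample graph at
the optimum threshold (OT): two samples join whenever their K2P distance is
below OT.  Each entity then receives one rank:

* SPECIES_MATCH — one entity, one nominal species, no divergent structure;
* MT_MOTU — an entity fusing two or more nominal species (the marker cannot
  separate them);
* IOTU — a divergent molecular lineage corroborated by at least one
  additional congruent character, here geography: the lineage's locality
  groups are disjoint from every sibling lineage of the same species;
* UCS — a divergent lineage with molecular support only (localities overlap
  or are unavailable);
* MOTU_UNLABELLED — an entity made solely of samples with no species label
  (only produced when unlabelled samples are explicitly admitted).

DCL and CCS ranks exist as labels for manual override — they require
morphological or formal-description evidence outside this data model — and
are never auto-assigned.

Unknown queries are identified against a labelled reference set: a query is
assigned to the species with the smallest minimum distance when that
distance is below OT and the runner-up species is at least ``tie_margin``
further away; otherwise AMBIGUOUS (two species close below OT) or
UNASSIGNED (nothing below OT).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, cross_distances
from .seq_qc import UNKNOWN, BarcodeAlignment
from .trees import LineageSet, detect_lineages, single_linkage_components

RANKS = (
    "SPECIES_MATCH",
    "MT_MOTU",
    "UCS",
    "IOTU",
    "MOTU_UNLABELLED",
    "DCL",   # manual override only
    "CCS",   # manual override only
)

# evidence codes
DIVERGENCE_GT_OT = "DIVERGENCE_GT_OT"
DIVERGENCE_2_TO_5 = "DIVERGENCE_2_TO_5"
DIVERGENCE_GT_5 = "DIVERGENCE_GT_5"
GEOGRAPHY_CONGRUENT = "GEOGRAPHY_CONGRUENT"
MULTIPLE_NOMINAL_SPECIES = "MULTIPLE_NOMINAL_SPECIES"

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class TaxonomicEntity:
    entity_id: str
    sample_ids: tuple[str, ...]
    species: frozenset[str]
    rank: str
    evidence: tuple[str, ...] = ()
    mean_internal_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.rank == "MT_MOTU" and len(self.species) < 2:
            raise ValueError("MT_MOTU requires >= 2 nominal species")
        molecular = {DIVERGENCE_GT_OT, DIVERGENCE_2_TO_5, DIVERGENCE_GT_5}
        if self.rank == "IOTU" and not set(self.evidence) - molecular:
            raise ValueError(
                "IOTU requires at least one non-molecular evidence code"
            )


@dataclass(frozen=True)
class AssignmentResult:
    sample_id: str
    assigned: str            # species name, UNASSIGNED or AMBIGUOUS
    min_distance_pct: Mapping[str, float]  # per candidate species
    threshold_pct: float

    @property
    def best_species(self) -> str | None:
        if not self.min_distance_pct:
            return None
        return min(self.min_distance_pct, key=lambda s: self.min_distance_pct[s])


# ---------------------------------------------------------------------------
# Entity partition
# ---------------------------------------------------------------------------

def partition_entities(matrix: DistanceMatrix, ot_pct: float) -> list[list[str]]:
    """Single-linkage components joining samples with K2P distance < OT (%)."""
    if ot_pct <= 0:
        raise ValueError("OT must be positive")
    comps = single_linkage_components(matrix.values * 100.0, ot_pct)
    return [[matrix.labels[i] for i in comp] for comp in comps]


def _mean_internal_pct(matrix: DistanceMatrix, members: Sequence[str]) -> float:
    idx = [matrix.index_of(m) for m in members]
    if len(idx) < 2:
        return float("nan")
    iu, ju = np.triu_indices(len(idx), k=1)
    vals = matrix.values[np.ix_(idx, idx)][iu, ju] * 100.0
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


# ---------------------------------------------------------------------------
# Rank assignment
# ---------------------------------------------------------------------------

def _divergence_evidence(means: Sequence[float], ucs_low: float, cryptic: float) -> str:
    if all(m <= cryptic for m in means):
        return DIVERGENCE_2_TO_5
    return DIVERGENCE_GT_5


def assign_ranks(
    partition: Sequence[Sequence[str]],
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    locality_groups: Sequence[str | None],
    ot_pct: float,
    ucs_low_pct: float = 2.0,
    cryptic_pct: float = 5.0,
    lineages: LineageSet | None = None,
    allow_unlabelled: bool = False,
) -> list[TaxonomicEntity]:
    """Assign one taxonomic rank to every entity of the OT partition.

    Rules, in order of precedence per entity:

    1. two or more nominal species fused -> MT_MOTU;
    2. the entity's species also occurs in other entities (a species split
       at the OT): IOTU when the entity's locality-group set is disjoint
       from every sibling entity of that species, else UCS;
    3. a single-species entity holding two or more internal lineages (at
       ``ucs_low_pct``, from the lineage detector): IOTU when the lineages'
       locality sets are pairwise disjoint (geography corroborates the
       molecular split), else UCS;
    4. otherwise SPECIES_MATCH.

    Samples labelled UNKNOWN must be identified first (or explicitly
    admitted with ``allow_unlabelled``, which ranks all-unlabelled entities
    MOTU_UNLABELLED).
    """
    if not 0 < ucs_low_pct < cryptic_pct:
        raise ValueError("need 0 < ucs_low_pct < cryptic_pct")
    label_of = dict(zip(matrix.labels, species_labels))
    locality_of = dict(zip(matrix.labels, locality_groups))
    unknown = [s for comp in partition for s in comp if label_of[s] == UNKNOWN]
    if unknown and not allow_unlabelled:
        raise ValueError(
            f"unknown-labelled samples present (route through identify_queries "
            f"first): {unknown[:5]}"
        )
    if lineages is None:
        lineages = detect_lineages(
            matrix, species_labels, locality_groups,
            min_divergence_pct=ucs_low_pct,
        )

    # which entities carry each species (for the split rule)
    entities_of_species: dict[str, list[int]] = {}
    for e_idx, comp in enumerate(partition):
        for sp in {label_of[s] for s in comp}:
            entities_of_species.setdefault(sp, []).append(e_idx)

    def locality_set(members: Sequence[str]) -> set[str]:
        return {locality_of[s] for s in members if locality_of[s] is not None}

    out: list[TaxonomicEntity] = []
    for e_idx, comp in enumerate(partition):
        species = frozenset(label_of[s] for s in comp)
        known_species = species - {UNKNOWN}
        mean_internal = _mean_internal_pct(matrix, comp)
        entity_id = f"E{e_idx + 1:03d}"

        if not known_species:
            rank, evidence = "MOTU_UNLABELLED", ()
        elif len(known_species) >= 2:
            rank, evidence = "MT_MOTU", (MULTIPLE_NOMINAL_SPECIES,)
        else:
            (sp,) = known_species
            siblings = [k for k in entities_of_species[sp] if k != e_idx]
            if siblings:
                # species split across entities: divergence exceeds the OT
                mine = locality_set(comp)
                disjoint = all(
                    not (mine & locality_set(partition[k])) for k in siblings
                ) and bool(mine)
                if disjoint:
                    rank = "IOTU"
                    evidence = (DIVERGENCE_GT_OT, GEOGRAPHY_CONGRUENT)
                else:
                    rank, evidence = "UCS", (DIVERGENCE_GT_OT,)
            else:
                sp_lineages = lineages.by_species.get(sp)
                local = None
                if sp_lineages is not None and sp_lineages.flagged:
                    member_set = set(comp)
                    local = [
                        l for l in sp_lineages.lineages
                        if member_set & set(l.sample_ids)
                    ]
                if local and len(local) >= 2:
                    sets = [set(l.locality_profile) for l in local]
                    disjoint = all(s for s in sets) and all(
                        not (a & b)
                        for i, a in enumerate(sets)
                        for b in sets[i + 1 :]
                    )
                    means = [
                        m for pair, m in sp_lineages.between_means_pct.items()
                    ]
                    div_code = _divergence_evidence(means, ucs_low_pct, cryptic_pct)
                    if disjoint:
                        rank = "IOTU"
                        evidence = (div_code, GEOGRAPHY_CONGRUENT)
                    else:
                        rank, evidence = "UCS", (div_code,)
                else:
                    rank, evidence = "SPECIES_MATCH", ()
        out.append(
            TaxonomicEntity(
                entity_id=entity_id,
                sample_ids=tuple(comp),
                species=species,
                rank=rank,
                evidence=evidence,
                mean_internal_pct=mean_internal,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Query identification
# ---------------------------------------------------------------------------

def identify_queries(
    query_alignment: BarcodeAlignment,
    reference_alignment: BarcodeAlignment,
    ot_pct: float,
    tie_margin_pct: float = 0.3,
) -> list[AssignmentResult]:
    """Assign unknown queries to reference species by minimum K2P distance.

    Reference species labels are taken from the reference alignment records.
    """
    ref_species = np.asarray(reference_alignment.species_labels)
    if UNKNOWN in set(ref_species):
        raise ValueError("reference alignment must not contain UNKNOWN labels")
    dist = cross_distances(query_alignment, reference_alignment) * 100.0
    species = sorted(set(ref_species))
    results = []
    for qi, rec in enumerate(query_alignment.records):
        mins: dict[str, float] = {}
        for sp in species:
            vals = dist[qi, ref_species == sp]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                mins[sp] = float(vals.min())
        below = sorted(
            (d, sp) for sp, d in mins.items() if d < ot_pct
        )
        if not below:
            assigned = UNASSIGNED
        elif len(below) >= 2 and below[1][0] - below[0][0] < tie_margin_pct:
            assigned = AMBIGUOUS
        else:
            assigned = below[0][1]
        results.append(
            AssignmentResult(
                sample_id=rec.sample_id,
                assigned=assigned,
                min_distance_pct=mins,
                threshold_pct=ot_pct,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def entity_report(
    entities: Sequence[TaxonomicEntity], path: str | Path
) -> pd.DataFrame:
    """Write one row per entity (id, rank, members, species, evidence) as TSV."""
    if not entities:
        raise ValueError("no entities to report")
    frame = pd.DataFrame(
        {
            "entity_id": [e.entity_id for e in entities],
            "rank": [e.rank for e in entities],
            "n_samples": [len(e.sample_ids) for e in entities],
            "species": [";".join(sorted(e.species)) for e in entities],
            "sample_ids": [";".join(e.sample_ids) for e in entities],
            "evidence": [";".join(e.evidence) for e in entities],
            "mean_internal_pct": [e.mean_internal_pct for e in entities],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return frame


def read_entity_report(path: str | Path) -> list[TaxonomicEntity]:
    frame = pd.read_csv(path, sep="\t", dtype={"evidence": str}).fillna("")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            TaxonomicEntity(
                entity_id=row.entity_id,
                sample_ids=tuple(str(row.sample_ids).split(";")),
                species=frozenset(str(row.species).split(";")),
                rank=row.rank,
                evidence=tuple(e for e in str(row.evidence).split(";") if e),
                mean_internal_pct=float(row.mean_internal_pct)
                if row.mean_internal_pct != "" else float("nan"),
            )
        )
    return out


def assignment_report(
    results: Sequence[AssignmentResult], path: str | Path
) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "assigned": [r.assigned for r in results],
            "best_species": [r.best_species for r in results],
            "best_distance_pct": [
                r.min_distance_pct.get(r.best_species, float("nan"))
                if r.best_species else float("nan")
                for r in results
            ],
            "threshold_pct": [r.threshold_pct for r in results],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return frame
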