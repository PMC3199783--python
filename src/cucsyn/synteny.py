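"""Transitive chromosome assignment and syntenic-block inference.

Source-map loci (e.g. a 12-chromosome consensus genetic map) are tied to
target-genome chromosomes either directly (the marker is on the target
reference map) or transitively through the scaffold their virtual-PCR
product lands on: the scaffold's previously mapped markers vote on a
chromosome, and the marker inherits their median position.  Syntenic blocks
are maximal same-target runs along each source chromosome, with a small
discordant-gap tolerance; block colinearity is summarized with Kendall tau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vpcr import MULTI_COPY, NO_HIT, REPEAT_REGION, UNIQUE, ScaffoldHit

logger = logging.getLogger(__name__)

DIRECT = "direct_map"
TRANSITIVE = "scaffold_transitive"

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNANCHORED = "unanchored"

COLINEAR = "colinear"
INVERTED = "inverted"
REARRANGED = "rearranged"
UNDETERMINED = "undetermined"


@dataclass
class ReferenceMap:
    """Target-genome reference map: marker -> (chromosome, cM, scaffold)."""

    table: pd.DataFrame  # columns: marker_id, chromosome, position_cM, scaffold

    def __post_init__(self) -> None:
        need = {"marker_id", "chromosome", "position_cM", "scaffold"}
        if not need <= set(self.table.columns):
            raise ValueError(f"reference map needs columns {sorted(need)}")
        self.table = self.table.reset_index(drop=True)
        self._by_marker = self.table.set_index("marker_id")
        self._by_scaffold = {
            sid: grp for sid, grp in self.table.groupby("scaffold")
        }

    def lookup(self, marker_id: str):
        if marker_id in self._by_marker.index:
            row = self._by_marker.loc[marker_id]
            return str(row["chromosome"]), float(row["position_cM"])
        return None

    def scaffold_markers(self, scaffold: str) -> pd.DataFrame:
        return self._by_scaffold.get(
            scaffold, self.table.iloc[0:0]
        )


@dataclass
class AnchoredMarker:
    marker_id: str
    source_chromosome: str
    source_cM: float
    status: str  # assigned | ambiguous | unanchored
    target_chromosome: str | None = None
    target_cM: float | None = None
    evidence: str | None = None  # direct_map | scaffold_transitive
    reason: str = ""


@dataclass
class SyntenicBlock:
    source_chromosome: str
    target_chromosome: str
    start_cM: float
    end_cM: float
    members: list[AnchoredMarker] = field(default_factory=list)
    discordant: list[AnchoredMarker] = field(default_factory=list)
    tau: float | None = None
    arrangement: str = UNDETERMINED

    @property
    def n_markers(self) -> int:
        return len(self.members)


def assign_chromosome(
    marker_id: str,
    source_chromosome: str,
    source_cm: float,
    classification: str,
    hits: list[ScaffoldHit],
    reference_map: ReferenceMap,
    majority: float = 2.0 / 3.0,
) -> AnchoredMarker:
    """Assign one source-map marker to a target chromosome.

    Markers on the reference map take their mapped location (direct
    evidence).  Otherwise a unique scaffold hit is assigned to the
    chromosome carried by a >= 2/3 majority of the scaffold's reference
    markers, at their median cM; split scaffolds are ambiguous and empty
    scaffolds unanchored.
    """
    direct = reference_map.lookup(marker_id)
    if direct is not None:
        chrom, pos = direct
        return AnchoredMarker(marker_id, source_chromosome, source_cm,
                              ASSIGNED, chrom, pos, DIRECT)
    if classification in (NO_HIT, MULTI_COPY, REPEAT_REGION):
        return AnchoredMarker(marker_id, source_chromosome, source_cm,
                              UNANCHORED, reason=classification)
    if classification != UNIQUE or not hits:
        return AnchoredMarker(marker_id, source_chromosome, source_cm,
                              UNANCHORED, reason="unclassified")
    scaffold = hits[0].scaffold
    refs = reference_map.scaffold_markers(scaffold)
    if len(refs) == 0:
        return AnchoredMarker(marker_id, source_chromosome, source_cm,
                              UNANCHORED, reason="scaffold without mapped markers")
    counts = refs["chromosome"].value_counts()
    top_chrom = counts.index[0]
    if len(counts) > 1 and counts.iloc[0] / counts.sum() < majority:
        return AnchoredMarker(marker_id, source_chromosome, source_cm,
                              AMBIGUOUS, reason="scaffold spans chromosomes")
    pos = float(refs.loc[refs["chromosome"] == top_chrom, "position_cM"].median())
    return AnchoredMarker(marker_id, source_chromosome, source_cm,
                          ASSIGNED, str(top_chrom), pos, TRANSITIVE)


# ---------------------------------------------------------------------------
# block segmentation
# ---------------------------------------------------------------------------

def detect_blocks(
    anchored: list[AnchoredMarker],
    min_block_markers: int = 2,
    max_gap_markers: int = 1,
) -> tuple[list[SyntenicBlock], list[AnchoredMarker]]:
    """Segment one source chromosome into maximal same-target runs.

    ``anchored`` must be sorted by source cM; unanchored/ambiguous loci are
    transparent (skipped).  A run may absorb up to ``max_gap_markers``
    interleaved discordant loci in total, and only between members (a run
    starts and ends on its own target); absorbed loci are noted, not
    members.  The sequence is partitioned into the minimal number of such
    runs (dynamic program; ties broken by preferring the longest leftmost
    run).  Runs with fewer than ``min_block_markers`` members are returned
    as singletons.
    """
    loci = [a for a in anchored if a.status == ASSIGNED]
    if not loci:
        return [], []
    n = len(loci)
    targets = [a.target_chromosome for a in loci]

    # ends[i]: all j >= i such that loci[i..j] is a valid run
    ends: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        bad = 0
        for j in range(i, n):
            if targets[j] != targets[i]:
                bad += 1
                if bad > max_gap_markers:
                    break
            else:
                ends[i].append(j)

    best = [0] * (n + 1)   # minimal number of runs covering loci[i:]
    choice = [0] * n
    for i in range(n - 1, -1, -1):
        options = [(1 + best[j + 1], -(j - i), j) for j in ends[i]]
        best[i], _, choice[i] = min(options)

    runs: list[tuple[list[AnchoredMarker], list[AnchoredMarker]]] = []
    i = 0
    while i < n:
        j = choice[i]
        seg = loci[i : j + 1]
        members = [a for a in seg if a.target_chromosome == targets[i]]
        absorbed = [a for a in seg if a.target_chromosome != targets[i]]
        runs.append((members, absorbed))
        i = j + 1

    blocks: list[SyntenicBlock] = []
    singletons: list[AnchoredMarker] = []
    for members, absorbed in runs:
        if len(members) < min_block_markers:
            singletons.extend(members)
            continue
        block = SyntenicBlock(
            source_chromosome=members[0].source_chromosome,
            target_chromosome=members[0].target_chromosome,
            start_cM=members[0].source_cM,
            end_cM=members[-1].source_cM,
            members=members,
            discordant=absorbed,
        )
        block.tau, block.arrangement = colinearity(
            [(m.source_cM, m.target_cM) for m in members]
        )
        blocks.append(block)
    return blocks, singletons


def colinearity(pairs: list[tuple[float, float]],
                cutoff: float = 0.8) -> tuple[float | None, str]:
    """Kendall tau between source and target positions, with a class label.

    colinear if tau >= cutoff, inverted if tau <= -cutoff, rearranged
    otherwise; fewer than 3 positioned members -> undetermined.
    """
    pairs = [(s, t) for s, t in pairs if t is not None]
    if len(pairs) < 3:
        return None, UNDETERMINED
    src = [s for s, _ in pairs]
    tgt = [t for _, t in pairs]
    tau = float(stats.kendalltau(src, tgt).statistic)
    if np.isnan(tau):
        return None, UNDETERMINED
    if tau >= cutoff:
        return tau, COLINEAR
    if tau <= -cutoff:
        return tau, INVERTED
    return tau, REARRANGED


# ---------------------------------------------------------------------------
# correspondence and views
# ---------------------------------------------------------------------------

def correspondence_table(blocks: list[SyntenicBlock]) -> pd.DataFrame:
    """Chromosome partner sets in both directions from one block list.

    One row per chromosome of either genome: direction ('source->target' or
    'target->source'), the ordered partner set, and supporting marker
    counts.  Both directions are derived from the same blocks, so the
    partner relation is symmetric by construction.
    """
    rows = []
    by_source: dict[str, dict[str, int]] = {}
    by_target: dict[str, dict[str, int]] = {}
    for b in blocks:
        by_source.setdefault(b.source_chromosome, {})
        by_source[b.source_chromosome][b.target_chromosome] = (
            by_source[b.source_chromosome].get(b.target_chromosome, 0) + b.n_markers
        )
        by_target.setdefault(b.target_chromosome, {})
        by_target[b.target_chromosome][b.source_chromosome] = (
            by_target[b.target_chromosome].get(b.source_chromosome, 0) + b.n_markers
        )
    for chrom in sorted(by_source):
        partners = sorted(by_source[chrom])
        rows.append({
            "direction": "source->target",
            "chromosome": chrom,
            "partners": ",".join(partners),
            "n_markers": ",".join(str(by_source[chrom][p]) for p in partners),
        })
    for chrom in sorted(by_target):
        partners = sorted(by_target[chrom])
        rows.append({
            "direction": "target->source",
            "chromosome": chrom,
            "partners": ",".join(partners),
            "n_markers": ",".join(str(by_target[chrom][p]) for p in partners),
        })
    return pd.DataFrame(rows, columns=["direction", "chromosome",
                                       "partners", "n_markers"])


def partner_sets(blocks: list[SyntenicBlock],
                 direction: str = "source->target") -> dict[str, set[str]]:
    """Convenience: chromosome -> set of partner chromosomes."""
    out: dict[str, set[str]] = {}
    for b in blocks:
        a, b_ = ((b.source_chromosome, b.target_chromosome)
                 if direction == "source->target"
                 else (b.target_chromosome, b.source_chromosome))
        out.setdefault(a, set()).add(b_)
    return out


def block_views(blocks: list[SyntenicBlock]) -> pd.DataFrame:
    """Stacked-segment descriptions of both genomes for plotting/export.

    For the source view, segments follow block order along each source
    chromosome; for the target view, blocks on a target chromosome are
    ordered by the median target cM of their members.  Segment length is the
    member count (chromosomes drawn proportional to marker loci).
    """
    rows = []
    by_source: dict[str, list[SyntenicBlock]] = {}
    for b in blocks:
        by_source.setdefault(b.source_chromosome, []).append(b)
    for chrom in sorted(by_source):
        ordered = sorted(by_source[chrom], key=lambda b: b.start_cM)
        for i, b in enumerate(ordered):
            rows.append({
                "view": "source", "chromosome": chrom, "segment": i + 1,
                "partner": b.target_chromosome, "n_markers": b.n_markers,
                "span_cM": round(b.end_cM - b.start_cM, 1),
            })
    by_target: dict[str, list[SyntenicBlock]] = {}
    for b in blocks:
        by_target.setdefault(b.target_chromosome, []).append(b)
    for chrom in sorted(by_target):
        ordered = sorted(
            by_target[chrom],
            key=lambda b: float(np.median([m.target_cM for m in b.members])),
        )
        for i, b in enumerate(ordered):
            rows.append({
                "view": "target", "chromosome": chrom, "segment": i + 1,
                "partner": b.source_chromosome, "n_markers": b.n_markers,
                "span_cM": round(b.end_cM - b.start_cM, 1),
            })
    return pd.DataFrame(rows, columns=["view", "chromosome", "segment",
                                       "partner", "n_markers", "span_cM"])
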