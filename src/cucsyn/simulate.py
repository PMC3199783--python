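"""Ground-truthed synthetic inputs for the comparative-mapping pipeline.

The generator emulates the study system: an ancestral genome with twelve
chromosomes carrying a panel of codominant markers (each with a planted
primer pair and amplicon), a descendant genome with seven chromosomes
produced by chromosome fusions (alternating, side-by-side, nested,
three-way), inversions and optional translocations, fragmentation of the
descendant into draft scaffolds, a partial reference genetic map of the
descendant, and F2 / F8-RIL meioses over the ancestral map.  Every output
is traceable to the planted truth (segments, correspondence, marker
locations), and everything is reproducible under a stated seed.

Chromosome naming follows the field convention for this system: Roman
numerals I-XII for the 12-chromosome genome, Arabic 1-7 for the
7-chromosome genome.  Default chromosome lengths and marker counts per
chromosome reproduce the consensus-map scale of the study (401 loci,
1,029 cM over 12 groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .linkage import GenotypeMatrix, PopulationType
from .vpcr import revcomp

logger = logging.getLogger(__name__)

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]

# consensus-map scale: per-chromosome cM lengths and locus counts
DEFAULT_LENGTHS_CM = {
    "I": 107.3, "II": 105.7, "III": 81.8, "IV": 116.9, "V": 58.2, "VI": 64.4,
    "VII": 108.0, "VIII": 87.2, "IX": 71.9, "X": 62.5, "XI": 87.4, "XII": 77.6,
}
DEFAULT_LOCI = {
    "I": 38, "II": 33, "III": 24, "IV": 50, "V": 28, "VI": 25,
    "VII": 41, "VIII": 39, "IX": 27, "X": 30, "XI": 43, "XII": 23,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SimMarker:
    id: str
    chrom: str          # ancestral chromosome
    pos_cM: float       # ancestral genetic position
    pos_bp: int         # ancestral physical position (amplicon start, 0-based)
    primer_fwd: str
    primer_rev: str
    amplicon_size: int


@dataclass
class AncestralGenome:
    chrom_names: list[str]
    lengths_cM: dict[str, float]
    sequences: dict[str, str]
    markers: list[SimMarker]
    bp_per_cM: float

    def markers_on(self, chrom: str) -> list[SimMarker]:
        return sorted((m for m in self.markers if m.chrom == chrom),
                      key=lambda m: m.pos_bp)


@dataclass
class SegmentSpec:
    """A fraction interval of an ancestral chromosome, optionally inverted."""

    source: str
    f0: float
    f1: float
    inverted: bool = False


@dataclass
class Fusion:
    kind: str  # intact | side_by_side | alternating | nested | three_way
    result: str
    segments: list[SegmentSpec]


@dataclass
class Inversion:
    chromosome: str  # derived chromosome name
    f0: float
    f1: float


@dataclass
class Translocation:
    """Move a fraction interval of an ancestral chromosome into a derived one."""

    source: str
    f0: float
    f1: float
    dest: str       # derived chromosome
    at_index: int   # segment index in the destination's segment list


@dataclass
class RearrangementScenario:
    events: list  # Fusion / Inversion / Translocation, applied in order

    def fusions(self) -> list[Fusion]:
        return [e for e in self.events if isinstance(e, Fusion)]


def fusion_intact(result: str, source: str) -> Fusion:
    return Fusion("intact", result, [SegmentSpec(source, 0.0, 1.0)])


def fusion_side_by_side(result: str, a: str, b: str) -> Fusion:
    return Fusion("side_by_side", result,
                  [SegmentSpec(a, 0.0, 1.0), SegmentSpec(b, 0.0, 1.0)])


def fusion_alternating(result: str, a: str, b: str) -> Fusion:
    return Fusion("alternating", result, [
        SegmentSpec(a, 0.0, 0.5), SegmentSpec(b, 0.0, 0.5),
        SegmentSpec(a, 0.5, 1.0), SegmentSpec(b, 0.5, 1.0),
    ])


def fusion_nested(result: str, outer: str, inner: SegmentSpec) -> Fusion:
    return Fusion("nested", result, [
        SegmentSpec(outer, 0.0, 0.5), inner, SegmentSpec(outer, 0.5, 1.0),
    ])


def fusion_three_way(result: str, pieces: list[SegmentSpec]) -> Fusion:
    return Fusion("three_way", result, list(pieces))


def default_scenario() -> RearrangementScenario:
    """The planted 12 -> 7 fusion pattern of the study system.

    Derived chromosome 1 alternates pieces of II and XII; 2 is a three-way
    joint of V, half of XI and half of III; 3 is a side-by-side fusion of IV
    and VI; 4 carries half of VIII nested inside VII; 5 alternates IX and X;
    6 joins the remaining halves of III, VIII and XI; 7 is chromosome I kept
    intact except for one planted inversion of its middle third.
    """
    return RearrangementScenario(events=[
        fusion_alternating("1", "II", "XII"),
        fusion_three_way("2", [SegmentSpec("V", 0.0, 1.0),
                               SegmentSpec("XI", 0.0, 0.5),
                               SegmentSpec("III", 0.0, 0.5)]),
        fusion_side_by_side("3", "IV", "VI"),
        fusion_nested("4", "VII", SegmentSpec("VIII", 0.0, 0.5)),
        fusion_alternating("5", "IX", "X"),
        fusion_three_way("6", [SegmentSpec("III", 0.5, 1.0),
                               SegmentSpec("VIII", 0.5, 1.0),
                               SegmentSpec("XI", 0.5, 1.0)]),
        fusion_intact("7", "I"),
        Inversion("7", 0.3, 0.7),
    ])


@dataclass
class TruthSegment:
    derived_chrom: str
    source_chrom: str
    derived_start_bp: int
    derived_end_bp: int
    source_start_bp: int
    source_end_bp: int
    inverted: bool


@dataclass
class MarkerLocation:
    chrom: str
    pos_bp: int
    pos_cM: float
    inverted: bool


@dataclass
class DerivedGenome:
    name: str
    chrom_sequences: dict[str, str]
    segments: list[TruthSegment]
    marker_loc: dict[str, MarkerLocation]
    bp_per_cM: float
    inversions: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class ScaffoldSet:
    scaffolds: dict[str, str]
    info: pd.DataFrame                       # scaffold, chrom, start_bp, end_bp
    marker_scaffold: dict[str, tuple[str, int]]  # marker -> (scaffold, offset)


@dataclass
class TruthSet:
    correspondence: dict[str, set[str]]       # source chrom -> derived partners
    correspondence_rev: dict[str, set[str]]   # derived chrom -> source partners
    segments: list[TruthSegment]
    marker_truth: pd.DataFrame
    inversions: list[tuple[str, int, int]]


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------

def simulate_ancestral_genome(
    n_chrom: int = 12,
    chrom_lengths_cM: dict[str, float] | None = None,
    markers_per_chrom: dict[str, int] | int | None = None,
    seed: int = 0,
    bp_per_cM: float = 1000.0,
    amplicon_range: tuple[int, int] = (150, 301),
    primer_len_range: tuple[int, int] = (20, 25),
) -> AncestralGenome:
    """Simulate the ancestral genome and its marker panel.

    Marker genetic positions are uniform on each chromosome; physical
    positions follow at ``bp_per_cM`` with a minimum spacing that keeps
    amplicons disjoint.  Each marker gets a unique random primer pair
    flanking a planted amplicon insert.
    """
    rng = np.random.default_rng(seed)
    if n_chrom == 12:
        names = list(ROMAN)
        lengths = dict(chrom_lengths_cM or DEFAULT_LENGTHS_CM)
        if markers_per_chrom is None:
            loci = dict(DEFAULT_LOCI)
        elif isinstance(markers_per_chrom, int):
            loci = {c: markers_per_chrom for c in names}
        else:
            loci = dict(markers_per_chrom)
    else:
        names = [f"A{i + 1}" for i in range(n_chrom)]
        lengths = dict(chrom_lengths_cM or {c: 100.0 for c in names})
        m = markers_per_chrom if isinstance(markers_per_chrom, int) else 20
        loci = {c: m for c in names}
    if any(v <= 0 for v in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    if any(v < 2 for v in loci.values()):
        raise ValueError("need at least two markers per chromosome")

    sep = amplicon_range[1] + 60
    used_primers: set[str] = set()
    markers: list[SimMarker] = []
    sequences: dict[str, str] = {}

    for chrom in names:
        m = loci[chrom]
        pos_cm = np.sort(rng.uniform(0.0, lengths[chrom], m))
        pos_bp = np.rint(pos_cm * bp_per_cM).astype(int)
        for i in range(1, m):  # keep amplicons physically disjoint
            if pos_bp[i] < pos_bp[i - 1] + sep:
                pos_bp[i] = pos_bp[i - 1] + sep
        chrom_bp = int(lengths[chrom] * bp_per_cM) + m * sep + 5000
        seq = list(_random_seq(rng, chrom_bp))

        for i in range(m):
            while True:
                lf = int(rng.integers(*primer_len_range))
                lr = int(rng.integers(*primer_len_range))
                fwd = _random_seq(rng, lf)
                rev = _random_seq(rng, lr)
                if fwd not in used_primers and rev not in used_primers and fwd != rev:
                    used_primers.update((fwd, rev))
                    break
                logger.info("primer collision for %s marker %d; regenerated",
                            chrom, i)
            size = int(rng.integers(*amplicon_range))
            insert = _random_seq(rng, size - lf - lr)
            amplicon = fwd + insert + revcomp(rev)
            start = int(pos_bp[i])
            seq[start : start + size] = amplicon
            markers.append(SimMarker(
                id=f"mk{chrom}_{i + 1:03d}", chrom=chrom,
                pos_cM=float(pos_cm[i]), pos_bp=start,
                primer_fwd=fwd, primer_rev=rev, amplicon_size=size,
            ))
        sequences[chrom] = "".join(seq)

    return AncestralGenome(names, lengths, sequences, markers, bp_per_cM)


# ---------------------------------------------------------------------------
# rearrangement
# ---------------------------------------------------------------------------

def _amplicon_intervals(markers: list[SimMarker]) -> list[tuple[int, int]]:
    return sorted((m.pos_bp, m.pos_bp + m.amplicon_size) for m in markers)


def _snap_outside(bp: int, intervals: list[tuple[int, int]], pad: int = 10) -> int:
    """Move a cut point out of (and away from) any planted amplicon."""
    for s, e in intervals:
        if s - pad <= bp < e + pad:
            return e + pad
    return bp


def apply_rearrangements(
    ancestral: AncestralGenome, scenario: RearrangementScenario
) -> tuple[DerivedGenome, TruthSet]:
    """Build the derived genome from the ancestral one under a scenario.

    Fusions concatenate (fraction-based) source segments; cut points are
    snapped outside planted amplicons so no marker is destroyed by a
    breakpoint.  Inversions reverse-complement an interval of a derived
    chromosome.  Each ancestral chromosome may be consumed by several
    fusions, but a given fraction may be used only once.
    """
    bp_per_cm = ancestral.bp_per_cM
    amp_by_chrom = {
        c: _amplicon_intervals(ancestral.markers_on(c)) for c in ancestral.chrom_names
    }
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in ancestral.chrom_names}

    def resolve(seg: SegmentSpec) -> tuple[int, int]:
        if seg.source not in ancestral.sequences:
            raise ValueError(f"unknown or consumed chromosome {seg.source}")
        length = len(ancestral.sequences[seg.source])
        b0 = _snap_outside(int(seg.f0 * length), amp_by_chrom[seg.source])
        b1 = length if seg.f1 >= 1.0 else _snap_outside(
            int(seg.f1 * length), amp_by_chrom[seg.source])
        for s, e in used[seg.source]:
            if b0 < e and s < b1:
                raise ValueError(
                    f"segment of {seg.source} [{b0},{b1}) already consumed")
        used[seg.source].append((b0, b1))
        return b0, b1

    chrom_sequences: dict[str, str] = {}
    segments: list[TruthSegment] = []
    marker_loc: dict[str, MarkerLocation] = {}
    derived_names: list[str] = []

    fusion_events = [e for e in scenario.events if isinstance(e, (Fusion,))]
    transloc = [e for e in scenario.events if isinstance(e, Translocation)]
    inversions = [e for e in scenario.events if isinstance(e, Inversion)]

    if not fusion_events:  # identity: ancestral passes through unchanged
        seg_lists = {c: [SegmentSpec(c, 0.0, 1.0)] for c in ancestral.chrom_names}
    else:
        seg_lists = {f.result: list(f.segments) for f in fusion_events}
    for t in transloc:
        if t.dest not in seg_lists:
            raise ValueError(f"translocation destination {t.dest} not built")
        seg_lists[t.dest].insert(t.at_index,
                                 SegmentSpec(t.source, t.f0, t.f1))

    for dname, specs in seg_lists.items():
        derived_names.append(dname)
        parts: list[str] = []
        offset = 0
        for spec in specs:
            b0, b1 = resolve(spec)
            src_seq = ancestral.sequences[spec.source][b0:b1]
            if spec.inverted:
                src_seq = revcomp(src_seq)
            parts.append(src_seq)
            segments.append(TruthSegment(
                dname, spec.source, offset, offset + (b1 - b0), b0, b1,
                spec.inverted))
            for mk in ancestral.markers_on(spec.source):
                if b0 <= mk.pos_bp and mk.pos_bp + mk.amplicon_size <= b1:
                    if spec.inverted:
                        new_bp = offset + (b1 - (mk.pos_bp + mk.amplicon_size))
                    else:
                        new_bp = offset + (mk.pos_bp - b0)
                    marker_loc[mk.id] = MarkerLocation(
                        dname, new_bp, new_bp / bp_per_cm, spec.inverted)
            offset += b1 - b0
        chrom_sequences[dname] = "".join(parts)

    # unconsumed fractions simply vanish (not part of the derived genome);
    # markers inside them are genuinely absent downstream
    derived = DerivedGenome("derived", chrom_sequences, segments, marker_loc,
                            bp_per_cm)

    for inv in inversions:
        _apply_inversion(derived, ancestral, inv)

    corr: dict[str, set[str]] = {}
    corr_rev: dict[str, set[str]] = {}
    for seg in derived.segments:
        corr.setdefault(seg.source_chrom, set()).add(seg.derived_chrom)
        corr_rev.setdefault(seg.derived_chrom, set()).add(seg.source_chrom)

    rows = []
    for mk in ancestral.markers:
        loc = derived.marker_loc.get(mk.id)
        rows.append({
            "marker_id": mk.id,
            "source_chrom": mk.chrom, "source_cM": mk.pos_cM,
            "derived_chrom": loc.chrom if loc else "",
            "derived_bp": loc.pos_bp if loc else -1,
            "derived_cM": round(loc.pos_cM, 3) if loc else np.nan,
            "inverted": bool(loc.inverted) if loc else False,
        })
    truth = TruthSet(corr, corr_rev, derived.segments, pd.DataFrame(rows),
                     derived.inversions)
    return derived, truth


def _apply_inversion(derived: DerivedGenome, ancestral: AncestralGenome,
                     inv: Inversion) -> None:
    if inv.chromosome not in derived.chrom_sequences:
        raise ValueError(f"inversion on unknown derived chromosome {inv.chromosome}")
    seq = derived.chrom_sequences[inv.chromosome]
    amp = sorted(
        (loc.pos_bp, loc.pos_bp + next(m.amplicon_size for m in ancestral.markers
                                       if m.id == mid))
        for mid, loc in derived.marker_loc.items()
        if loc.chrom == inv.chromosome
    )
    a = _snap_outside(int(inv.f0 * len(seq)), amp)
    b = _snap_outside(int(inv.f1 * len(seq)), amp)
    if not 0 <= a < b <= len(seq):
        raise ValueError("inversion interval out of range")
    derived.chrom_sequences[inv.chromosome] = seq[:a] + revcomp(seq[a:b]) + seq[b:]
    for mid, loc in list(derived.marker_loc.items()):
        if loc.chrom != inv.chromosome:
            continue
        size = next(m.amplicon_size for m in ancestral.markers if m.id == mid)
        if a <= loc.pos_bp and loc.pos_bp + size <= b:
            new_bp = a + (b - (loc.pos_bp + size))
            derived.marker_loc[mid] = replace(
                loc, pos_bp=new_bp, pos_cM=new_bp / derived.bp_per_cM,
                inverted=not loc.inverted)
    derived.inversions.append((inv.chromosome, a, b))


# ---------------------------------------------------------------------------
# scaffolds and reference map
# ---------------------------------------------------------------------------

def fragment_scaffolds(
    derived: DerivedGenome,
    ancestral: AncestralGenome,
    mean_bp: float = 9000.0,
    sigma: float = 0.5,
    min_bp: int = 2500,
    seed: int = 0,
) -> ScaffoldSet:
    """Fragment derived chromosomes into draft scaffolds (lognormal sizes).

    Cut points are snapped outside planted amplicons, so every surviving
    marker sits wholly inside one scaffold.  Scaffold-to-chromosome truth is
    retained in the info table (the pipeline itself never reads it).
    """
    rng = np.random.default_rng(seed)
    size_by_marker = {m.id: m.amplicon_size for m in ancestral.markers}
    scaffolds: dict[str, str] = {}
    rows = []
    marker_scaffold: dict[str, tuple[str, int]] = {}
    counter = 0
    mu = np.log(mean_bp) - sigma**2 / 2
    for chrom in sorted(derived.chrom_sequences):
        seq = derived.chrom_sequences[chrom]
        amp = sorted(
            (loc.pos_bp, loc.pos_bp + size_by_marker[mid])
            for mid, loc in derived.marker_loc.items() if loc.chrom == chrom
        )
        cuts = [0]
        while cuts[-1] < len(seq):
            size = max(int(rng.lognormal(mu, sigma)), min_bp)
            nxt = _snap_outside(cuts[-1] + size, amp)
            cuts.append(min(nxt, len(seq)))
        for s, e in zip(cuts, cuts[1:]):
            if e <= s:
                continue
            counter += 1
            sid = f"scf{counter:05d}"
            scaffolds[sid] = seq[s:e]
            rows.append({"scaffold": sid, "chrom": chrom,
                         "start_bp": s, "end_bp": e})
            for mid, loc in derived.marker_loc.items():
                if loc.chrom == chrom and s <= loc.pos_bp < e:
                    marker_scaffold[mid] = (sid, loc.pos_bp - s)
    return ScaffoldSet(scaffolds, pd.DataFrame(rows), marker_scaffold)


def make_reference_map(
    derived: DerivedGenome,
    scaffold_set: ScaffoldSet,
    n_reference_loci: int = 1244,
    panel_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """A reference genetic map of the derived genome.

    Emulates the target genome's own mapping resource: ``n_reference_loci``
    dedicated loci (the study system's published maps carry 1,244 unique
    loci with known scaffolds, about three times the query panel) placed
    uniformly along the derived chromosomes, plus a ``panel_fraction``
    sample of surviving panel markers that were "previously mapped" in the
    target genome (about 79 of 401 in the study) and therefore anchor
    directly.  Each row carries chromosome, cM position and scaffold.
    """
    rng = np.random.default_rng(seed)
    info = scaffold_set.info
    chroms = sorted(derived.chrom_sequences)
    lengths = np.array([len(derived.chrom_sequences[c]) for c in chroms], float)
    rows = []
    starts = {c: info.loc[info["chrom"] == c, "start_bp"].to_numpy() for c in chroms}
    names = {c: info.loc[info["chrom"] == c, "scaffold"].to_numpy() for c in chroms}
    picks = rng.choice(len(chroms), size=n_reference_loci, p=lengths / lengths.sum())
    for i, ci in enumerate(picks):
        chrom = chroms[ci]
        bp = int(rng.integers(0, lengths[ci]))
        k = int(np.searchsorted(starts[chrom], bp, side="right")) - 1
        rows.append({
            "marker_id": f"ref{i + 1:04d}", "chromosome": chrom,
            "position_cM": round(bp / derived.bp_per_cM, 3),
            "scaffold": str(names[chrom][max(k, 0)]),
        })
    ids = sorted(mid for mid in derived.marker_loc
                 if mid in scaffold_set.marker_scaffold)
    n_pick = int(round(panel_fraction * len(ids)))
    picked = sorted(rng.choice(ids, size=n_pick, replace=False).tolist())
    for mid in picked:
        loc = derived.marker_loc[mid]
        rows.append({
            "marker_id": mid, "chromosome": loc.chrom,
            "position_cM": round(loc.pos_cM, 3),
            "scaffold": scaffold_set.marker_scaffold[mid][0],
        })
    return pd.DataFrame(rows, columns=["marker_id", "chromosome",
                                       "position_cM", "scaffold"])


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction between adjacent loci under no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


def _gametes(haps: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from (n, 2, m) parental haplotypes."""
    n, _, m = haps.shape
    start = rng.integers(0, 2, size=n)
    if m > 1:
        switch = rng.random((n, m - 1)) < r
        idx = np.cumsum(np.concatenate([start[:, None], switch], axis=1), axis=1) % 2
    else:
        idx = start[:, None]
    return np.take_along_axis(haps, idx[:, None, :], axis=1)[:, 0, :]


def simulate_population(
    marker_table: pd.DataFrame,
    population_type: PopulationType,
    n: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    n_selfing: int = 7,
) -> GenotypeMatrix:
    """Simulate F2 or F8-RIL genotypes over a genetic map.

    ``marker_table`` needs columns marker_id, chrom, pos_cM.  Crossovers
    follow a no-interference (Haldane) process between adjacent loci;
    chromosomes assort independently.  RILs are produced by ``n_selfing``
    rounds of selfing from the F1 (F8 by default), leaving the expected
    (1/2)^7 residual heterozygosity per locus.
    """
    if n < 1:
        raise ValueError("population size must be at least 1")
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    marker_ids: list[str] = []
    for chrom, grp in marker_table.groupby("chrom", sort=True):
        grp = grp.sort_values("pos_cM")
        marker_ids.extend(grp["marker_id"].tolist())
        m = len(grp)
        r = haldane_r(np.diff(grp["pos_cM"].to_numpy()))
        if population_type is PopulationType.F2:
            g1 = _gametes(np.broadcast_to(
                np.array([[0], [1]], dtype=np.int8), (n, 2, m)).copy(), r, rng)
            g2 = _gametes(np.broadcast_to(
                np.array([[0], [1]], dtype=np.int8), (n, 2, m)).copy(), r, rng)
            cols.append((g1 + g2).astype(np.int8))
        else:
            haps = np.broadcast_to(
                np.array([[0], [1]], dtype=np.int8), (n, 2, m)).copy()
            for _ in range(n_selfing):
                ga = _gametes(haps, r, rng)
                gb = _gametes(haps, r, rng)
                haps = np.stack([ga, gb], axis=1).astype(np.int8)
            cols.append((haps[:, 0, :] + haps[:, 1, :]).astype(np.int8))
    calls = np.concatenate(cols, axis=1)
    if missing_rate > 0:
        calls = calls.copy()
        calls[rng.random(calls.shape) < missing_rate] = -1
    individuals = [f"ind{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(population_type, individuals, marker_ids, calls)


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

@dataclass
class CorruptionRates:
    no_hit: float = 0.0
    multi_copy: float = 0.0
    mis_anchor: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.no_hit, self.multi_copy, self.mis_anchor)
        if any(not 0 <= v <= 1 for v in vals) or sum(vals) > 1:
            raise ValueError("rates must lie in [0,1] and sum to at most 1")


def corrupt(
    scaffold_set: ScaffoldSet,
    ancestral: AncestralGenome,
    rates: CorruptionRates,
    seed: int = 0,
) -> tuple[ScaffoldSet, pd.DataFrame]:
    """Degrade the scaffold set to emulate no-hit / multi-copy / mis-anchored
    markers; truth labels are retained in the returned table.

    no_hit scrambles the planted amplicon in place; multi_copy appends a
    second amplicon copy to another scaffold; mis_anchor moves the amplicon
    to a scaffold of a different chromosome.  Appending keeps every other
    marker's coordinates valid.
    """
    rng = np.random.default_rng(seed)
    scaffolds = dict(scaffold_set.scaffolds)
    marker_scaffold = dict(scaffold_set.marker_scaffold)
    chrom_of = dict(zip(scaffold_set.info["scaffold"], scaffold_set.info["chrom"]))
    by_marker = {m.id: m for m in ancestral.markers}
    records = []
    all_sids = sorted(scaffolds)
    for mid in sorted(marker_scaffold):
        u = rng.random()
        mk = by_marker[mid]
        sid, off = marker_scaffold[mid]
        label = "intact"
        if u < rates.no_hit:
            label = "no_hit"
            seq = scaffolds[sid]
            scaffolds[sid] = (seq[:off] + _random_seq(rng, mk.amplicon_size)
                              + seq[off + mk.amplicon_size :])
            del marker_scaffold[mid]
        elif u < rates.no_hit + rates.multi_copy:
            label = "multi_copy"
            other = all_sids[int(rng.integers(0, len(all_sids)))]
            amplicon = scaffolds[sid][off : off + mk.amplicon_size]
            if other == sid:
                other = all_sids[(all_sids.index(sid) + 1) % len(all_sids)]
            scaffolds[other] = scaffolds[other] + amplicon
        elif u < rates.no_hit + rates.multi_copy + rates.mis_anchor:
            label = "mis_anchor"
            foreign = [s for s in all_sids if chrom_of[s] != chrom_of[sid]]
            dest = foreign[int(rng.integers(0, len(foreign)))]
            seq = scaffolds[sid]
            amplicon = seq[off : off + mk.amplicon_size]
            scaffolds[sid] = (seq[:off] + _random_seq(rng, mk.amplicon_size)
                              + seq[off + mk.amplicon_size :])
            marker_scaffold[mid] = (dest, len(scaffolds[dest]))
            scaffolds[dest] = scaffolds[dest] + amplicon
        records.append({"marker_id": mid, "corruption": label})
    out = ScaffoldSet(scaffolds, scaffold_set.info.copy(), marker_scaffold)
    return out, pd.DataFrame(records)


def marker_table(ancestral: AncestralGenome) -> pd.DataFrame:
    """Source-map marker table (marker_id, chrom, pos_cM, primers)."""
    return pd.DataFrame([
        {"marker_id": m.id, "chrom": m.chrom, "pos_cM": m.pos_cM,
         "pos_bp": m.pos_bp, "primer_fwd": m.primer_fwd,
         "primer_rev": m.primer_rev, "amplicon_size": m.amplicon_size}
        for m in ancestral.markers
    ])
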