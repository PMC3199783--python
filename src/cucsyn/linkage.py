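"""Two-point linkage analysis for F2 and selfed-RIL populations.

Implements segregation screening against Mendelian expectations,
maximum-likelihood recombination-fraction estimation (EM for codominant F2
data, closed form with the Haldane-Waddington correction for selfing RILs),
LOD-threshold grouping, SARF marker ordering, and the Kosambi map function.

Genotype codes throughout: 0 = A (parent-1 homozygote), 1 = H
(heterozygote), 2 = B (parent-2 homozygote), -1 = missing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import xlogy

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)

CODE_OF = {"A": 0, "H": 1, "B": 2, "-": -1, "U": -1, ".": -1}
SYMBOL_OF = {0: "A", 1: "H", 2: "B", -1: "-"}


class PopulationType(str, Enum):
    F2 = "F2_codominant"
    RIL = "RIL_selfed"


@dataclass
class Marker:
    """A molecular marker with optional primer pair / source sequence."""

    id: str
    source_genome: str = "other"  # cucumber | melon | watermelon | other
    marker_class: str = "SSR"  # SSR | CAPS | SNP | gene
    primer_fwd: str | None = None
    primer_rev: str | None = None
    source_sequence: str | None = None

    @property
    def anchorable(self) -> bool:
        return (self.primer_fwd is not None and self.primer_rev is not None) or (
            self.source_sequence is not None
        )


@dataclass
class GenotypeMatrix:
    """Individuals x markers call matrix for one mapping population."""

    population_type: PopulationType
    individuals: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.marker_ids)):
            raise ValueError("calls shape does not match individual/marker lists")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes limited to {A, H, B, missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_ids.index(marker_id)]


@dataclass
class SegregationResult:
    marker_id: str
    n_a: int
    n_h: int
    n_b: int
    chi2: float
    df: int
    p_value: float
    distorted: bool


@dataclass
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int
    population: PopulationType
    reliable: bool = True
    # data needed to re-evaluate the likelihood (heterogeneity testing):
    # F2 -> flattened 3x3 joint table; RIL -> (n_recombinant, n_scored)
    counts: tuple = ()

    def loglik(self, r: float) -> float:
        """Natural log-likelihood at meiotic recombination fraction r."""
        if self.population is PopulationType.F2:
            n = np.asarray(self.counts, dtype=float).reshape(3, 3)
            return float(np.sum(xlogy(n, f2_class_probs(r))))
        k, n = self.counts
        big_r = 2.0 * r / (1.0 + 2.0 * r)  # meiotic r -> observed RIL fraction
        return float(xlogy(k, big_r) + xlogy(n - k, 1.0 - big_r))


@dataclass
class GeneticMap:
    """Named linkage groups of (marker_id, position_cM), ordered within group."""

    groups: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    chromosome_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, loci in self.groups.items():
            pos = [p for _, p in loci]
            if pos and abs(pos[0]) > 1e-9:
                raise ValueError(f"group {name}: first locus must sit at 0.0 cM")
            if any(b < a - 1e-9 for a, b in zip(pos, pos[1:])):
                raise ValueError(f"group {name}: positions must be nondecreasing")
            ids = {m for m, _ in loci}
            if ids & seen:
                raise ValueError("marker present in more than one group")
            seen |= ids

    @property
    def marker_ids(self) -> set[str]:
        return {m for loci in self.groups.values() for m, _ in loci}

    def position_of(self, marker_id: str) -> tuple[str, float]:
        for name, loci in self.groups.items():
            for m, p in loci:
                if m == marker_id:
                    return name, p
        raise KeyError(marker_id)

    def group_length(self, name: str) -> float:
        loci = self.groups[name]
        return loci[-1][1] if loci else 0.0


# ---------------------------------------------------------------------------
# segregation screening
# ---------------------------------------------------------------------------

def test_segregation(
    counts: tuple[int, int, int],
    population_type: PopulationType,
    marker_id: str = "",
    alpha: float = 0.01,
) -> SegregationResult:
    """Pearson goodness-of-fit of genotype counts to Mendelian expectation.

    F2 populations are tested against 1:2:1 (df = 2).  Selfed RILs are
    tested against 1:1 on the two homozygote classes (df = 1); residual
    heterozygotes are excluded, with a warning if they exceed 5% of calls.
    """
    n_a, n_h, n_b = (int(c) for c in counts)
    if min(n_a, n_h, n_b) < 0:
        raise ValueError("negative genotype count")
    total = n_a + n_h + n_b
    if total == 0:
        raise ValueError("empty marker")

    if population_type is PopulationType.F2:
        observed = np.array([n_a, n_h, n_b], dtype=float)
        expected = total * np.array([0.25, 0.5, 0.25])
        df = 2
    else:
        if n_h / total > 0.05:
            logger.warning(
                "marker %s: RIL heterozygote fraction %.3f > 0.05; "
                "H calls excluded from the 1:1 test",
                marker_id,
                n_h / total,
            )
        observed = np.array([n_a, n_b], dtype=float)
        expected = (n_a + n_b) * np.array([0.5, 0.5])
        if n_a + n_b == 0:
            raise ValueError("empty marker")
        df = 1

    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(marker_id, n_a, n_h, n_b, chi2, df, p, p < alpha)


# ---------------------------------------------------------------------------
# two-point recombination fractions
# ---------------------------------------------------------------------------

def f2_class_probs(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities in an F2 at recombination fraction r.

    Rows index the genotype at the first locus (A, H, B), columns the
    second.  Derived from two independent gametes, each recombinant with
    probability r; the double heterozygote pools the cis and trans phases.
    """
    a, b = 1.0 - r, r
    return np.array(
        [
            [a * a / 4, a * b / 2, b * b / 4],
            [a * b / 2, (a * a + b * b) / 2, a * b / 2],
            [b * b / 4, a * b / 2, a * a / 4],
        ]
    )


def joint_counts(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """3x3 table of individuals typed at both markers."""
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    ok = (calls_a >= 0) & (calls_b >= 0)
    n = np.zeros((3, 3), dtype=np.int64)
    np.add.at(n, (calls_a[ok], calls_b[ok]), 1)
    return n


# expected recombinant gametes contributed by each joint genotype class;
# the double heterozygote (H,H) is phase-ambiguous and handled in the E-step
_F2_REC = np.array([[0, 1, 2], [1, np.nan, 1], [2, 1, 0]], dtype=float)


def _em_rf_f2(tables: np.ndarray, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Vectorized EM for the F2 recombination fraction.

    tables: (..., 3, 3) joint genotype counts. Returns r of shape (...,).
    """
    tables = np.asarray(tables, dtype=float)
    n = tables.sum(axis=(-2, -1))
    n_safe = np.where(n > 0, n, 1.0)
    fixed_rec = np.nansum(tables * _F2_REC, axis=(-2, -1))
    n_hh = tables[..., 1, 1]
    r = np.full(n.shape, 0.25)
    for _ in range(max_iter):
        # E-step: expected recombinant gametes in the double-het class
        denom = (1.0 - r) ** 2 + r**2
        e_hh = np.where(denom > 0, 2.0 * r**2 / denom, 0.0)
        r_new = (fixed_rec + n_hh * e_hh) / (2.0 * n_safe)
        r_new = np.clip(r_new, 0.0, 0.5)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    return r


def _f2_loglik(tables: np.ndarray, r: np.ndarray) -> np.ndarray:
    probs = np.stack(
        [
            (1 - r) ** 2 / 4, (1 - r) * r / 2, r**2 / 4,
            (1 - r) * r / 2, ((1 - r) ** 2 + r**2) / 2, (1 - r) * r / 2,
            r**2 / 4, (1 - r) * r / 2, (1 - r) ** 2 / 4,
        ],
        axis=-1,
    )
    flat = np.asarray(tables, dtype=float).reshape(*np.shape(r), 9)
    return np.sum(xlogy(flat, probs), axis=-1)


def estimate_rf_f2(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    marker_a: str = "a",
    marker_b: str = "b",
    min_informative: int = 10,
) -> TwoPointEstimate:
    """Maximum-likelihood r between two codominant F2 markers, via EM."""
    table = joint_counts(calls_a, calls_b)
    n_inf = int(table.sum())
    r = float(_em_rf_f2(table[None])[0])
    lod = float((_f2_loglik(table[None], np.array([r]))
                 - _f2_loglik(table[None], np.array([0.5])))[0] / LN10)
    lod = max(lod, 0.0)
    reliable = n_inf >= min_informative
    if not reliable:
        logger.info("pair (%s, %s): only %d informative individuals; "
                    "estimate flagged unreliable", marker_a, marker_b, n_inf)
    return TwoPointEstimate(
        marker_a, marker_b, r, lod, n_inf, PopulationType.F2,
        reliable=reliable, counts=tuple(table.ravel().tolist()),
    )


def haldane_waddington(big_r: float) -> float:
    """Map an observed selfing-RIL recombinant fraction R to meiotic r.

    r = R / (2 - 2R), treating the lines as fully inbred (RIL-infinity).
    """
    if not 0.0 <= big_r <= 1.0:
        raise ValueError("R must lie in [0, 1]")
    if big_r >= 0.5:
        return 0.5
    return big_r / (2.0 - 2.0 * big_r)


def estimate_rf_ril(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    marker_a: str = "a",
    marker_b: str = "b",
    min_informative: int = 10,
) -> TwoPointEstimate:
    """r between two RIL markers from the observed recombinant fraction.

    Residual heterozygous calls are treated as missing.  The observed
    fraction R among A/B-typed pairs is corrected to the meiotic scale with
    the Haldane-Waddington map r = R/(2-2R).
    """
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    ok = np.isin(calls_a, (0, 2)) & np.isin(calls_b, (0, 2))
    n = int(ok.sum())
    k = int(np.sum(calls_a[ok] != calls_b[ok]))
    big_r = k / n if n else 0.5
    r = haldane_waddington(min(big_r, 1.0 - 1e-12)) if big_r < 0.5 else 0.5
    if big_r >= 0.5:
        lod = 0.0
    else:
        lod = (xlogy(k, big_r) + xlogy(n - k, 1 - big_r)
               - n * np.log(0.5)) / LN10
        lod = max(float(lod), 0.0)
    reliable = n >= min_informative
    if not reliable:
        logger.info("pair (%s, %s): only %d informative lines; "
                    "estimate flagged unreliable", marker_a, marker_b, n)
    return TwoPointEstimate(
        marker_a, marker_b, float(r), float(lod), n, PopulationType.RIL,
        reliable=reliable, counts=(k, n),
    )


def pairwise_estimates(matrix: GenotypeMatrix, min_informative: int = 10):
    """All-pairs (r, lod, n_informative) matrices for one population.

    Joint 3x3 tables are accumulated with indicator-matrix products and the
    EM / closed-form estimators run vectorized over every pair, so the full
    panel (hundreds of markers) stays fast.  Returns (r, lod, n, reliable)
    square arrays aligned with matrix.marker_ids.
    """
    calls = matrix.calls
    m = calls.shape[1]
    ind = [(calls == g).astype(np.float64) for g in (0, 1, 2)]

    if matrix.population_type is PopulationType.F2:
        tables = np.empty((m, m, 3, 3))
        for a in range(3):
            for b in range(3):
                tables[:, :, a, b] = ind[a].T @ ind[b]
        n = tables.sum(axis=(2, 3))
        r = _em_rf_f2(tables)
        flat = tables.reshape(m, m, 9)
        lod = (_f2_loglik(flat, r) - _f2_loglik(flat, np.full((m, m), 0.5))) / LN10
        lod = np.maximum(lod, 0.0)
    else:
        hom_a, hom_b = ind[0], ind[2]
        scored = hom_a + hom_b
        n = scored.T @ scored
        disc = hom_a.T @ hom_b + hom_b.T @ hom_a
        with np.errstate(invalid="ignore", divide="ignore"):
            big_r = np.where(n > 0, disc / np.where(n > 0, n, 1), 0.5)
        r = np.where(big_r < 0.5, big_r / np.maximum(2 - 2 * big_r, 1e-300), 0.5)
        lod = xlogy(disc, big_r) + xlogy(n - disc, 1 - big_r) - n * np.log(0.5)
        lod = np.maximum(np.nan_to_num(lod / LN10), 0.0)
        lod = np.where(big_r >= 0.5, 0.0, lod)

    reliable = n >= min_informative
    np.fill_diagonal(reliable, False)
    return r, lod, n.astype(int), reliable


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------

def group_markers(
    marker_ids: list[str],
    r: np.ndarray,
    lod: np.ndarray,
    reliable: np.ndarray,
    lod_threshold: float = 4.0,
) -> list[list[str]]:
    """Partition markers into linkage groups by single-linkage at a LOD cut.

    An edge joins two markers when lod >= threshold, r < 0.5 and the pair
    had enough informative individuals.  Groups come back numbered by
    descending size, ties broken by smallest member id; isolated markers
    become trailing singleton groups.
    """
    g = nx.Graph()
    g.add_nodes_from(marker_ids)
    m = len(marker_ids)
    for i in range(m):
        for j in range(i + 1, m):
            if reliable[i, j] and lod[i, j] >= lod_threshold and r[i, j] < 0.5:
                g.add_edge(marker_ids[i], marker_ids[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def sarf(order: list[int], d: np.ndarray) -> float:
    """Sum of adjacent recombination fractions along an order."""
    return float(sum(d[a, b] for a, b in zip(order, order[1:])))


def _fill_missing_distances(ids: list[str], r: np.ndarray, reliable: np.ndarray):
    """Complete a within-group distance matrix.

    Unreliable / unlinked pairs are filled with additive Kosambi distance
    along the shortest path through reliable pairs, converted back to r.
    """
    m = len(ids)
    d = np.full((m, m), np.nan)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for i in range(m):
        d[i, i] = 0.0
        for j in range(i + 1, m):
            if reliable[i, j] and r[i, j] < 0.5:
                d[i, j] = d[j, i] = r[i, j]
                g.add_edge(i, j, weight=kosambi_distance(r[i, j]))
    if np.isnan(d).any():
        logger.info("group [%s...]: filling missing pairwise estimates by "
                    "shortest-path additive distance", ids[0])
        paths = dict(nx.all_pairs_dijkstra_path_length(g))
        for i in range(m):
            for j in range(m):
                if np.isnan(d[i, j]):
                    cm = paths.get(i, {}).get(j)
                    d[i, j] = kosambi_inverse(cm) if cm is not None else 0.49
    return d


def order_markers(
    group: list[str],
    marker_ids: list[str],
    r: np.ndarray,
    reliable: np.ndarray,
    max_passes: int = 30,
) -> list[str]:
    """Order one linkage group by minimizing the sum of adjacent r (SARF).

    Greedy insertion (seeded with the most distant reliable pair) followed
    by window-2/3 two-opt improvement passes.  Orientation is normalized so
    the lexicographically smaller terminal marker comes first.
    """
    if len(group) < 2:
        return list(group)
    idx = {mid: marker_ids.index(mid) for mid in group}
    local_ids = sorted(group)
    sub = np.ix_([idx[m] for m in local_ids], [idx[m] for m in local_ids])
    d = _fill_missing_distances(local_ids, r[sub], reliable[sub])

    m = len(local_ids)
    # seed with the farthest pair (deterministic tie-break by index)
    seed = max(
        ((i, j) for i in range(m) for j in range(i + 1, m)),
        key=lambda p: (d[p], -p[0], -p[1]),
    )
    order = [seed[0], seed[1]]
    for k in sorted(set(range(m)) - set(order)):
        best_pos, best_cost = 0, np.inf
        for pos in range(len(order) + 1):
            cand = order[:pos] + [k] + order[pos:]
            cost = sarf(cand, d)
            if cost < best_cost - 1e-15:
                best_cost, best_pos = cost, pos
        order.insert(best_pos, k)

    improved = True
    passes = 0
    while improved and passes < max_passes:
        improved = False
        passes += 1
        for w in (2, 3):
            for start in range(len(order) - w + 1):
                window = order[start : start + w]
                base = sarf(order, d)
                for perm in itertools.permutations(window):
                    cand = order[:start] + list(perm) + order[start + w :]
                    if sarf(cand, d) < base - 1e-12:
                        order = cand
                        base = sarf(order, d)
                        improved = True

    out = [local_ids[i] for i in order]
    if out[-1] < out[0]:
        out.reverse()
    return out


# ---------------------------------------------------------------------------
# Kosambi mapping function
# ---------------------------------------------------------------------------

def kosambi_distance(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centiMorgans."""
    if not 0.0 <= r < 0.5:
        raise ValueError("unlinked pair in ordered group")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Inverse Kosambi: r = 0.5 tanh(2d/100)."""
    if d_cm < 0:
        raise ValueError("negative map distance")
    return 0.5 * np.tanh(2.0 * d_cm / 100.0)


def positions_from_order(
    order: list[str],
    marker_ids: list[str],
    r: np.ndarray,
    reliable: np.ndarray,
) -> list[tuple[str, float]]:
    """Kosambi positions for an ordered group, first locus at 0.0 cM."""
    if len(order) == 1:
        return [(order[0], 0.0)]
    idx = {mid: marker_ids.index(mid) for mid in order}
    d = _fill_missing_distances(order, r[np.ix_([idx[m] for m in order],
                                                [idx[m] for m in order])],
                                reliable[np.ix_([idx[m] for m in order],
                                                [idx[m] for m in order])])
    pos = [0.0]
    for k in range(1, len(order)):
        rf = min(d[k - 1, k], 0.499999)
        pos.append(pos[-1] + kosambi_distance(rf))
    return list(zip(order, pos))


def split_at_gaps(
    ordered: list[tuple[str, float]],
    max_interval_cm: float = 22.0,
    cross_support: list[int] | None = None,
    min_cross_support: int = 2,
) -> list[list[tuple[str, float]]]:
    """Split an ordered group at oversized or weakly supported junctions.

    Standard map hygiene: across tens of thousands of pairwise tests a
    single spuriously significant pair can chain two chromosomes into one
    component.  Such a junction shows up as an oversized adjacent interval
    and/or as a boundary bridged by only one significant pair, whereas a
    genuine map interval is corroborated by many flanking pairs.
    ``cross_support[k]`` counts the significant pairs spanning the boundary
    between loci k and k+1.  Each fragment is re-based to start at 0.0 cM.
    """
    pieces: list[list[tuple[str, float]]] = [[ordered[0]]]
    for k, ((m0, p0), (m1, p1)) in enumerate(zip(ordered, ordered[1:])):
        weak = cross_support is not None and cross_support[k] < min_cross_support
        if p1 - p0 > max_interval_cm or weak:
            pieces.append([])
        pieces[-1].append((m1, p1))
    out = []
    for piece in pieces:
        base = piece[0][1]
        out.append([(m, p - base) for m, p in piece])
    if len(out) > 1:
        logger.info("group split at %d junction(s)", len(out) - 1)
    return out


def _cross_support(
    order: list[str],
    marker_ids: list[str],
    r: np.ndarray,
    lod: np.ndarray,
    reliable: np.ndarray,
    lod_threshold: float,
) -> list[int]:
    """Significant-pair counts across each adjacent boundary of an order."""
    idx = [marker_ids.index(m) for m in order]
    sub_l = lod[np.ix_(idx, idx)]
    sub_r = r[np.ix_(idx, idx)]
    sub_ok = reliable[np.ix_(idx, idx)]
    sig = sub_ok & (sub_l >= lod_threshold) & (sub_r < 0.5)
    m = len(order)
    return [int(sig[:k + 1, k + 1:].sum()) for k in range(m - 1)]


def build_map(
    matrix: GenotypeMatrix,
    lod_threshold: float = 4.0,
    min_informative: int = 10,
    min_group_size: int = 2,
    max_interval_cm: float = 22.0,
) -> tuple[GeneticMap, list[str]]:
    """Full map construction for one population.

    Returns the genetic map (groups numbered LG1, LG2, ... by descending
    size) and the list of unplaced markers (singletons or too few
    informative individuals).
    """
    r, lod, n, reliable = pairwise_estimates(matrix, min_informative)
    comps = group_markers(matrix.marker_ids, r, lod, reliable, lod_threshold)
    placed_groups: list[list[tuple[str, float]]] = []
    unplaced: list[str] = []
    for comp in comps:
        if len(comp) < min_group_size:
            unplaced.extend(comp)
            continue
        order = order_markers(comp, matrix.marker_ids, r, reliable)
        loci = positions_from_order(order, matrix.marker_ids, r, reliable)
        support = _cross_support(order, matrix.marker_ids, r, lod, reliable,
                                 lod_threshold)
        placed_groups.extend(split_at_gaps(loci, max_interval_cm, support))
    placed_groups = [g for g in placed_groups if len(g) >= min_group_size] + [
        g for g in placed_groups if len(g) < min_group_size
    ]
    singles = [g for g in placed_groups if len(g) < min_group_size]
    placed_groups = [g for g in placed_groups if len(g) >= min_group_size]
    unplaced.extend(m for g in singles for m, _ in g)
    placed_groups.sort(key=lambda g: (-len(g), g[0][0]))
    gmap = GeneticMap(
        groups={f"LG{i + 1}": loci for i, loci in enumerate(placed_groups)}
    )
    return gmap, sorted(unplaced)
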