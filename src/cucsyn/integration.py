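"""Consensus-map construction from two population maps.

Shared (anchor) markers are screened with a likelihood-ratio heterogeneity
test of the recombination fraction across populations; retained anchors then
drive a fixed-order merge in which the first (reference) map's locus order
is preserved and second-map-only loci are interpolated into the reference
centiMorgan frame between their flanking anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .linkage import GeneticMap, TwoPointEstimate

logger = logging.getLogger(__name__)


@dataclass
class HeterogeneityResult:
    pair: tuple[str, str]
    g_statistic: float
    p_value: float
    pooled_r: float

    @property
    def heterogeneous(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ConsensusMap:
    map: GeneticMap
    provenance: dict[str, str] = field(default_factory=dict)  # F2_only | RIL_only | shared
    unplaced: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (marker, reason)


def heterogeneity_test(
    est1: TwoPointEstimate, est2: TwoPointEstimate
) -> HeterogeneityResult:
    """Likelihood-ratio test that two populations share one r for a pair.

    G = 2[lnL1(r1) + lnL2(r2) - lnL1(rp) - lnL2(rp)] with the pooled MLE rp
    maximizing the joint likelihood on the meiotic scale; p from chi-square
    with 1 df.  Pairs with p < 0.05 are flagged for exclusion from merging.
    """
    def neg_joint(r: float) -> float:
        return -(est1.loglik(r) + est2.loglik(r))

    if abs(est1.r_hat - est2.r_hat) < 1e-12:
        # identical MLEs (including both clamped at a boundary): the pooled
        # estimate coincides with them and G is exactly zero
        return HeterogeneityResult((est1.marker_a, est1.marker_b), 0.0, 1.0,
                                   float(est1.r_hat))
    ll_sep = est1.loglik(est1.r_hat) + est2.loglik(est2.r_hat)
    if not np.isfinite(ll_sep):
        # degenerate likelihood (e.g. all or no recombinants in a population
        # with an estimate clamped at the boundary)
        logger.info("heterogeneity test (%s, %s): degenerate likelihood, G = 0",
                    est1.marker_a, est1.marker_b)
        return HeterogeneityResult((est1.marker_a, est1.marker_b), 0.0, 1.0,
                                   float(est1.r_hat))
    res = minimize_scalar(neg_joint, bounds=(1e-9, 0.5 - 1e-9), method="bounded",
                          options={"xatol": 1e-12})
    pooled = float(res.x)
    g = 2.0 * (ll_sep + float(res.fun))
    g = max(g, 0.0)
    p = float(stats.chi2.sf(g, df=1))
    return HeterogeneityResult((est1.marker_a, est1.marker_b), g, p, pooled)


def _longest_consistent_anchors(ref_order: list[str],
                                second_pos: dict[str, float]) -> list[str]:
    """Largest anchor subset whose second-map positions follow reference order.

    Longest (strictly) increasing subsequence; conflicting anchors are demoted
    to ordinary loci.  Deterministic: on ties the earliest anchors win.
    """
    seq = [second_pos[m] for m in ref_order]
    n = len(seq)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = int(np.argmax(best_len))
    keep = []
    while end != -1:
        keep.append(ref_order[end])
        end = prev[end]
    return keep[::-1]


def _piecewise(x: float, xs: list[float], ys: list[float]) -> float:
    """Piecewise-linear map through (xs, ys); terminal-segment extrapolation."""
    if len(xs) == 1:
        return ys[0] + (x - xs[0])
    i = int(np.searchsorted(xs, x, side="right")) - 1
    i = min(max(i, 0), len(xs) - 2)
    x0, x1 = xs[i], xs[i + 1]
    y0, y1 = ys[i], ys[i + 1]
    slope = (y1 - y0) / (x1 - x0) if x1 > x0 else 1.0
    return y0 + (x - x0) * slope


def merge_maps(
    reference_map: GeneticMap,
    second_map: GeneticMap,
    excluded_anchors: set[str] | None = None,
    w_reference: float = 1.0,
    w_second: float = 1.0,
    max_extrapolation_cm: float = 25.0,
) -> ConsensusMap:
    """Fixed-order merge of a second map into a reference map.

    Reference loci keep their relative order.  Within each reference group,
    anchors shared with the second map (grouped by their second-map linkage
    group, order conflicts demoted) define piecewise-linear frame maps; each
    second-only locus is rescaled into the consensus frame between its
    flanking anchors, extrapolating with the terminal segment's scale.
    Anchor consensus positions are the information-weighted mean of the
    reference position and the second map's rescaled estimate.  Groups
    contributing fewer than two anchors leave their second-map loci
    unplaced, as do loci lying more than ``max_extrapolation_cm`` beyond the
    terminal anchors on the second map (no reliable projection exists for
    them).  Final positions are shifted so every group starts at 0.0 cM.
    """
    excluded_anchors = excluded_anchors or set()
    shared_all = reference_map.marker_ids & second_map.marker_ids
    second_group_of = {m: g for g, loci in second_map.groups.items() for m, _ in loci}
    second_pos = {m: p for loci in second_map.groups.values() for m, p in loci}

    groups: dict[str, list[tuple[str, float]]] = {}
    provenance: dict[str, str] = {}
    unplaced: list[str] = []
    excluded_log: list[tuple[str, str]] = []
    placed_second: set[str] = set()

    for gname, ref_loci in reference_map.groups.items():
        ref_ids = [m for m, _ in ref_loci]
        ref_posn = dict(ref_loci)
        anchors_here = [m for m in ref_ids
                        if m in shared_all and m not in excluded_anchors]
        for m in ref_ids:
            if m in shared_all and m in excluded_anchors:
                excluded_log.append((m, "heterogeneous rf (P < 0.05)"))

        # anchors handled per second-map group (the second map may be split)
        anchors_by_sg: dict[str, list[str]] = {}
        for m in anchors_here:
            anchors_by_sg.setdefault(second_group_of[m], []).append(m)

        consensus_pos: dict[str, float] = {m: ref_posn[m] for m in ref_ids}
        inserted: list[tuple[str, float]] = []

        for sg, anchors in anchors_by_sg.items():
            anchors = [m for m in ref_ids if m in anchors]  # reference order
            anchors = _longest_consistent_anchors(anchors, second_pos)
            demoted = set(anchors_by_sg[sg]) - set(anchors)
            for m in demoted:
                excluded_log.append((m, "anchor order conflict"))
            if len(anchors) < 2:
                for m, _ in second_map.groups[sg]:
                    if m not in reference_map.marker_ids and m not in placed_second:
                        unplaced.append(m)
                continue
            xs = [second_pos[m] for m in anchors]   # second frame
            ys = [ref_posn[m] for m in anchors]     # reference frame
            # second-map estimate of each anchor, interpolated from its
            # neighbours, averaged with the reference position by information
            wtot = w_reference + w_second
            for i, m in enumerate(anchors):
                nb = [j for j in range(len(anchors)) if j != i]
                if len(nb) < 2:
                    # no scale information beyond the anchor itself
                    est = ref_posn[m]
                else:
                    est = _piecewise(xs[i], [xs[j] for j in nb], [ys[j] for j in nb])
                consensus_pos[m] = (w_reference * ref_posn[m] + w_second * est) / wtot
            for m, p in second_map.groups[sg]:
                if m in reference_map.marker_ids or m in placed_second:
                    continue
                if p < xs[0] - max_extrapolation_cm or p > xs[-1] + max_extrapolation_cm:
                    logger.info("locus %s lies %.1f cM beyond the terminal "
                                "anchor; left unplaced", m,
                                min(abs(p - xs[0]), abs(p - xs[-1])))
                    unplaced.append(m)
                    continue
                inserted.append((m, _piecewise(p, xs, ys)))
                placed_second.add(m)

        # assemble: reference loci in reference order; second-only loci
        # slotted by their rescaled positions
        ordered = [(m, consensus_pos[m]) for m in ref_ids]
        for m, p in sorted(inserted, key=lambda t: (t[1], t[0])):
            k = 0
            while k < len(ordered) and ordered[k][1] <= p:
                k += 1
            ordered.insert(k, (m, p))
        # enforce monotone positions (weighted anchors can locally overshoot)
        pos = np.maximum.accumulate([p for _, p in ordered])
        pos = pos - pos[0]
        groups[gname] = [(m, float(p)) for (m, _), p in zip(ordered, pos)]

        for m, _ in groups[gname]:
            in_ref = m in reference_map.marker_ids
            in_sec = m in second_map.marker_ids
            provenance[m] = ("shared" if in_ref and in_sec
                             else "F2_only" if in_ref else "RIL_only")

    for m in sorted(second_map.marker_ids - reference_map.marker_ids - placed_second):
        if m not in unplaced:
            unplaced.append(m)

    cmap = GeneticMap(groups=groups,
                      chromosome_labels=dict(reference_map.chromosome_labels))
    return ConsensusMap(cmap, provenance, sorted(set(unplaced)), excluded_log)


def map_summary(gmap: GeneticMap, provenance: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-group and total map statistics.

    Mean marker interval is computed as (group length in cM) / (locus
    count), reported to one decimal.  A TOTAL row aggregates all groups.
    """
    rows = []
    for name, loci in gmap.groups.items():
        length = gmap.group_length(name)
        n = len(loci)
        row = {
            "group": name,
            "chromosome": gmap.chromosome_labels.get(name, ""),
            "n_loci": n,
            "length_cM": round(length, 1),
            "mean_interval_cM": round(length / n, 1) if n else 0.0,
        }
        if provenance is not None:
            for src in ("shared", "F2_only", "RIL_only"):
                row[f"n_{src}"] = sum(
                    1 for m, _ in loci if provenance.get(m) == src
                )
        rows.append(row)
    df = pd.DataFrame(rows)
    total_len = float(df["length_cM"].sum()) if len(df) else 0.0
    total_loci = int(df["n_loci"].sum()) if len(df) else 0
    total = {
        "group": "TOTAL",
        "chromosome": "",
        "n_loci": total_loci,
        "length_cM": round(total_len, 1),
        "mean_interval_cM": round(total_len / total_loci, 1) if total_loci else 0.0,
    }
    if provenance is not None and len(df):
        for src in ("shared", "F2_only", "RIL_only"):
            total[f"n_{src}"] = int(df[f"n_{src}"].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
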