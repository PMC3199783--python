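"""End-to-end orchestration of the comparative-mapping pipeline.

Stages: synthetic genome + population generation, per-population linkage
mapping, heterogeneity-screened consensus merging, virtual-PCR anchoring of
consensus markers onto derived-genome scaffolds, transitive chromosome
assignment, and syntenic-block / correspondence inference.  Every stage is a
pure function of (inputs, config, seed); outputs are written with stable
filenames when an output directory is configured.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .integration import ConsensusMap, heterogeneity_test, map_summary, merge_maps
from .linkage import (GeneticMap, PopulationType, build_map, estimate_rf_f2,
                      estimate_rf_ril, pairwise_estimates, test_segregation)
from .simulate import (CorruptionRates, RearrangementScenario, corrupt,
                       default_scenario, fragment_scaffolds, make_reference_map,
                       marker_table, simulate_ancestral_genome,
                       simulate_population, apply_rearrangements)
from .synteny import (AnchoredMarker, ReferenceMap, SyntenicBlock,
                      assign_chromosome, block_views, correspondence_table,
                      detect_blocks, partner_sets)
from .vpcr import Assembly, VpcrParams, classify_hits, virtual_pcr

logger = logging.getLogger(__name__)


def pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, round half up (0.0 for an empty base)."""
    if denominator == 0:
        return 0.0
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults."""

    seed: int = 0
    # populations (study scale)
    n_f2: int = 91
    n_ril: int = 80
    missing_rate: float = 0.02
    # marker polymorphism: fraction of the panel scored in each population
    f2_fraction: float = 0.8
    ril_fraction: float = 0.5
    # linkage
    lod_threshold: float = 4.0
    min_informative: int = 10
    max_interval_cm: float = 22.0
    segregation_alpha: float = 0.01
    heterogeneity_alpha: float = 0.05
    # genome / anchoring
    bp_per_cm: float = 1000.0
    scaffold_mean_bp: float = 9000.0
    scaffold_sigma: float = 0.5
    n_reference_loci: int = 1244          # target genome's own mapped loci
    direct_fraction: float = 0.2          # panel markers already on target maps
    source_reference_fraction: float = 0.5  # source markers with known chromosome
    vpcr: VpcrParams = field(default_factory=VpcrParams)
    # blocks
    min_block_markers: int = 2
    max_gap_markers: int = 1
    # corruption (all zero by default)
    corruption: CorruptionRates = field(default_factory=CorruptionRates)
    out_dir: str | None = None

    def child_seeds(self, n: int = 10) -> list[int]:
        state = np.random.SeedSequence(self.seed).generate_state(n)
        return [int(s & 0x7FFFFFFF) for s in state]


@dataclass
class PipelineResult:
    f2_map: GeneticMap
    ril_map: GeneticMap
    consensus: ConsensusMap
    group_labels: dict[str, str]
    segregation: pd.DataFrame
    heterogeneity: pd.DataFrame
    classification: dict[str, str]
    anchored: list[AnchoredMarker]
    blocks: list[SyntenicBlock]
    singletons: list[AnchoredMarker]
    correspondence: pd.DataFrame
    views: pd.DataFrame
    truth: object
    report: pd.DataFrame
    summaries: dict[str, pd.DataFrame]


def label_groups(
    gmap: GeneticMap,
    source_reference: pd.DataFrame,
    population_maps: tuple[GeneticMap, ...] = (),
) -> dict[str, str]:
    """Assign each linkage group to a source chromosome.

    Majority vote among the group's markers present on previously published
    source-genome maps (emulated by the generator's source reference
    subset).  A group with no previously mapped marker is relegated
    transitively: any population-map group sharing markers with it lends the
    votes of its own previously mapped members.  Groups that still have no
    votes stay unlabeled.
    """
    known = dict(zip(source_reference["marker_id"], source_reference["chrom"]))
    labels: dict[str, str] = {}
    for name, loci in gmap.groups.items():
        votes = [known[m] for m, _ in loci if m in known]
        if not votes:
            ids = {m for m, _ in loci}
            for pmap in population_maps:
                for ploci in pmap.groups.values():
                    pids = {m for m, _ in ploci}
                    if ids & pids:
                        votes.extend(known[m] for m in sorted(pids) if m in known)
        series = pd.Series(votes)
        labels[name] = str(series.mode().iloc[0]) if len(series) else ""
    return labels


def relegate_by_linkage(
    group_labels: dict[str, str],
    gmap: GeneticMap,
    matrices: list,
    lod_threshold: float = 4.0,
) -> dict[str, str]:
    """Label leftover groups by their strongest residual linkage.

    A small fragment with no previously mapped marker can still be relegated
    to a chromosome: among labeled groups, find the one containing the
    marker with the highest two-point LOD (at r < 0.5) to any fragment
    member, and inherit its label if that LOD reaches the grouping
    threshold.  ``matrices`` holds (marker index, r, lod, reliable) tuples,
    one per population.  Returns the updated label dict.
    """
    labels = dict(group_labels)
    for gname in sorted(g for g, lab in labels.items() if not lab):
        ids = [m for m, _ in gmap.groups[gname]]
        best_lod, best_label = 0.0, ""
        for oname in sorted(labels):
            if oname == gname or not labels[oname]:
                continue
            oids = [m for m, _ in gmap.groups[oname]]
            for idx, r_m, lod_m, rel_m in matrices:
                ii = [idx[m] for m in ids if m in idx]
                jj = [idx[m] for m in oids if m in idx]
                if not ii or not jj:
                    continue
                sub = np.ix_(ii, jj)
                ok = rel_m[sub] & (r_m[sub] < 0.5)
                if ok.any():
                    top = float(lod_m[sub][ok].max())
                    if top > best_lod:
                        best_lod, best_label = top, labels[oname]
        if best_lod >= lod_threshold:
            logger.info("group %s relegated to chromosome %s by residual "
                        "linkage (LOD %.1f)", gname, best_label, best_lod)
            labels[gname] = best_label
    return labels


def transferability_report(screening: pd.DataFrame) -> pd.DataFrame:
    """Marker screening counts with derived one-decimal percentages.

    ``screening`` needs columns source, tested, amplified, polymorphic.
    Adds pct_amplified (= amplified/tested), pct_polymorphic_of_amplified,
    pct_polymorphic_of_tested, and a TOTAL row.
    """
    df = screening.copy()
    if ((df["amplified"] > df["tested"]) | (df["polymorphic"] > df["amplified"])).any():
        raise ValueError("screening counts must satisfy polymorphic <= amplified <= tested")
    total = {
        "source": "TOTAL",
        "tested": int(df["tested"].sum()),
        "amplified": int(df["amplified"].sum()),
        "polymorphic": int(df["polymorphic"].sum()),
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df["pct_amplified"] = [pct(a, t) for a, t in zip(df["amplified"], df["tested"])]
    df["pct_polymorphic_of_amplified"] = [
        pct(p, a) for p, a in zip(df["polymorphic"], df["amplified"])
    ]
    df["pct_polymorphic_of_tested"] = [
        pct(p, t) for p, t in zip(df["polymorphic"], df["tested"])
    ]
    return df


def marker_accounting(n_total: int, n_no_hit: int, n_repeat: int) -> int:
    """Markers assignable to scaffolds after removing no-hit and repeat cases."""
    n = n_total - n_no_hit - n_repeat
    if n < 0:
        raise ValueError("more excluded markers than markers")
    return n


def _segregation_screen(matrix, alpha: float) -> pd.DataFrame:
    rows = []
    for j, mid in enumerate(matrix.marker_ids):
        col = matrix.calls[:, j]
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        res = test_segregation(counts, matrix.population_type, mid, alpha)
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def _adjacent_shared_pairs(f2_map: GeneticMap, ril_map: GeneticMap):
    """Consecutive shared markers within one F2 group and one RIL group."""
    shared = f2_map.marker_ids & ril_map.marker_ids
    ril_group = {m: g for g, loci in ril_map.groups.items() for m, _ in loci}
    pairs = []
    for loci in f2_map.groups.values():
        chain = [m for m, _ in loci if m in shared]
        for a, b in zip(chain, chain[1:]):
            if ril_group[a] == ril_group[b]:
                pairs.append((a, b))
    return pairs


def run_pipeline(config: RunConfig,
                 scenario: RearrangementScenario | None = None) -> PipelineResult:
    """Run every stage on a synthetic scenario and return all artifacts."""
    seeds = config.child_seeds(10)
    scenario = scenario or default_scenario()

    # --- generation -------------------------------------------------------
    ancestral = simulate_ancestral_genome(seed=seeds[0],
                                          bp_per_cM=config.bp_per_cm)
    derived, truth = apply_rearrangements(ancestral, scenario)
    scaffold_set = fragment_scaffolds(
        derived, ancestral, mean_bp=config.scaffold_mean_bp,
        sigma=config.scaffold_sigma, seed=seeds[1])
    if (config.corruption.no_hit or config.corruption.multi_copy
            or config.corruption.mis_anchor):
        scaffold_set, _ = corrupt(scaffold_set, ancestral, config.corruption,
                                  seed=seeds[2])
    ref_df = make_reference_map(derived, scaffold_set,
                                n_reference_loci=config.n_reference_loci,
                                panel_fraction=config.direct_fraction,
                                seed=seeds[3])
    panel = marker_table(ancestral)

    rng = np.random.default_rng(seeds[4])
    in_f2 = rng.random(len(panel)) < config.f2_fraction
    in_ril = rng.random(len(panel)) < config.ril_fraction
    f2_geno = simulate_population(panel[in_f2], PopulationType.F2, config.n_f2,
                                  seed=seeds[5], missing_rate=config.missing_rate)
    ril_geno = simulate_population(panel[in_ril], PopulationType.RIL, config.n_ril,
                                   seed=seeds[6], missing_rate=config.missing_rate)
    src_rng = np.random.default_rng(seeds[7])
    known_src = src_rng.random(len(panel)) < config.source_reference_fraction
    source_reference = panel.loc[known_src, ["marker_id", "chrom", "pos_cM"]]

    # --- linkage maps -----------------------------------------------------
    seg_f2 = _segregation_screen(f2_geno, config.segregation_alpha)
    seg_ril = _segregation_screen(ril_geno, config.segregation_alpha)
    seg_f2["population"], seg_ril["population"] = "F2", "RIL"
    segregation = pd.concat([seg_f2, seg_ril], ignore_index=True)
    n_distorted = int(segregation["distorted"].sum())
    if n_distorted:
        logger.info("%d marker(s) show segregation distortion at P < %.2f",
                    n_distorted, config.segregation_alpha)

    f2_map, f2_unplaced = build_map(
        f2_geno, config.lod_threshold, config.min_informative,
        max_interval_cm=config.max_interval_cm)
    ril_map, ril_unplaced = build_map(
        ril_geno, config.lod_threshold, config.min_informative,
        max_interval_cm=config.max_interval_cm)
    logger.info("F2 map: %d loci in %d groups (%d unplaced); RIL map: %d loci "
                "in %d groups (%d unplaced)",
                len(f2_map.marker_ids), len(f2_map.groups), len(f2_unplaced),
                len(ril_map.marker_ids), len(ril_map.groups), len(ril_unplaced))

    # --- heterogeneity screening and merge --------------------------------
    het_rows = []
    excluded: set[str] = set()
    for a, b in _adjacent_shared_pairs(f2_map, ril_map):
        e1 = estimate_rf_f2(f2_geno.column(a), f2_geno.column(b), a, b)
        e2 = estimate_rf_ril(ril_geno.column(a), ril_geno.column(b), a, b)
        res = heterogeneity_test(e1, e2)
        het_rows.append({"marker_a": a, "marker_b": b, "G": res.g_statistic,
                         "p_value": res.p_value,
                         "excluded": res.heterogeneous})
        if res.heterogeneous:
            excluded.update((a, b))
    heterogeneity = pd.DataFrame(
        het_rows, columns=["marker_a", "marker_b", "G", "p_value", "excluded"])
    logger.info("heterogeneity screen: %d of %d shared adjacent pairs "
                "heterogeneous; %d anchor markers excluded",
                int(heterogeneity["excluded"].sum()) if len(heterogeneity) else 0,
                len(heterogeneity), len(excluded))

    consensus = merge_maps(f2_map, ril_map, excluded,
                           w_reference=config.n_f2, w_second=config.n_ril)
    group_labels = label_groups(consensus.map, source_reference,
                                (f2_map, ril_map))
    if any(not lab for lab in group_labels.values()):
        matrices = []
        for geno in (f2_geno, ril_geno):
            r_m, lod_m, _, rel_m = pairwise_estimates(geno, config.min_informative)
            idx = {m: i for i, m in enumerate(geno.marker_ids)}
            matrices.append((idx, r_m, lod_m, rel_m))
        group_labels = relegate_by_linkage(group_labels, consensus.map,
                                           matrices, config.lod_threshold)
    consensus.map.chromosome_labels.update(group_labels)

    # --- anchoring --------------------------------------------------------
    assembly = Assembly("draft", scaffold_set.scaffolds)
    primer_of = panel.set_index("marker_id")
    hits_by_marker = {}
    for mid in sorted(consensus.map.marker_ids):
        row = primer_of.loc[mid]
        hits_by_marker[mid] = virtual_pcr(mid, row["primer_fwd"],
                                          row["primer_rev"], assembly,
                                          config.vpcr)
    classification = classify_hits(hits_by_marker)

    reference_map = ReferenceMap(ref_df)
    anchored: list[AnchoredMarker] = []
    for gname, loci in consensus.map.groups.items():
        label = group_labels.get(gname, "") or gname
        for mid, pos in loci:
            anchored.append(assign_chromosome(
                mid, label, pos, classification[mid], hits_by_marker[mid],
                reference_map))

    # --- blocks and correspondence ----------------------------------------
    by_source: dict[str, list[list[AnchoredMarker]]] = {}
    for gname, loci in consensus.map.groups.items():
        label = group_labels.get(gname, "")
        if not label:
            # a group with no previously mapped marker cannot be tied to a
            # source chromosome; its loci stay out of per-chromosome synteny
            logger.info("group %s has no chromosome assignment; %d loci "
                        "excluded from block detection", gname, len(loci))
            continue
        ids = [m for m, _ in loci]
        by_source.setdefault(label, []).append(
            [a for a in anchored if a.marker_id in set(ids)])
    blocks: list[SyntenicBlock] = []
    singletons: list[AnchoredMarker] = []
    for label in sorted(by_source):
        chunks = sorted(by_source[label], key=lambda c: -len(c))
        offset = 0.0
        merged: list[AnchoredMarker] = []
        for chunk in chunks:
            chunk = sorted(chunk, key=lambda a: a.source_cM)
            for a in chunk:
                merged.append(dataclasses.replace(a, source_cM=a.source_cM + offset))
            if chunk:
                offset = merged[-1].source_cM + 10.0
        b, s = detect_blocks(merged, config.min_block_markers,
                             config.max_gap_markers)
        blocks.extend(b)
        singletons.extend(s)

    correspondence = correspondence_table(blocks)
    views = block_views(blocks)

    # --- report ------------------------------------------------------------
    n_cons = len(consensus.map.marker_ids)
    n_no_hit = sum(1 for m in consensus.map.marker_ids
                   if classification[m] == "no_hit")
    n_multi = sum(1 for m in consensus.map.marker_ids
                  if classification[m] == "multi_copy")
    n_repeat = sum(1 for m in consensus.map.marker_ids
                   if classification[m] == "repeat_region")
    n_assigned = sum(1 for a in anchored if a.status == "assigned")
    shared = sorted(f2_map.marker_ids & ril_map.marker_ids)
    report = pd.DataFrame([
        {"quantity": "panel markers", "count": len(panel), "pct": ""},
        {"quantity": "markers on F2 map", "count": len(f2_map.marker_ids), "pct": ""},
        {"quantity": "markers on RIL map", "count": len(ril_map.marker_ids), "pct": ""},
        {"quantity": "shared anchor markers", "count": len(shared), "pct": ""},
        {"quantity": "consensus loci", "count": n_cons, "pct": ""},
        {"quantity": "no virtual-PCR product", "count": n_no_hit,
         "pct": pct(n_no_hit, n_cons)},
        {"quantity": "multi-copy", "count": n_multi, "pct": pct(n_multi, n_cons)},
        {"quantity": "repeat region", "count": n_repeat, "pct": pct(n_repeat, n_cons)},
        {"quantity": "assigned to target chromosome", "count": n_assigned,
         "pct": pct(n_assigned, n_cons)},
        {"quantity": "syntenic blocks", "count": len(blocks), "pct": ""},
    ])

    summaries = {
        "F2": map_summary(f2_map),
        "RIL": map_summary(ril_map),
        "consensus": map_summary(consensus.map, consensus.provenance),
    }

    result = PipelineResult(
        f2_map, ril_map, consensus, group_labels, segregation, heterogeneity,
        classification, anchored, blocks, singletons, correspondence, views,
        truth, report, summaries,
    )
    if config.out_dir:
        _write_outputs(result, scaffold_set, panel, ref_df, config)
    return result


def _write_outputs(result: PipelineResult, scaffold_set, panel, ref_df,
                   config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_fasta(scaffold_set.scaffolds, out / "scaffolds.fasta")
    cio.write_primers(panel, out / "primers.tsv")
    ref_df.to_csv(out / "reference_map.tsv", sep="\t", index=False)
    cio.write_map(result.f2_map, out / "f2_map.tsv")
    cio.write_map(result.ril_map, out / "ril_map.tsv")
    cio.write_map(result.consensus.map, out / "consensus_map.tsv")
    pd.DataFrame(result.consensus.excluded,
                 columns=["marker_id", "reason"]).to_csv(
        out / "merge_exclusions.tsv", sep="\t", index=False)
    result.segregation.to_csv(out / "segregation.tsv", sep="\t", index=False)
    result.heterogeneity.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
    cio.write_anchored(result.anchored, out / "anchored_markers.tsv")
    cio.write_blocks(result.blocks, out / "blocks.tsv")
    result.correspondence.to_csv(out / "correspondence.tsv", sep="\t", index=False)
    result.views.to_csv(out / "block_views.tsv", sep="\t", index=False)
    result.report.to_csv(out / "report.tsv", sep="\t", index=False)
    for name, df in result.summaries.items():
        df.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
    cio.write_json({"correspondence": result.truth.correspondence,
                    "correspondence_rev": result.truth.correspondence_rev},
                   out / "truth_correspondence.json")
    cio.write_json(
        {f.name: str(getattr(config, f.name)) for f in dataclasses.fields(config)},
        out / "run_config.json")


def recovered_partner_sets(result: PipelineResult) -> dict[str, set[str]]:
    return partner_sets(result.blocks, "source->target")
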