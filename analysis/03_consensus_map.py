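#!/usr/bin/env python
"""Merge the two maps into a consensus map.

Runs the recombination-fraction heterogeneity test on adjacent shared
markers, excludes heterogeneous anchors, merges with the F2 map as the
fixed-order reference, and assigns each consensus group to a source
chromosome via previously mapped markers (with residual-linkage relegation
for small fragments).
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from cucsyn import io as cio
from cucsyn.integration import map_summary, merge_maps
from cucsyn.linkage import (PopulationType, estimate_rf_f2, estimate_rf_ril,
                            pairwise_estimates)
from cucsyn.integration import heterogeneity_test
from cucsyn.pipeline import (RunConfig, _adjacent_shared_pairs, label_groups,
                             relegate_by_linkage)

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--maps", type=Path, default=Path("results/maps"))
    parser.add_argument("--out", type=Path, default=Path("results/consensus"))
    args = parser.parse_args()
    cfg = RunConfig()
    args.out.mkdir(parents=True, exist_ok=True)

    f2_map = cio.read_map(args.maps / "map_f2.tsv")
    ril_map = cio.read_map(args.maps / "map_ril.tsv")
    f2_geno = cio.read_genotypes(args.sim / "genotypes_f2.tsv", PopulationType.F2)
    ril_geno = cio.read_genotypes(args.sim / "genotypes_ril.tsv", PopulationType.RIL)

    het_rows, excluded = [], set()
    for a, b in _adjacent_shared_pairs(f2_map, ril_map):
        res = heterogeneity_test(
            estimate_rf_f2(f2_geno.column(a), f2_geno.column(b), a, b),
            estimate_rf_ril(ril_geno.column(a), ril_geno.column(b), a, b))
        het_rows.append({"marker_a": a, "marker_b": b, "G": res.g_statistic,
                         "p_value": res.p_value, "excluded": res.heterogeneous})
        if res.heterogeneous:
            excluded.update((a, b))
    het = pd.DataFrame(het_rows)
    het.to_csv(args.out / "heterogeneity.tsv", sep="\t", index=False)

    consensus = merge_maps(f2_map, ril_map, excluded,
                           w_reference=cfg.n_f2, w_second=cfg.n_ril)
    source_reference = pd.read_csv(args.sim / "source_reference.tsv", sep="\t")
    labels = label_groups(consensus.map, source_reference, (f2_map, ril_map))
    if any(not v for v in labels.values()):
        matrices = []
        for geno in (f2_geno, ril_geno):
            r_m, lod_m, _, rel_m = pairwise_estimates(geno, cfg.min_informative)
            idx = {m: i for i, m in enumerate(geno.marker_ids)}
            matrices.append((idx, r_m, lod_m, rel_m))
        labels = relegate_by_linkage(labels, consensus.map, matrices,
                                     cfg.lod_threshold)
    consensus.map.chromosome_labels.update(labels)

    cio.write_map(consensus.map, args.out / "consensus_map.tsv")
    pd.DataFrame(consensus.excluded, columns=["marker_id", "reason"]).to_csv(
        args.out / "exclusions.tsv", sep="\t", index=False)
    summary = map_summary(consensus.map, consensus.provenance)
    summary.to_csv(args.out / "summary_consensus.tsv", sep="\t", index=False)

    shared = f2_map.marker_ids & ril_map.marker_ids
    n_het = int(het["excluded"].sum()) if len(het) else 0
    total = summary.iloc[-1]
    print(f"shared anchor markers: {len(shared)}; heterogeneous pairs: "
          f"{n_het}/{len(het)} -> {len(excluded)} anchors excluded")
    print(f"consensus: {int(total['n_loci'])} loci, {total['length_cM']} cM, "
          f"mean interval {total['mean_interval_cM']} cM; "
          f"{len(consensus.unplaced)} RIL loci unplaced")
    n_labels = len({v for v in labels.values() if v})
    print(f"groups assigned to {n_labels} source chromosomes")


if __name__ == "__main__":
    main()
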