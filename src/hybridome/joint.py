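"""Integration of gene and sRNA differential expression through genomic links.

Detects the concomitant signature in which flank-linked sRNA clusters lose
expression in hybrid seeds while the associated gene gains expression in
hybrid endosperm, lists "silent targets" (genes with DE-linked clusters but
no detectable endosperm expression), and builds the normal-vs-hybrid
expression-distribution report per maternal plant.

Gene counts (endosperm mRNA) and sRNA counts (whole seed) come from
different tissues; they are never mixed numerically, only joined through
(cluster, gene) links.
"""

from __future__ import annotations

import pandas as pd

from .dge import cpm, cross_means, wilcoxon_compare
from .io import CountTable, SampleSheet

__all__ = [
    "find_joint_signatures",
    "find_silent_targets",
    "distribution_report",
]


def _check_de_invariants(dge: pd.DataFrame, ids, want_direction: str) -> None:
    sub = dge.loc[list(ids)]
    bad = sub[(~sub["is_de"]) | (sub["direction"] != want_direction)]
    if len(bad):
        raise ValueError(
            f"DE invariant violated for {want_direction!r}: {list(bad.index[:5])}"
        )


def find_joint_signatures(
    dge_genes: pd.DataFrame,
    dge_srna: pd.DataFrame,
    links: pd.DataFrame,
    counts_genes: CountTable,
    counts_srna: CountTable,
    sheet_genes: SampleSheet,
    sheet_srna: SampleSheet,
) -> pd.DataFrame:
    """One row per gene that is DE-overexpressed with >= 1 linked DE-under
    sRNA cluster.

    ``per_direction_consistent`` records whether the sign of the hybrid shift
    holds separately in both cross directions (gene means up in PC vs PP and
    CP vs CC; every listed cluster down in both) — reported as a flag, never
    used as a filter. Columns: gene_id (index), cluster_ids (comma list),
    gene_log2fc, cluster_log2fcs, per_direction_consistent.
    """
    if links is None or not {"cluster_id", "gene_id"} <= set(links.columns):
        raise ValueError("links table with cluster_id/gene_id columns required")

    genes_over = set(dge_genes.index[(dge_genes["is_de"]) & (dge_genes["direction"] == "over")])
    srna_under = set(dge_srna.index[(dge_srna["is_de"]) & (dge_srna["direction"] == "under")])

    pairs = links[
        links["gene_id"].isin(genes_over) & links["cluster_id"].isin(srna_under)
    ]
    if pairs.empty:
        return pd.DataFrame(
            columns=["cluster_ids", "gene_log2fc", "cluster_log2fcs",
                     "per_direction_consistent"]
        ).rename_axis("gene_id")

    gm = cross_means(counts_genes, sheet_genes)
    sm = cross_means(counts_srna, sheet_srna)

    rows = []
    for gene_id, grp in pairs.groupby("gene_id"):
        cluster_ids = sorted(set(grp["cluster_id"]))
        _check_de_invariants(dge_genes, [gene_id], "over")
        _check_de_invariants(dge_srna, cluster_ids, "under")
        g = gm.loc[gene_id]
        gene_ok = (g["PC"] > g["PP"]) and (g["CP"] > g["CC"])
        s = sm.loc[cluster_ids]
        srna_ok = bool(((s["PC"] < s["PP"]) & (s["CP"] < s["CC"])).all())
        rows.append(
            {
                "gene_id": gene_id,
                "cluster_ids": ",".join(cluster_ids),
                "gene_log2fc": float(dge_genes.loc[gene_id, "log2fc"]),
                "cluster_log2fcs": ",".join(
                    f"{dge_srna.loc[c, 'log2fc']:.4f}" for c in cluster_ids
                ),
                "per_direction_consistent": bool(gene_ok and srna_ok),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def find_silent_targets(
    dge_srna: pd.DataFrame,
    links: pd.DataFrame,
    counts_genes: CountTable,
    detection_min: int = 1,
) -> pd.DataFrame:
    """Genes linked to >= 1 DE sRNA cluster whose total raw endosperm count
    is below ``detection_min`` (default 1, i.e. entirely undetected)."""
    de_clusters = set(dge_srna.index[dge_srna["is_de"]])
    if not de_clusters:
        return pd.DataFrame(columns=["cluster_ids", "total_count"]).rename_axis("gene_id")
    pairs = links[links["cluster_id"].isin(de_clusters)]
    totals = counts_genes.df.sum(axis=1)
    rows = []
    for gene_id, grp in pairs.groupby("gene_id"):
        total = int(totals.get(gene_id, 0))
        if total < detection_min:
            rows.append(
                {
                    "gene_id": gene_id,
                    "cluster_ids": ",".join(sorted(set(grp["cluster_id"]))),
                    "total_count": total,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "cluster_ids", "total_count"]
    ).set_index("gene_id")


def distribution_report(
    counts: CountTable,
    sheet: SampleSheet,
    de_set: list[str],
    significance: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normal-vs-hybrid CPM distribution comparison per maternal plant.

    For each maternal plant, the CPM values of the DE features in that
    plant's within-species libraries are compared with its hybrid libraries
    by the Wilcoxon rank-sum test. Returns (long_table, stats): the long
    table holds one row per (feature, library) for violin-style plotting;
    stats holds n, medians, the test and compact letter groups at the given
    significance level.
    """
    de_set = list(de_set)
    if not de_set:
        raise ValueError("de_set must be nonempty")
    table = cpm(counts)
    missing = [f for f in de_set if f not in table.index]
    if missing:
        raise ValueError(f"DE features absent from counts: {missing[:5]}")
    table = table.loc[de_set]

    meta = sheet.df.set_index("library_id")
    long_rows = []
    stats_rows = []
    for plant, plant_meta in meta.groupby("maternal_plant"):
        normal_libs = plant_meta.index[plant_meta["cross"].isin(["PP", "CC"])].tolist()
        hybrid_libs = plant_meta.index[plant_meta["cross"].isin(["PC", "CP"])].tolist()
        if not normal_libs or not hybrid_libs:
            raise ValueError(f"maternal plant {plant}: empty normal or hybrid group")
        normal_vals = table[normal_libs].to_numpy().ravel()
        hybrid_vals = table[hybrid_libs].to_numpy().ravel()
        stat, p = wilcoxon_compare(normal_vals, hybrid_vals)
        letters = ("a", "b") if p < significance else ("a", "a")
        stats_rows.append(
            {
                "maternal_plant": plant,
                "n_features": len(de_set),
                "median_normal_cpm": float(pd.Series(normal_vals).median()),
                "median_hybrid_cpm": float(pd.Series(hybrid_vals).median()),
                "statistic": stat,
                "p_value": p,
                "letter_normal": letters[0],
                "letter_hybrid": letters[1],
            }
        )
        for lib in normal_libs + hybrid_libs:
            seed_type = "normal" if lib in normal_libs else "hybrid"
            cross = plant_meta.loc[lib, "cross"]
            for fid, value in table[lib].items():
                long_rows.append((fid, lib, cross, plant, seed_type, float(value)))

    long_table = pd.DataFrame(
        long_rows,
        columns=["feature_id", "library_id", "cross", "maternal_plant",
                 "seed_type", "cpm"],
    )
    return long_table, pd.DataFrame(stats_rows).set_index("maternal_plant")
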