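"""Synthetic study generator with planted truth.

Emulates the crossing design of the wild-tomato hybrid seed failure study:
two within-species crosses (PP = S. peruvianum x S. peruvianum, CC =
S. chilense x S. chilense) and the two reciprocal hybrids (PC, CP; maternal
species first), with endosperm mRNA and whole-seed sRNA libraries replicated
per cross. It generates

* a gene annotation laid out so flank membership is unambiguous, including
  planted physical clusters of >= 3 same-annotation genes within 5 kb;
* an sRNA cluster annotation in which a configurable fraction of clusters is
  planted inside 2.5-kb gene flanks (each within reach of exactly one gene)
  and the rest far (> 2.5 kb) from every gene, plus a fraction tagged with
  structural RNA classes to exercise the pre-DE filter;
* negative-binomial count tables (Var = mu + alpha * mu^2) with planted
  differential expression, planted inheritance modes, planted joint
  sRNA-down/gene-up pairs, and planted silent target genes;
* truth tables for every planted property.

Planted-mode geometry keeps a guard margin of 0.5 log2 units beyond every
classification boundary so mode recovery is well-posed under noise, and the
per-cross means are arranged so that the hybrid-vs-normal contrast is exactly
the planted log2 fold change (0 for conserved/additive features, the small
dominance shift for dominant features, +/- the DE magnitude for planted-DE
features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CROSSES,
    CountTable,
    GeneFeature,
    SampleSheet,
    SrnaCluster,
    write_bed_clusters,
    write_counts,
    write_gff3,
)
from .modes import MODES

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "build_design",
    "simulate_annotation",
    "simulate_counts",
    "simulate_study",
    "write_study",
    "sample_nb",
]

GUARD_MARGIN = 0.5  # log2 units beyond each classification boundary

#: default inheritance-mode mix for features without a planted DE effect,
#: loosely shaped like genome-wide patterns in hybrid endosperm (conserved
#: expression dominating, species dominance next).
DEFAULT_MODE_PROPORTIONS: dict[str, float] = {
    "conserved": 0.60,
    "additive": 0.06,
    "dominant_P": 0.11,
    "dominant_C": 0.05,
    "overdominant": 0.10,
    "underdominant": 0.08,
}

STRUCTURAL_CHOICES = ("antisense", "rRNA", "tRNA", "snoRNA", "snRNA", "SRPRNA")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the simulator.

    The DE/mode geometry is derived from the class-specific thresholds:
    genes use mode threshold 1.0 and DE |log2FC| threshold 2.5; sRNA clusters
    use 0.5 and 2.0.
    """

    n_genes: int = 2000
    n_srna_clusters: int = 2000
    frac_de_genes: float = 0.07
    frac_de_srna: float = 0.012
    de_log2fc_magnitude: float = 4.0
    dispersion: float = 0.05  # NB alpha with Var = mu + alpha mu^2
    baseline_mean_log10_range: tuple[float, float] = (2.0, 3.0)
    mode_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    frac_flank_linked: float = 0.5
    n_planted_gene_clusters: int = 10
    gene_cluster_size: int = 3
    library_depth: int = 1_000_000
    seed: int = 0
    # fractions of DE features shifted upward in hybrids
    de_frac_up_genes: float = 0.66
    de_frac_up_srna: float = 0.10
    # planted integration structure
    frac_structural_rna: float = 0.08
    frac_joint_pairs: float = 0.015
    n_silent_targets: int = 5
    # design
    reps_mrna: int = 3
    reps_srna: int = 3
    n_chromosomes: int = 2
    # class-specific thresholds mirrored from the analysis defaults
    mode_threshold_genes: float = 1.0
    mode_threshold_srna: float = 0.5
    de_logfc_threshold_genes: float = 2.5
    de_logfc_threshold_srna: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "frac_de_genes",
            "frac_de_srna",
            "frac_flank_linked",
            "frac_structural_rna",
            "frac_joint_pairs",
            "de_frac_up_genes",
            "de_frac_up_srna",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.de_log2fc_magnitude <= 0 or self.dispersion < 0:
            raise ValueError("de_log2fc_magnitude must be > 0, dispersion >= 0")
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_proportions must sum to 1, got {total}")
        unknown = set(self.mode_proportions) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes in mode_proportions: {sorted(unknown)}")
        lo, hi = self.baseline_mean_log10_range
        if not lo < hi:
            raise ValueError("baseline_mean_log10_range must be (low, high)")
        for assay in ("genes", "srna"):
            t = getattr(self, f"mode_threshold_{assay}")
            de_t = getattr(self, f"de_logfc_threshold_{assay}")
            need = max(t + GUARD_MARGIN, de_t + GUARD_MARGIN)
            if self.de_log2fc_magnitude < need:
                raise ValueError(
                    f"de_log2fc_magnitude {self.de_log2fc_magnitude} too small for "
                    f"{assay} thresholds; need >= {need}"
                )


def build_design(reps_mrna: int = 3, reps_srna: int = 3) -> tuple[SampleSheet, SampleSheet]:
    """Sample sheets for the two assays.

    Maternal plants follow the study's usage: the S. peruvianum mother for PP
    and PC, the S. chilense mother for CC and CP.
    """
    mother = {"PP": "1616A", "PC": "1616A", "CC": "4329B", "CP": "4329B"}
    rows_mrna = [
        (f"mrna_{cross}_r{r}", cross, mother[cross], r, "endosperm-mRNA")
        for cross in CROSSES
        for r in range(1, reps_mrna + 1)
    ]
    rows_srna = [
        (f"srna_{cross}_r{r}", cross, mother[cross], r, "seed-sRNA")
        for cross in CROSSES
        for r in range(1, reps_srna + 1)
    ]
    cols = ["library_id", "cross", "maternal_plant", "replicate", "assay"]
    return (
        SampleSheet(pd.DataFrame(rows_mrna, columns=cols)),
        SampleSheet(pd.DataFrame(rows_srna, columns=cols)),
    )


# ---------------------------------------------------------------------------
# Annotation geometry
# ---------------------------------------------------------------------------

_GENE_LEN = (1500, 4000)
_INTRA_CLUSTER_GAP = (800, 4000)   # <= 5 kb so planted runs chain
_INTER_UNIT_GAP = (8000, 12000)    # > 2 * flank so flanks never overlap
_CLUSTER_LEN = (80, 400)
_FLANK = 2500
_GAP_MARGIN = 100


def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneFeature], list[SrnaCluster], pd.DataFrame, pd.DataFrame]:
    """Lay out genes and sRNA clusters with unambiguous flank geometry.

    Returns (genes, clusters, gene_truth, cluster_truth). gene_truth carries
    ``in_gene_cluster`` (planted physical-cluster label or ''); cluster_truth
    carries ``linked_gene`` (host gene for flank-planted clusters, else ''),
    ``link_distance`` and ``structural`` flags.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_cluster_genes = cfg.n_planted_gene_clusters * cfg.gene_cluster_size
    if cfg.gene_cluster_size < 3:
        raise ValueError("gene_cluster_size must be >= 3 to form a cluster")
    if n_cluster_genes > cfg.n_genes:
        raise ValueError(
            f"{cfg.n_planted_gene_clusters} planted clusters x "
            f"{cfg.gene_cluster_size} genes exceed n_genes={cfg.n_genes}"
        )

    n_singletons = cfg.n_genes - n_cluster_genes
    units: list[tuple[str, int]] = [
        ("run", i) for i in range(cfg.n_planted_gene_clusters)
    ] + [("single", i) for i in range(n_singletons)]
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    genes: list[GeneFeature] = []
    gene_cluster_of: dict[str, str] = {}
    singleton_ids: list[str] = []
    # inter-unit gaps available for far-from-gene cluster placement
    free_gaps: list[tuple[str, int, int]] = []

    per_chrom = np.array_split(np.arange(len(units)), cfg.n_chromosomes)
    gid = 0
    for ci, unit_idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(*_INTER_UNIT_GAP))
        for ui in unit_idx:
            kind, label_i = units[ui]
            n_in_unit = cfg.gene_cluster_size if kind == "run" else 1
            for k in range(n_in_unit):
                if k > 0:
                    pos += int(rng.integers(*_INTRA_CLUSTER_GAP))
                length = int(rng.integers(*_GENE_LEN))
                gene_id = f"g{gid:06d}"
                gid += 1
                if kind == "run":
                    label = f"FAM{label_i:03d}"
                    gene_cluster_of[gene_id] = label
                else:
                    label = f"ANN_{gene_id}"
                    singleton_ids.append(gene_id)
                genes.append(
                    GeneFeature(
                        chrom=chrom,
                        start=pos,
                        end=pos + length,
                        gene_id=gene_id,
                        strand="+" if rng.random() < 0.5 else "-",
                        annotation_label=label,
                        biotype="protein_coding",
                    )
                )
                pos += length
            gap = int(rng.integers(*_INTER_UNIT_GAP))
            free_gaps.append((chrom, pos, pos + gap))
            pos += gap

    # --- sRNA clusters ---
    n_linked = int(round(cfg.frac_flank_linked * cfg.n_srna_clusters))
    n_far = cfg.n_srna_clusters - n_linked
    if not singleton_ids and n_linked:
        raise ValueError("no isolated genes available to host flank-linked clusters")
    usable_gaps = [
        g for g in free_gaps if (g[2] - g[1]) >= 2 * (_FLANK + _GAP_MARGIN) + _CLUSTER_LEN[1]
    ]
    if n_far > len(usable_gaps):
        raise ValueError(
            f"geometry infeasible: {n_far} far clusters requested but only "
            f"{len(usable_gaps)} inter-gene gaps are wide enough"
        )

    gene_by_id = {g.gene_id: g for g in genes}
    placements: list[tuple[str, int, int, str, int]] = []  # chrom,start,end,host,dist

    hosts = rng.choice(np.array(singleton_ids), size=n_linked, replace=True)
    for host_id in hosts:
        host = gene_by_id[str(host_id)]
        length = int(rng.integers(*_CLUSTER_LEN))
        u = rng.random()
        if u < 0.30:  # inside the gene body
            start = int(rng.integers(host.start, host.end - length))
            dist = 0
        elif u < 0.65:  # upstream flank (chromosome sense)
            dist = int(rng.integers(10, _FLANK - length - 10))
            start = host.start - dist - length
        else:  # downstream flank
            dist = int(rng.integers(10, _FLANK - length - 10))
            start = host.end + dist
        placements.append((host.chrom, start, start + length, str(host_id), dist))

    far_gap_idx = rng.choice(len(usable_gaps), size=n_far, replace=False)
    for gi in far_gap_idx:
        chrom, lo, hi = usable_gaps[int(gi)]
        length = int(rng.integers(*_CLUSTER_LEN))
        lo_ok = lo + _FLANK + _GAP_MARGIN
        hi_ok = hi - _FLANK - _GAP_MARGIN - length
        start = int(rng.integers(lo_ok, hi_ok + 1))
        placements.append((chrom, start, start + length, "", -1))

    order = sorted(range(len(placements)), key=lambda i: (placements[i][0], placements[i][1]))
    dicer = rng.choice(
        np.array(["24", "21", "22", "miRNA", "none"]),
        size=len(placements),
        p=[0.87, 0.025, 0.025, 0.05, 0.03],
    )
    n_structural = int(round(cfg.frac_structural_rna * len(placements)))
    structural_idx = set(
        rng.choice(len(placements), size=n_structural, replace=False).tolist()
    )

    clusters: list[SrnaCluster] = []
    truth_rows = []
    for rank, i in enumerate(order):
        chrom, start, end, host, dist = placements[i]
        cid = f"sc{rank:06d}"
        if rank in structural_idx:
            rna_class = str(rng.choice(np.array(STRUCTURAL_CHOICES)))
        elif dicer[i] == "miRNA":
            rna_class = "miRNA_annotated"
        else:
            rna_class = "clean"
        clusters.append(
            SrnaCluster(chrom, start, end, cid, str(dicer[i]), rna_class)
        )
        truth_rows.append((cid, host, dist, rna_class in STRUCTURAL_CHOICES))

    cluster_truth = pd.DataFrame(
        truth_rows, columns=["cluster_id", "linked_gene", "link_distance", "structural"]
    ).set_index("cluster_id")
    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "in_gene_cluster": [gene_cluster_of.get(g.gene_id, "") for g in genes],
        }
    ).set_index("gene_id")
    return genes, clusters, gene_truth, cluster_truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def sample_nb(
    rng: np.random.Generator, mean: np.ndarray, alpha: float, size=None
) -> np.ndarray:
    """Draw NB counts with Var = mean + alpha * mean^2 (Poisson when
    alpha ~ 0); zero means yield zero counts."""
    mean = np.asarray(mean, dtype=float)
    if size is not None:
        mean = np.broadcast_to(mean, size)
    if alpha < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(r, p)


def _mode_geometry(assay: str, cfg: SimConfig) -> dict[str, float]:
    t = cfg.mode_threshold_genes if assay == "genes" else cfg.mode_threshold_srna
    de_t = (
        cfg.de_logfc_threshold_genes if assay == "genes" else cfg.de_logfc_threshold_srna
    )
    return {
        "t": t,
        # parental half-separation for additive features (|r| = a > t + guard)
        "additive": t + GUARD_MARGIN + 0.5,
        # dominance shift d: near parent at r = 0, far parent at 2d > t + guard
        "dominant": (t + GUARD_MARGIN) / 2.0 + 0.25,
        # transgressive shift for features not planted as DE: beyond the mode
        # boundary but >= guard below the DE threshold
        "transgressive": min(t + GUARD_MARGIN + 0.5, de_t - GUARD_MARGIN),
    }


def simulate_counts(
    cfg: SimConfig,
    sheet: SampleSheet,
    assay: str,
    feature_ids: list[str],
    rng: np.random.Generator | None = None,
    forced_de: Mapping[str, int] | None = None,
    forced_zero: set[str] | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Draw a count table with planted DE effects and inheritance modes.

    ``forced_de`` maps feature ids to +1/-1 hybrid shifts (used to coordinate
    joint sRNA/gene pairs); ``forced_zero`` features get zero means in every
    cross (silent targets). Returns the counts and a truth table.
    """
    if assay not in ("genes", "srna"):
        raise ValueError("assay must be 'genes' or 'srna'")
    sheet.require_crosses(CROSSES, min_reps=2)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    forced_de = dict(forced_de or {})
    forced_zero = set(forced_zero or set())
    if forced_de.keys() & forced_zero:
        raise ValueError("a feature cannot be both forced-DE and forced-zero")

    n = len(feature_ids)
    id_pos = {f: i for i, f in enumerate(feature_ids)}
    geo = _mode_geometry(assay, cfg)
    frac_de = cfg.frac_de_genes if assay == "genes" else cfg.frac_de_srna
    frac_up = cfg.de_frac_up_genes if assay == "genes" else cfg.de_frac_up_srna

    lo, hi = cfg.baseline_mean_log10_range
    log2_base = np.log2(10.0 ** rng.uniform(lo, hi, size=n))

    # --- choose DE features; forced ones always included ---
    de_sign = np.zeros(n, dtype=int)
    for fid, sign in forced_de.items():
        de_sign[id_pos[fid]] = 1 if sign > 0 else -1
    n_de_target = int(round(frac_de * n))
    free = np.array(
        [
            i
            for i, f in enumerate(feature_ids)
            if de_sign[i] == 0 and f not in forced_zero
        ]
    )
    n_extra = max(n_de_target - int(np.count_nonzero(de_sign)), 0)
    if n_extra > 0 and free.size:
        chosen = rng.choice(free, size=min(n_extra, free.size), replace=False)
        signs = np.where(rng.random(chosen.size) < frac_up, 1, -1)
        de_sign[chosen] = signs
    is_de = de_sign != 0

    # --- modes ---
    mode_names = np.array(MODES)
    probs = np.array([cfg.mode_proportions.get(m, 0.0) for m in MODES])
    modes = rng.choice(mode_names, size=n, p=probs / probs.sum())
    modes[de_sign > 0] = "overdominant"
    modes[de_sign < 0] = "underdominant"
    zero_mask = np.array([f in forced_zero for f in feature_ids])
    modes[zero_mask] = "conserved"
    is_de = is_de & ~zero_mask

    # --- per-cross log2 means ---
    lm = {c: log2_base.copy() for c in CROSSES}
    parent_high = np.where(rng.random(n) < 0.5, 1.0, -1.0)  # which parent is high
    a, d, m_tr = geo["additive"], geo["dominant"], geo["transgressive"]
    for i in range(n):
        mode = modes[i]
        s = parent_high[i]
        if mode == "additive":
            lm["PP"][i] += s * a
            lm["CC"][i] -= s * a
        elif mode == "dominant_P":
            lm["PP"][i] += s * d
            lm["CC"][i] -= s * d
            lm["PC"][i] += s * d
            lm["CP"][i] += s * d
        elif mode == "dominant_C":
            lm["PP"][i] += s * d
            lm["CC"][i] -= s * d
            lm["PC"][i] -= s * d
            lm["CP"][i] -= s * d
        elif mode in ("overdominant", "underdominant"):
            shift = cfg.de_log2fc_magnitude if is_de[i] else m_tr
            sign = 1.0 if mode == "overdominant" else -1.0
            lm["PC"][i] += sign * shift
            lm["CP"][i] += sign * shift

    mu = np.column_stack([2.0 ** lm[c] for c in CROSSES])
    mu[zero_mask] = 0.0
    true_log2fc = np.where(
        zero_mask,
        0.0,
        0.5 * (lm["PC"] + lm["CP"]) - 0.5 * (lm["PP"] + lm["CC"]),
    )

    # --- library means scaled to the target depth, then NB draws ---
    cross_col = {c: j for j, c in enumerate(CROSSES)}
    expected_colsum = mu.sum(axis=0)
    counts = np.zeros((n, len(sheet.library_ids)), dtype=np.int64)
    for j, (lib, cross) in enumerate(zip(sheet.library_ids, sheet.crosses)):
        depth = cfg.library_depth * rng.uniform(0.7, 1.3)
        col = cross_col[cross]
        scale = depth / expected_colsum[col] if expected_colsum[col] > 0 else 0.0
        counts[:, j] = sample_nb(rng, mu[:, col] * scale, cfg.dispersion)

    table = CountTable(
        pd.DataFrame(
            counts,
            index=pd.Index(feature_ids, name="feature_id"),
            columns=sheet.library_ids,
        )
    )
    truth = pd.DataFrame(
        {
            "true_de": is_de,
            "true_log2fc": true_log2fc,
            "true_mode_PC": modes,
            "true_mode_CP": modes,
            "mu_PP": mu[:, cross_col["PP"]],
            "mu_CC": mu[:, cross_col["CC"]],
            "mu_PC": mu[:, cross_col["PC"]],
            "mu_CP": mu[:, cross_col["CP"]],
            "forced_zero": zero_mask,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimConfig
    genes: list[GeneFeature]
    clusters: list[SrnaCluster]
    sheet_genes: SampleSheet
    sheet_srna: SampleSheet
    counts_genes: CountTable
    counts_srna: CountTable
    truth_genes: pd.DataFrame
    truth_srna: pd.DataFrame


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate the full, mutually consistent study under one seed.

    Joint pairs are planted among clean flank-linked clusters: the host gene
    is planted DE-up and the cluster DE-down (the concomitant signature).
    Silent targets are genes zeroed in every library whose linked cluster is
    still planted DE-down.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, clusters, gene_truth, cluster_truth = simulate_annotation(cfg, rng)
    sheet_genes, sheet_srna = build_design(cfg.reps_mrna, cfg.reps_srna)

    linked_clean = cluster_truth[
        (cluster_truth["linked_gene"] != "") & (~cluster_truth["structural"])
    ]
    n_joint = int(round(cfg.frac_joint_pairs * len(linked_clean)))
    joint_cluster_ids = list(
        rng.choice(linked_clean.index.to_numpy(), size=n_joint, replace=False)
    ) if n_joint else []
    joint_gene_ids = sorted(
        {str(linked_clean.loc[c, "linked_gene"]) for c in joint_cluster_ids}
    )

    remaining = linked_clean.drop(index=joint_cluster_ids)
    remaining = remaining[~remaining["linked_gene"].isin(set(joint_gene_ids))]
    n_silent = min(cfg.n_silent_targets, len(remaining))
    silent_cluster_ids = list(
        rng.choice(remaining.index.to_numpy(), size=n_silent, replace=False)
    ) if n_silent else []
    silent_gene_ids = sorted(
        {str(remaining.loc[c, "linked_gene"]) for c in silent_cluster_ids}
    )

    forced_de_genes = {g: +1 for g in joint_gene_ids}
    forced_de_srna = {c: -1 for c in joint_cluster_ids}
    forced_de_srna.update({c: -1 for c in silent_cluster_ids})

    counts_genes, truth_g = simulate_counts(
        cfg,
        sheet_genes,
        assay="genes",
        feature_ids=[g.gene_id for g in genes],
        rng=rng,
        forced_de=forced_de_genes,
        forced_zero=set(silent_gene_ids),
    )
    counts_srna, truth_s = simulate_counts(
        cfg,
        sheet_srna,
        assay="srna",
        feature_ids=[c.cluster_id for c in clusters],
        rng=rng,
        forced_de=forced_de_srna,
    )

    truth_g = truth_g.join(gene_truth)
    truth_g["is_silent_target"] = truth_g.index.isin(set(silent_gene_ids))
    truth_g["joint_pair_gene"] = truth_g.index.isin(set(joint_gene_ids))
    truth_s = truth_s.join(cluster_truth)
    truth_s["joint_pair_cluster"] = truth_s.index.isin(set(joint_cluster_ids))

    return SimulatedStudy(
        config=cfg,
        genes=genes,
        clusters=clusters,
        sheet_genes=sheet_genes,
        sheet_srna=sheet_srna,
        counts_genes=counts_genes,
        counts_srna=counts_srna,
        truth_genes=truth_g,
        truth_srna=truth_s,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard file set: genes.gff3, srna_clusters.bed, counts and
    sample TSVs, and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes_gff3": out / "genes.gff3",
        "clusters_bed": out / "srna_clusters.bed",
        "counts_genes": out / "counts_genes.tsv",
        "counts_srna": out / "counts_srna.tsv",
        "samples": out / "samples.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_srna": out / "truth_srna.tsv",
    }
    write_gff3(study.genes, paths["genes_gff3"])
    write_bed_clusters(study.clusters, paths["clusters_bed"])
    write_counts(study.counts_genes, paths["counts_genes"])
    write_counts(study.counts_srna, paths["counts_srna"])
    pd.concat([study.sheet_genes.df, study.sheet_srna.df]).to_csv(
        paths["samples"], sep="\t", index=False
    )
    study.truth_genes.to_csv(paths["truth_genes"], sep="\t")
    study.truth_srna.to_csv(paths["truth_srna"], sep="\t")
    return paths
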