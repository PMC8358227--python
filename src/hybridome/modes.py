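"""Inheritance-mode classification of hybrid expression.

Each feature's expression in a hybrid cross (PC or CP) is compared with both
within-species crosses through two log2 ratios,

    r_P = log2((mu_H + eps) / (mu_PP + eps)),
    r_C = log2((mu_H + eps) / (mu_CC + eps)),

where mu are per-cross means of size-factor-normalized counts and eps a
pseudocount. With threshold t (1.0 log2 units for genes, 0.5 for sRNA
clusters) the plane partitions exhaustively and exclusively into six modes:

    |r_P| <= t and |r_C| <= t        -> conserved
    |r_P| <= t and |r_C| >  t        -> dominant_P  (S. peruvianum-like)
    |r_C| <= t and |r_P| >  t        -> dominant_C  (S. chilense-like)
    both > t, r_P > 0 and r_C > 0    -> overdominant
    both > t, r_P < 0 and r_C < 0    -> underdominant
    both > t, opposite signs         -> additive (hybrid between parents)

Boundary values |r| = t count as "near" (the conserved/dominant side).
Dominance is labeled by species, not by parental role, so reciprocal hybrids
can be compared directly (maternal dominance = dominant_P in PC, dominant_C
in CP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, SampleSheet, HYBRID_CROSSES
from .dge import cross_means

__all__ = [
    "MODES",
    "ModeParams",
    "classify_mode",
    "classify_modes",
    "classify_all",
    "mode_summary",
    "GENE_MODE_PARAMS",
    "SRNA_MODE_PARAMS",
]

MODES = (
    "conserved",
    "additive",
    "dominant_P",
    "dominant_C",
    "overdominant",
    "underdominant",
)


@dataclass(frozen=True)
class ModeParams:
    """threshold in log2 units (1.0 genes / 0.5 sRNA); pseudocount added to
    normalized means before the log ratios."""

    threshold: float = 1.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


GENE_MODE_PARAMS = ModeParams(threshold=1.0)
SRNA_MODE_PARAMS = ModeParams(threshold=0.5)


def classify_mode(r_P: float, r_C: float, t: float) -> str:
    """Classify one (r_P, r_C) pair; total function over finite reals."""
    near_p = abs(r_P) <= t
    near_c = abs(r_C) <= t
    if near_p and near_c:
        return "conserved"
    if near_p:
        return "dominant_P"
    if near_c:
        return "dominant_C"
    if r_P > 0 and r_C > 0:
        return "overdominant"
    if r_P < 0 and r_C < 0:
        return "underdominant"
    return "additive"


def classify_modes(r_P: np.ndarray, r_C: np.ndarray, t: float) -> np.ndarray:
    """Vectorized :func:`classify_mode`."""
    r_P = np.asarray(r_P, dtype=float)
    r_C = np.asarray(r_C, dtype=float)
    near_p = np.abs(r_P) <= t
    near_c = np.abs(r_C) <= t
    out = np.where(
        near_p & near_c,
        "conserved",
        np.where(
            near_p,
            "dominant_P",
            np.where(
                near_c,
                "dominant_C",
                np.where(
                    (r_P > 0) & (r_C > 0),
                    "overdominant",
                    np.where((r_P < 0) & (r_C < 0), "underdominant", "additive"),
                ),
            ),
        ),
    )
    return out.astype(object)


def classify_all(
    counts: CountTable,
    sheet: SampleSheet,
    params: ModeParams,
    which_hybrid: str,
    subset: list[str] | None = None,
) -> pd.DataFrame:
    """Mode-call every feature for one hybrid direction.

    Classification runs on the full feature set regardless of DE status;
    pass ``subset`` to restrict (e.g. to DE features). Returns a DataFrame
    indexed by feature id with columns hybrid, mode, r_P, r_C, mu_PP,
    mu_CC, mu_H.
    """
    if which_hybrid not in HYBRID_CROSSES:
        raise ValueError(f"which_hybrid must be one of {HYBRID_CROSSES}")
    sheet.require_crosses(("PP", "CC", which_hybrid), min_reps=1)
    means = cross_means(counts, sheet)
    if subset is not None:
        means = means.loc[list(subset)]
    eps = params.pseudocount
    mu_pp = means["PP"].to_numpy()
    mu_cc = means["CC"].to_numpy()
    mu_h = means[which_hybrid].to_numpy()
    r_p = np.log2((mu_h + eps) / (mu_pp + eps))
    r_c = np.log2((mu_h + eps) / (mu_cc + eps))
    return pd.DataFrame(
        {
            "hybrid": which_hybrid,
            "mode": classify_modes(r_p, r_c, params.threshold),
            "r_P": r_p,
            "r_C": r_c,
            "mu_PP": mu_pp,
            "mu_CC": mu_cc,
            "mu_H": mu_h,
        },
        index=means.index.rename("feature_id"),
    )


def mode_summary(
    calls: pd.DataFrame, subset: list[str] | None = None
) -> pd.DataFrame:
    """Per-hybrid-direction proportions of the six modes (stacked-bar table).

    ``calls`` may hold one or both hybrid directions (concatenated frames
    from :func:`classify_all`); proportions sum to 1 within each direction.
    """
    if calls.empty:
        raise ValueError("no mode calls to summarize")
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("empty feature subset")
        calls = calls.loc[calls.index.isin(set(subset))]
        if calls.empty:
            raise ValueError("feature subset matches no mode calls")
    rows = []
    for hybrid, grp in calls.groupby("hybrid"):
        props = grp["mode"].value_counts(normalize=True)
        rows.append(
            {"hybrid": hybrid, "n": len(grp)}
            | {mode: float(props.get(mode, 0.0)) for mode in MODES}
        )
    return pd.DataFrame(rows).set_index("hybrid")
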