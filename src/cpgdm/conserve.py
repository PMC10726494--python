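"""Pairwise cross-strain methylation conservation statistics.

Two complementary measures per 2-kb segment distinguish how methylation is
conserved between two strains:

* the **same-state probability**: the fraction of homologous CpG sites that
  are in the same state (both methylated or both unmethylated) — high when
  the *identity* of methylated sites is conserved;
* the **methylated-count ratio**: min/max of the two strains' methylated-site
  counts — high when the *amount* of methylation is conserved, regardless of
  which sites carry it.

Sites with no call in either strain of a pair are excluded from that pair's
comparison. Statistics are pooled by density bin by concatenating the member
segments' site vectors, not by averaging per-segment values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: column vocabulary of the pooled-by-density output table
SUM_BY_DENSITY_COLUMNS = [
    "seg", "s1", "s2", "CG.all", "CG.me.0", "CG.me.1",
    "mutant.me.0", "mutant.me.1", "prob", "ratio", "s1.me", "s2.me",
]


@dataclass(frozen=True)
class PropOccurrence:
    """Joint state proportions for two equal-length binary call vectors."""

    prop_p_a: float  # fraction methylated in A
    prop_p_b: float
    prop_q_a: float  # fraction unmethylated in A
    prop_q_b: float
    prop_pp: float  # fraction methylated in both at the same site
    prop_qq: float  # fraction unmethylated in both at the same site

    @property
    def same_state(self) -> float:
        return self.prop_pp + self.prop_qq


def prop_occurrence(calls_a, calls_b) -> PropOccurrence:
    """Joint-state proportions of two binary vectors (NA removed beforehand).

    Any truthy value counts as methylated (1), falsy as unmethylated (0).
    All six proportions use the common vector length as denominator, so
    ``prop_pp + prop_qq`` is the same-state probability.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty call vector")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = (a.astype(float) != 0).astype(int)
    b = (b.astype(float) != 0).astype(int)
    n = a.size
    return PropOccurrence(
        prop_p_a=float(np.sum(a == 1)) / n,
        prop_p_b=float(np.sum(b == 1)) / n,
        prop_q_a=float(np.sum(a == 0)) / n,
        prop_q_b=float(np.sum(b == 0)) / n,
        prop_pp=float(np.sum((a == 1) & (b == 1))) / n,
        prop_qq=float(np.sum((a == 0) & (b == 0))) / n,
    )


def methylated_count_ratio(n1: int, n2: int) -> float:
    """min/max of two methylated-site counts, bounded in [0, 1].

    The larger count is the denominator; 1 means equal totals. Undefined
    (NaN) when both counts are zero — such segments are excluded from pooled
    ratios.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("negative methylated count")
    if n1 == 0 and n2 == 0:
        return float("nan")
    return min(n1, n2) / max(n1, n2)


def pairwise_segment_stats(
    sites_with_calls: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    mutated_col: str | None = None,
) -> pd.DataFrame:
    """Per-segment conservation statistics for one strain pair.

    Uses only sites callable in *both* strains. Columns: seg_id, n_sites,
    n1, n2 (methylated counts), prop_pp, prop_qq, same_state, ratio, and
    mutant counts split by strain-A methylation state when ``mutated_col``
    names a boolean column.
    """
    ca = sites_with_calls[f"{strain_a}.call"]
    cb = sites_with_calls[f"{strain_b}.call"]
    ok = ca.notna() & cb.notna()
    sub = sites_with_calls[ok].copy()
    sub["_a"] = sub[f"{strain_a}.call"].astype(int)
    sub["_b"] = sub[f"{strain_b}.call"].astype(int)
    sub["_pp"] = ((sub["_a"] == 1) & (sub["_b"] == 1)).astype(int)
    sub["_qq"] = ((sub["_a"] == 0) & (sub["_b"] == 0)).astype(int)
    if mutated_col is not None:
        sub["_mut1"] = (sub[mutated_col] & (sub["_a"] == 1)).astype(int)
        sub["_mut0"] = (sub[mutated_col] & (sub["_a"] == 0)).astype(int)
    else:
        sub["_mut1"] = 0
        sub["_mut0"] = 0
    grp = sub.groupby("seg_id")
    out = grp.agg(
        n_sites=("_a", "size"),
        n1=("_a", "sum"),
        n2=("_b", "sum"),
        n_pp=("_pp", "sum"),
        n_qq=("_qq", "sum"),
        mutant_me_1=("_mut1", "sum"),
        mutant_me_0=("_mut0", "sum"),
    ).reset_index()
    out["prop_pp"] = out["n_pp"] / out["n_sites"]
    out["prop_qq"] = out["n_qq"] / out["n_sites"]
    out["same_state"] = out["prop_pp"] + out["prop_qq"]
    out["ratio"] = [
        methylated_count_ratio(int(r.n1), int(r.n2)) for r in out.itertuples()
    ]
    return out


def aggregate_by_density(
    segment_stats: pd.DataFrame,
    segments: pd.DataFrame,
    strain_a: str,
    strain_b: str,
) -> pd.DataFrame:
    """Pool pairwise statistics per density bin by recomputing them on the
    concatenation of all member segments' sites.

    Because the same-state probability and the joint proportions are site
    averages, pooling reduces to site-count-weighted sums; the pooled ratio
    is min/max over the bin's total methylated counts. Output follows the
    pairwise-summary vocabulary (``seg`` = density bin, ``prob`` = same-state
    probability): seg, s1, s2, CG.all, CG.me.0, CG.me.1, mutant.me.0,
    mutant.me.1, prob, ratio, s1.me, s2.me.  Empty bins are omitted.
    """
    merged = segment_stats.merge(
        segments[["seg_id", "density_bin"]], on="seg_id", how="inner"
    )
    rows = []
    for bin_value, grp in merged.groupby("density_bin"):
        n_all = int(grp["n_sites"].sum())
        if n_all == 0:
            continue
        n1 = int(grp["n1"].sum())
        n2 = int(grp["n2"].sum())
        n_pp = int(grp["n_pp"].sum())
        n_qq = int(grp["n_qq"].sum())
        rows.append(
            {
                "seg": bin_value,
                "s1": strain_a,
                "s2": strain_b,
                "CG.all": n_all,
                # methylated / unmethylated site totals keyed to strain 1
                "CG.me.1": n1,
                "CG.me.0": n_all - n1,
                "mutant.me.1": int(grp["mutant_me_1"].sum()),
                "mutant.me.0": int(grp["mutant_me_0"].sum()),
                "prob": (n_pp + n_qq) / n_all,
                "ratio": methylated_count_ratio(n1, n2),
                "s1.me": n1,
                "s2.me": n2,
            }
        )
    return pd.DataFrame(rows, columns=SUM_BY_DENSITY_COLUMNS)


def conservation_curves(
    sites_with_calls: pd.DataFrame,
    segments: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    mutated_col: str | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: per-segment stats then density pooling."""
    stats = pairwise_segment_stats(sites_with_calls, strain_a, strain_b, mutated_col)
    return aggregate_by_density(stats, segments, strain_a, strain_b)
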