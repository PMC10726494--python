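"""Genome segmentation, CpG density, methylation calling, and density curves.

The genome is tiled into fixed windows (2 kb by default, the size that
captures regions of clustered methylation).  Per window we compute the CpG
sequence density (CpG dinucleotides per kilobase, irrespective of
methylation), call per-site methylation per strain, equalise coverage
between strains by thinning, and pool call statistics by integer density
bin to produce the methylation-fraction and mutation-fraction curves.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methio import site_table_strains

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 2000
MIN_COVERAGE = 5
MIN_METH_FRACTION = 0.10


# ---------------------------------------------------------------------------
# segmentation & density
# ---------------------------------------------------------------------------


def segment_genome(
    chrom_sizes: Mapping[str, int], window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Tile each chromosome into non-overlapping ``window``-bp segments.

    A trailing partial window is emitted and flagged ``partial``; its density
    downstream uses its true length. Columns: chrom, start, end, seg_id,
    partial (intervals 0-based half-open).
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    rows = []
    seg_id = 0
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, window):
            end = min(start + window, size)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "seg_id": seg_id,
                    "partial": end - start < window,
                }
            )
            seg_id += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "seg_id", "partial"])


def cpg_density(start: int, end: int, cpg_positions: Sequence[int]) -> float:
    """CpGs per kilobase within [start, end): count of 1-based C positions
    with ``start <= pos - 1 < end``, divided by the true segment length in kb."""
    pos = np.asarray(cpg_positions)
    n = int(np.count_nonzero((pos - 1 >= start) & (pos - 1 < end)))
    return n / ((end - start) / 1000.0)


def assign_sites_to_segments(
    sites: pd.DataFrame, segments: pd.DataFrame
) -> pd.DataFrame:
    """Annotate each site row with its segment's seg_id; sites outside every
    segment get seg_id -1 (counted and logged by callers)."""
    out = sites.copy()
    out["seg_id"] = -1
    for chrom, seg_chr in segments.groupby("chrom", sort=False):
        mask = out["chrom"] == chrom
        if not mask.any():
            continue
        pos0 = out.loc[mask, "pos"].to_numpy() - 1  # 0-based
        starts = seg_chr["start"].to_numpy()
        ends = seg_chr["end"].to_numpy()
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        seg_ids = np.where(ok, seg_chr["seg_id"].to_numpy()[np.clip(idx, 0, None)], -1)
        out.loc[mask, "seg_id"] = seg_ids
    return out


def annotate_segment_density(
    segments: pd.DataFrame, cpg_sites: pd.DataFrame, bin_width: int = 1
) -> pd.DataFrame:
    """Add cpg_count, density (CpG/kb on true length) and integer density_bin
    (floor of density / bin_width times bin_width) to a segment table.

    ``cpg_sites`` needs chrom and 1-based pos columns (reference CpGs,
    regardless of methylation).
    """
    assigned = assign_sites_to_segments(cpg_sites[["chrom", "pos"]], segments)
    counts = assigned[assigned["seg_id"] >= 0].groupby("seg_id").size()
    out = segments.copy()
    out["cpg_count"] = out["seg_id"].map(counts).fillna(0).astype(int)
    out["density"] = out["cpg_count"] / ((out["end"] - out["start"]) / 1000.0)
    out["density_bin"] = (out["density"] // bin_width).astype(int) * bin_width
    return out


# ---------------------------------------------------------------------------
# methylation calling
# ---------------------------------------------------------------------------


def call_methylation(
    mc, cov, min_cov: int = MIN_COVERAGE, min_frac: float = MIN_METH_FRACTION
):
    """Call per-site methylation: NaN (no call) if coverage < ``min_cov``;
    methylated (1.0) if mc/cov >= ``min_frac``; else unmethylated (0.0).

    A site with adequate coverage but no evidence of methylation is regarded
    as not methylated, not as missing. Vectorised over arrays; scalar in,
    scalar out.
    """
    mc_a = np.asarray(mc, dtype=float)
    cov_a = np.asarray(cov, dtype=float)
    if np.any(mc_a > cov_a):
        raise ValueError("mc exceeds cov")
    if np.any(mc_a < 0):
        raise ValueError("negative mc")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cov_a > 0, mc_a / np.where(cov_a > 0, cov_a, 1), 0.0)
    calls = np.where(cov_a < min_cov, np.nan, (frac >= min_frac).astype(float))
    if np.isscalar(mc) and np.isscalar(cov):
        return float(calls)
    return calls


def add_calls(
    sites: pd.DataFrame,
    strains: Sequence[str] | None = None,
    min_cov: int = MIN_COVERAGE,
    min_frac: float = MIN_METH_FRACTION,
) -> pd.DataFrame:
    """Add a ``<strain>.call`` column per strain (1.0 / 0.0 / NaN)."""
    strains = strains or site_table_strains(sites)
    out = sites.copy()
    for s in strains:
        out[f"{s}.call"] = call_methylation(
            out[f"{s}.mc"].to_numpy(), out[f"{s}.cov"].to_numpy(), min_cov, min_frac
        )
    return out


# ---------------------------------------------------------------------------
# coverage downsampling
# ---------------------------------------------------------------------------


def downsample_pair(
    sites: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    seed: int,
    seg_col: str = "seg_id",
) -> pd.DataFrame:
    """Equalise a strain pair's coverage per segment by thinning methylated reads.

    In each segment the strain with the larger total read count has each of
    its methylated reads kept independently with probability
    (lower total cov)/(higher total cov), so its expected methylated total is
    scaled by the coverage ratio; the lower-coverage strain is untouched.
    Bernoulli thinning of individual reads makes the per-site thinned count
    Binomial(mc, ratio).  Returns a copy with adjusted ``<strain>.mc`` columns
    (coverage columns are left as observed). Seeded and reproducible;
    segments with both totals zero are returned unchanged.
    """
    rng = np.random.default_rng(seed)
    out = sites.sort_values([seg_col], kind="stable").copy()
    tot = out.groupby(seg_col)[[f"{strain_a}.cov", f"{strain_b}.cov"]].transform("sum")
    tot_a = tot[f"{strain_a}.cov"].to_numpy(dtype=float)
    tot_b = tot[f"{strain_b}.cov"].to_numpy(dtype=float)
    both_zero = (tot_a == 0) & (tot_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_a = np.where(tot_a > tot_b, tot_b / np.where(tot_a > 0, tot_a, 1), 1.0)
        ratio_b = np.where(tot_b > tot_a, tot_a / np.where(tot_b > 0, tot_b, 1), 1.0)
    ratio_a = np.where(both_zero, 1.0, ratio_a)
    ratio_b = np.where(both_zero, 1.0, ratio_b)
    for strain, ratio in ((strain_a, ratio_a), (strain_b, ratio_b)):
        mc = out[f"{strain}.mc"].to_numpy()
        thin = ratio < 1.0
        new_mc = mc.copy()
        if thin.any():
            new_mc[thin] = rng.binomial(mc[thin].astype(np.int64), ratio[thin])
        out[f"{strain}.mc"] = new_mc
    return out.sort_index()


# ---------------------------------------------------------------------------
# density curves
# ---------------------------------------------------------------------------


def methylation_fraction_by_density(
    sites_with_calls: pd.DataFrame,
    strain: str,
    segments: pd.DataFrame,
) -> pd.DataFrame:
    """Percent of callable CpG sites called methylated, pooled per integer
    density bin.

    No-call (NaN) sites are excluded from both numerator and denominator;
    bins with zero callable sites are omitted. Columns: density_bin,
    pct_methylated, n_callable, n_methylated.
    """
    merged = sites_with_calls.merge(
        segments[["seg_id", "density_bin"]], on="seg_id", how="inner"
    )
    call = merged[f"{strain}.call"]
    callable_mask = call.notna()
    sub = merged[callable_mask]
    grp = sub.groupby("density_bin")[f"{strain}.call"]
    out = grp.agg(n_callable="size", n_methylated="sum").reset_index()
    out["n_methylated"] = out["n_methylated"].astype(int)
    out["pct_methylated"] = 100.0 * out["n_methylated"] / out["n_callable"]
    return out[["density_bin", "pct_methylated", "n_callable", "n_methylated"]]


def cpg_disrupting_variant_mask(
    sites: pd.DataFrame, variants: pd.DataFrame, strain: str, outgroup: str
) -> tuple[pd.Series, int]:
    """Flag sites where strain and outgroup differ by the loss or gain of a
    cytosine at the CpG's C position.

    A variant at the site where neither the strain nor the outgroup allele is
    C (e.g. a substitution at the partner G) does not count; those records
    are excluded and their number returned for logging.
    """
    v = variants.merge(
        sites[["chrom", "pos"]], on=["chrom", "pos"], how="inner"
    )
    differs = v[strain] != v[outgroup]
    c_involved = (v[strain] == "C") | (v[outgroup] == "C")
    usable = v[differs & c_involved]
    non_c_excluded = int((differs & ~c_involved).sum())
    key = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
    hit = key.isin(usable["chrom"].astype(str) + ":" + usable["pos"].astype(str))
    return hit, non_c_excluded


def mutation_fraction_by_density(
    sites_with_calls: pd.DataFrame,
    segments: pd.DataFrame,
    variants: pd.DataFrame,
    strain: str,
    outgroup: str,
) -> pd.DataFrame:
    """Percent of CpG sites carrying a C-loss/C-gain variant versus the
    outgroup, per density bin, separately for called-methylated and
    called-unmethylated sites of ``strain``.

    Variant = strain and outgroup alleles differ and one of them is C
    (other nucleotides excluded).  Within each bin the percentage is the
    mutated share of that call class. Columns: density_bin, meth_class
    ("methylated"/"unmethylated"), pct_mutated, n_sites, n_mutated.
    """
    mutated, n_excluded = cpg_disrupting_variant_mask(
        sites_with_calls, variants, strain, outgroup
    )
    if n_excluded:
        log.info(
            "mutation_fraction_by_density: excluded %d non-C variant sites",
            n_excluded,
        )
    merged = sites_with_calls.assign(mutated=mutated.to_numpy()).merge(
        segments[["seg_id", "density_bin"]], on="seg_id", how="inner"
    )
    call = merged[f"{strain}.call"]
    rows = []
    for label, mask in (("methylated", call == 1.0), ("unmethylated", call == 0.0)):
        sub = merged[mask]
        grp = sub.groupby("density_bin")["mutated"]
        agg = grp.agg(n_sites="size", n_mutated="sum").reset_index()
        agg["meth_class"] = label
        agg["pct_mutated"] = 100.0 * agg["n_mutated"] / agg["n_sites"]
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    return out[["density_bin", "meth_class", "pct_mutated", "n_sites", "n_mutated"]]


def segments_to_bed(segments: pd.DataFrame, path) -> None:
    """BED6 export with density in the score column."""
    bed = pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"],
            "end": segments["end"],
            "name": "seg" + segments["seg_id"].astype(str),
            "score": segments.get("density", 0.0),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
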