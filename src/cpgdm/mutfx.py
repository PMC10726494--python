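"""Mutation-expression analysis: does the effect of losing a methylated CpG
on transcript abundance depend on local CpG sequence density?

Candidate mutations are single-nucleotide sites where one strain carries a
called-methylated CpG and the other strain's allele at the C is A or T, so
the site cannot be methylated on either strand. Each candidate is annotated
with its segment's CpG density, a high/low density class (high iff density
strictly exceeds the threshold, 40 CpG/kb by default), every overlapping
extended gene interval (transcript span plus 2 kb on both sides), and an
optional chromatin-state label.

Per-gene log2 fold changes (focal:reference, e.g. D2:B6) are inverse-normal
transformed and modelled per site.  Because every site of a gene shares that
gene's expression value, default inference uses cluster-robust (by gene)
standard errors; naive OLS errors are available but anticonservative for
multi-site genes. Calibration can be checked empirically by permuting
expression values among genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DENSITY_THRESHOLD = 40.0
GENE_FLANK = 2000
CANDIDATE_ALLELES = frozenset({"A", "T"})
#: the multiple-testing family of the chromatin-state scan: 2 classes x 15 states
N_STATE_TESTS = 30
#: printed convention for the scan threshold alongside alpha/30
BONFERRONI_PRINTED = 0.001


# ---------------------------------------------------------------------------
# elementary transforms & tests
# ---------------------------------------------------------------------------


def invnorm(values) -> np.ndarray:
    """Inverse-normal (rank) transform: Phi^-1((rank - 0.5) / n).

    Ranks use average ties; n counts non-missing entries; missing (NaN)
    values stay missing in place. Raises on all-missing input.
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if not mask.any():
        raise ValueError("invnorm: all values missing")
    ranks = stats.rankdata(x[mask], method="average")
    out = np.full(x.shape, np.nan)
    out[mask] = stats.norm.ppf((ranks - 0.5) / mask.sum())
    return out


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance two-sample t test.

    Returns (t, Welch-Satterthwaite df, two-sided p). Each group needs at
    least two values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t: each group needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def classify_density(density, threshold: float = DENSITY_THRESHOLD):
    """High iff density > threshold (strict; a segment at exactly the
    threshold is low). Vectorised; returns bool."""
    d = np.asarray(density, dtype=float)
    high = d > threshold
    if np.isscalar(density):
        return bool(high)
    return high


def gene_interval(
    tx_start: int, tx_end: int, flank: int = GENE_FLANK, chrom_length: int | None = None
) -> tuple[int, int]:
    """Extended gene interval [txStart - flank, txEnd + flank), clamped at
    chromosome bounds; flanks are symmetric regardless of strand."""
    start = max(0, tx_start - flank)
    end = tx_end + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


# ---------------------------------------------------------------------------
# interval annotation
# ---------------------------------------------------------------------------


def assign_genes(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = GENE_FLANK,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Match sites to extended gene intervals; one output row per site-gene
    overlap (a site in two genes yields two rows). Sites in no gene are
    dropped."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        start, end = gene_interval(int(g.txStart), int(g.txEnd), flank, size)
        trees.setdefault(g.chrom, IntervalTree()).addi(start, end, g.gene_id)
    rows = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for idx, pos in zip(sub.index, sub["pos"].to_numpy()):
            for iv in tree.at(int(pos) - 1):
                rows.append((idx, iv.data))
    if not rows:
        return sites.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    match = pd.DataFrame(rows, columns=["_site_idx", "gene_id"])
    out = sites.loc[match["_site_idx"]].reset_index(drop=True)
    out["gene_id"] = match["gene_id"].to_numpy()
    return out


def assign_states(sites: pd.DataFrame, states: pd.DataFrame | None) -> pd.Series:
    """Chromatin-state label per site (at most one; the first overlapping
    interval wins), or None outside every interval / when no track given."""
    labels = pd.Series([None] * len(sites), index=sites.index, dtype=object)
    if states is None or len(states) == 0:
        return labels
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for s in states.itertuples():
        trees.setdefault(s.chrom, IntervalTree()).addi(int(s.start), int(s.end), s.state)
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for idx, pos in zip(sub.index, sub["pos"].to_numpy()):
            hits = tree.at(int(pos) - 1)
            if hits:
                labels.at[idx] = min(hits).data
    return labels


def filter_states_by_accessibility(
    sites: pd.DataFrame,
    state_labels: pd.Series,
    accessibility: pd.DataFrame | None,
    min_reads: int = 10,
) -> pd.Series:
    """Keep a state label only where pooled open-chromatin support reaches
    ``min_reads`` across the strains; skipped (labels unchanged) when no
    accessibility table is supplied.

    ``accessibility`` columns: chrom, start, end, plus one or more ``reads*``
    columns that are summed.
    """
    if accessibility is None:
        return state_labels
    read_cols = [c for c in accessibility.columns if c.startswith("reads")]
    acc = accessibility.assign(_total=accessibility[read_cols].sum(axis=1))
    acc = acc[acc["_total"] >= min_reads]
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in acc.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end), True)
    out = state_labels.copy()
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        for idx, pos in zip(sub.index, sub["pos"].to_numpy()):
            if tree is None or not tree.at(int(pos) - 1):
                out.at[idx] = None
    return out


# ---------------------------------------------------------------------------
# candidate mutations & the combined analysis table
# ---------------------------------------------------------------------------


def candidate_mutations(
    sites_with_calls: pd.DataFrame,
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    genes: pd.DataFrame,
    focal_strain: str,
    reference_strain: str,
    direction: str = "reference_methylated",
    density_threshold: float = DENSITY_THRESHOLD,
    flank: int = GENE_FLANK,
    states: pd.DataFrame | None = None,
    accessibility: pd.DataFrame | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select CpG-disrupting candidate mutations and annotate them.

    Default direction ``reference_methylated``: the reference strain carries
    a called-methylated CpG (its allele at the C is C) and the focal strain's
    allele is A or T, so the focal strain cannot be methylated there on
    either strand. ``focal_methylated`` applies the literal mirrored reading
    (methylated CpG in the focal strain, reference carries A/T).

    Returns one record per mutation-gene overlap plus a counter dict of
    exclusions (wrong allele, unmethylated, uncovered by any segment,
    outside genes).
    """
    if direction not in ("reference_methylated", "focal_methylated"):
        raise ValueError(f"unknown direction {direction!r}")
    carrier, mutated = (
        (reference_strain, focal_strain)
        if direction == "reference_methylated"
        else (focal_strain, reference_strain)
    )
    log.info(
        "candidate_mutations: methylated CpG carried by %r, A/T allele in %r "
        "(direction=%s)", carrier, mutated, direction,
    )
    v = variants.merge(
        sites_with_calls[["chrom", "pos", f"{carrier}.call"]],
        on=["chrom", "pos"],
        how="inner",
    )
    counts = {"variants_at_cpg": len(v)}
    methylated = v[f"{carrier}.call"] == 1.0
    carrier_is_c = v[carrier] == "C"
    focal_at = v[mutated].isin(CANDIDATE_ALLELES)
    keep = methylated & carrier_is_c & focal_at
    counts["excluded_unmethylated"] = int((~methylated).sum())
    counts["excluded_allele"] = int((methylated & ~(carrier_is_c & focal_at)).sum())
    cand = v[keep][["chrom", "pos"]].copy()
    cand["focal_allele"] = v.loc[keep, mutated].to_numpy()
    cand["ref_allele"] = v.loc[keep, carrier].to_numpy()
    cand["methylated"] = True

    from .segmetrics import assign_sites_to_segments

    cand = assign_sites_to_segments(cand, segments)
    uncovered = cand["seg_id"] < 0
    counts["excluded_no_segment"] = int(uncovered.sum())
    if counts["excluded_no_segment"]:
        log.info("candidate_mutations: %d sites outside every segment", counts["excluded_no_segment"])
    cand = cand[~uncovered].merge(
        segments[["seg_id", "density"]], on="seg_id", how="left"
    )
    cand["high"] = classify_density(cand["density"].to_numpy(), density_threshold)
    n_before = len(cand)
    cand = assign_genes(cand, genes, flank=flank, chrom_sizes=chrom_sizes)
    counts["excluded_no_gene"] = n_before - cand["pos"].nunique() if len(cand) else n_before
    labels = assign_states(cand, states)
    cand["state"] = filter_states_by_accessibility(cand, labels, accessibility)
    return cand.reset_index(drop=True), counts


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression CSV (gene, log2FoldChange, pvalue at
    minimum; DESeq2 column names accepted) into gene_id, log2fold, de_p."""
    de = pd.read_csv(path)
    rename = {}
    for src, dst in (
        ("gene", "gene_id"), ("gene_id", "gene_id"),
        ("log2FoldChange", "log2fold"), ("log2fold", "log2fold"),
        ("pvalue", "de_p"), ("de_p", "de_p"), ("padj", "padj"),
    ):
        if src in de.columns:
            rename[src] = dst
    de = de.rename(columns=rename)
    missing = {"gene_id", "log2fold", "de_p"} - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if len(de) and ((de["de_p"] <= 0) | (de["de_p"] > 1)).any():
        raise ValueError("DE p-values must lie in (0, 1]")
    if de["gene_id"].duplicated().any():
        raise ValueError("DE table must have one row per gene")
    return de


def build_analysis_table(
    sites_with_calls: pd.DataFrame,
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    genes: pd.DataFrame,
    de_table: pd.DataFrame,
    reference_strain: str,
    de_p_threshold: float | None = 0.05,
    log2fc_threshold: float | None = None,
    flank: int = GENE_FLANK,
    states: pd.DataFrame | None = None,
    density_threshold: float = DENSITY_THRESHOLD,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Merge methylated sites, mutations, density, states, and expression
    into the per-site modelling table.

    Rows are (methylated-in-reference CpG site) x (overlapping gene), with
    ``mutation`` flagging candidate records, joined to the gene's log2 fold
    change and DE p-value. Genes failing the DE p filter (default p < 0.05,
    unadjusted) or the optional |log2FC| ceiling are dropped.
    """
    meth = sites_with_calls[sites_with_calls[f"{reference_strain}.call"] == 1.0]
    base = meth[["chrom", "pos"]].copy()

    from .segmetrics import assign_sites_to_segments

    base = assign_sites_to_segments(base, segments)
    base = base[base["seg_id"] >= 0].merge(
        segments[["seg_id", "density"]], on="seg_id", how="left"
    )
    base["high"] = classify_density(base["density"].to_numpy(), density_threshold)
    base = assign_genes(base, genes, flank=flank, chrom_sizes=chrom_sizes)
    base["state"] = assign_states(base, states)
    mut_key = set(
        zip(mutations["chrom"], mutations["pos"], mutations["gene_id"])
    ) if len(mutations) else set()
    base["mutation"] = [
        (c, p, g) in mut_key
        for c, p, g in zip(base["chrom"], base["pos"], base["gene_id"])
    ]
    de = de_table.copy()
    if de_p_threshold is not None:
        de = de[de["de_p"] < de_p_threshold]
    if log2fc_threshold is not None:
        de = de[de["log2fold"].abs() < log2fc_threshold]
    out = base.merge(de[["gene_id", "log2fold", "de_p"]], on="gene_id", how="inner")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted linear model (optionally with a nested-model comparison)."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    nobs: int
    cov_type: str
    fstat: float | None = None
    fpvalue: float | None = None
    df_num: float | None = None
    df_den: float | None = None
    dropped_terms: list[str] = field(default_factory=list)


def _fit_ols(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray | None):
    import statsmodels.api as sm

    model = sm.OLS(y, X.astype(float))
    if groups is not None and len(np.unique(groups)) > 1:
        return model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    if groups is not None:
        log.warning("single cluster: falling back to nonrobust covariance")
    return model.fit()


def _result_to_fit(res, dropped: list[str] | None = None) -> ModelFit:
    return ModelFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        conf_int=res.conf_int(),
        nobs=int(res.nobs),
        cov_type=res.cov_type,
        dropped_terms=dropped or [],
    )


def _drop_degenerate(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop zero-variance predictors (other than the intercept), warning."""
    dropped = []
    for col in list(X.columns):
        if col == "const":
            continue
        if np.nanstd(X[col].to_numpy(dtype=float)) == 0:
            dropped.append(col)
            X = X.drop(columns=col)
    if dropped:
        log.warning("dropping zero-variance predictors: %s", dropped)
    return X, dropped


def _groups(table: pd.DataFrame, cluster_by_gene: bool) -> np.ndarray | None:
    if cluster_by_gene and "gene_id" in table.columns:
        return pd.factorize(table["gene_id"])[0]
    return None


def fit_within_class_model(
    table: pd.DataFrame,
    density_class: str,
    cluster_by_gene: bool = True,
    normalize: bool = True,
) -> ModelFit:
    """OLS of (inverse-normal transformed) log2 fold change on the mutation
    indicator and continuous CpG density, within one density class.

    The transform is computed over the full table before subsetting so both
    classes share one normalised scale. ``density_class`` is "high" or
    "low". Zero-variance predictors are dropped with a warning.
    """
    if density_class not in ("high", "low"):
        raise ValueError("density_class must be 'high' or 'low'")
    y_all = invnorm(table["log2fold"]) if normalize else table["log2fold"].to_numpy(float)
    mask = table["high"].to_numpy(bool) == (density_class == "high")
    sub = table[mask]
    if len(sub) < 3:
        raise ValueError(f"too few rows in class {density_class!r}")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "mutation": sub["mutation"].astype(float).to_numpy(),
            "density": sub["density"].to_numpy(float),
        },
        index=sub.index,
    )
    X, dropped = _drop_degenerate(X)
    res = _fit_ols(y_all[mask], X, _groups(sub, cluster_by_gene))
    return _result_to_fit(res, dropped)


def _interaction_design(
    table: pd.DataFrame, with_interaction: bool, covariates: bool = True
) -> pd.DataFrame:
    """Design matrix: intercept, optional chromosome/position/state
    covariates, density class, mutation, and optionally their interaction."""
    cols = {"const": np.ones(len(table))}
    if covariates:
        if "chrom" in table.columns and table["chrom"].nunique() > 1:
            dummies = pd.get_dummies(table["chrom"], prefix="chrom", drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(float)
        if "pos" in table.columns:
            pos = table["pos"].to_numpy(float)
            scale = pos.std() or 1.0
            cols["position"] = (pos - pos.mean()) / scale
        if "state" in table.columns and table["state"].notna().any():
            dummies = pd.get_dummies(
                table["state"].astype(object).fillna("(none)"),
                prefix="state", drop_first=True,
            )
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(float)
    cols["high"] = table["high"].astype(float).to_numpy()
    cols["mutation"] = table["mutation"].astype(float).to_numpy()
    if with_interaction:
        cols["high:mutation"] = cols["high"] * cols["mutation"]
    return pd.DataFrame(cols, index=table.index)


def interaction_anova(
    table: pd.DataFrame,
    cluster_by_gene: bool = True,
    covariates: bool = True,
    normalize: bool = True,
) -> ModelFit:
    """Nested-model test for the density x mutation interaction.

    Fits ``y ~ covariates + density + mutation`` (fit0) against the same
    model plus ``density:mutation`` (fit1), y being the inverse-normal
    transformed log2 fold change, and tests the added term. With
    cluster-robust (by gene) covariance the comparison is a robust Wald F;
    without clustering it is the classical nested ANOVA F. Raises when the
    interaction column is collinear with fit0's design (e.g. a single
    density class present).
    """
    y = invnorm(table["log2fold"]) if normalize else table["log2fold"].to_numpy(float)
    X0 = _interaction_design(table, with_interaction=False, covariates=covariates)
    X1 = _interaction_design(table, with_interaction=True, covariates=covariates)
    X0, dropped0 = _drop_degenerate(X0)
    X1, dropped1 = _drop_degenerate(X1)
    if "high:mutation" not in X1.columns:
        raise ValueError("degenerate design: interaction term has zero variance")
    r0 = np.linalg.matrix_rank(X0.to_numpy(float))
    r1 = np.linalg.matrix_rank(X1.to_numpy(float))
    if r1 != r0 + 1:
        raise ValueError(
            "degenerate design: density:mutation is collinear with the null "
            "model (is only one density class present?)"
        )
    groups = _groups(table, cluster_by_gene)
    res1 = _fit_ols(y, X1, groups)
    if groups is not None:
        k = list(X1.columns).index("high:mutation")
        contrast = np.zeros((1, X1.shape[1]))
        contrast[0, k] = 1.0
        wald = res1.wald_test(contrast, use_f=True, scalar=True)
        fstat, fp = float(wald.statistic), float(wald.pvalue)
        df_num, df_den = 1.0, float(res1.df_resid)
    else:
        res0 = _fit_ols(y, X0, None)
        rss0, rss1 = float(res0.ssr), float(res1.ssr)
        df_num = 1.0
        df_den = float(res1.df_resid)
        fstat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
        fp = float(stats.f.sf(fstat, df_num, df_den))
    fit = _result_to_fit(res1, sorted(set(dropped0) | set(dropped1)))
    fit.fstat, fit.fpvalue, fit.df_num, fit.df_den = fstat, fp, df_num, df_den
    return fit


# ---------------------------------------------------------------------------
# chromatin-state scan
# ---------------------------------------------------------------------------


def chromatin_state_scan(
    table: pd.DataFrame,
    alpha: float = 0.05,
    cluster_by_gene: bool = True,
) -> pd.DataFrame:
    """Per chromatin state and density class: site counts with/without
    mutations, percent mutated, and the p-value of the mutation term in a
    linear model on the inverse-normal fold change.

    Reports significance at both Bonferroni conventions (alpha / 30 for
    2 x 15 tests, and the printed 0.001). States with zero mutated sites get
    a missing p, not 1. An empty/absent state track degenerates to the
    unstratified model (state "(all)").
    """
    y_all = invnorm(table["log2fold"])
    has_states = "state" in table.columns and table["state"].notna().any()
    state_values = (
        sorted(table["state"].dropna().unique()) if has_states else ["(all)"]
    )
    bonf = alpha / N_STATE_TESTS
    rows = []
    for state in state_values:
        for cls, is_high in (("high", True), ("low", False)):
            mask = table["high"].astype(bool) == is_high
            if has_states:
                mask &= table["state"] == state
            sub = table[mask]
            n_mut = int(sub["mutation"].sum())
            n_nomut = int(len(sub) - n_mut)
            pct = 100.0 * n_mut / len(sub) if len(sub) else np.nan
            p = np.nan
            beta = np.nan
            if n_mut > 0 and n_nomut > 0:
                X = pd.DataFrame(
                    {"const": 1.0, "mutation": sub["mutation"].astype(float)},
                    index=sub.index,
                )
                res = _fit_ols(
                    y_all[mask.to_numpy()], X, _groups(sub, cluster_by_gene)
                )
                beta = float(res.params["mutation"])
                p = float(res.pvalues["mutation"])
            rows.append(
                {
                    "state": state,
                    "density_class": cls,
                    "n_no_mutation": n_nomut,
                    "n_mutation": n_mut,
                    "pct_mutated": pct,
                    "beta": beta,
                    "p": p,
                    "significant_bonferroni": bool(p < bonf) if np.isfinite(p) else False,
                    "significant_printed": bool(p < BONFERRONI_PRINTED)
                    if np.isfinite(p)
                    else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed_stat: float
    observed_p: float
    empirical_p: float
    perm_stats: np.ndarray
    perm_pvalues: np.ndarray
    ks_stat: float
    ks_pvalue: float
    n_perm: int


def _interaction_statistic(table: pd.DataFrame, cluster_by_gene: bool = True):
    fit = interaction_anova(table, cluster_by_gene=cluster_by_gene, covariates=False)
    return fit.fstat, fit.fpvalue


def permutation_calibration(
    table: pd.DataFrame,
    statistic=None,
    n_perm: int = 10_000,
    seed: int = 0,
    cluster_by_gene: bool = True,
) -> PermutationResult:
    """Gene-level permutation null for a model statistic.

    Expression values move between genes as a block: each permutation
    reassigns every gene's log2 fold change (and its sites' copies) to a
    different gene, keeping all mutation/density/state labels fixed. The
    statistic (default: the density x mutation interaction F and its nominal
    p) is recomputed per permutation; the empirical p uses the add-one
    convention (b + 1)/(n_perm + 1) so it is never zero; a Kolmogorov-Smirnov
    comparison of the permuted nominal p-values against Uniform(0, 1)
    diagnoses calibration. Fully determined by ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic is None:
        statistic = lambda t: _interaction_statistic(t, cluster_by_gene)  # noqa: E731
    rng = np.random.default_rng(seed)
    obs_stat, obs_p = statistic(table)
    gene_values = table.drop_duplicates("gene_id")[["gene_id", "log2fold"]]
    gene_ids = gene_values["gene_id"].to_numpy()
    values = gene_values["log2fold"].to_numpy()
    perm_stats = np.empty(n_perm)
    perm_ps = np.empty(n_perm)
    work = table.copy()
    for b in range(n_perm):
        shuffled = values[rng.permutation(len(values))]
        mapping = dict(zip(gene_ids, shuffled))
        work["log2fold"] = work["gene_id"].map(mapping).to_numpy()
        perm_stats[b], perm_ps[b] = statistic(work)
    empirical_p = (1 + int(np.sum(perm_stats >= obs_stat))) / (n_perm + 1)
    ks = stats.kstest(perm_ps, "uniform")
    return PermutationResult(
        observed_stat=float(obs_stat),
        observed_p=float(obs_p),
        empirical_p=float(empirical_p),
        perm_stats=perm_stats,
        perm_pvalues=perm_ps,
        ks_stat=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# sensitivity sweeps
# ---------------------------------------------------------------------------


def sweep_density_threshold(
    table: pd.DataFrame,
    thresholds=range(14, 61),
    cluster_by_gene: bool = True,
    covariates: bool = False,
) -> pd.DataFrame:
    """Refit the interaction model while sliding the high/low density cut.

    Per threshold the density class is recomputed (high iff density >
    threshold) and the interaction coefficient, F and p recorded. Thresholds
    leaving one class empty (or collinear) are flagged inestimable.
    Columns: threshold, estimable, beta_interaction, fstat, p, n_high, n_low.
    """
    rows = []
    for t in thresholds:
        work = table.copy()
        work["high"] = classify_density(work["density"].to_numpy(), float(t))
        n_high = int(work["high"].sum())
        n_low = int(len(work) - n_high)
        row = {
            "threshold": int(t), "estimable": False,
            "beta_interaction": np.nan, "fstat": np.nan, "p": np.nan,
            "n_high": n_high, "n_low": n_low,
        }
        if n_high and n_low:
            try:
                fit = interaction_anova(
                    work, cluster_by_gene=cluster_by_gene, covariates=covariates
                )
            except ValueError:
                pass
            else:
                row.update(
                    estimable=True,
                    beta_interaction=float(fit.params["high:mutation"]),
                    fstat=fit.fstat,
                    p=fit.fpvalue,
                )
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_transcript_filter(
    table: pd.DataFrame,
    log2fc_thresholds=(0.2, 0.5, 1, 2, 4, 8),
    de_p_threshold: float | None = None,
    cluster_by_gene: bool = True,
) -> pd.DataFrame:
    """Refit the interaction model under sliding transcript-inclusion filters.

    Per |log2FC| ceiling: genes below the ceiling (and below the DE p cut
    when given) are retained and the interaction refit; the complementary
    large-effect gene set gets its own mutation-term fit (no interaction).
    Filters retaining fewer than two genes are flagged inestimable.
    """
    rows = []
    for c in log2fc_thresholds:
        keep_genes = table["log2fold"].abs() < c
        if de_p_threshold is not None:
            keep_genes &= table["de_p"] < de_p_threshold
        small = table[keep_genes]
        large = table[table["log2fold"].abs() >= c]
        row = {
            "log2fc_threshold": float(c),
            "n_genes_small": int(small["gene_id"].nunique()),
            "n_genes_large": int(large["gene_id"].nunique()),
            "estimable": False, "beta_interaction": np.nan, "p": np.nan,
            "beta_mutation_large": np.nan, "p_mutation_large": np.nan,
        }
        if row["n_genes_small"] >= 2:
            try:
                fit = interaction_anova(
                    small, cluster_by_gene=cluster_by_gene, covariates=False
                )
                row.update(
                    estimable=True,
                    beta_interaction=float(fit.params["high:mutation"]),
                    p=fit.fpvalue,
                )
            except ValueError:
                pass
        if row["n_genes_large"] >= 2 and large["mutation"].astype(bool).any():
            y = invnorm(large["log2fold"])
            X = pd.DataFrame(
                {"const": 1.0, "mutation": large["mutation"].astype(float)},
                index=large.index,
            )
            X, _ = _drop_degenerate(X)
            if "mutation" in X.columns:
                res = _fit_ols(y, X, _groups(large, cluster_by_gene))
                row["beta_mutation_large"] = float(res.params["mutation"])
                row["p_mutation_large"] = float(res.pvalues["mutation"])
        rows.append(row)
    return pd.DataFrame(rows)
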