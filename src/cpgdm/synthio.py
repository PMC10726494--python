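"""Synthetic multi-strain methylome generator with a ground-truth ledger.

The generator emulates the statistical structure that the downstream stages
assume, at desk scale:

* a genome tiled into 2-kb segments spanning a configurable CpG-density
  spectrum, with CpGs placed uniformly inside segments and a CpG-free
  background (A/T bases) elsewhere;
* a three-level methylation-vs-density curve (highly methylated below the
  first breakpoint, intermediate between the breakpoints, lowly methylated
  above the second);
* two conservation regimes between strains: below the conservation
  breakpoint the *amount* of methylation is conserved (count-conserving
  relocation of methylated sites, pairwise same-state probability near the
  configured concordance), above it the *identity* of methylated sites is
  conserved (each strain independently drops ancestrally methylated sites
  at a strain-specific rate, so counts drift apart while surviving sites
  coincide);
* sequence divergence versus an outgroup with a higher rate at methylated
  than unmethylated CpGs below the breakpoint and the reverse above it;
* focal-strain candidate mutations (A/T replacing a C methylated in the
  reference strain) whose effect on per-gene log2 fold change is present
  only in high-density segments (beta_high per mutation, beta_low = 0 by
  default), plus an optional subset of genes with a large negative
  structural effect;
* a 15-label chromatin-state partition, optionally concentrating the
  expression effect in "Active enhancers".

Default parameter magnitudes echo the printed analysis (breakpoints 25/40,
concordance 0.8, beta_high 0.16, beta_low 0); they are study conditions,
not fitted values, and all are overridable.

Seeding: one master seed fans out to per-layer child generators via
``SeedSequence((master_seed, layer_index))`` with fixed layer indices, so
regenerating one layer never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .methio import CHROMATIN_STATES, write_fasta, write_states_bed, write_site_table, write_variants_tsv

_LAYERS = {
    "reference": 0,
    "methylomes": 1,
    "variants": 2,
    "genes": 3,
    "expression": 4,
    "states": 5,
}

_DEFAULT_SPECTRUM = tuple(
    (float(d), 100)
    for d in (5, 10, 15, 20, 25, 30, 35, 45, 50, 60, 70, 90, 100, 120)
)

_DEFAULT_STATE_WEIGHTS = {s: 1.0 for s in CHROMATIN_STATES}
_DEFAULT_STATE_WEIGHTS["Active enhancers"] = 4.0
_DEFAULT_STATE_WEIGHTS["Quiescent"] = 4.0


def layer_rng(seed: int, layer: str) -> np.random.Generator:
    """Child generator for one layer of the simulation (documented scheme)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _LAYERS[layer])))


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the package's study conditions."""

    window: int = 2000
    n_chroms: int = 2
    density_spectrum: tuple = _DEFAULT_SPECTRUM  # (target CpG/kb, n segments)
    strains: tuple = ("b6", "d2", "fvb")
    outgroup: str = "cast"
    reference_strain: str = "b6"
    focal_strain: str = "d2"
    # methylation-vs-density curve (fractions below/between/above breakpoints)
    meth_breakpoints: tuple = (25.0, 40.0)
    meth_levels: tuple = (0.86, 0.50, 0.12)
    # cross-strain conservation
    concordance_low: float = 0.8          # pairwise same-state target, low regime
    conservation_breakpoint: float = 40.0  # count-conserving at or below, site-conserving above
    site_drop_base: float = 0.15          # per-strain methylated-site loss, high regime
    site_drop_step: float = 0.15          # increment per strain index (count asymmetry)
    # read-coverage model
    coverage_mean: float = 20.0
    coverage_dispersion: float = 10.0     # negative-binomial size parameter
    meth_read_level: float = 0.8          # P(read methylated | site methylated)
    read_error: float = 0.01              # P(read methylated | site unmethylated)
    # mutation rates (per CpG site)
    divergence_rate_me_low: float = 0.05
    divergence_rate_un_low: float = 0.02
    divergence_rate_me_high: float = 0.008
    divergence_rate_un_high: float = 0.02
    candidate_rate: float = 0.06          # focal-strain A/T at reference-methylated CpG
    background_rate: float = 0.001        # non-C variants outside CpGs
    # genes & expression
    gene_span_segments: int = 2
    gene_flank: int = 2000
    density_threshold: float = 40.0
    beta_high: float = 0.16
    beta_low: float = 0.0
    density_slope: float = 0.0
    noise_sd: float = 1.0
    struct_fraction: float = 0.05
    struct_offset: float = -3.0
    struct_mut_beta: float = -0.8
    # chromatin states
    state_interval: int = 500
    state_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATE_WEIGHTS)
    )
    enhancer_effect: bool = False

    def validate(self) -> None:
        rates = [
            self.concordance_low, self.meth_read_level, self.read_error,
            self.divergence_rate_me_low, self.divergence_rate_un_low,
            self.divergence_rate_me_high, self.divergence_rate_un_high,
            self.candidate_rate, self.background_rate, self.struct_fraction,
        ] + list(self.meth_levels)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if not self.meth_breakpoints[0] < self.meth_breakpoints[1]:
            raise ValueError("meth_breakpoints must be increasing")
        for d, n in self.density_spectrum:
            if d > 500:
                raise ValueError(
                    f"target density {d}/kb impossible: CpGs need 2 bp each"
                )
            if d < 0 or n < 0:
                raise ValueError("density spectrum entries must be non-negative")

    @property
    def all_strains(self) -> tuple:
        return tuple(self.strains) + (self.outgroup,)

    def drop_rate(self, strain: str) -> float:
        i = self.all_strains.index(strain)
        return min(0.95, self.site_drop_base + i * self.site_drop_step)

    def meth_level(self, density: float) -> float:
        lo, hi = self.meth_breakpoints
        if density < lo:
            return self.meth_levels[0]
        if density <= hi:
            return self.meth_levels[1]
        return self.meth_levels[2]


@dataclass
class Reference:
    genome: dict[str, str]
    cpg_sites: pd.DataFrame       # chrom, pos (1-based C), seg_id
    segments: pd.DataFrame        # chrom, start, end, seg_id, partial, target_density,
                                  # cpg_count, density, density_bin


@dataclass
class SyntheticBundle:
    """Everything one simulation produced, plus the ground-truth ledger."""

    config: SyntheticConfig
    seed: int
    reference: Reference
    site_table: pd.DataFrame
    variants: pd.DataFrame
    genes: pd.DataFrame
    states: pd.DataFrame
    de_table: pd.DataFrame
    truth: dict[str, pd.DataFrame]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference.genome, outdir / "genome.fa")
        self.reference.segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
        write_site_table(self.site_table, outdir / "sites.tsv")
        write_variants_tsv(self.variants, outdir / "variants.tsv")
        _write_gtf(self.genes, outdir / "genes.gtf")
        write_states_bed(self.states, outdir / "states.bed")
        de = self.de_table.rename(
            columns={"gene_id": "gene", "log2fold": "log2FoldChange", "de_p": "pvalue"}
        )
        de.to_csv(outdir / "deseq_results.csv", index=False)
        for name, frame in self.truth.items():
            frame.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


def _write_gtf(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples():
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tcpgdm_sim\tgene\t{g.txStart + 1}\t{g.txEnd}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# layer 0: reference genome
# ---------------------------------------------------------------------------


def generate_reference(config: SyntheticConfig, seed: int) -> Reference:
    """Build the reference genome: 2-kb segments hitting each target density
    within Poisson tolerance, CpGs placed uniformly (on even offsets so pairs
    never collide), CpG-free A/T background elsewhere."""
    config.validate()
    rng = layer_rng(seed, "reference")
    window = config.window
    n_slots = window // 2
    seg_specs = []
    for target, count in config.density_spectrum:
        seg_specs += [float(target)] * int(count)
    order = rng.permutation(len(seg_specs))
    rows, cpg_rows, chrom_seqs = [], [], {}
    per_chrom = -(-len(seg_specs) // config.n_chroms)  # ceil
    seg_id = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        parts = []
        for j in range(per_chrom):
            k = c * per_chrom + j
            if k >= len(seg_specs):
                break
            target = seg_specs[order[k]]
            n_cpg = min(int(rng.poisson(target * window / 1000.0)), n_slots)
            slots = rng.choice(n_slots, size=n_cpg, replace=False) if n_cpg else np.empty(0, int)
            seq = rng.choice(np.array([b"A", b"T"], dtype="S1"), size=window)
            offsets = np.sort(slots) * 2
            seq[offsets] = b"C"
            seq[offsets + 1] = b"G"
            start = len(parts) * window
            parts.append(seq.tobytes().decode())
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": start + window,
                    "seg_id": seg_id, "partial": False, "target_density": target,
                    "cpg_count": int(n_cpg),
                }
            )
            for off in offsets:
                cpg_rows.append({"chrom": chrom, "pos": start + int(off) + 1, "seg_id": seg_id})
            seg_id += 1
        chrom_seqs[chrom] = "".join(parts)
    segments = pd.DataFrame(rows)
    segments["density"] = segments["cpg_count"] / (window / 1000.0)
    segments["density_bin"] = segments["density"].astype(int)
    cpg_sites = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "seg_id"])
    return Reference(genome=chrom_seqs, cpg_sites=cpg_sites, segments=segments)


# ---------------------------------------------------------------------------
# layer 1: strain methylomes
# ---------------------------------------------------------------------------


def generate_strain_methylomes(
    config: SyntheticConfig, reference: Reference, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-strain methylation states and read counts at every
    reference CpG.

    Ancestral states are Bernoulli draws from the density-dependent
    methylation level. In count-conserving segments (density <= conservation
    breakpoint) each strain relocates a Binomial(n, (1-c)/4) number of
    methylated sites so pairwise same-state probability is ~c while counts
    are preserved; in site-conserving segments each strain drops ancestrally
    methylated sites at its own rate and never gains any. Read counts are
    negative-binomial coverage with binomial methylated reads.

    Returns (site_table, truth_states).
    """
    rng = layer_rng(seed, "methylomes")
    sites = reference.cpg_sites.merge(
        reference.segments[["seg_id", "density"]], on="seg_id"
    )
    n = len(sites)
    density = sites["density"].to_numpy()
    level = np.array([config.meth_level(d) for d in density])
    ancestral = rng.random(n) < level
    low_regime = density <= config.conservation_breakpoint
    seg_ids = sites["seg_id"].to_numpy()

    truth = sites[["chrom", "pos", "seg_id", "density"]].copy()
    truth["regime"] = np.where(low_regime, "count", "site")
    truth["ancestral"] = ancestral.astype(int)

    table = sites[["chrom", "pos"]].copy()
    table["strand"] = "+"
    table["context"] = "CG"

    mismatch_target = 1.0 - config.concordance_low
    for strain in config.all_strains:
        state = ancestral.copy()
        # count-conserving relocation, segment by segment: k methylated sites
        # are switched off and k unmethylated sites switched on, so the
        # methylated count is preserved exactly.  Two strains relocating
        # independently collide (pick the same sites) often when one class is
        # small, which *reduces* realized disagreement, so k solves
        # 2(2k - k^2 (1/m + 1/u)) / n = 1 - c (expected pairwise mismatch
        # with expected collision overlap) rather than the naive k = n(1-c)/4.
        for seg in np.unique(seg_ids[low_regime]):
            idx = np.flatnonzero(seg_ids == seg)
            m_idx = idx[ancestral[idx]]
            u_idx = idx[~ancestral[idx]]
            m, u = len(m_idx), len(u_idx)
            if m == 0 or u == 0 or mismatch_target <= 0:
                continue
            a = 1.0 / m + 1.0 / u
            disc = 16.0 - 8.0 * a * (m + u) * mismatch_target
            k_target = (
                (4.0 - np.sqrt(disc)) / (4.0 * a) if disc > 0 else 2.0 / a
            )
            k = int(k_target) + int(rng.random() < (k_target % 1.0))
            k = min(k, m, u)
            if k > 0:
                off = rng.choice(m_idx, size=k, replace=False)
                on = rng.choice(u_idx, size=k, replace=False)
                state[off] = False
                state[on] = True
        # site-conserving loss
        hi = ~low_regime
        drop = rng.random(n) < config.drop_rate(strain)
        state[hi] = state[hi] & ~drop[hi]

        size = config.coverage_dispersion
        p_nb = size / (size + config.coverage_mean)
        cov = rng.negative_binomial(size, p_nb, size=n)
        p_read = np.where(state, config.meth_read_level, config.read_error)
        mc = rng.binomial(cov, p_read)
        table[f"{strain}.mc"] = mc
        table[f"{strain}.cov"] = cov
        truth[f"{strain}.state"] = state.astype(int)
    return table, truth


# ---------------------------------------------------------------------------
# layer 2: variants
# ---------------------------------------------------------------------------


def generate_variants(
    config: SyntheticConfig, reference: Reference, truth_states: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place sequence variants: outgroup-lineage C->T divergence at CpGs
    (methylated rate > unmethylated below the breakpoint, reversed above),
    focal-strain C->A/T candidate mutations at reference-methylated CpGs,
    and a sprinkle of non-C background variants.

    Returns (variant_table, truth_variants). The site table should
    subsequently have the focal strain's coverage zeroed at candidate sites
    (the C no longer exists in that strain); ``simulate_all`` does this.
    """
    rng = layer_rng(seed, "variants")
    t = truth_states
    density = t["density"].to_numpy()
    ancestral = t["ancestral"].to_numpy().astype(bool)
    high = density > config.conservation_breakpoint
    rate = np.where(
        high,
        np.where(ancestral, config.divergence_rate_me_high, config.divergence_rate_un_high),
        np.where(ancestral, config.divergence_rate_me_low, config.divergence_rate_un_low),
    )
    div_hit = rng.random(len(t)) < rate

    ref_state = t[f"{config.reference_strain}.state"].to_numpy().astype(bool)
    cand_hit = (rng.random(len(t)) < config.candidate_rate) & ref_state
    cand_allele = rng.choice(np.array(["A", "T"]), size=len(t))

    rows, truth_rows = [], []
    strains = list(config.all_strains)
    for i in np.flatnonzero(div_hit | cand_hit):
        row = {
            "chrom": t["chrom"].iat[i], "pos": int(t["pos"].iat[i]), "ref": "C",
            **{s: "C" for s in strains},
        }
        kinds = []
        if div_hit[i]:
            row[config.outgroup] = "T"
            kinds.append("divergence")
        if cand_hit[i]:
            row[config.focal_strain] = cand_allele[i]
            kinds.append("candidate")
        rows.append(row)
        truth_rows.append(
            {
                "chrom": row["chrom"], "pos": row["pos"], "kind": "+".join(kinds),
                "methylated_ancestral": int(ancestral[i]),
                "methylated_reference": int(ref_state[i]),
            }
        )

    # background non-C variants on the A/T backbone
    cpg_pos = {
        (c, p) for c, p in zip(reference.cpg_sites["chrom"], reference.cpg_sites["pos"])
    }
    for chrom, seq in reference.genome.items():
        n_bg = rng.binomial(len(seq), config.background_rate)
        for pos in rng.integers(1, len(seq) + 1, size=n_bg):
            pos = int(pos)
            base = seq[pos - 1]
            if base not in "AT" or (chrom, pos) in cpg_pos:
                continue
            non_ref = [s for s in strains if s != config.reference_strain]
            strain = non_ref[rng.integers(len(non_ref))]
            row = {"chrom": chrom, "pos": pos, "ref": base, **{s: base for s in strains}}
            row[strain] = "G"
            rows.append(row)
            truth_rows.append(
                {
                    "chrom": chrom, "pos": pos, "kind": "background",
                    "methylated_ancestral": -1, "methylated_reference": -1,
                }
            )
    cols = ["chrom", "pos", "ref"] + strains
    variants = (
        pd.DataFrame(rows, columns=cols)
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    truth_variants = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "kind", "methylated_ancestral", "methylated_reference"],
    )
    return variants, truth_variants


# ---------------------------------------------------------------------------
# layers 3-5: genes, chromatin states, expression
# ---------------------------------------------------------------------------


def generate_genes(config: SyntheticConfig, reference: Reference) -> pd.DataFrame:
    """Deterministically tile genes over consecutive segment blocks."""
    rows = []
    gid = 0
    span = config.gene_span_segments * config.window
    for chrom, seq in reference.genome.items():
        for start in range(0, len(seq) - span + 1, span):
            rows.append(
                {
                    "gene_id": f"gene_{gid:04d}", "chrom": chrom,
                    "strand": "+" if gid % 2 == 0 else "-",
                    "txStart": start, "txEnd": start + span,
                }
            )
            gid += 1
    if not rows:
        raise ValueError("genome too small to place any gene")
    return pd.DataFrame(rows)


def generate_chromatin_states(
    config: SyntheticConfig, reference: Reference, seed: int
) -> pd.DataFrame:
    """Partition every chromosome into fixed-width intervals labelled from
    the 15-state vocabulary with the configured weights."""
    rng = layer_rng(seed, "states")
    labels = list(config.state_weights.keys())
    w = np.array([config.state_weights[s] for s in labels], dtype=float)
    w = w / w.sum()
    rows = []
    for chrom, seq in reference.genome.items():
        for start in range(0, len(seq), config.state_interval):
            end = min(start + config.state_interval, len(seq))
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "state": labels[rng.choice(len(labels), p=w)],
                }
            )
    return pd.DataFrame(rows)


def generate_expression(
    config: SyntheticConfig,
    reference: Reference,
    truth_states: pd.DataFrame,
    truth_variants: pd.DataFrame,
    genes: pd.DataFrame,
    states: pd.DataFrame | None,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 fold change from true candidate-mutation counts.

    log2FC = beta_high * n_high + beta_low * n_low + slope * mean density
    + Gaussian noise; a configured fraction of genes receives an additional
    large negative structural effect (base offset plus a negative per-
    mutation term). When the enhancer flag is set, only high-density
    mutations inside "Active enhancers" carry beta_high. DE p-values follow
    the noise model. Returns (de_table, truth_genes).
    """
    from .mutfx import assign_genes, assign_states, classify_density

    rng = layer_rng(seed, "expression")
    cand = truth_variants[truth_variants["kind"].str.contains("candidate")]
    cand_sites = cand.merge(
        truth_states[["chrom", "pos", "density"]], on=["chrom", "pos"], how="left"
    )
    cand_sites["high"] = classify_density(
        cand_sites["density"].to_numpy(), config.density_threshold
    )
    chrom_sizes = {c: len(s) for c, s in reference.genome.items()}
    assigned = assign_genes(
        cand_sites, genes, flank=config.gene_flank, chrom_sizes=chrom_sizes
    )
    if config.enhancer_effect:
        labels = assign_states(assigned, states)
        effective_high = assigned["high"].to_numpy(bool) & (
            labels == "Active enhancers"
        ).to_numpy(bool)
    else:
        effective_high = assigned["high"].to_numpy(bool)
    assigned = assigned.assign(_eff_high=effective_high)
    per_gene = assigned.groupby("gene_id").agg(
        n_high=("_eff_high", "sum"),
        n_low=("_eff_high", lambda v: int((~v.astype(bool)).sum())),
        n_total=("_eff_high", "size"),
    )

    truth_genes = genes[["gene_id", "chrom", "txStart", "txEnd"]].copy()
    truth_genes = truth_genes.join(per_gene, on="gene_id")
    for c in ("n_high", "n_low", "n_total"):
        filled = pd.to_numeric(truth_genes[c], errors="coerce").fillna(0)
        truth_genes[c] = filled.astype(int)
    # mean CpG density of the segments the gene span overlaps
    seg = reference.segments
    mean_density = []
    for g in truth_genes.itertuples():
        overlap = seg[
            (seg["chrom"] == g.chrom)
            & (seg["start"] < g.txEnd)
            & (seg["end"] > g.txStart)
        ]
        mean_density.append(float(overlap["density"].mean()) if len(overlap) else 0.0)
    truth_genes["mean_density"] = mean_density

    n_genes = len(truth_genes)
    structural = rng.random(n_genes) < config.struct_fraction
    noise = rng.normal(0.0, config.noise_sd, size=n_genes)
    signal = (
        config.beta_high * truth_genes["n_high"].to_numpy()
        + config.beta_low * truth_genes["n_low"].to_numpy()
        + config.density_slope * truth_genes["mean_density"].to_numpy()
    )
    struct_part = structural * (
        config.struct_offset + config.struct_mut_beta * truth_genes["n_total"].to_numpy()
    )
    log2fold = signal + struct_part + noise
    # the DE p-value comes from an independent re-measurement of the fold
    # change, as a replicate-based test would, so filtering on it does not
    # sharply truncate the response itself
    sd = config.noise_sd if config.noise_sd > 0 else 1.0
    z = (log2fold + rng.normal(0.0, sd, size=n_genes)) / (sd * np.sqrt(2.0))
    de_p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    truth_genes["structural"] = structural.astype(int)
    truth_genes["signal"] = signal
    truth_genes["noise"] = noise
    truth_genes["log2fold"] = log2fold
    de_table = pd.DataFrame(
        {"gene_id": truth_genes["gene_id"], "log2fold": log2fold, "de_p": de_p}
    )
    return de_table, truth_genes


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------


def simulate_all(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticBundle:
    """Run every layer with the documented seed fan-out and assemble the
    bundle; optionally write all files to ``outdir``."""
    config = config or SyntheticConfig()
    config.validate()
    reference = generate_reference(config, seed)
    site_table, truth_states = generate_strain_methylomes(config, reference, seed)
    variants, truth_variants = generate_variants(config, reference, truth_states, seed)
    genes = generate_genes(config, reference)
    states = generate_chromatin_states(config, reference, seed)
    de_table, truth_genes = generate_expression(
        config, reference, truth_states, truth_variants, genes, states, seed
    )
    # the focal strain has no C at candidate sites: zero its reads there
    cand = truth_variants[truth_variants["kind"].str.contains("candidate")]
    key = set(zip(cand["chrom"], cand["pos"]))
    mask = [
        (c, p) in key for c, p in zip(site_table["chrom"], site_table["pos"])
    ]
    site_table.loc[mask, f"{config.focal_strain}.mc"] = 0
    site_table.loc[mask, f"{config.focal_strain}.cov"] = 0
    bundle = SyntheticBundle(
        config=config,
        seed=seed,
        reference=reference,
        site_table=site_table,
        variants=variants,
        genes=genes,
        states=states,
        de_table=de_table,
        truth={
            "states": truth_states,
            "variants": truth_variants,
            "genes": truth_genes,
        },
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


# ---------------------------------------------------------------------------
# fast expression-layer sampler (for calibration / power studies)
# ---------------------------------------------------------------------------


def sample_analysis_table(
    n_genes: int,
    seed: int,
    beta_high: float = 0.16,
    beta_low: float = 0.0,
    noise_sd: float = 1.0,
    mean_sites: float = 6.0,
    p_mut: float = 0.15,
    p_high: float = 0.3,
    density_threshold: float = 40.0,
    density_slope: float = 0.0,
    struct_fraction: float = 0.0,
    struct_offset: float = -3.0,
    struct_mut_beta: float = -0.8,
    enhancer_only: bool = False,
    with_states: bool = False,
    state_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Sample the per-site modelling table directly, skipping the sequence
    layers.

    Distributionally matches what the full pipeline produces: genes with a
    Poisson number of methylated-CpG sites, continuous site densities (low
    uniform on [5, 40], high uniform on (40, 120] with probability
    ``p_high``), Bernoulli mutations, and per-gene log2 fold changes built
    from the same effect model as :func:`generate_expression` (the density
    class at the *true* threshold carries the effect). Intended for
    calibration, power, recovery and sweep studies where the sequence layers
    only add runtime.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 97)))
    k = 1 + rng.poisson(max(mean_sites - 1.0, 0.0), size=n_genes)
    gene_idx = np.repeat(np.arange(n_genes), k)
    n = len(gene_idx)
    is_high_region = rng.random(n) < p_high
    density = np.where(
        is_high_region,
        rng.uniform(density_threshold + 1e-9, 120.0, size=n),
        rng.uniform(5.0, density_threshold, size=n),
    )
    high = density > density_threshold
    mutation = rng.random(n) < p_mut
    if with_states or enhancer_only:
        weights = dict(state_weights or _DEFAULT_STATE_WEIGHTS)
        labels = list(weights)
        w = np.array([weights[s] for s in labels], float)
        state = np.array(labels)[rng.choice(len(labels), size=n, p=w / w.sum())]
    else:
        state = None
    eff_high = high & mutation
    if enhancer_only:
        eff_high &= state == "Active enhancers"
    eff_low = (~high) & mutation
    n_high = np.bincount(gene_idx, weights=eff_high, minlength=n_genes)
    n_low = np.bincount(gene_idx, weights=eff_low, minlength=n_genes)
    n_tot = np.bincount(gene_idx, weights=mutation, minlength=n_genes)
    mean_density = np.bincount(gene_idx, weights=density, minlength=n_genes) / k
    structural = rng.random(n_genes) < struct_fraction
    noise = rng.normal(0.0, noise_sd, size=n_genes)
    log2fold = (
        beta_high * n_high
        + beta_low * n_low
        + density_slope * mean_density
        + structural * (struct_offset + struct_mut_beta * n_tot)
        + noise
    )
    sd = noise_sd if noise_sd > 0 else 1.0
    z = (log2fold + rng.normal(0.0, sd, size=n_genes)) / (sd * np.sqrt(2.0))
    de_p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "chrom": np.where(gene_idx % 2 == 0, "chr1", "chr2"),
            "pos": np.arange(1, n + 1, dtype=np.int64),
            "gene_id": np.char.add("gene_", gene_idx.astype(str)),
            "density": density,
            "high": high,
            "mutation": mutation,
            "log2fold": log2fold[gene_idx],
            "de_p": de_p[gene_idx],
        }
    )
    if state is not None:
        table["state"] = state
    return table


def null_config(**overrides) -> SyntheticConfig:
    """A configuration with every expression effect switched off (for type-I
    error and permutation-calibration studies)."""
    base = SyntheticConfig(
        beta_high=0.0, beta_low=0.0, density_slope=0.0,
        struct_fraction=0.0, struct_mut_beta=0.0,
    )
    return replace(base, **overrides)
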