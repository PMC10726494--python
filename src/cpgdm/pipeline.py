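"""End-to-end orchestration: simulate/load -> segment -> curves -> conserve
-> mutation-effect models -> sweeps -> report.

A run is a pure function of (inputs, config, seed): the same configuration
writes byte-identical TSVs. Outputs land in a config-hash-named directory
(no timestamps) with a manifest recording per-stage parameter hashes, so a
rerun that only changes a downstream stage's parameters reuses the upstream
outputs untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conserve, methio, mutfx, segmetrics, synthio

log = logging.getLogger(__name__)

#: provenance of each default, echoed into the run log
PARAM_PROVENANCE = {
    "window": "study-stated (2 kb windows)",
    "min_cov": "study-stated (minimum coverage of 5 reads)",
    "min_frac": "study-stated (>=10% methylated reads)",
    "density_threshold": "study-stated (high density > 40 CpG/kb)",
    "de_p_threshold": "study-stated (DE p < 0.05, unadjusted)",
    "log2fc_threshold": "study-stated when 2 (|log2FC| < 2); None = tool-chosen",
    "density_sweep": "study-stated (thresholds 14-60)",
    "fc_sweep": "study-stated (log2FC thresholds 0.2-8)",
    "n_perm": "tool-chosen default; study used 10,000",
    "seed": "tool-chosen",
}


@dataclass
class RunConfig:
    """Declarative configuration of a full run.

    Either ``simulate`` holds overrides for :class:`synthio.SyntheticConfig`
    (possibly empty, meaning defaults) or ``inputs`` maps the keys
    genome/sites/variants/genes/states/de to file paths.
    """

    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    window: int = 2000
    min_cov: int = 5
    min_frac: float = 0.10
    density_threshold: float = 40.0
    de_p_threshold: float | None = 0.05
    log2fc_threshold: float | None = None
    density_sweep: tuple = (14, 60)
    fc_sweep: tuple = (0.2, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_perm: int = 0
    seed: int = 0
    outdir: str = "cpgdm_out"
    make_plots: bool = False

    REQUIRED_INPUTS = ("genome", "sites", "variants", "genes", "de")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise ValueError(
                    f"no simulate block and missing inputs: {missing}"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["density_sweep"] = list(self.density_sweep)
        d["fc_sweep"] = list(self.fc_sweep)
        return d


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""


@dataclass
class RunResult:
    outdir: Path
    results: dict
    stages_run: list
    stages_reused: list


def _stage_params(config: RunConfig) -> dict[str, dict]:
    return {
        "data": {"simulate": config.simulate, "inputs": config.inputs, "seed": config.seed},
        "segment": {"window": config.window},
        "curves": {"min_cov": config.min_cov, "min_frac": config.min_frac},
        "conserve": {"min_cov": config.min_cov, "min_frac": config.min_frac},
        "mutfx": {
            "density_threshold": config.density_threshold,
            "de_p_threshold": config.de_p_threshold,
            "log2fc_threshold": config.log2fc_threshold,
            "density_sweep": list(config.density_sweep),
            "fc_sweep": list(config.fc_sweep),
            "n_perm": config.n_perm,
            "seed": config.seed,
        },
    }


def run_full(config: RunConfig) -> RunResult:
    """Execute all stages, reusing cached stage outputs whose parameter hash
    is unchanged. Any failure halts with the stage name; completed outputs
    are preserved."""
    config.validate()
    params = _stage_params(config)
    upstream_hash = _hash({k: params[k] for k in ("data", "segment")})
    outdir = Path(config.outdir) / f"run-{upstream_hash[:12]}"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    for key, prov in PARAM_PROVENANCE.items():
        log.info("param %s=%r [%s]", key, getattr(config, key, None), prov)

    stages_run, stages_reused = [], []
    dirty = False  # once a stage reruns, everything downstream must too

    def fresh(stage: str, outputs: list[str]) -> bool:
        nonlocal dirty
        h = _hash(params[stage])
        ok = (
            not dirty
            and manifest.get(stage) == h
            and all((outdir / f).exists() for f in outputs)
        )
        if ok:
            stages_reused.append(stage)
        else:
            dirty = True
            stages_run.append(stage)
        return ok

    def done(stage: str) -> None:
        manifest[stage] = _hash(params[stage])
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results: dict = {}
    try:
        # ---------------- data ----------------
        stage = "data"
        data_files = [
            "genome.fa", "sites.tsv", "variants.tsv", "genes.gtf",
            "states.bed", "deseq_results.csv",
        ]
        if config.simulate is not None:
            if not fresh(stage, data_files):
                syn_conf = synthio.SyntheticConfig(**config.simulate)
                synthio.simulate_all(syn_conf, seed=config.seed, outdir=outdir)
                done(stage)
            paths = {k: outdir / f for k, f in zip(
                ("genome", "sites", "variants", "genes", "states", "de"), data_files
            )}
        else:
            fresh(stage, [])
            done(stage)
            paths = {k: Path(v) for k, v in config.inputs.items()}
        genome = methio.read_fasta(paths["genome"])
        sites = methio.read_site_table(paths["sites"])
        variants = methio.read_variants(paths["variants"])
        genes = methio.read_genes(paths["genes"])
        states = (
            methio.read_states_bed(paths["states"]) if "states" in paths else None
        )
        de_table = mutfx.read_de_table(paths["de"])
        strains = methio.site_table_strains(sites)

        # ---------------- segment ----------------
        stage = "segment"
        if not fresh(stage, ["segments_density.tsv"]):
            chrom_sizes = {c: len(s) for c, s in genome.items()}
            segments = segmetrics.segment_genome(chrom_sizes, config.window)
            cpgs = methio.find_cpg_sites(genome)
            ref_cpgs = cpgs[(cpgs["strain"] == "reference") & cpgs["in_reference"]]
            segments = segmetrics.annotate_segment_density(
                segments, ref_cpgs[["chrom", "pos"]]
            )
            segments.to_csv(outdir / "segments_density.tsv", sep="\t", index=False)
            segmetrics.segments_to_bed(segments, outdir / "segments.bed")
            done(stage)
        segments = pd.read_csv(outdir / "segments_density.tsv", sep="\t", dtype={"chrom": str})

        # ---------------- curves ----------------
        stage = "curves"
        sites_seg = segmetrics.assign_sites_to_segments(sites, segments)
        called = segmetrics.add_calls(
            sites_seg, strains, config.min_cov, config.min_frac
        )
        if not fresh(stage, ["methylation_by_density.tsv", "mutation_by_density.tsv"]):
            meth_curves, mut_curves = [], []
            # the last strain column is treated as the outgroup by convention
            outgroup = strains[-1]
            for s in strains[:-1]:
                c = segmetrics.methylation_fraction_by_density(called, s, segments)
                meth_curves.append(c.assign(strain=s))
                m = segmetrics.mutation_fraction_by_density(
                    called, segments, variants, s, outgroup
                )
                mut_curves.append(m.assign(strain=s))
            pd.concat(meth_curves).to_csv(
                outdir / "methylation_by_density.tsv", sep="\t", index=False
            )
            pd.concat(mut_curves).to_csv(
                outdir / "mutation_by_density.tsv", sep="\t", index=False
            )
            done(stage)

        # ---------------- conserve ----------------
        stage = "conserve"
        if not fresh(stage, ["conservation_by_density.tsv"]):
            rows = []
            focal = [s for s in strains[:-1]]
            for i in range(len(focal)):
                for j in range(i + 1, len(focal)):
                    a, b = focal[i], focal[j]
                    ds = segmetrics.downsample_pair(called, a, b, seed=config.seed)
                    ds = segmetrics.add_calls(ds, [a, b], config.min_cov, config.min_frac)
                    rows.append(conserve.conservation_curves(ds, segments, a, b))
            pd.concat(rows).to_csv(
                outdir / "conservation_by_density.tsv", sep="\t", index=False
            )
            done(stage)

        # ---------------- mutfx ----------------
        stage = "mutfx"
        mutfx_files = [
            "candidate_mutations.tsv", "analysis_table.tsv", "model_results.json",
            "state_scan.tsv", "sweep_density.tsv", "sweep_transcripts.tsv",
        ]
        if not fresh(stage, mutfx_files):
            chrom_sizes = {c: len(s) for c, s in genome.items()}
            reference_strain, focal_strain = strains[0], strains[1]
            cand, counts = mutfx.candidate_mutations(
                called, variants, segments, genes,
                focal_strain=focal_strain, reference_strain=reference_strain,
                density_threshold=config.density_threshold,
                states=states, chrom_sizes=chrom_sizes,
            )
            cand.to_csv(outdir / "candidate_mutations.tsv", sep="\t", index=False)
            table = mutfx.build_analysis_table(
                called, cand, segments, genes, de_table,
                reference_strain=reference_strain,
                de_p_threshold=config.de_p_threshold,
                log2fc_threshold=config.log2fc_threshold,
                states=states,
                density_threshold=config.density_threshold,
                chrom_sizes=chrom_sizes,
            )
            table.to_csv(outdir / "analysis_table.tsv", sep="\t", index=False)
            res: dict = {"n_candidate_mutations": int(cand["pos"].nunique()),
                         "n_candidate_high": int(cand.loc[cand["high"], "pos"].nunique()),
                         "exclusion_counts": counts,
                         "n_table_rows": int(len(table)),
                         "n_genes": int(table["gene_id"].nunique()) if len(table) else 0}
            if len(table) and table["high"].nunique() == 2:
                y = mutfx.invnorm(table["log2fold"])
                mut_rows = table["mutation"].to_numpy(bool)
                high_rows = table["high"].to_numpy(bool)
                res["welch_high_vs_low"] = {}
                for label, rows in (("mutated", mut_rows), ("unmutated", ~mut_rows)):
                    if (rows & high_rows).sum() >= 2 and (rows & ~high_rows).sum() >= 2:
                        t, df, p = mutfx.welch_t(
                            y[rows & high_rows], y[rows & ~high_rows]
                        )
                        res["welch_high_vs_low"][label] = {"t": t, "df": df, "p": p}
                for cls in ("high", "low"):
                    fit = mutfx.fit_within_class_model(table, cls)
                    res[f"{cls}_class_model"] = {
                        "beta_mutation": float(fit.params.get("mutation", np.nan)),
                        "p_mutation": float(fit.pvalues.get("mutation", np.nan)),
                        "beta_density": float(fit.params.get("density", np.nan)),
                        "p_density": float(fit.pvalues.get("density", np.nan)),
                    }
                anova = mutfx.interaction_anova(table)
                res["interaction"] = {
                    "F": anova.fstat, "p": anova.fpvalue,
                    "beta": float(anova.params["high:mutation"]),
                }
                scan = mutfx.chromatin_state_scan(table)
                scan.to_csv(outdir / "state_scan.tsv", sep="\t", index=False)
                lo, hi = config.density_sweep
                sweep_d = mutfx.sweep_density_threshold(table, range(int(lo), int(hi) + 1))
                sweep_d.to_csv(outdir / "sweep_density.tsv", sep="\t", index=False)
                est = sweep_d[sweep_d["estimable"]]
                if len(est):
                    # the F peak coincides with the effect-size peak when the
                    # signal is real but is robust to noisy extreme thresholds
                    res["sweep_density_peak"] = int(
                        est.loc[est["fstat"].idxmax(), "threshold"]
                    )
                    res["sweep_density_peak_beta"] = int(
                        est.loc[est["beta_interaction"].idxmax(), "threshold"]
                    )
                sweep_f = mutfx.sweep_transcript_filter(table, config.fc_sweep)
                sweep_f.to_csv(outdir / "sweep_transcripts.tsv", sep="\t", index=False)
                if config.n_perm > 0:
                    perm = mutfx.permutation_calibration(
                        table, n_perm=config.n_perm, seed=config.seed
                    )
                    res["permutation"] = {
                        "empirical_p": perm.empirical_p,
                        "ks_stat": perm.ks_stat,
                        "ks_p": perm.ks_pvalue,
                    }
            else:
                for f in ("state_scan.tsv", "sweep_density.tsv", "sweep_transcripts.tsv"):
                    (outdir / f).write_text("")
            with open(outdir / "model_results.json", "w") as fh:
                json.dump(res, fh, indent=2, sort_keys=True)
            done(stage)
        results = json.loads((outdir / "model_results.json").read_text() or "{}")

        # ---------------- report ----------------
        stage = "report"
        stages_run.append(stage)
        make_report(outdir, make_plots=config.make_plots)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return RunResult(
        outdir=outdir, results=results,
        stages_run=stages_run, stages_reused=stages_reused,
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def _read_tsv(path: Path) -> pd.DataFrame | None:
    if not path.exists() or path.stat().st_size == 0:
        return None
    return pd.read_csv(path, sep="\t")


def make_report(outdir: str | Path, make_plots: bool = False) -> Path:
    """Write a human-readable summary of whatever stage outputs exist.

    Missing stages are marked absent; the report is always produced.
    Optional matplotlib figures mirror the density-curve, conservation and
    effect-by-class views.
    """
    outdir = Path(outdir)
    lines = ["# cpgdm run report", ""]
    meth = _read_tsv(outdir / "methylation_by_density.tsv")
    lines.append("## Methylation fraction vs. CpG density")
    if meth is None:
        lines.append("_absent_")
    else:
        for strain, sub in meth.groupby("strain"):
            low = sub[sub["density_bin"] < 25]
            high = sub[sub["density_bin"] > 40]
            lines.append(
                f"- {strain}: {_wmean(low, 'pct_methylated', 'n_callable'):.1f}% "
                f"methylated below 25 CpG/kb, "
                f"{_wmean(high, 'pct_methylated', 'n_callable'):.1f}% above 40"
            )
    mut = _read_tsv(outdir / "mutation_by_density.tsv")
    lines.append("\n## Mutated fraction vs. CpG density (vs. outgroup)")
    if mut is None:
        lines.append("_absent_")
    else:
        for (strain, cls), sub in mut.groupby(["strain", "meth_class"]):
            low = sub[sub["density_bin"] <= 40]
            high = sub[sub["density_bin"] > 40]
            lines.append(
                f"- {strain}/{cls}: {_wmean(low, 'pct_mutated', 'n_sites'):.2f}% "
                f"mutated at density <= 40, {_wmean(high, 'pct_mutated', 'n_sites'):.2f}% above"
            )
    cons = _read_tsv(outdir / "conservation_by_density.tsv")
    lines.append("\n## Same-state probability vs. methylated-count ratio")
    if cons is None:
        lines.append("_absent_")
    else:
        for (a, b), sub in cons.groupby(["s1", "s2"]):
            low = sub[sub["seg"] < 40]
            high = sub[sub["seg"] > 80]
            lines.append(
                f"- {a} vs {b}: below 40 CpG/kb prob="
                f"{_wmean(low, 'prob', 'CG.all'):.3f} ratio={_pooled_ratio(low):.3f}; "
                f"above 80 prob={_wmean(high, 'prob', 'CG.all'):.3f} "
                f"ratio={_pooled_ratio(high):.3f}"
            )
    lines.append("\n## Mutation effect on expression")
    res_path = outdir / "model_results.json"
    if not res_path.exists():
        lines.append("_absent_")
    else:
        res = json.loads(res_path.read_text() or "{}")
        if "interaction" in res:
            it = res["interaction"]
            lines.append(
                f"- candidate mutations: {res.get('n_candidate_mutations')} "
                f"({res.get('n_candidate_high')} in high-density segments)"
            )
            for cls in ("high", "low"):
                m = res.get(f"{cls}_class_model", {})
                lines.append(
                    f"- {cls}-density mutation effect: beta="
                    f"{m.get('beta_mutation', float('nan')):.4f} "
                    f"(p={m.get('p_mutation', float('nan')):.3g})"
                )
            lines.append(
                f"- density x mutation interaction: F={it['F']:.2f}, p={it['p']:.3g}"
            )
            if "sweep_density_peak" in res:
                lines.append(
                    f"- density-threshold sweep peak effect at "
                    f"{res['sweep_density_peak']} CpG/kb"
                )
        else:
            lines.append("_absent_")
    if make_plots:
        _plots(outdir, meth, mut, cons)
    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _wmean(df: pd.DataFrame, col: str, weight: str) -> float:
    if df is None or len(df) == 0 or df[weight].sum() == 0:
        return float("nan")
    return float(np.average(df[col], weights=df[weight]))


def _pooled_ratio(df: pd.DataFrame) -> float:
    if df is None or len(df) == 0:
        return float("nan")
    n1, n2 = df["s1.me"].sum(), df["s2.me"].sum()
    if n1 == 0 and n2 == 0:
        return float("nan")
    return float(min(n1, n2) / max(n1, n2))


def _plots(outdir: Path, meth, mut, cons) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if meth is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        for strain, sub in meth.groupby("strain"):
            ax.plot(sub["density_bin"], sub["pct_methylated"], label=strain)
        ax.set_xlabel("CpG density (CpG/kb)")
        ax.set_ylabel("% CpGs methylated")
        ax.legend()
        fig.savefig(outdir / "fig_methylation_by_density.png", dpi=100)
        plt.close(fig)
    if mut is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        for (strain, cls), sub in mut.groupby(["strain", "meth_class"]):
            ax.plot(
                sub["density_bin"], sub["pct_mutated"],
                label=f"{strain} {cls}",
                color="tab:blue" if cls == "methylated" else "gray",
                alpha=0.7,
            )
        ax.set_xlabel("CpG density (CpG/kb)")
        ax.set_ylabel("% CpG sites mutated")
        ax.legend(fontsize=7)
        fig.savefig(outdir / "fig_mutation_by_density.png", dpi=100)
        plt.close(fig)
    if cons is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        for (a, b), sub in cons.groupby(["s1", "s2"]):
            ax.plot(sub["seg"], sub["prob"], color="black", alpha=0.7)
            ax.plot(sub["seg"], sub["ratio"], color="tab:blue", alpha=0.7)
        ax.set_xlabel("CpG density (CpG/kb)")
        ax.set_ylabel("probability (black) / ratio (blue)")
        fig.savefig(outdir / "fig_conservation_by_density.png", dpi=100)
        plt.close(fig)
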