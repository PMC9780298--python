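"""End-to-end orchestration: simulate -> filter -> metrics -> discriminate ->
signature -> screen, under one flat configuration with a provenance manifest.

Each stage reads and writes plain-text tables with schemas owned by the
stage's module; the manifest records parameters and content hashes so that an
identical configuration and seed reproduce byte-identical primary outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, discrimination, filtering, instability, screen, survival

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "demo_config"]

ALL_STAGES = ["simulate", "filter", "metrics", "discriminate", "signature", "screen"]

# stage -> stages it consumes outputs from (when no external input is given)
STAGE_DEPS = {
    "filter": ["simulate"],
    "metrics": ["simulate", "filter"],
    "discriminate": ["simulate", "filter"],
    "signature": ["simulate"],
    "screen": ["simulate"],
}


class ConfigError(ValueError):
    pass


def _default_simulate() -> dict:
    return {
        "n_bins": 120,
        "bin_length": 2000,
        "gc_range": [0.3, 0.7],
        "n_baseline": 8,
        "n_test": 16,
        "n_better": 8,
        "gc_bias_strength": 1.0,
        "depth_mean": 200.0,
        "nb_dispersion": 50.0,
        "cnv_multiplier": 2.0,
        "n_event_bins": 6,
        "mutation_rate_better": 12.0,
        "mutation_rate_poor": 45.0,
        "vaf_params": [2.0, 8.0],
        "contamination_fraction": 0.3,
        "expr_n_samples": 100,
        "expr_n_genes": 40,
        "n_signature_genes": 12,
        "dosage_slope": 1.0,
        "noise_sd": 0.5,
        "baseline_hazard": 0.1,
        "hazard_ratio": 3.0,
        "censor_rate": 0.2,
        "n_normal": 30,
        "n_cell_lines": 30,
        "n_drugs": 4,
    }


@dataclass
class PipelineConfig:
    seed: int = 42
    out_dir: str = "pipeline_out"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulate: dict = field(default_factory=_default_simulate)
    metrics: dict = field(
        default_factory=lambda: {
            "window_fraction": 0.3,
            "percentile": 95.0,
            "sd_multiplier": 2.0,
            "two_sided": False,
            "math_convention": "literal",
        }
    )
    discriminate: dict = field(default_factory=lambda: {"loading_quantile": 0.75})
    signature: dict = field(
        default_factory=lambda: {"quantile_window": [0.1, 0.9], "scale_unit_variance": False}
    )
    screen: dict = field(default_factory=lambda: {"alpha": 0.05, "collapse": "binary"})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        enabled = set(self.stages)
        for stage in self.stages:
            for dep in STAGE_DEPS.get(stage, []):
                if dep not in enabled:
                    raise ConfigError(
                        f"stage {stage!r} requires outputs of disabled stage {dep!r}"
                    )


def demo_config(out_dir: str = "pipeline_out", seed: int = 42) -> PipelineConfig:
    return PipelineConfig(seed=seed, out_dir=out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest
    (also written to out_dir/manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    if "simulate" in config.stages:
        _stage_simulate(config, rng, out, state, emit)
        manifest["stages"]["simulate"] = "ok"
    if "filter" in config.stages:
        retained, report = filtering.filter_table(state["variants"])
        state["retained"] = retained
        filtering.write_variant_table(retained, out / "retained.tsv")
        (out / "filter_report.json").write_text(json.dumps(report.summary(), indent=1))
        emit("retained", out / "retained.tsv")
        emit("filter_report", out / "filter_report.json")
        manifest["stages"]["filter"] = report.summary()
    if "metrics" in config.stages:
        _stage_metrics(config, out, state, emit, manifest)
    if "discriminate" in config.stages:
        _stage_discriminate(config, out, state, emit, manifest)
    if "signature" in config.stages:
        _stage_signature(config, out, state, emit, manifest)
    if "screen" in config.stages:
        _stage_screen(config, out, state, emit, manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _stage_simulate(config, rng, out: Path, state: dict, emit) -> None:
    p = config.simulate
    seeds = rng.integers(0, 2**31 - 1, size=8)
    panel = cohort.generate_panel(
        p["n_bins"], p["bin_length"], tuple(p["gc_range"]), seed=int(seeds[0])
    )
    test_samples = [f"T{i:02d}" for i in range(p["n_test"])]
    better = test_samples[: p["n_better"]]
    poor = test_samples[p["n_better"]:]
    groups = {s: ("better" if s in better else "poor") for s in test_samples}

    # multi-bin copy gains planted in the better group (higher CNI there):
    # one region shared across the group (a recurrently gained locus, the
    # gene-level discrimination signal) plus one random region per sample
    bins = panel.bins
    events = []
    ev_rng = np.random.default_rng(int(seeds[1]))
    k = p["n_event_bins"]

    def region_event(s: str, start_bin: int) -> cohort.CnvEvent:
        rows = bins.iloc[start_bin : start_bin + k]
        return cohort.CnvEvent(
            s, rows.iloc[0]["chrom"], int(rows.iloc[0]["start"]), int(rows.iloc[-1]["end"]),
            p["cnv_multiplier"],
        )

    shared_start = panel.n_bins // 4
    for s in better:
        events.append(region_event(s, shared_start))
        events.append(region_event(s, int(ev_rng.integers(0, panel.n_bins - k))))
    bin_counts, cnv_truth = cohort.generate_bin_counts(
        panel,
        p["n_baseline"],
        p["n_test"],
        events,
        gc_bias_strength=p["gc_bias_strength"],
        depth_mean=p["depth_mean"],
        nb_dispersion=p["nb_dispersion"],
        seed=int(seeds[2]),
    )
    rates = {s: (p["mutation_rate_better"] if s in better else p["mutation_rate_poor"]) for s in test_samples}
    variants, var_truth = cohort.generate_variants(
        panel,
        test_samples,
        mutation_rate_per_mb=rates,
        vaf_params=tuple(p["vaf_params"]),
        contamination_fraction=p["contamination_fraction"],
        seed=int(seeds[3]),
    )

    expr_samples = [f"E{i:03d}" for i in range(p["expr_n_samples"])]
    expr_groups = {
        s: ("better" if i < p["expr_n_samples"] // 2 else "poor") for i, s in enumerate(expr_samples)
    }
    genes = [f"SIG{i:02d}" for i in range(p["n_signature_genes"])] + [
        f"BG{i:02d}" for i in range(p["expr_n_genes"] - p["n_signature_genes"])
    ]
    sig_genes = genes[: p["n_signature_genes"]]
    states = cohort.generate_cnv_states(
        genes, expr_samples, expr_groups, signal_genes=sig_genes, effect=1.5, seed=int(seeds[4])
    )
    expression, clinical, surv_truth = cohort.generate_expression_survival(
        expr_samples,
        states,
        expr_groups,
        dosage_slope=p["dosage_slope"],
        noise_sd=p["noise_sd"],
        baseline_hazard=p["baseline_hazard"],
        hazard_ratio=p["hazard_ratio"],
        censor_rate=p["censor_rate"],
        seed=int(seeds[5]),
    )

    normal_samples = [f"N{i:03d}" for i in range(p["n_normal"])]
    normal_states = cohort.generate_cnv_states(
        genes, normal_samples, background_alteration_rate=0.05, seed=int(seeds[6])
    )
    condition = {**{s: "tumor" for s in expr_samples}, **{s: "normal" for s in normal_samples}}

    lines = [f"CL{i:02d}" for i in range(p["n_cell_lines"])]
    cl_rng = np.random.default_rng(int(seeds[7]))
    cl_expr = pd.DataFrame(
        cl_rng.normal(8, 1.5, size=(len(sig_genes), len(lines))), index=sig_genes, columns=lines
    )
    # linear expression -> sensitivity coupling plus noise, one drug per row
    drug_rows = {}
    for d in range(p["n_drugs"]):
        g = sig_genes[d % len(sig_genes)]
        drug_rows[f"DRUG{d:02d}"] = 0.8 * cl_expr.loc[g] + cl_rng.normal(0, 1.0, size=len(lines))
    drug_response = pd.DataFrame(drug_rows).T

    state.update(
        panel=panel,
        bin_counts=bin_counts,
        variants=variants,
        groups=groups,
        expr_groups=expr_groups,
        expression=expression,
        clinical=clinical,
        cnv_states=pd.concat([states, normal_states], axis=1),
        condition=condition,
        signature_genes=sig_genes,
        cl_expression=cl_expr,
        drug_response=drug_response,
        truths={"cnv": cnv_truth, "variants": var_truth, "survival": surv_truth},
    )

    panel.to_tsv(out / "panel.tsv")
    bin_counts.to_tsv(out / "bin_counts.tsv")
    filtering.write_variant_table(state["variants"], out / "variants.tsv")
    expression.to_csv(out / "expression.tsv", sep="\t")
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    state["cnv_states"].to_csv(out / "cnv_states.tsv", sep="\t")
    pd.Series(groups, name="group").rename_axis("sample").to_csv(out / "groups.tsv", sep="\t")
    var_truth.to_json(out / "truth_variants.json")
    cnv_truth.to_json(out / "truth_cnv.json")
    for name in ["panel", "bin_counts", "variants", "expression", "clinical", "cnv_states", "groups"]:
        emit(name, out / f"{name}.tsv")


def _stage_metrics(config, out: Path, state: dict, emit, manifest) -> None:
    m = config.metrics
    table = instability.compute_metrics_table(
        state["bin_counts"],
        state["retained"],
        math_convention=m["math_convention"],
        window_fraction=m["window_fraction"],
        percentile=m["percentile"],
        sd_multiplier=m["sd_multiplier"],
        two_sided=m["two_sided"],
    )
    state["metrics"] = table
    table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    emit("metrics", out / "metrics.tsv")

    groups = state["groups"]
    comparisons = {}
    for metric in ["cni", "tmb", "math"]:
        vals = table.set_index("sample")[metric].dropna()
        a = [vals[s] for s in vals.index if groups[s] == "better"]
        b = [vals[s] for s in vals.index if groups[s] == "poor"]
        if a and b:
            u, pval = instability.compare_groups_mannwhitney(a, b)
            comparisons[metric] = {
                "U": u,
                "p": pval,
                "median_better": float(np.median(a)),
                "median_poor": float(np.median(b)),
            }
    (out / "group_comparisons.json").write_text(json.dumps(comparisons, indent=1))
    emit("group_comparisons", out / "group_comparisons.json")
    manifest["stages"]["metrics"] = comparisons


def _stage_discriminate(config, out: Path, state: dict, emit, manifest) -> None:
    groups = state["groups"]
    results = {}
    for kind, data in [
        ("snv_binary", state["retained"]),
        ("cnv_level", None),
    ]:
        if kind == "cnv_level":
            # gene x sample log2-like CNV values from the planted bin events
            table, details = instability.cni_for_cohort(state["bin_counts"])
            z = pd.DataFrame(details["z_traces"]).T  # samples x bins
            z.columns = state["panel"].bins["gene"].to_numpy()
            data = z.T
        try:
            mat = discrimination.build_alteration_matrix(data, kind, groups)
        except ValueError as exc:
            results[kind] = {"skipped": str(exc)}
            continue
        n_comp = min(2, min(len(mat.samples) - 1, len(mat.genes)))
        model = discrimination.fit_pca(
            mat, n_components=n_comp, loading_quantile=config.discriminate["loading_quantile"]
        )
        auc = discrimination.discrimination_auc(model.scores.iloc[:, 0], groups)
        clus = discrimination.cluster_samples(model.scores, groups)
        model.scores.to_csv(out / f"pca_scores_{kind}.tsv", sep="\t")
        model.loadings.to_csv(out / f"pca_loadings_{kind}.tsv", sep="\t")
        emit(f"pca_scores_{kind}", out / f"pca_scores_{kind}.tsv")
        results[kind] = {
            "auc_pc1": auc,
            "explained_variance_ratio": [float(x) for x in model.explained_variance_ratio],
            "cluster_agreement": clus.get("agreement"),
            "pc_genes": model.pc_genes,
        }
    state["discrimination"] = results
    (out / "discrimination.json").write_text(json.dumps(results, indent=1, default=str))
    emit("discrimination", out / "discrimination.json")
    manifest["stages"]["discriminate"] = {
        k: {kk: v[kk] for kk in ("auc_pc1", "cluster_agreement") if kk in v}
        for k, v in results.items()
    }


def _stage_signature(config, out: Path, state: dict, emit, manifest) -> None:
    sig = survival.compute_nctps(
        state["expression"],
        state["signature_genes"],
        scale_unit_variance=config.signature["scale_unit_variance"],
    )
    clin = state["clinical"].set_index("sample")
    times = clin["time"].to_numpy()
    events = clin["event"].to_numpy()
    scores = sig.nctps.reindex(clin.index)
    cutoff, stat, under_null = survival.maxstat_cutoff(
        scores, times, events, tuple(config.signature["quantile_window"])
    )
    sig.apply_cutoff(cutoff)
    lr = survival.logrank_test(sig.high_low.reindex(clin.index).to_numpy(), times, events)

    tmb_like = state["expression"].loc[state["signature_genes"]].mean(axis=0)
    tmb_cutoff, _, _ = survival.maxstat_cutoff(tmb_like.reindex(clin.index), times, events)
    tmb_group = survival.assign_high_low(tmb_like.reindex(clin.index), tmb_cutoff)
    strat = survival.stratified_prognosis(
        sig.high_low.reindex(clin.index).to_numpy(), tmb_group.to_numpy(), times, events
    )

    scores.rename("nctps").to_csv(out / "nctps_scores.tsv", sep="\t")
    sig.loadings.to_csv(out / "signature_loadings.tsv", sep="\t")
    summary = {
        "cutoff": cutoff,
        "maxstat_statistic": stat,
        "selected_under_null": under_null,
        "logrank": {"statistic": lr.statistic, "df": lr.df, "p": lr.p, "note": "uncorrected for cutoff selection"},
        "stratified_logrank": {"statistic": strat.statistic, "df": strat.df, "p": strat.p},
    }
    (out / "signature_summary.json").write_text(json.dumps(summary, indent=1))
    emit("nctps_scores", out / "nctps_scores.tsv")
    emit("signature_summary", out / "signature_summary.json")
    state["signature_result"] = summary
    manifest["stages"]["signature"] = summary


def _stage_screen(config, out: Path, state: dict, emit, manifest) -> None:
    alpha = config.screen["alpha"]
    chisq = screen.cnv_chisquare_screen(
        state["cnv_states"], state["condition"], collapse=config.screen["collapse"], alpha=alpha
    )
    tumor_samples = [s for s, c in state["condition"].items() if c == "tumor"]
    dosage = screen.dosage_screen(
        state["expression"], state["cnv_states"][tumor_samples], alpha=alpha
    )
    set_a = set(chisq.index[chisq["significant"]])
    set_b = set(dosage.index[dosage["significant"]])
    set_c = set(state["signature_genes"])  # the response-discriminating panel
    venn = screen.intersect_screens(set_a, set_b, set_c)
    drugcorr = screen.drug_sensitivity_correlation(
        state["cl_expression"], state["drug_response"]
    )

    chisq.to_csv(out / "screen_chisq.tsv", sep="\t")
    dosage.to_csv(out / "screen_dosage.tsv", sep="\t")
    drugcorr.to_csv(out / "screen_drugcorr.tsv", sep="\t", index=False)
    (out / "venn.json").write_text(json.dumps(venn.regions, indent=1))
    for name in ["screen_chisq", "screen_dosage", "screen_drugcorr"]:
        emit(name, out / f"{name}.tsv")
    emit("venn", out / "venn.json")
    summary = {
        "n_cnv_significant": int(len(set_a)),
        "n_dosage_significant": int(len(set_b)),
        "n_signature_genes": int(len(set_c)),
        "venn_counts": venn.counts(),
    }
    state["screen_result"] = summary
    manifest["stages"]["screen"] = summary
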