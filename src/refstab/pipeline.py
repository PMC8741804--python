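"""End-to-end pipeline: simulate -> stability (x3) -> consensus -> downstream.

:class:`RunConfig` collects every switch and threshold of the analysis
chain under named keys with the conventional defaults (advisory geNorm
M < 1.5, fold change > 2, p < 0.05, FPKM >= 5, q >= 0.05).
:func:`run_pipeline` executes the enabled stages in dependency order,
writes per-stage CSV/JSON into an output directory and returns a combined
report.  Stage outputs are pure functions of inputs + config, so two runs
with the same seed produce byte-identical tabular files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ct_io, synthetic
from .consensus import assign_dense_ranks, mean_rank_consensus
from .expression import differential_expression_filter, kmeans_cluster, zscore_standardize
from .quantification import delta_delta_ct
from .stability import bestkeeper_report, bestkeeper_stats, genorm_report, \
    genorm_stepwise_ranking, normfinder_stability

__all__ = ["RunConfig", "run_pipeline"]

#: advisory geNorm cutoff: genes with M above this are annotated, never dropped
M_ADVISORY_CUTOFF = 1.5


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run (YAML-loadable)."""

    seed: int = 0
    # inputs; when ct_table is None and simulate is True a synthetic dataset is drawn
    ct_table: str | None = None
    group_table: str | None = None
    expression_table: str | None = None
    simulate: bool = False
    sim_n_genes: int = 12
    sim_n_groups: int = 4
    sim_samples_per_group: int = 3
    sim_replicates: int = 3
    # stage toggles
    stability: bool = False
    consensus: bool = False
    quantify: bool = False
    cluster: bool = False
    de: bool = False
    # algorithm options
    genorm_efficiency: float | None = None
    normfinder_grouped: bool | None = None
    bestkeeper_sd: str = "sd"
    # quantification
    targets: list[str] = field(default_factory=list)
    references: list[str] = field(default_factory=list)
    calibrator: str | None = None
    # clustering / DE thresholds
    kmeans_k: int = 6
    m_cutoff: float = M_ADVISORY_CUTOFF
    fold_threshold: float = 2.0
    alpha: float = 0.05
    min_fpkm: float = 5.0
    min_q: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fold_threshold", "alpha", "min_fpkm", "min_q", "m_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_ct(config: RunConfig):
    if config.ct_table is not None:
        groups = None
        if config.group_table is not None:
            groups = ct_io.read_group_table(config.group_table)
        m = ct_io.read_ct_table(config.ct_table, groups=groups)
        return ct_io.as_collapsed(m), None
    if config.simulate:
        params = synthetic.default_params(
            n_genes=config.sim_n_genes,
            n_groups=config.sim_n_groups,
            samples_per_group=config.sim_samples_per_group,
            replicates=config.sim_replicates,
            seed=config.seed,
        )
        m, truth = synthetic.simulate_ct_matrix(params)
        return ct_io.as_collapsed(m), truth
    return None, None


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, float_format="%.10g", **kw)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages; write outputs under ``outdir``.

    Returns the combined report (also written as ``report.json`` and
    ``report.md``).  A configuration with no stages enabled yields an
    empty report and succeeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    m, truth = _load_ct(config)
    if truth is not None:
        truth.save(outdir / "simulation_truth.json")
        ct_io.write_ct_table(
            ct_io.as_collapsed(
                synthetic.simulate_ct_matrix(truth.params)[0]
            ),
            outdir / "ct_matrix.csv",
        )
        report["stages"].append("simulate")

    rankings = None
    if config.stability:
        if m is None:
            raise RuntimeError("stability stage enabled but no Ct input configured")
        gn = genorm_stepwise_ranking(m, config.genorm_efficiency)
        nf = normfinder_stability(m, grouped=config.normfinder_grouped)
        bk_stats = bestkeeper_stats(m, sd_method=config.bestkeeper_sd)
        bk = bestkeeper_report(m, sd_method=config.bestkeeper_sd, unrankable="last")
        gn_rep = genorm_report(m, config.genorm_efficiency)
        for name, rep in (("genorm", gn_rep), ("normfinder", nf), ("bestkeeper", bk)):
            _write_csv(rep.to_frame(), outdir / f"stability_{name}.csv", index=False)
        _write_csv(bk_stats.table, outdir / "bestkeeper_stats.csv", index_label="gene")
        flagged = sorted(gn.m_values.index[gn.m_values > config.m_cutoff])
        diagnostics = {
            "genorm_v_ratios": {str(k): v for k, v in gn.v_ratios.items()},
            "genorm_recommended_n": gn.recommended_n,
            "genorm_m_above_cutoff": flagged,  # advisory only
        }
        (outdir / "stability_diagnostics.json").write_text(
            json.dumps(diagnostics, indent=2, sort_keys=True) + "\n"
        )
        rankings = {
            "genorm": assign_dense_ranks(gn_rep),
            "normfinder": assign_dense_ranks(nf),
            "bestkeeper": assign_dense_ranks(bk, unrankable="last"),
        }
        report["stages"].append("stability")
        report["stability"] = {
            "genorm_order": gn.stability_order,
            "genorm_recommended_n": gn.recommended_n,
            "m_above_cutoff": flagged,
        }

    if config.consensus:
        if rankings is None:
            raise RuntimeError("consensus stage requires the stability stage")
        cons = mean_rank_consensus(
            rankings["genorm"], rankings["normfinder"], rankings["bestkeeper"]
        )
        _write_csv(cons.table, outdir / "consensus.csv", index_label="gene")
        report["stages"].append("consensus")
        report["consensus"] = {
            "order": cons.order,
            "top4": cons.top(4),
            "mean_rank": {g: cons.table.loc[g, "mean_rank_display"] for g in cons.order},
        }

    if config.quantify:
        if m is None:
            raise RuntimeError("quantification stage enabled but no Ct input configured")
        if not config.targets or not config.references or config.calibrator is None:
            raise RuntimeError("quantification needs targets, references and calibrator")
        rel = delta_delta_ct(m, config.targets, config.references, config.calibrator)
        tidy = rel.fold_change.reset_index(names="gene").melt(
            id_vars="gene", var_name="sample", value_name="fold_change"
        )
        _write_csv(tidy, outdir / "fold_changes.csv", index=False)
        report["stages"].append("quantify")

    expr = None
    if config.expression_table is not None:
        groups = None
        if config.group_table is not None:
            groups = ct_io.read_group_table(config.group_table)
        expr = ct_io.read_expression_table(config.expression_table, groups=groups)

    if config.cluster:
        if expr is None:
            raise RuntimeError("cluster stage enabled but no expression table configured")
        z, flags = zscore_standardize(expr)
        res = kmeans_cluster(z, k=config.kmeans_k, seed=config.seed)
        out = pd.DataFrame({"gene": res.labels.index, "cluster": res.labels.values})
        _write_csv(out, outdir / "clusters.csv", index=False)
        report["stages"].append("cluster")
        report["cluster"] = {"k": res.k, "inertia": res.inertia,
                             "degenerate_rows": sorted(flags.index[flags])}

    if config.de:
        if expr is None:
            raise RuntimeError("de stage enabled but no expression table configured")
        de = differential_expression_filter(
            expr, fold_threshold=config.fold_threshold, alpha=config.alpha
        )
        _write_csv(de.table, outdir / "differential_expression.csv", index=False)
        report["stages"].append("de")
        report["de"] = {
            "comparisons": sorted(de.table["comparison"].unique().tolist()),
            "n_pass": int(de.table["passes"].sum()),
        }

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# refstab pipeline report", "",
             f"Seed: {report['seed']}", f"Stages run: {', '.join(report['stages']) or 'none'}", ""]
    if "stability" in report:
        s = report["stability"]
        lines += ["## Stability", "",
                  f"geNorm stability order (most stable first): {', '.join(s['genorm_order'])}",
                  f"geNorm recommended reference count: {s['genorm_recommended_n']}",
                  f"Genes with advisory M > cutoff: {', '.join(s['m_above_cutoff']) or 'none'}", ""]
    if "consensus" in report:
        c = report["consensus"]
        lines += ["## Comprehensive ranking", "",
                  "| Gene | Mean rank |", "|---|---|"]
        lines += [f"| {g} | {c['mean_rank'][g]} |" for g in c["order"]]
        lines += ["", f"Top 4: {', '.join(c['top4'])}", ""]
    if "cluster" in report:
        lines += ["## Clustering", "", f"k = {report['cluster']['k']}, "
                  f"inertia = {report['cluster']['inertia']:.6g}", ""]
    if "de" in report:
        lines += ["## Differential expression", "",
                  f"{report['de']['n_pass']} gene x comparison calls passed "
                  "the fold-change and p-value rules.", ""]
    return "\n".join(lines) + "\n"
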