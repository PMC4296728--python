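"""End-to-end case-control workflow: clean -> collapse -> alpha -> beta ->
clusters -> tests -> report, with a deterministic run manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from .beta import divergence_matrix, hierarchical_clusters, linkage_to_newick
from .cleaning import apply_exclusions, case_subset, read_metadata
from .inference import (
    cluster_case_test,
    covariate_logistic,
    group_clustering_permutation_test,
    taxon_wald_tests,
)
from .table import ANALYSIS_LEVELS, collapse_to_level, pool_levels, read_taxon_table, to_relative

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    table_path: str
    metadata_path: str
    out_dir: str
    tree_path: str | None = None
    case_field: str = "cesarean"
    levels: tuple[str, ...] = ANALYSIS_LEVELS
    n_permutations: int = 10_000
    k_clusters: int = 4
    cluster_level: str = "genus"
    linkage: str = "average"
    seed: int = 0
    log_base: float | None = None
    two_sided: bool = False
    transform: str | None = None
    columns: dict[str, str] = field(default_factory=dict)


#: artifacts every complete run directory must contain
EXPECTED_ARTIFACTS = [
    "attrition.tsv",
    "alpha_diversity.tsv",
    "covariate_associations.tsv",
    "clustering_pvalues.tsv",
    "taxon_associations.tsv",
    "clusters.tsv",
    "cluster_case_table.tsv",
    "dendrogram.nwk",
    "manifest.json",
]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Writes: attrition report; per-level J-S divergence matrices and
    permutation p-values; genus-level dendrogram, cluster assignment and
    cluster-by-case chi-square; per-sample alpha diversity; per-variable
    covariate logistic regressions; pooled multi-rank taxon screen; and a
    JSON manifest sufficient to re-run bit-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    table = stage("read table")(read_taxon_table, config.table_path)
    metadata = stage("read metadata")(read_metadata, config.metadata_path)
    tree = (
        stage("read tree")(alpha_mod.read_tree, config.tree_path)
        if config.tree_path
        else None
    )

    metadata, table, attrition = stage("exclusions")(
        apply_exclusions, metadata, table, config.columns or None
    )
    attrition.to_frame().to_csv(out / "attrition.tsv", sep="\t", index=False)

    md_case, case = stage("case subset")(case_subset, metadata, config.case_field, config.columns or None)
    if case.sum() < 2 or (~case).sum() < 2:
        raise RuntimeError(
            f"pipeline stage 'case subset' failed: fewer than 2 cases or controls "
            f"for {config.case_field!r} ({int(case.sum())}/{int((~case).sum())})"
        )
    table_case = table.subset_samples(list(md_case.index))

    # alpha diversity at the finest level, on counts when available
    alpha_df = stage("alpha diversity")(alpha_mod.alpha_diversity_table, table_case, tree, config.log_base)
    alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t")

    rel = stage("to relative")(to_relative, table_case)

    # per-level J-S divergence + permutation test
    perm_rows = []
    cluster_records = {}
    for i, level in enumerate(config.levels):
        collapsed = stage(f"collapse {level}")(collapse_to_level, rel, level)
        D = stage(f"divergence {level}")(divergence_matrix, collapsed, level, config.log_base)
        D.to_frame().to_csv(out / f"divergence_{level}.tsv", sep="\t")
        res = stage(f"permutation test {level}")(
            group_clustering_permutation_test,
            D,
            case.to_numpy(),
            config.n_permutations,
            config.seed + i,
            "within",
            config.two_sided,
        )
        perm_rows.append(
            dict(level=level, statistic=res.statistic, observed=res.observed,
                 n_permutations=res.n_permutations, p_value=res.p_value)
        )
        if level == config.cluster_level:
            cluster_records["D"] = D

    pd.DataFrame(perm_rows).to_csv(out / "clustering_pvalues.tsv", sep="\t", index=False)

    # hierarchical clusters at the chosen level + cluster x case test
    D = cluster_records.get("D")
    if D is None:
        collapsed = collapse_to_level(rel, config.cluster_level)
        D = divergence_matrix(collapsed, config.cluster_level, config.log_base)
    clusters = stage("clustering")(hierarchical_clusters, D, config.k_clusters, config.linkage)
    clusters.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(linkage_to_newick(clusters.linkage, D.sample_ids) + "\n")
    chi2, dof, chi_p, ctab = stage("cluster-case test")(cluster_case_test, clusters, case)
    ctab.assign(chi2=chi2, df=dof, p_value=chi_p).to_csv(out / "cluster_case_table.tsv", sep="\t")

    # Table-1-style covariate regressions
    covs = stage("covariate regressions")(covariate_logistic, md_case, case)
    pd.DataFrame(
        [
            dict(variable=c.variable, level=c.level, estimate=c.estimate,
                 std_error=c.std_error, z_value=c.z_value, p_value=c.p_value,
                 flagged=c.flagged)
            for c in covs
        ]
    ).to_csv(out / "covariate_associations.tsv", sep="\t", index=False)

    # pooled multi-rank taxon screen
    pooled = stage("pool levels")(pool_levels, rel, config.levels)
    assoc = stage("taxon screen")(taxon_wald_tests, pooled, md_case, case)
    assoc.sort_values("wald_p").to_csv(out / "taxon_associations.tsv", sep="\t")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "n_samples_after_exclusions": int(len(metadata)),
        "n_samples_case_analysis": int(len(md_case)),
        "n_cases": int(case.sum()),
        "n_controls": int((~case).sum()),
        "cluster_chi2": {"chi2": chi2, "df": dof, "p_value": chi_p},
        "artifacts": EXPECTED_ARTIFACTS + [f"divergence_{l}.tsv" for l in config.levels],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def make_report(run_dir: str | Path) -> str:
    """Render a markdown summary of a completed run; written to report.md.

    If artifacts are missing the report lists them instead of failing.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    lines = ["# Case-control microbiome run summary", ""]
    if not manifest_path.exists():
        lines.append("Run incomplete: manifest.json missing.")
        return _write_report(run_dir, lines)
    manifest = json.loads(manifest_path.read_text())
    missing = [a for a in manifest.get("artifacts", []) if not (run_dir / a).exists()]
    if missing:
        lines.append("Run incomplete; missing artifacts:")
        lines += [f"- {m}" for m in missing]
        return _write_report(run_dir, lines)

    lines += [
        f"Case field: **{manifest['config']['case_field']}**",
        f"Samples after exclusions: {manifest['n_samples_after_exclusions']}",
        f"Case analysis: {manifest['n_cases']} cases / {manifest['n_controls']} controls",
        "",
        "## Attrition",
        "",
    ]
    attr = pd.read_csv(run_dir / "attrition.tsv", sep="\t")
    lines += _md_table(attr)

    lines += ["", "## Beta-diversity permutation tests", ""]
    perms = pd.read_csv(run_dir / "clustering_pvalues.tsv", sep="\t")
    lines += _md_table(perms[["level", "observed", "n_permutations", "p_value"]])

    lines += ["", "## Clusters x case", ""]
    ctab = pd.read_csv(run_dir / "cluster_case_table.tsv", sep="\t")
    if manifest["n_cases"] == 0:
        lines.append("Cluster-case test skipped: no cases.")
    else:
        lines += _md_table(ctab)
        prev = ctab["case"] / (ctab["case"] + ctab["control"])
        for c, p in zip(ctab.iloc[:, 0], prev):
            lines.append(f"- cluster {c}: case prevalence {100 * p:.1f}%")

    lines += ["", "## Top taxa (smallest Wald p)", ""]
    taxa = pd.read_csv(run_dir / "taxon_associations.tsv", sep="\t").head(10)
    lines += _md_table(taxa[["lineage", "wald_p", "q_value", "control_mean", "case_mean", "difference"]])
    return _write_report(run_dir, lines)


def _md_table(df: pd.DataFrame) -> list[str]:
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "---|" * len(df.columns)
    rows = ["| " + " | ".join(fmt(v) for v in rec) + " |" for rec in df.itertuples(index=False)]
    return [header, sep, *rows]


def _write_report(run_dir: Path, lines: list[str]) -> str:
    body = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(body)
    return body
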