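"""End-to-end orchestration: simulate -> WD -> node tests -> link tests ->
restriction -> clinical correlations -> report.

One run is a pure function of (config, seed): every table is written with a
fixed float format, the JSON summary has sorted keys, and a MANIFEST of
SHA-256 checksums is emitted so repeat runs can be verified byte-identical.

Three covariate models are first-class, mirroring the standard reporting
sequence for this analysis: age + sex; age + sex + psychotropic medication;
age + sex + BDI + STAI-T. Node and link comparisons run as two separate
one-sided families (reduced and heightened integrity in patients), each
FDR-corrected on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import clinical_corr as cc
from . import group_stats as gs
from .connectome_io import (
    FND_ONLY_COLUMNS,
    ValidationError,
    read_cohort,
    read_connectome,
    write_cohort,
)
from .graph_metrics import link_values, wd_table, write_wd_table
from .synthetic import GeneratorConfig, default_scenarios, generate_cohort

log = logging.getLogger("fndconn")

#: the three standard covariate models, in reporting order
COVARIATE_MODELS = {
    "age_sex": ("age", "sex"),
    "age_sex_medication": ("age", "sex", "medication_any_psychotropic"),
    "age_sex_bdi_stait": ("age", "sex", "bdi", "stai_trait"),
}

NODE_DIRECTIONS = ("fnd_lower", "fnd_higher")

BASE_VARIABLES = ("sf36_physical_health", "sf36_mental_health", "sf36_general_health",
                  "sf36_physical_functioning", "bdi", "stai_trait", "stai_state")
FND_EXTRA_VARIABLES = ("illness_duration", "sfmdrs", "cgi")

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    scenario: str = "paper_like"
    seed: int = 0
    q_fdr: float = 0.05
    presence_threshold: float = 0.5
    log_level: str = "INFO"
    #: overrides applied on top of the named scenario's GeneratorConfig
    generator_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in default_scenarios():
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; available: {sorted(default_scenarios())}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def generator_config(self) -> GeneratorConfig:
        base = default_scenarios()[self.scenario]
        if self.generator_overrides:
            base = GeneratorConfig.from_dict({**base.to_dict(), **self.generator_overrides})
        return base


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a simulated cohort; returns the summary dict.

    Writes under ``config.out_dir``: the cohort and ground truth, the WD
    table, node results per covariate model and direction, link results per
    weight kind, the connectogram edge list restricted to node-level
    findings with per-node altered-link counts, correlation tables and
    sorted p-value curves per (scope, adjustment), region-filtered
    correlations, ``summary.json`` and a SHA-256 ``MANIFEST.tsv``. On a
    stage failure, partial outputs are retained and the MANIFEST marks the
    run incomplete.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"scenario": config.scenario, "seed": config.seed,
                     "q_fdr": config.q_fdr,
                     "presence_threshold": config.presence_threshold}
    stage = "setup"
    try:
        # --- simulate -------------------------------------------------------
        stage = "simulate"
        gen = config.generator_config()
        connectomes, cohort, truth = generate_cohort(gen, seed=config.seed)
        log.info("simulate: %d FND / %d HC subjects, %d planted nodes",
                 (cohort["group"] == "FND").sum(), (cohort["group"] == "HC").sum(),
                 len(truth.planted_nodes))
        written.append(write_cohort(cohort, out / "cohort.tsv"))
        written.append(truth.to_json(out / "ground_truth.json"))
        from .synthetic import save_config
        written.append(save_config(gen, out / "generator_config.yaml"))
        summary["n_fnd"] = int((cohort["group"] == "FND").sum())
        summary["n_hc"] = int((cohort["group"] == "HC").sum())
        summary["planted_nodes"] = sorted(truth.planted_nodes)

        stage = "cohort_summary"
        written.append(_write_tsv(cohort_summary(cohort), out / "cohort_summary.tsv"))

        # --- weighted degree ------------------------------------------------
        stage = "weighted_degree"
        wd = wd_table(connectomes["fa"])
        written.append(write_wd_table(wd, out / "wd.tsv"))

        # --- node tests -----------------------------------------------------
        stage = "node_tests"
        node_sig: dict[str, list[str]] = {}
        for model, covs in COVARIATE_MODELS.items():
            for direction in NODE_DIRECTIONS:
                design = gs.DesignSpec(covariates=covs, direction=direction,
                                       q_fdr=config.q_fdr)
                res = gs.test_nodes(wd, cohort, design)
                written.append(_write_tsv(res, out / f"node_results_{model}_{direction}.tsv"))
                key = f"{model}_{direction}"
                node_sig[key] = sorted(res.loc[res["significant"], "node"])
                log.info("node_tests %s: %d/84 significant", key, len(node_sig[key]))
        summary["significant_nodes"] = {k: len(v) for k, v in node_sig.items()}
        reference_nodes = set(node_sig["age_sex_fnd_lower"])
        summary["reference_node_set"] = sorted(reference_nodes)

        # --- link tests -----------------------------------------------------
        stage = "link_tests"
        design = gs.DesignSpec(covariates=COVARIATE_MODELS["age_sex"],
                               direction="fnd_lower", q_fdr=config.q_fdr)
        link_results = {}
        for kind in ("fa", "nstreamlines", "mean_length_mm"):
            links = link_values(connectomes[kind])
            res = gs.test_links(links, cohort, design, config.presence_threshold)
            link_results[kind] = res
            written.append(_write_tsv(res[res["tested"]], out / f"link_results_{kind}.tsv"))
            log.info("link_tests %s: %d tested, %d significant", kind,
                     int(res["tested"].sum()), int(res["significant"].sum()))
        summary["significant_links"] = {k: int(v["significant"].sum())
                                        for k, v in link_results.items()}
        summary["tested_links"] = {k: int(v["tested"].sum()) for k, v in link_results.items()}

        # --- hierarchical restriction ---------------------------------------
        stage = "link_restriction"
        kept, counts = gs.restrict_links_to_nodes(link_results["fa"], reference_nodes)
        edges = kept[["region_a", "region_b", "t_stat", "p_adj"]]
        written.append(_write_tsv(edges, out / "connectogram_edges.tsv"))
        counts_frame = counts.rename("n_altered_links_of_83").rename_axis("node").reset_index()
        written.append(_write_tsv(counts_frame, out / "node_link_counts.tsv"))
        summary["restricted_links"] = int(len(kept))

        # --- clinical correlations ------------------------------------------
        stage = "correlations"
        corr_counts: dict[str, dict[str, int]] = {}
        fnd_frames = {}
        for scope in ("HC", "FND", "combined"):
            variables = BASE_VARIABLES + (FND_EXTRA_VARIABLES if scope == "FND" else ())
            for adjustment, covs in cc.ADJUSTMENTS.items():
                use_vars = tuple(v for v in variables if v not in covs)
                spec = cc.CorrelationSpec(clinical_variables=use_vars, group_scope=scope,
                                          adjustment=adjustment, q_fdr=config.q_fdr)
                results = cc.correlate_wd_clinical(wd, cohort, spec)
                combined = pd.concat(results.values(), ignore_index=True)
                tag = f"{scope}_{adjustment}"
                written.append(_write_tsv(combined, out / f"corr_results_{tag}.tsv"))
                written.append(_write_tsv(cc.sorted_p_curves(results),
                                          out / f"sorted_p_curves_{tag}.tsv"))
                corr_counts[tag] = {v: int(f["significant"].sum()) for v, f in results.items()}
                if scope == "FND" and adjustment == "age_sex_bdi_stait":
                    fnd_frames = results
        summary["significant_correlations"] = corr_counts

        # --- region filtering -----------------------------------------------
        stage = "region_filter"
        all_fnd = pd.concat(fnd_frames.values(), ignore_index=True) if fnd_frames \
            else pd.DataFrame(columns=["node", "variable", "significant"])
        filtered = cc.filter_to_regions(all_fnd, reference_nodes)
        written.append(_write_tsv(filtered, out / "filtered_regions.tsv"))
        summary["filtered_correlated_regions"] = {
            v: int(n) for v, n in filtered.groupby("variable").size().items()}

        plot_cohort, n_excluded = cc.exclude_zero_sfmdrs(cohort)
        summary["sfmdrs_zero_excluded_from_plots"] = int(n_excluded)
        if "sfmdrs" in fnd_frames and len(plot_cohort):
            top = fnd_frames["sfmdrs"].head(2)["node"]
            keep_ids = wd.index.isin(plot_cohort["subject_id"])
            for node in top:
                scatter = pd.DataFrame({
                    "subject_id": wd.index[keep_ids],
                    "wd": wd.loc[keep_ids, node].to_numpy(),
                    "sfmdrs": plot_cohort.set_index("subject_id").loc[
                        wd.index[keep_ids], "sfmdrs"].to_numpy(),
                })
                written.append(_write_tsv(scatter, out / f"scatter_sfmdrs_{node}.tsv"))

        # --- report ----------------------------------------------------------
        stage = "report"
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        written.append(summary_path)
        _write_manifest(out, written, complete=True)
        return summary
    except Exception as exc:  # retain partial outputs with an incomplete MANIFEST
        _write_manifest(out, written, complete=False, failed_stage=stage)
        raise PipelineStageError(stage, exc) from exc


def _write_manifest(out: Path, written: list[Path], complete: bool,
                    failed_stage: str | None = None) -> None:
    lines = ["path\tsha256"]
    for path in sorted(set(written)):
        lines.append(f"{path.relative_to(out)}\t{_sha256(path)}")
    if not complete:
        lines.append(f"#INCOMPLETE\tfailed_stage={failed_stage}")
    (out / "MANIFEST.tsv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

_CONTINUOUS = ["age", "bdi", "stai_state", "stai_trait", "sf36_physical_health",
               "sf36_mental_health", "sf36_general_health", "sf36_physical_functioning",
               "sfmdrs", "cgi", "illness_duration_months"]


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics table: per-group mean (SD) and group-difference p-values.

    Continuous fields get a pooled two-sample t test, sex a chi-square test;
    FND-only fields are summarized for patients with no test. With fewer
    than two subjects in a group the tests are skipped with a notice.
    """
    fnd = cohort[cohort["group"] == "FND"]
    hc = cohort[cohort["group"] == "HC"]
    testable = len(fnd) >= 2 and len(hc) >= 2
    rows = []

    def fmt(series: pd.Series) -> str:
        vals = series.dropna()
        if vals.empty:
            return "NA"
        sd = vals.std(ddof=1) if len(vals) > 1 else float("nan")
        return f"{vals.mean():.2f} ({sd:.2f})"

    for col in _CONTINUOUS:
        fnd_only = col in FND_ONLY_COLUMNS
        a, b = fnd[col].dropna(), hc[col].dropna()
        if fnd_only or not testable or len(a) < 2 or len(b) < 2:
            p = "NA" if fnd_only else "skipped (too few subjects)"
        elif a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            p = f"{1.0:.4g}"
        else:
            p = f"{stats.ttest_ind(a, b, equal_var=True).pvalue:.4g}"
        rows.append({"field": col, "FND": fmt(fnd[col]),
                     "HC": "NA" if fnd_only else fmt(hc[col]), "p_value": p})

    f_counts = fnd["sex"].value_counts()
    h_counts = hc["sex"].value_counts()
    if testable:
        table = [[f_counts.get("female", 0), f_counts.get("male", 0)],
                 [h_counts.get("female", 0), h_counts.get("male", 0)]]
        if min(min(r) for r in table) >= 0 and all(sum(r) for r in table):
            chi_p = f"{stats.chi2_contingency(table)[1]:.4g}"
        else:
            chi_p = "skipped (empty cell)"
    else:
        chi_p = "skipped (too few subjects)"
    rows.append({"field": "sex (female/male)",
                 "FND": f"{f_counts.get('female', 0)}/{f_counts.get('male', 0)}",
                 "HC": f"{h_counts.get('female', 0)}/{h_counts.get('male', 0)}",
                 "p_value": chi_p})
    rows.append({"field": "medication_any_psychotropic (n)",
                 "FND": str(int(fnd["medication_any_psychotropic"].sum())),
                 "HC": str(int(hc["medication_any_psychotropic"].sum())),
                 "p_value": "NA"})
    return pd.DataFrame(rows, columns=["field", "FND", "HC", "p_value"])


# ---------------------------------------------------------------------------
# loading helpers for file-based CLI subcommands
# ---------------------------------------------------------------------------

def load_connectome_dir(directory: str | Path, weight_kind: str, cohort: pd.DataFrame):
    """Load ``<subject_id>_<weight_kind>.csv`` for every cohort subject."""
    directory = Path(directory)
    conns = []
    for sid in cohort["subject_id"]:
        path = directory / f"{sid}_{weight_kind}.csv"
        if not path.exists():
            raise ValidationError(f"missing connectome file {path}")
        conns.append(read_connectome(path, weight_kind, subject_id=sid))
    return conns
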