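"""End-to-end study orchestration.

One config drives the full replica of the study design: obtain data
(synthetic, or files on disk) -> filter subjects -> harmonize sites ->
CPM per behavioural score and per diagnostic-subtype subset -> transfer
the consensus networks to the validation and control samples (with FDR
within each sample's family of tests) -> network-anatomy summaries. Every
stage writes plain-text outputs under a run directory, together with a
key-value manifest and a log.

Harmonization is applied once to each pooled sample before CPM (model,
validation, and control samples separately); fitting the harmonizer on the
pooled model sample means fold test subjects contributed to the site
estimates — accepted here to mirror the common order of operations, and a
``harmonization_strict`` switch is deliberately left out of scope of this
driver (the library's ``combat_fit_transform`` can be applied per fold by
hand where that comparison is wanted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import n_nodes_from_edges
from .cpm import fdr_bh, run_cpm
from .filtering import FilterConfig, filter_subjects
from .harmonize import combat_fit_transform, covariate_matrix
from .io import (
    read_edge_table, read_phenotype, write_edge_mask, write_edge_list,
)
from .simulate import GeneratorSpec, generate, make_atlas
from .validation import (
    external_validate, fit_consensus_model, rank_nodes, summarize_network,
)

logger = logging.getLogger("cpmconn")

SCORE_COLUMNS = {
    "total": "score_total",
    "social": "score_social",
    "communication": "score_communication",
    "rrb": "score_rrb",
}


def usable_covariates(pheno: pd.DataFrame, names: list,
                      min_level_count: int = 3) -> list:
    """Covariates that can be adjusted for in this sample.

    Drops columns absent from the table, constant columns, and two-level
    (categorical) columns whose minority level has fewer than
    ``min_level_count`` subjects — a near-singleton level makes
    leave-one-out covariate adjustment rank deficient (the held-out
    subject's indicator coincides with the covariate column).
    """
    out = []
    for c in names:
        if c not in pheno.columns:
            continue
        v = pheno[c]
        nu = v.nunique()
        if nu < 2:
            continue
        if nu == 2 and v.value_counts().min() < min_level_count:
            logger.info("covariate '%s' dropped: minority level has < %d "
                        "subjects", c, min_level_count)
            continue
        out.append(c)
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    seed: int
    #: overrides for GeneratorSpec when simulating; None -> use `paths`
    simulate: dict | None = field(default_factory=dict)
    #: per-sample {"edges": csv, "pheno": csv} when loading from disk
    paths: dict | None = None
    filter: dict = field(default_factory=dict)
    harmonize: bool = True
    harmonize_mode: str = "parametric"
    harmonize_covariates: list = field(default_factory=lambda: [
        "group", "age", "sex", "fiq", "mfd"])
    cpm_covariates: list = field(default_factory=lambda: ["age", "sex", "mfd"])
    p_threshold: float = 0.01
    n_perm: int = 1000
    tail: str = "both"
    scores: list = field(default_factory=lambda: [
        "total", "social", "communication", "rrb"])
    subtypes: list = field(default_factory=lambda: ["all", "CA", "AS"])
    min_n: int = 30
    truncate_timepoints: int | None = None   # reserved for time-series input

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _get_samples(config: RunConfig) -> dict:
    """{sample: {"edges": n x E, "pheno": DataFrame}} from sim or disk."""
    if config.paths:
        out = {}
        for name, p in config.paths.items():
            ids, edges = read_edge_table(p["edges"])
            pheno = read_phenotype(p["pheno"])
            pheno = pheno.set_index("subject_id").loc[ids].reset_index()
            out[name] = {"edges": edges, "pheno": pheno}
        return out
    spec = GeneratorSpec(**{**(config.simulate or {}), "seed": config.seed})
    ds = generate(spec)
    out = {}
    for name in ("model", "validation", "control"):
        edges, pheno = ds.sample(name)
        out[name] = {"edges": edges, "pheno": pheno}
    out["_truth"] = ds.truth
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns a results dict and writes
    stage outputs, a manifest, and a log under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_fh = logging.FileHandler(out / "run.log", mode="w")
    log_fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_fh)
    logger.setLevel(logging.INFO)
    manifest = {"cpmconn_version": __version__, "seed": config.seed}
    t0 = time.time()
    stage = "load"
    try:
        samples = _get_samples(config)
        truth = samples.pop("_truth", None)
        for name, s in samples.items():
            manifest[f"digest_{name}_edges"] = _digest(s["edges"])
        manifest["t_load_s"] = round(time.time() - t0, 2)

        # ---------------- filter ----------------
        stage = "filter"
        t = time.time()
        fcfg_fields = {k: v for k, v in (config.filter or {}).items()}
        fcfg = FilterConfig(**fcfg_fields)
        for name, s in samples.items():
            included, report = filter_subjects(s["pheno"], fcfg)
            keep = s["pheno"]["subject_id"].astype(str).isin(included).to_numpy()
            logger.info("filter[%s]: kept %d / %d", name, keep.sum(), len(keep))
            report.to_csv(out / f"filter_{name}.csv", index=False)
            s["edges"] = s["edges"][keep]
            s["pheno"] = s["pheno"].loc[keep].reset_index(drop=True)
        manifest["t_filter_s"] = round(time.time() - t, 2)

        # ---------------- harmonize ----------------
        stage = "harmonize"
        t = time.time()
        if config.harmonize:
            for name, s in samples.items():
                covs = usable_covariates(s["pheno"], config.harmonize_covariates)
                C = covariate_matrix(s["pheno"], covs) if covs else None
                s["edges"], _ = combat_fit_transform(
                    s["edges"], s["pheno"]["site"], C,
                    mode=config.harmonize_mode, covariate_names=covs)
                logger.info("harmonize[%s]: %s mode, covariates %s", name,
                            config.harmonize_mode, covs)
        manifest["t_harmonize_s"] = round(time.time() - t, 2)

        # ---------------- CPM per subtype x score ----------------
        stage = "cpm"
        t = time.time()
        model = samples["model"]
        n_nodes = n_nodes_from_edges(model["edges"].shape[1])
        analyses = {}
        for subtype in config.subtypes:
            if subtype == "all":
                rows = np.ones(len(model["pheno"]), dtype=bool)
            else:
                rows = (model["pheno"]["subtype"] == subtype).to_numpy()
            for score in config.scores:
                col = SCORE_COLUMNS[score]
                ok = rows & model["pheno"][col].notna().to_numpy()
                n = int(ok.sum())
                key = f"{subtype}_{score}"
                if n < config.min_n:
                    logger.info("cpm[%s]: skipped, n=%d < min_n=%d",
                                key, n, config.min_n)
                    analyses[key] = None
                    continue
                pheno = model["pheno"].loc[ok]
                covs = usable_covariates(pheno, config.cpm_covariates)
                C = covariate_matrix(pheno, covs) if covs else None
                res = run_cpm(
                    model["edges"][ok], pheno[col].to_numpy(float), C,
                    p_threshold=config.p_threshold, tail=config.tail,
                    n_perm=config.n_perm, seed=config.seed,
                    subject_ids=pheno["subject_id"].tolist())
                analyses[key] = {"result": res, "rows": ok, "score_col": col}
                _write_cpm(out / f"cpm_{key}", res)
                logger.info("cpm[%s]: n=%d %s", key, n, {
                    tl: f"r={res.evaluation[tl][0]:.3f} "
                        f"p_perm={res.permutation[tl].p_perm:.4f}"
                    for tl in res.permutation})
        manifest["t_cpm_s"] = round(time.time() - t, 2)

        # ---------------- validation / specificity ----------------
        stage = "validate"
        t = time.time()
        reports = []
        for key, a in analyses.items():
            if a is None:
                continue
            res, col = a["result"], a["score_col"]
            pheno_m = samples["model"]["pheno"].loc[a["rows"]]
            for tl, sign in (("neg", -1), ("pos", 1)):
                if tl not in res.consensus or res.consensus[tl].n_edges == 0:
                    continue
                tm = fit_consensus_model(
                    samples["model"]["edges"][a["rows"]],
                    pheno_m[col].to_numpy(float), res.consensus[tl], sign)
                for sample_name in ("validation", "control"):
                    if sample_name not in samples:
                        continue
                    s = samples[sample_name]
                    ok = s["pheno"][col].notna().to_numpy()
                    if ok.sum() < 10:
                        continue
                    covs_v = usable_covariates(s["pheno"].loc[ok],
                                               config.cpm_covariates,
                                               min_level_count=1)
                    C = covariate_matrix(s["pheno"].loc[ok], covs_v) \
                        if covs_v else None
                    rep = external_validate(
                        res.consensus[tl], tm, s["edges"][ok],
                        s["pheno"].loc[ok, col].to_numpy(float), C,
                        sign=sign, sample=sample_name,
                        provenance=f"{key}:{tl}")
                    reports.append(rep)
        # FDR within each sample's family of tests
        for sample_name in ("validation", "control"):
            fam = [r for r in reports if r.sample == sample_name]
            if fam:
                q = fdr_bh([r.p for r in fam])
                for r, qv in zip(fam, q):
                    r.p_fdr = float(qv)
        pd.DataFrame([asdict(r) for r in reports]).to_csv(
            out / "validation_reports.csv", index=False)
        manifest["t_validate_s"] = round(time.time() - t, 2)

        # ---------------- anatomy ----------------
        stage = "anatomy"
        t = time.time()
        atlas = make_atlas(n_nodes, 6)
        for key, a in analyses.items():
            if a is None:
                continue
            for tl in a["result"].consensus:
                mask = a["result"].consensus[tl]
                if mask.n_edges == 0:
                    continue
                d = out / f"anatomy_{key}_{tl}"
                d.mkdir(exist_ok=True)
                summ = summarize_network(mask, atlas)
                summ.node_degree.to_csv(d / "degrees.csv")
                summ.pair_counts.to_csv(d / "pair_counts.csv")
                summ.edge_list.to_csv(d / "edges.csv", index=False)
                rank_nodes(summ, 10).to_csv(d / "top_nodes.csv", index=False)
        manifest["t_anatomy_s"] = round(time.time() - t, 2)
    except Exception:
        logger.exception("pipeline aborted in stage '%s'", stage)
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        raise
    finally:
        logger.removeHandler(log_fh)
        log_fh.close()

    manifest["t_total_s"] = round(time.time() - t0, 2)
    _write_manifest(out, manifest)
    return {"analyses": analyses, "reports": reports, "truth": truth,
            "manifest": manifest, "samples": samples}


def _write_cpm(d: Path, res) -> None:
    d.mkdir(parents=True, exist_ok=True)
    pred = pd.DataFrame({"subject_id": res.subject_ids,
                         "observed": res.observed})
    for tl, p in res.predictions.items():
        pred[f"predicted_{tl}"] = p
    pred.to_csv(d / "predictions.csv", index=False)
    for tl, mask in res.consensus.items():
        write_edge_mask(mask.values, d / f"consensus_{tl}.csv")
        write_edge_list(mask.values, d / f"consensus_{tl}_edges.csv")
    summary = {}
    for tl in res.predictions:
        r, p, df = res.evaluation[tl]
        summary[tl] = {"r": r, "p_parametric": p, "df": df,
                       "n_empty_folds": res.n_empty_folds[tl],
                       "invalid": res.invalid[tl]}
        if tl in res.consensus:
            summary[tl]["n_consensus_edges"] = res.consensus[tl].n_edges
        if tl in res.permutation:
            pr = res.permutation[tl]
            summary[tl].update({"p_perm": pr.p_perm,
                                "mean_null_r": pr.mean_null_r})
            np.savetxt(d / f"null_r_{tl}.csv", pr.null_r, fmt="%.17g")
    summary["config"] = {k: v for k, v in res.config.items()
                         if not k.startswith("_")}
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k} = {v}\n")
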