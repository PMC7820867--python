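"""End-to-end orchestration: simulate -> preprocess -> diversity -> screen ->
bvs -> report, with a JSON run manifest for reproducibility.

Stages are run in dependency order and each records the SHA-256 digests of
its inputs in the manifest; rerunning with an unchanged configuration and
inputs skips stages whose digests match and whose outputs are present.
Tumor and healthy tissues are analyzed separately (each tissue's samples are
screened and modelled on their own), which is the default stratification for
paired mucosa designs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bvs import BvsConfig, render_association_tables, run_bvs
from .diversity import diversity_profile, paired_signed_rank, pairing_cluster_check, rarefaction_curve
from .preprocess import (
    aggregate_to_rank,
    apply_loq,
    build_composition_response,
    standardize_covariates,
)
from .screening import screen_cytokines
from .synthetic import StudyConfig, generate_paired_study
from .tables import (
    packaged_loq_table,
    read_cytokine_panel,
    read_loq_table,
    read_otu_table,
    read_pairing,
    write_cytokine_panel,
    write_otu_table,
    write_pairing,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "make_report", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "cytodm_run",
    "stages": ["simulate", "preprocess", "diversity", "screen", "bvs", "report"],
    "tissues": ["tumor", "healthy"],
    "inputs": {},  # counts / taxonomy / cytokines / pairing / loq paths
    "simulate": {},  # StudyConfig overrides
    "preprocess": {"transform": "log1p_zscore", "top_k": 3, "uloq_policy": "flag"},
    "diversity": {"step": 50, "slope_threshold": 1e-5},
    "screen": {"top_m": 3},
    "bvs": {"iterations": 20000, "burn_in": 10000, "cytokines": None},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise PipelineError(f"config file {path} must define a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _validate_config(cfg: dict) -> None:
    known = set(DEFAULT_CONFIG)
    unknown = set(cfg) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    stages = cfg["stages"]
    allowed = ["simulate", "preprocess", "diversity", "screen", "bvs", "report"]
    bad = [s for s in stages if s not in allowed]
    if bad:
        raise PipelineError(f"unknown stages: {bad}")
    if "simulate" not in stages:
        needed = ["counts", "cytokines", "pairing"]
        missing = [k for k in needed if not cfg["inputs"].get(k)]
        if missing and {"preprocess", "screen", "bvs"} & set(stages):
            raise PipelineError(f"inputs missing required paths: {missing}")
        if "diversity" in stages and not cfg["inputs"].get("counts"):
            raise PipelineError("inputs missing required paths: ['counts']")


def run_pipeline(
    config: str | Path | dict | None = None, overrides: dict | None = None
) -> Path:
    """Execute the configured stages; returns the artifact directory.

    ``config`` may be a YAML path or an already-merged mapping. Raises
    :class:`PipelineError` (naming the stage) on any failure.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config, overrides)
    else:
        cfg = _merge(DEFAULT_CONFIG, config or {})
        if overrides:
            cfg = _merge(cfg, overrides)
    _validate_config(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            previous = {}
    manifest: dict[str, Any] = {
        "config": cfg,
        "seed": cfg["seed"],
        "version": __version__,
        "stages": {},
        "warnings": [],
    }
    logger.info("run config: %s", json.dumps(cfg, default=str))

    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "cytokines": outdir / "cytokines.csv",
        "pairing": outdir / "pairing.tsv",
    }
    if "simulate" not in cfg["stages"]:
        for key in paths:
            if cfg["inputs"].get(key):
                paths[key] = Path(cfg["inputs"][key])

    def stage_record(name: str, inputs: list[Path], outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "inputs": {str(p): _digest(p) for p in inputs if p.exists()},
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(time.time() - t0, 3),
        }

    def unchanged(name: str, inputs: list[Path], outputs: list[Path]) -> bool:
        prev = previous.get(name)
        if not prev:
            return False
        cur = {str(p): _digest(p) for p in inputs if p.exists()}
        return prev.get("inputs") == cur and all(Path(o).exists() for o in prev.get("outputs", []))

    stages = cfg["stages"]
    try:
        if "simulate" in stages:
            t0 = time.time()
            sim_outputs = list(paths.values()) + [outdir / "truth.json"]
            sc = StudyConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
            study = generate_paired_study(sc)
            write_otu_table(study.otu_table, paths["counts"], paths["taxonomy"])
            write_cytokine_panel(study.cytokine_panel, paths["cytokines"])
            write_pairing(study.pairing, paths["pairing"])
            truth = {
                "coefficient_matrix": study.truth.coefficient_matrix.tolist(),
                "active_set": sorted(study.truth.active_set),
                "overdispersion": study.truth.overdispersion,
                "seed": study.truth.seed,
                "cytokine_names": study.cytokine_panel.cytokine_names,
                "category_names": study.composition.category_names,
            }
            (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
            stage_record("simulate", [], sim_outputs)

        table = panel = pairing = None

        def load_inputs():
            nonlocal table, panel, pairing
            if table is None:
                table = read_otu_table(
                    paths["counts"],
                    paths["taxonomy"] if paths["taxonomy"].exists() else None,
                )
            if panel is None and paths["cytokines"].exists():
                panel = read_cytokine_panel(paths["cytokines"])
            if pairing is None and paths["pairing"].exists():
                pairing = read_pairing(paths["pairing"])

        pre = cfg["preprocess"]
        genus_path = outdir / "genus_counts.tsv"
        censored_path = outdir / "cytokines_censored.csv"
        comp_paths = {t: outdir / f"composition_{t}.csv" for t in cfg["tissues"]}

        if "preprocess" in stages:
            t0 = time.time()
            ins = [paths["counts"], paths["taxonomy"], paths["cytokines"], paths["pairing"]]
            outs = [genus_path, censored_path] + list(comp_paths.values())
            if unchanged("preprocess", ins, outs):
                logger.info("preprocess unchanged; skipping")
                manifest["stages"]["preprocess"] = previous["preprocess"]
            else:
                load_inputs()
                loq_src = cfg["inputs"].get("loq")
                loq = read_loq_table(loq_src) if loq_src else packaged_loq_table()
                if any(c not in loq for c in panel.cytokine_names):
                    # synthetic cytokine names are not in the packaged Luminex panel
                    from .synthetic import default_loq

                    loq = default_loq(panel.cytokine_names)
                censored = apply_loq(panel, loq, pre["uloq_policy"])
                write_cytokine_panel(censored, censored_path)
                genus = aggregate_to_rank(table, "genus")
                write_otu_table(genus, genus_path)
                for tissue in cfg["tissues"]:
                    sids = pairing.samples_for_tissue(tissue)
                    comp = build_composition_response(
                        genus.select_samples(sids), pre["top_k"]
                    )
                    comp.to_frame().to_csv(comp_paths[tissue], index_label="sample_id")
                stage_record("preprocess", ins, outs)

        if "diversity" in stages:
            t0 = time.time()
            div = cfg["diversity"]
            div_path = outdir / "diversity_profile.csv"
            rare_path = outdir / "rarefaction.csv"
            ins = [paths["counts"], paths["pairing"]]
            outs = [div_path, rare_path]
            if unchanged("diversity", ins, outs):
                logger.info("diversity unchanged; skipping")
                manifest["stages"]["diversity"] = previous["diversity"]
            else:
                load_inputs()
                prof = diversity_profile(
                    table, step=div["step"], slope_threshold=div["slope_threshold"]
                )
                grids = []
                for i, sid in enumerate(table.sample_ids):
                    curve = rarefaction_curve(
                        table.counts[i], div["step"], div["slope_threshold"]
                    )
                    grids.append(
                        pd.DataFrame(
                            {
                                "sample_id": sid,
                                "depth_reads": curve.depths,
                                "expected_otus": curve.expected_otus,
                            }
                        )
                    )
                pd.concat(grids).to_csv(rare_path, index=False)
                if pairing is not None and len(pairing.pairs) >= 2:
                    frac = pairing_cluster_check(table, pairing)
                    prof.attrs["paired_fraction"] = frac
                    tests = {}
                    tum = pairing.tumor_samples()
                    hea = pairing.healthy_samples()
                    for col in ("richness", "shannon", "evenness", "chao1"):
                        a = prof.loc[tum, col].to_numpy(dtype=float)
                        b = prof.loc[hea, col].to_numpy(dtype=float)
                        try:
                            stat, p = paired_signed_rank(a, b)
                        except ValueError:
                            stat, p = float("nan"), float("nan")
                        tests[col] = {"statistic": stat, "p_value": p}
                    (outdir / "diversity_tests.json").write_text(
                        json.dumps({"paired_cluster_fraction": frac, "paired_tests": tests}, indent=1)
                    )
                prof.to_csv(div_path)
                stage_record("diversity", ins, outs)

        screen_paths = {t: outdir / f"screening_{t}.csv" for t in cfg["tissues"]}
        selections: dict[str, list[str]] = {}
        if "screen" in stages:
            t0 = time.time()
            load_inputs()
            from .tables import CompositionResponse

            ins = [paths["cytokines"]] + list(comp_paths.values())
            outs = list(screen_paths.values())
            if unchanged("screen", ins, outs):
                logger.info("screen unchanged; skipping")
                manifest["stages"]["screen"] = previous["screen"]
                # bvs falls back to reading the existing screening CSVs
            else:
                for tissue in cfg["tissues"]:
                    comp_df = pd.read_csv(comp_paths[tissue], index_col=0)
                    comp = CompositionResponse(
                        comp_df.to_numpy(dtype=np.int64),
                        [str(s) for s in comp_df.index],
                        [str(c) for c in comp_df.columns],
                    )
                    sub = panel.select_samples(list(comp_df.index))
                    res = screen_cytokines(
                        sub, comp, transform=pre["transform"], m=cfg["screen"]["top_m"]
                    )
                    res.to_frame().to_csv(screen_paths[tissue])
                    selections[tissue] = res.selection
                stage_record("screen", ins, outs)

        if "bvs" in stages:
            t0 = time.time()
            load_inputs()
            from .tables import CompositionResponse

            bcfg = cfg["bvs"]
            ins = [paths["cytokines"]] + list(comp_paths.values()) + list(screen_paths.values())
            expected = [
                outdir / f"{stem}_{t}.csv"
                for t in cfg["tissues"]
                for stem in ("ppi", "coefficients")
            ]
            if unchanged("bvs", ins, expected):
                logger.info("bvs unchanged; skipping")
                manifest["stages"]["bvs"] = previous["bvs"]
                cfg_tissues_bvs: list[str] = []
            else:
                cfg_tissues_bvs = list(cfg["tissues"])
            outs = []
            for tissue in cfg_tissues_bvs:
                comp_df = pd.read_csv(comp_paths[tissue], index_col=0)
                comp = CompositionResponse(
                    comp_df.to_numpy(dtype=np.int64),
                    [str(s) for s in comp_df.index],
                    [str(c) for c in comp_df.columns],
                )
                chosen = bcfg.get("cytokines")
                if not chosen:
                    if tissue in selections:
                        chosen = selections[tissue]
                    elif screen_paths[tissue].exists():
                        sdf = pd.read_csv(screen_paths[tissue], index_col=0)
                        chosen = list(sdf[sdf["selected"]].sort_values("rank").index)
                    else:
                        raise PipelineError(
                            "bvs needs either an explicit cytokine list or a prior screen"
                        )
                sub = panel.select_samples(list(comp_df.index)).select_cytokines(chosen)
                design = standardize_covariates(sub, pre["transform"])
                config_b = BvsConfig(
                    n_iterations=bcfg["iterations"],
                    burn_in=bcfg["burn_in"],
                    seed=cfg["seed"],
                )
                result = run_bvs(design, comp, config_b)
                ppi, coef = render_association_tables(result)
                ppi_path = outdir / f"ppi_{tissue}.csv"
                coef_path = outdir / f"coefficients_{tissue}.csv"
                ppi.to_csv(ppi_path, index_label="cytokine")
                coef.to_csv(coef_path, index_label="cytokine")
                n_kept, p, J = result.theta_draws.shape
                chain = pd.DataFrame(
                    result.theta_draws.reshape(n_kept, p * J),
                    columns=[
                        f"{r}|{c}"
                        for r in ["intercept"] + result.covariate_names
                        for c in result.category_names
                    ],
                )
                chain["threshold"] = result.threshold_draws
                chain.to_csv(outdir / f"chains_{tissue}.csv", index_label="draw")
                (outdir / f"bvs_meta_{tissue}.json").write_text(
                    json.dumps(
                        {
                            "cytokines": chosen,
                            "acceptance_rates": result.acceptance_rates,
                            "config": asdict(config_b),
                        },
                        indent=1,
                    )
                )
                outs += [ppi_path, coef_path]
            if cfg_tissues_bvs:
                stage_record("bvs", ins, outs)

        if "report" in stages:
            t0 = time.time()
            report = make_report(outdir, tissues=cfg["tissues"])
            stage_record("report", [], [outdir / "report.md"])
            (outdir / "report.md").write_text(report)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage failed: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return outdir


def make_report(outdir: str | Path, tissues: list[str] | None = None) -> str:
    """Render a human-readable markdown summary of whatever stage outputs are
    present in the artifact directory. Idempotent."""
    outdir = Path(outdir)
    tissues = tissues or ["tumor", "healthy"]
    lines = ["# cytodm run report", ""]
    found = False
    div_path = outdir / "diversity_profile.csv"
    if div_path.exists():
        found = True
        prof = pd.read_csv(div_path, index_col=0)
        lines += ["## Alpha diversity (per-sample means)", ""]
        means = prof[["richness", "shannon", "evenness", "chao1", "goods_coverage"]].mean()
        lines += [means.round(3).to_string(), ""]
        tests_path = outdir / "diversity_tests.json"
        if tests_path.exists():
            tests = json.loads(tests_path.read_text())
            lines += [
                f"Paired-sample dendrogram fraction: {tests['paired_cluster_fraction']:.2f}",
                "",
                "Paired signed-rank tests (tumor vs healthy):",
            ]
            for k, v in tests["paired_tests"].items():
                lines.append(f"- {k}: W = {v['statistic']:.1f}, p = {v['p_value']:.4g}")
            lines.append("")
    for tissue in tissues:
        sp = outdir / f"screening_{tissue}.csv"
        if sp.exists():
            found = True
            sdf = pd.read_csv(sp, index_col=0).sort_values("rank")
            lines += [f"## Screening ({tissue})", "", sdf.round(4).to_string(), ""]
        pp = outdir / f"ppi_{tissue}.csv"
        cp = outdir / f"coefficients_{tissue}.csv"
        if pp.exists() and cp.exists():
            found = True
            lines += [
                f"## Posterior probabilities of inclusion ({tissue})",
                "",
                pd.read_csv(pp, index_col=0).to_string(),
                "",
                f"## Posterior mean coefficients ({tissue})",
                "",
                pd.read_csv(cp, index_col=0).to_string(),
                "",
            ]
    if not found:
        raise PipelineError(f"no stage outputs found under {outdir}")
    return "\n".join(lines) + "\n"
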