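"""End-to-end pipeline: simulate (optional) -> screen -> calibrate -> score
-> reliability -> DIF -> validity, with a manifest recording the seed,
input hashes, and per-stage status."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data import read_dataset, screen_scores, DataError
from .grm import GradedResponseModel
from .reliability import conditional_reliability, fit_location_scale
from .invariance import detect_dif, sensitivity_analysis
from .validity import (criterion_regression, impute, part_correlation,
                       validity_report)
from .simulate import GeneratorConfig, generate_dataset

log = logging.getLogger("kidbank")


@dataclass
class PipelineConfig:
    """Run configuration; every stage draws from one root seed."""

    outdir: str = "run"
    seed: int = 0
    simulate: dict = None            # GeneratorConfig fields, or None
    bank_path: str = None
    responses_path: str = None
    children_path: str = None
    knots: tuple = (12, 24, 36, 48, 60)
    n_quadrature: int = 101
    em_max_cycles: int = 500
    screening_threshold_sd: float = 5.0
    screening_columns: tuple = ()
    reliability_cutoff: float = 0.80
    dif_groupings: tuple = ("education", "race_ethnicity")
    dif_fdr: float = 0.05
    mi_m: int = 10
    correlation_min: float = 0.50
    correlation_ideal: float = 0.70
    concurrent_columns: tuple = ()

    def __post_init__(self):
        if not 0 < self.reliability_cutoff < 1:
            raise DataError("reliability cutoff must be in (0,1)")
        if not 0 < self.correlation_min < 1 or not 0 < self.correlation_ideal < 1:
            raise DataError("correlation thresholds must be in (0,1)")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def validate_paths(self):
        if self.simulate is None:
            for p in (self.bank_path, self.responses_path,
                      self.children_path):
                if p is None or not Path(p).exists():
                    raise DataError(f"input file missing: {p}")


def _hash_file(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig):
    """Execute all stages; returns a dict of per-stage outputs and writes a
    manifest plus stage artifacts under ``config.outdir``."""
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    import kidbank
    manifest = {"version": kidbank.__version__, "seed": config.seed, "stages": {},
                "outputs": {}}
    results = {}

    def stage(name, fn):
        t0 = time.time()
        log.info("stage %s ...", name)
        try:
            results[name] = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed",
                                        "error": str(exc)}
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 2)}
        return results[name]

    # -- data -------------------------------------------------------------
    if config.simulate is not None:
        def do_sim():
            gc = GeneratorConfig(seed=config.seed, **config.simulate)
            ds = generate_dataset(gc)
            ds.save(out / "data")
            return ds
        ds = stage("simulate", do_sim)
        bank, responses, covariates = ds.item_bank, ds.responses, ds.covariates
    else:
        bank, responses, covariates = stage("read", lambda: read_dataset(
            config.bank_path, config.responses_path, config.children_path))

    # -- screening --------------------------------------------------------
    def do_screen():
        reports = {}
        keep = np.ones(len(covariates.table), bool)
        for col in config.screening_columns:
            if col not in covariates.table.columns:
                continue
            rep = screen_scores(covariates.table[col].to_numpy(float),
                                threshold_sd=config.screening_threshold_sd,
                                ids=covariates.child_ids)
            reports[col] = rep.to_json()
            drop = set(rep.excluded_ids)
            keep &= ~covariates.table["child_id"].isin(drop).to_numpy()
        with open(out / "screening.json", "w") as fh:
            json.dump(reports, fh, indent=2)
        return keep
    keep = stage("screen", do_screen)
    cov_tbl = covariates.table[keep].reset_index(drop=True)
    kept_ids = set(cov_tbl["child_id"])
    resp_tbl = responses.table[responses.table["child_id"].isin(kept_ids)]
    from .data import CovariateTable, ResponseMatrix
    covariates = CovariateTable(cov_tbl)
    responses = ResponseMatrix(resp_tbl.reset_index(drop=True))

    # -- calibration ------------------------------------------------------
    def do_calibrate():
        model = GradedResponseModel.from_dataset(
            bank, responses, covariates, knots=config.knots,
            n_quadrature=config.n_quadrature)
        res = model.fit(max_cycles=config.em_max_cycles)
        res.params.save(out / "params.json")
        return res
    fit = stage("calibrate", do_calibrate)

    # -- scoring ----------------------------------------------------------
    def do_score():
        ss = fit.score()
        ss.to_csv(out / "scores.csv")
        return ss
    scores = stage("score", do_score)

    # -- reliability ------------------------------------------------------
    def do_reliability():
        ls = fit_location_scale(scores, knots=config.knots)
        rep = conditional_reliability(scores, ls,
                                      cutoff=config.reliability_cutoff,
                                      knots=config.knots)
        rep.to_json(out / "reliability.json")
        rep.curve_frame().to_csv(out / "reliability_curve.csv", index=False)
        return rep
    stage("reliability", do_reliability)

    # -- DIF --------------------------------------------------------------
    def do_dif():
        reports = {}
        ages = covariates.table["age_months"].to_numpy(float)
        cov_idx = covariates.table.set_index("child_id")
        for grouping in config.dif_groupings:
            if grouping not in covariates.table.columns:
                continue
            Y, child_ids = responses.to_dense(bank)
            g = cov_idx.loc[child_ids, grouping].to_numpy()
            a = cov_idx.loc[child_ids, "age_months"].to_numpy(float)
            rep = detect_dif(Y, bank, a, g, fdr=config.dif_fdr,
                             grouping_name=grouping)
            rep.to_json(out / f"dif_{grouping}.json")
            sens = sensitivity_analysis(
                Y, bank, a, g,
                dif_items=[bank.item_ids.index(i) for i in rep.flagged_items],
                seed=config.seed)
            sens.to_json(out / f"sensitivity_{grouping}.json")
            reports[grouping] = (rep, sens)
        return reports
    stage("dif", do_dif)

    # -- validity ---------------------------------------------------------
    def do_validity():
        corr = []
        ctab = covariates.table.set_index("child_id")
        aligned = ctab.loc[scores.table["child_id"]]
        for col in config.concurrent_columns:
            if col not in aligned.columns:
                continue
            corr.append(part_correlation(
                scores.eap, aligned[col].to_numpy(float),
                scores.ages, x_name="ability", y_name=col,
                knots=config.knots))
        imps = impute(covariates, m=config.mi_m, seed=config.seed,
                      scores=scores)
        pooled = criterion_regression(scores, imps, knots=config.knots)
        rep = validity_report(corr, pooled, path=out / "validity_report.json")
        pooled.to_csv(out / "criterion_models.csv")
        return rep
    stage("validity", do_validity)

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _hash_file(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
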