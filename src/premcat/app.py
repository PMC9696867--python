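"""Command-line interface and end-to-end analysis pipeline.

``premcat pipeline`` chains the full validation sequence on a response
file: descriptive screening -> assumption checks -> GPCM calibration
(with PCM comparison) -> DIF -> CAT simulation, writing one JSON report
per stage plus a human-readable summary. Every report is stamped with the
package version, a configuration hash, and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

import premcat
from premcat.databank import (
    ResponseMatrix, cronbach_alpha, read_bank, read_responses,
    recode_categories, screen_items, write_bank, write_responses,
)
from premcat.calibration import (
    QuadratureGrid, eap_score_matrix, fit_gpcm, infit_outfit, information,
    likelihood_ratio_test,
)
from premcat.dimensionality import (
    bifactor_indices, monotonicity_check, polychoric_matrix, q3_residuals,
)
from premcat.dif import dif_olr, dif_summary
from premcat.catengine import CatConfig, administer_interactive, simulate_cat_study
from premcat.simulate import paper_like_design, simulate_responses

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, YAML-serializable."""

    responses: str = ""
    out_dir: str = "premcat_out"
    item_columns: list = field(default_factory=list)
    covariate_columns: list = field(default_factory=list)
    r_max: float = 0.70
    recode_min_count: int = 10
    q3_threshold: float = 0.20
    n_group_factors: int = 2
    dif_alpha: float = 0.01
    dif_r2_threshold: float = 0.035
    sem_grid: list = field(default_factory=lambda: [0.33, 0.44, 0.55])
    seed: int = 0

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def stamp(payload: dict, config: PipelineConfig = None, seed: int = None) -> dict:
    """Attach version/config-hash/seed provenance to a JSON report."""
    payload = dict(payload)
    payload["_provenance"] = {
        "package": "premcat",
        "version": premcat.__version__,
        "config_hash": config.config_hash() if config is not None else None,
        "seed": seed if seed is not None else (config.seed if config else None),
    }
    return payload


def _write_json(path, payload):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, data: ResponseMatrix = None) -> dict:
    """Run the full validation pipeline; returns the stage reports.

    ``data`` may be passed directly (tests, library use); otherwise it is
    read from ``config.responses``. Writes JSONs under ``config.out_dir``.
    Raises on the first failing stage (partial outputs are retained).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = read_responses(config.responses, item_columns=config.item_columns,
                              covariate_columns=config.covariate_columns)
    reports = {}

    logger.info("stage 1/5: descriptive screening")
    screen = screen_items(data, r_max=config.r_max)
    reports["screening"] = screen.to_dict()
    _write_json(out / "screening.json", stamp(reports["screening"], config))
    survivors = screen.surviving_items
    data_s = data.subset_items(survivors)
    data_s, recode_map = recode_categories(data_s, min_count=config.recode_min_count)
    reports["recode_map"] = recode_map

    logger.info("stage 2/5: dimensionality diagnostics on %d items", len(survivors))
    corr = polychoric_matrix(data_s)
    dim = bifactor_indices(data_s, n_group_factors=config.n_group_factors,
                           corr=corr,
                           parallel_kwargs={"seed": config.seed})
    mono = monotonicity_check(data_s)
    reports["dimensionality"] = {**dim.to_dict(), "monotonicity": mono.to_dict()}
    _write_json(out / "dimensionality.json", stamp(reports["dimensionality"], config))

    logger.info("stage 3/5: GPCM calibration (with PCM comparison)")
    grid = QuadratureGrid.default()
    bank, fit_g = fit_gpcm(data_s, grid)
    _, fit_p = fit_gpcm(data_s, grid, pcm=True)
    fit_g.lrt = likelihood_ratio_test(fit_g, fit_p)
    thetas = eap_score_matrix(data_s, bank, grid)
    itemfit = infit_outfit(data_s, bank, thetas)
    q3 = q3_residuals(data_s, bank, thetas, threshold=config.q3_threshold)
    info = information(bank)
    reports["fit"] = {
        "gpcm": fit_g.to_dict(), "pcm": fit_p.to_dict(),
        "infit": itemfit.infit, "outfit": itemfit.outfit,
        "alpha": cronbach_alpha(data_s),
        "q3": q3.to_dict(),
        "information_share_-2_2": info.share_in(-2.0, 2.0),
    }
    write_bank(bank, out / "bank.json")
    _write_json(out / "fit.json", stamp(reports["fit"], config))

    logger.info("stage 4/5: DIF analyses")
    dif_results = {}
    for grouping in data_s.covariates.columns:
        if data_s.covariates[grouping].nunique() < 2:
            logger.warning("skipping single-level grouping %r", grouping)
            continue
        dif_results[grouping] = dif_olr(data_s, grouping, thetas,
                                        alpha=config.dif_alpha,
                                        r2_threshold=config.dif_r2_threshold)
    reports["dif"] = dif_summary(dif_results)
    _write_json(out / "dif.json", stamp(reports["dif"], config))

    logger.info("stage 5/5: CAT simulation (replay)")
    catsim = simulate_cat_study(bank, sem_grid=config.sem_grid, data=data_s,
                                seed=config.seed)
    reports["catsim"] = catsim.to_dict()
    _write_json(out / "catsim.json", stamp(reports["catsim"], config))

    summary = {
        "n_respondents": data.n_respondents,
        "n_items_input": data.n_items,
        "n_items_removed": len(screen.removed_items),
        "n_items_bank": len(bank),
        "alpha": reports["fit"]["alpha"],
        "gpcm_aic": fit_g.aic, "pcm_aic": fit_p.aic,
        "dif_flagged": reports["dif"]["n_flagged_total"],
        "cat_mean_items": {s["sem_threshold"]: s["mean_items"]
                           for s in reports["catsim"]["scenarios"]},
    }
    reports["summary"] = summary
    _write_json(out / "summary.json", stamp(summary, config))
    lines = [f"{k}: {v}" for k, v in summary.items()]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return reports


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def main(verbose):
    """premcat: polytomous-IRT item banking and adaptive testing."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")


@main.command("simulate")
@click.option("--design", "design_path", type=click.Path(exists=True),
              help="YAML design (keys of paper_like_design).")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--truth", "truth_path", type=click.Path())
def simulate_cmd(design_path, seed, out_path, truth_path):
    """Simulate GPCM responses from the study-like preset design."""
    kwargs = {}
    if design_path:
        with open(design_path) as fh:
            kwargs = yaml.safe_load(fh) or {}
    design = paper_like_design(seed=seed, **kwargs)
    data, theta = simulate_responses(design)
    write_responses(data, out_path)
    if truth_path:
        np.savetxt(truth_path, theta, header="theta", comments="")
    click.echo(f"wrote {data.n_respondents} x {data.n_items} responses to {out_path}")


def _load_data(responses, items, covariates):
    item_cols = items.split(",") if items else None
    cov_cols = covariates.split(",") if covariates else []
    if item_cols is None:
        import pandas as pd
        header = list(pd.read_csv(responses, nrows=0).columns)
        item_cols = [c for c in header if c not in cov_cols]
    return read_responses(responses, item_columns=item_cols,
                          covariate_columns=cov_cols)


@main.command("screen")
@click.option("--responses", required=True, type=click.Path(exists=True))
@click.option("--items", help="Comma-separated item columns (default: all non-covariate).")
@click.option("--covariates", default="", help="Comma-separated covariate columns.")
@click.option("--r-max", default=0.70, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def screen_cmd(responses, items, covariates, r_max, out_path):
    """Descriptive screening: distributions, redundancy removals, alpha."""
    data = _load_data(responses, items, covariates)
    report = screen_items(data, r_max=r_max)
    _write_json(out_path, stamp(report.to_dict()))
    click.echo(f"removed {len(report.removed_items)} of {data.n_items} items; "
               f"alpha = {report.alpha:.3f}")


@main.command("check")
@click.option("--responses", required=True, type=click.Path(exists=True))
@click.option("--items", help="Comma-separated item columns.")
@click.option("--covariates", default="")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def check_cmd(responses, items, covariates, seed, out_path):
    """IRT assumption checks: dimensionality, parallel analysis, monotonicity."""
    data = _load_data(responses, items, covariates)
    dim = bifactor_indices(data, parallel_kwargs={"seed": seed})
    mono = monotonicity_check(data)
    _write_json(out_path, stamp({**dim.to_dict(), "monotonicity": mono.to_dict()},
                                seed=seed))
    click.echo(f"eigenvalue ratio = {dim.first_second_ratio:.2f}, "
               f"omega_h = {dim.omega_h:.3f}, ECV general = {dim.ecv_general:.1f}%")


@main.command("calibrate")
@click.option("--responses", required=True, type=click.Path(exists=True))
@click.option("--items", help="Comma-separated item columns.")
@click.option("--covariates", default="")
@click.option("--model", type=click.Choice(["gpcm", "pcm"]), default="gpcm",
              show_default=True)
@click.option("--out", "bank_path", required=True, type=click.Path())
@click.option("--report", "report_path", type=click.Path())
def calibrate_cmd(responses, items, covariates, model, bank_path, report_path):
    """Calibrate the item bank by marginal maximum likelihood (EM)."""
    data = _load_data(responses, items, covariates)
    grid = QuadratureGrid.default()
    bank, fit = fit_gpcm(data, grid, pcm=(model == "pcm"))
    if model == "gpcm":
        _, fit_p = fit_gpcm(data, grid, pcm=True)
        fit.lrt = likelihood_ratio_test(fit, fit_p)
    write_bank(bank, bank_path)
    if report_path:
        thetas = eap_score_matrix(data, bank, grid)
        itemfit = infit_outfit(data, bank, thetas)
        _write_json(report_path, stamp({**fit.to_dict(), "infit": itemfit.infit,
                                        "outfit": itemfit.outfit}))
    click.echo(f"{model} LL = {fit.log_likelihood:.2f}, AIC = {fit.aic:.2f}, "
               f"converged = {fit.converged}")


@main.command("dif")
@click.option("--responses", required=True, type=click.Path(exists=True))
@click.option("--bank", "bank_path", required=True, type=click.Path(exists=True))
@click.option("--items", help="Comma-separated item columns.")
@click.option("--group", required=True, help="Comma-separated grouping covariates.")
@click.option("--alpha", default=0.01, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def dif_cmd(responses, bank_path, items, group, alpha, out_path):
    """DIF screen by ordinal logistic regression for each grouping."""
    groupings = group.split(",")
    data = _load_data(responses, items, ",".join(groupings))
    bank = read_bank(bank_path)
    data = data.subset_items(bank.item_ids)
    thetas = eap_score_matrix(data, bank)
    results = {g: dif_olr(data, g, thetas, alpha=alpha) for g in groupings}
    summary = dif_summary(results)
    _write_json(out_path, stamp(summary))
    click.echo(f"{summary['n_flagged_total']} of {summary['n_tests_total']} "
               f"tests flagged")


@main.command("cat-sim")
@click.option("--bank", "bank_path", required=True, type=click.Path(exists=True))
@click.option("--responses", type=click.Path(exists=True),
              help="Replay these response vectors (else generative).")
@click.option("--items", help="Comma-separated item columns.")
@click.option("--n", default=500, show_default=True, help="Generative sample size.")
@click.option("--sem", default="0.33,0.44,0.55", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def cat_sim_cmd(bank_path, responses, items, n, sem, seed, out_path):
    """Simulate CAT scenarios and report accuracy/precision/burden."""
    bank = read_bank(bank_path)
    sem_grid = [float(s) for s in sem.split(",")]
    data = _load_data(responses, items, "") if responses else None
    report = simulate_cat_study(bank, sem_grid=sem_grid, data=data,
                                n=None if data is not None else n, seed=seed)
    _write_json(out_path, stamp(report.to_dict(), seed=seed))
    for s in report.scenarios:
        click.echo(f"SEM<{s.sem_threshold}: r={s.r_vs_full:.3f} "
                   f"RMSE={s.rmse_vs_full:.3f} items={s.mean_items:.2f}")


@main.command("cat-run")
@click.option("--bank", "bank_path", required=True, type=click.Path(exists=True))
@click.option("--sem", default=0.33, show_default=True)
@click.option("--log", "log_path", type=click.Path(),
              help="Write the session transcript as JSON.")
def cat_run_cmd(bank_path, sem, log_path):
    """Administer the CAT interactively on the terminal."""
    bank = read_bank(bank_path)
    session = administer_interactive(bank, CatConfig(sem_threshold=sem))
    if log_path:
        _write_json(log_path, stamp({
            "administered": session.administered,
            "responses": session.responses,
            "trace": session.trace,
            "theta": session.final.theta, "se": session.final.se,
            "score_0_100": session.final.score_0_100,
            "stop_reason": session.stop_reason,
        }))


@main.command("pipeline")
@click.option("--config", "config_path", type=click.Path(exists=True),
              help="YAML PipelineConfig.")
@click.option("--responses", type=click.Path(exists=True))
@click.option("--items", help="Comma-separated item columns.")
@click.option("--covariates", default="")
@click.option("--out-dir", default="premcat_out", show_default=True)
@click.option("--seed", default=0, show_default=True)
def pipeline_cmd(config_path, responses, items, covariates, out_dir, seed):
    """Run screen -> check -> calibrate -> dif -> cat-sim end to end."""
    if config_path:
        config = PipelineConfig.from_yaml(config_path)
    else:
        config = PipelineConfig(
            responses=responses or "", out_dir=out_dir, seed=seed,
            item_columns=items.split(",") if items else [],
            covariate_columns=covariates.split(",") if covariates else [])
    if not config.item_columns and config.responses:
        import pandas as pd
        header = list(pd.read_csv(config.responses, nrows=0).columns)
        config.item_columns = [c for c in header
                               if c not in config.covariate_columns]
    try:
        run_pipeline(config)
    except Exception as exc:  # noqa: BLE001 - name the failing stage, exit non-zero
        click.echo(f"pipeline failed: {exc}", err=True)
        raise SystemExit(1)
    click.echo(f"pipeline complete; reports in {config.out_dir}")


if __name__ == "__main__":
    main()
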