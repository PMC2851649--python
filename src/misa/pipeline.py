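"""End-to-end pipeline orchestration and publication-style outputs.

Stages run in the order qc -> imputation -> screen -> model search ->
report. All randomness flows from a single configured seed through
per-stage substreams; re-running with the same configuration reproduces
every output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import StudyDataset, read_study, write_study
from .evidence import Priors, bf_to_evidence, screen
from .impute import draw_imputations, fit_imputer, missingness_bf, modal_fill
from .qc import apply_qc
from .search import run_search
from .simulate import SimulationConfig, default_scenario, simulate_study

__all__ = ["PipelineConfig", "run_pipeline", "render_tables"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; seed is mandatory for the sampler
    stages."""

    seed: int
    input_path: str | None = None  # None -> simulate the default scenario
    output_dir: str = "misa_run"
    # stage toggles
    run_qc: bool = True
    run_imputation: bool = True
    run_screen: bool = True
    run_search: bool = True
    # QC
    call_rate_threshold: float = 0.99
    concordance_threshold: float = 0.95
    hwe_alpha: float = 0.01
    scan_quality: bool = True
    # imputation
    n_imputations: int = 100
    imputer_window: int = 5
    # screen / priors
    screen_threshold: float = 1.0
    effect_sd: float = 0.5
    prior_a: float = 1.0 / 8.0
    # sampler
    n_iterations: int = 50_000
    n_chains: int = 5
    temp_low: float = 0.3
    # simulation overrides (used when input_path is None)
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("call_rate_threshold", 0.0, 1.0),
            ("concordance_threshold", 0.0, 1.0),
            ("hwe_alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}]")
        if self.seed is None:
            raise ValueError("a seed is required")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def log(self, stage: str, **info) -> None:
        rec = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        self.records.append(rec)
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Artifacts: ``study.tsv`` (input or simulated data), ``qc_report.json``,
    ``hwe_pvalues.tsv``, ``missingness_bf.tsv``, ``screen_results.tsv``,
    ``snp_report.tsv``, ``model_image.tsv``, ``evidence_summary.tsv`` and a
    JSON-lines run log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    ss = np.random.SeedSequence(config.seed)
    sub = ss.spawn(3)  # simulate, imputation, sampler
    log.log("start", version=__version__, config_hash=_config_hash(config), seed=config.seed)

    if config.input_path is None:
        sim = default_scenario(seed=int(sub[0].generate_state(1)[0] % (2**31)), **config.simulation)
        dataset, truth = simulate_study(sim)
        (out / "truth_manifest.json").write_text(json.dumps(truth, default=str, indent=1))
        log.log("simulate", n_subjects=dataset.n_subjects, n_snps=dataset.n_snps)
    else:
        dataset = read_study(config.input_path)
        log.log("load", path=config.input_path, n_subjects=dataset.n_subjects, n_snps=dataset.n_snps)
    write_study(dataset, out / "study.tsv")

    if config.run_qc:
        dataset, report = apply_qc(
            dataset,
            call_rate_threshold=config.call_rate_threshold,
            concordance_threshold=config.concordance_threshold,
            hwe_alpha=config.hwe_alpha,
            scan_quality=config.scan_quality,
        )
        report.hwe_p.rename("hwe_p").to_csv(out / "hwe_pvalues.tsv", sep="\t")
        from .qc import hwe_tail_diagnostic

        diag = hwe_tail_diagnostic(report.hwe_p.to_numpy(), alpha=config.hwe_alpha)
        pd.DataFrame(
            {"uniform_quantile": diag.qq_uniform, "hwe_p": diag.qq_observed}
        ).to_csv(out / "hwe_qq.tsv", sep="\t", index=False)
        (out / "qc_report.json").write_text(
            json.dumps(
                {
                    "call_rate_removed": report.call_rate_removed,
                    "concordance_removed": report.concordance_removed,
                    "redundant_removed": report.redundant_removed,
                    "quality_threshold": report.quality_threshold,
                    "samples_removed": report.samples_removed,
                    "counts": report.counts,
                },
                indent=1,
            )
        )
        log.log("qc", **report.counts, quality_threshold=report.quality_threshold)

    priors = Priors(effect_sd=config.effect_sd, a=config.prior_a)

    imputations = None
    completed = dataset.genotypes
    if config.run_imputation and np.isnan(dataset.genotypes).any():
        rows = []
        for j in range(dataset.n_snps):
            res = missingness_bf(dataset, j, priors=priors)
            if res.evaluated:
                rows.append(dataclasses.asdict(res))
        pd.DataFrame(rows or [], columns=["snp_id", "missing_count", "bf", "evaluated"]).to_csv(
            out / "missingness_bf.tsv", sep="\t", index=False
        )
        imputer = fit_imputer(dataset.genotypes, window_size=config.imputer_window)
        imp_seed = int(sub[1].generate_state(1)[0] % (2**31))
        imputations = draw_imputations(
            imputer, dataset.genotypes, m=config.n_imputations, seed=imp_seed
        )
        completed = modal_fill(imputations)
        log.log("imputation", m=config.n_imputations, seed=imp_seed,
                n_missing=int(np.isnan(dataset.genotypes).sum()))

    screen_table = None
    survivors = dataset
    if config.run_screen:
        screen_table = screen(
            dataset, priors=priors, imputations=imputations, threshold=config.screen_threshold
        )
        screen_table.to_csv(out / "screen_results.tsv", sep="\t", index=False)
        passing = screen_table["pass"].to_numpy(dtype=bool)
        survivors = dataset.select_snps(passing)
        survivors.genotypes = completed[:, passing]
        log.log("screen", n_snps=int(passing.size), n_pass=int(passing.sum()))

    if config.run_search:
        if not config.run_screen:
            raise RuntimeError(
                "model search requires the screen stage: enable run_screen so the "
                "search receives the screen survivors"
            )
        if survivors.n_snps == 0:
            log.log("search", skipped="no screen survivors")
        else:
            est = run_search(
                survivors,
                priors=priors,
                a=config.prior_a,
                seed=int(sub[2].generate_state(1)[0] % (2**31)),
                n_iterations=config.n_iterations,
                n_chains=config.n_chains,
                temp_low=config.temp_low,
            )
            est.report_.to_csv(out / "snp_report.tsv", sep="\t", index=False)
            from .search import model_image

            model_image(est.sample_).to_csv(out / "model_image.tsv", sep="\t", index=False)
            prior_pi = est.sample_.prior.inclusion_probability
            rows = []
            for _, r in est.report_.iterrows():
                if r["bf"] > 0 and math.isfinite(r["bf"]):
                    ev = bf_to_evidence(r["bf"], prior_pi)
                    rows.append(
                        {
                            "snp_id": r["snp_id"],
                            "bf": ev.bf,
                            "prior_odds": ev.prior_odds,
                            "posterior_odds": ev.posterior_odds,
                            "ppa": ev.ppa,
                            "category": ev.category,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "evidence_summary.tsv", sep="\t", index=False)
            log.log(
                "search",
                n_snps=survivors.n_snps,
                global_bf=est.global_bf_,
                acceptance=est.sample_.diagnostics.get("acceptance"),
            )
    log.log("done")
    return out


_BANDS = [
    ("decisive", 100.0, math.inf),
    ("very strong", 30.0, 100.0),
    ("strongly supportive", 10.0, 30.0),
    ("supportive", 3.2, 10.0),
    ("weakly supportive", 1.0, 3.2),
]


def render_tables(run_dir) -> dict[str, pd.DataFrame]:
    """Publication-style tables from a finished run.

    ``table1``: SNPs with BF >= 1 grouped into Jeffreys evidence bands
    (lower bounds inclusive), sorted by BF within band, with NA odds
    ratios rendered as the string "NA". ``table_s2``: the full marginal
    screen table. Both are also written back into the run directory.
    """
    run_dir = Path(run_dir)
    out: dict[str, pd.DataFrame] = {}
    snp_path = run_dir / "snp_report.tsv"
    if snp_path.exists():
        rep = pd.read_csv(snp_path, sep="\t")
        rows = []
        for band, lo, hi in _BANDS:
            sel = rep[(rep["bf"] >= lo) & (rep["bf"] < hi)].sort_values("bf", ascending=False)
            for _, r in sel.iterrows():
                orr = r.get("median_or")
                if orr is None or (isinstance(orr, float) and math.isnan(orr)):
                    or_text = "NA"
                else:
                    or_text = f"{orr:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
                rows.append(
                    {
                        "band": band,
                        "snp_id": r["snp_id"],
                        "gene": r.get("gene", ""),
                        "most_likely_model": r.get("most_likely_model", ""),
                        "model_probability": r.get("model_probability"),
                        "median_or_ci": or_text,
                        "bf": r["bf"],
                    }
                )
        cols = ["band", "snp_id", "gene", "most_likely_model", "model_probability", "median_or_ci", "bf"]
        table1 = pd.DataFrame(rows, columns=cols)
        table1.to_csv(run_dir / "table1.tsv", sep="\t", index=False)
        out["table1"] = table1
    screen_path = run_dir / "screen_results.tsv"
    if screen_path.exists():
        out["table_s2"] = pd.read_csv(screen_path, sep="\t")
    return out
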