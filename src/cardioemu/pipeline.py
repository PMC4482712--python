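"""End-to-end orchestration of the emulation study.

The pipeline reproduces the full workflow: generate Latin-hypercube
design and test datasets with the cell simulator, fit one GP emulator
per output, validate each against the held-out test runs (Mahalanobis
distance vs its reference distribution), refit on the combined runs,
run analytic uncertainty and sensitivity analysis under the normal
input distribution, and fit the PLS comparison baseline.  Every
artifact is written as CSV/JSON alongside the seeds and a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import (
    DesignSet,
    InputSpace,
    OUTPUT_NAMES,
    INPUT_NAMES,
    generate_dataset,
    write_dataset,
)
from .emulator import GaussianProcessEmulator
from .lr1991 import StimulusProtocol
from .pls import pls_sensitivity
from .sensitivity import InputDistribution, main_effect_indices, uncertainty_analysis
from .validation import validate_emulator

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Study configuration; defaults reproduce the full-size analysis."""

    design_n: int = 200
    test_n: int = 20
    seed: int = 0
    include_restitution: bool = True
    restitution_n: Optional[int] = None
    input_mean: float = 0.5
    input_var: float = 0.04
    s1_count: int = 9
    s1_cycle_length: float = 1000.0
    stim_amplitude: float = -25.5
    stim_duration: float = 2.0
    n_restarts: int = 10
    pls_components: int = 6
    method: str = "rl"
    outdir: str = "pipeline_out"

    def protocol(self) -> StimulusProtocol:
        return StimulusProtocol(
            s1_count=self.s1_count,
            s1_cycle_length=self.s1_cycle_length,
            stim_amplitude=self.stim_amplitude,
            stim_duration=self.stim_duration,
        )

    def distribution(self) -> InputDistribution:
        return InputDistribution(
            mean=np.full(6, self.input_mean), var=np.full(6, self.input_var)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineReport:
    summary: pd.DataFrame
    emulators: dict
    validations: dict
    sa_indices: pd.DataFrame
    pls_coefficients: pd.DataFrame
    design: DesignSet
    test: DesignSet
    outdir: Path


def _complete_rows(ds: DesignSet, col: int):
    mask = ~np.isnan(ds.y[:, col])
    return ds.x[mask], ds.y[mask, col]


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4) % (2**31)
    protocol = cfg.protocol()
    space = InputSpace()
    dist = cfg.distribution()

    logger.info("stage 1/6: %d design runs", cfg.design_n)
    design = generate_dataset(
        cfg.design_n, space, protocol, seed=int(seeds[0]),
        include_restitution=cfg.include_restitution,
        restitution_n=cfg.restitution_n, method=cfg.method,
    )
    write_dataset(design, outdir / "design.csv")
    logger.info("stage 2/6: %d test runs", cfg.test_n)
    test = generate_dataset(
        cfg.test_n, space, protocol, seed=int(seeds[1]),
        include_restitution=cfg.include_restitution,
        restitution_n=None if cfg.restitution_n is None else max(
            0, min(cfg.test_n, cfg.restitution_n)),
        method=cfg.method,
    )
    write_dataset(test, outdir / "test.csv")
    combined = design.combined_with(test)
    write_dataset(combined, outdir / "combined.csv")

    emulators, validations, ua_results, sa_results = {}, {}, {}, {}
    rows = []
    for col, name in enumerate(OUTPUT_NAMES):
        x_fit, y_fit = _complete_rows(design, col)
        if y_fit.size <= 8:
            logger.warning("skipping %s: too few complete rows", name)
            continue
        logger.info("stage 3/6: fitting %s emulator (n=%d)", name, y_fit.size)
        em = GaussianProcessEmulator(
            n_restarts=cfg.n_restarts, random_state=int(seeds[2]),
            output_name=name,
        ).fit(x_fit, y_fit)
        x_t, y_t = _complete_rows(test, col)
        report = validate_emulator(em, x_t, y_t) if y_t.size else None
        validations[name] = report

        xc, yc = _complete_rows(combined, col)
        logger.info("stage 4/6: refit %s on combined n=%d", name, yc.size)
        em_comb = GaussianProcessEmulator(
            n_restarts=cfg.n_restarts, random_state=int(seeds[3]),
            output_name=name,
        ).fit(xc, yc)
        em_comb.to_json(outdir / f"emulator_{name}.json")
        emulators[name] = em_comb

        ua = uncertainty_analysis(em_comb, dist)
        sa = main_effect_indices(em_comb, dist)
        ua_results[name], sa_results[name] = ua, sa
        rows.append({
            "output": name,
            "design_mean": float(np.nanmean(design.y[:, col])),
            "e_mean": ua.e_mean,
            "var_mean": ua.var_mean,
            "cov_percent": 100.0 * ua.cov,
            "md": report.md if report else np.nan,
        })

    summary = pd.DataFrame(rows).set_index("output")
    sa_table = pd.DataFrame(
        {name: sa.indices for name, sa in sa_results.items()},
        index=list(INPUT_NAMES),
    ).T
    sa_table["sum"] = sa_table.sum(axis=1)

    logger.info("stage 5/6: PLS baseline")
    complete = ~np.isnan(combined.y).any(axis=1)
    pls = pls_sensitivity(
        DesignSet(combined.x[complete], combined.y[complete]),
        n_components=cfg.pls_components,
    )

    logger.info("stage 6/6: writing artifacts to %s", outdir)
    summary.to_csv(outdir / "summary.csv")
    sa_table.to_csv(outdir / "sa_indices.csv")
    pls.coefficients.to_csv(outdir / "pls_coefficients.csv")
    with open(outdir / "validation.json", "w") as fh:
        json.dump(
            {
                name: None if rep is None else {
                    "md": rep.md, "md_ref_mean": rep.md_ref_mean,
                    "md_ref_sd": rep.md_ref_sd, "passed": rep.passed,
                    "standardized_errors": rep.standardized_errors.tolist(),
                }
                for name, rep in validations.items()
            },
            fh, indent=1,
        )
    with open(outdir / "run.json", "w") as fh:
        json.dump(
            {
                "config": cfg.to_dict(),
                "config_hash": cfg.hash(),
                "stage_seeds": [int(s) for s in seeds],
                "design_failures": design.metadata.get("failures", []),
                "test_failures": test.metadata.get("failures", []),
            },
            fh, indent=1,
        )
    return PipelineReport(
        summary=summary, emulators=emulators, validations=validations,
        sa_indices=sa_table, pls_coefficients=pls.coefficients,
        design=design, test=test, outdir=outdir,
    )
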