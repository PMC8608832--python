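"""End-to-end synthetic recovery benchmark.

Generates a phantom cohort whose primary-event hazard is log-linear in
standardized LVEF (unit slope on -LVEF), runs the full no-leak sixfold
two-network pipeline on the rendered cine sequences, and evaluates the
pooled out-of-fold cine risk score.  All randomness derives from one seed.

Default conditions: 240 subjects, 64 x 64 pixels x 8 frames covering one
cardiac cycle (4.4 mm spacing, i.e. the standard 280 mm field of view),
pixel noise sd 0.02, ~27% primary events under 10-year administrative
censoring.
"""

from __future__ import annotations

import numpy as np

from .io import CineSequence, CohortTable, crop_and_resample
from .phantom import SurvivalSimConfig, sample_cohort, simulate_survival
from .pipeline import RunConfig, RunResult, run_pipeline, stage_seed

__all__ = ["make_benchmark_cohort", "run_recovery_benchmark"]


def make_benchmark_cohort(
    seed: int,
    n: int = 240,
    size_px: int = 64,
    spacing_mm: float = 4.4,
    n_frames: int = 8,
    noise_sd: float = 0.02,
    beta_lv_ef: float = -1.0,
) -> tuple[list[CineSequence], CohortTable]:
    """Rendered, preprocessed sequences plus simulated survival outcomes."""
    cohort = sample_cohort(
        n,
        seed=stage_seed(seed, "simulate", 0),
        spacing_mm=spacing_mm,
        size_px=size_px,
        noise_sd=noise_sd,
        n_frames=n_frames,
    )
    seqs = [
        crop_and_resample(seq, out_size=size_px, out_spacing_mm=spacing_mm)
        for _, _, seq in cohort
    ]
    surv = simulate_survival(
        cohort,
        SurvivalSimConfig(
            log_hazard_coeffs={"lv_ef": beta_lv_ef},
            seed=stage_seed(seed, "simulate", 1),
        ),
    )
    return seqs, surv


def run_recovery_benchmark(
    seed: int = 1,
    n: int = 240,
    size_px: int = 64,
    config: RunConfig | None = None,
) -> tuple[RunResult, CohortTable]:
    """Full sixfold pipeline on a fresh synthetic cohort; returns (result, outcomes)."""
    seqs, surv = make_benchmark_cohort(seed, n=n, size_px=size_px)
    cfg = config if config is not None else RunConfig(seed=seed)
    return run_pipeline(seqs, surv, cfg), surv
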