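"""No-leak sixfold orchestration of the two networks and the evaluation stack.

For each fold f the fingerprint extractor is trained on the other folds,
fingerprints are extracted with that model, the risk predictor is trained
(per outcome) on the other folds' fingerprints, and fold f is scored by
the model that never saw it.  The pooled out-of-fold scores cover the
whole cohort exactly once per outcome and feed the survival report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fingerprint import ExtractorConfig, extract_fingerprint, train_extractor
from .io import CineSequence, CohortTable
from .risk import (
    PredictorConfig,
    RiskResult,
    combine_fold_predictions,
    predict_risk,
    train_risk_predictor,
)
from . import stats as ss

__all__ = ["FoldAssignment", "RunConfig", "make_folds", "run_pipeline", "evaluate_outcome"]

# documented counter scheme: every stage derives its own seed from the one
# run seed, so stages are independently reproducible
_STAGE_OFFSETS = {"folds": 1, "extractor": 2, "risk": 3, "evaluate": 4, "simulate": 5}


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    return (seed * 100003 + _STAGE_OFFSETS[stage] * 1009 + index) % (2**31)


@dataclass
class FoldAssignment:
    fold_of: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        sizes = np.bincount(list(self.fold_of.values()), minlength=self.k)
        if len(sizes) != self.k or sizes.max() - sizes.min() > 1:
            raise ValueError(f"fold sizes must differ by <= 1; got {sizes.tolist()}")

    def ids_in_fold(self, f: int) -> list[str]:
        return [s for s, g in self.fold_of.items() if g == f]

    def ids_not_in_fold(self, f: int) -> list[str]:
        return [s for s, g in self.fold_of.items() if g != f]

    def sizes(self) -> list[int]:
        return np.bincount(list(self.fold_of.values()), minlength=self.k).tolist()


def make_folds(
    subject_ids: Sequence[str],
    k: int = 6,
    seed: int = 0,
    stratify_on: Sequence[int] | None = None,
) -> FoldAssignment:
    """Random k-fold partition; optionally event-stratified.

    With stratification each fold's event count differs by at most 1, and
    fold sizes always differ by at most 1 (non-events are dealt to the
    currently smallest fold).
    """
    ids = list(subject_ids)
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    if stratify_on is None:
        order = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(order, k)):
            for i in chunk:
                fold_of[ids[i]] = f
    else:
        flags = np.asarray(stratify_on, dtype=int)
        if len(flags) != n:
            raise ValueError("stratify_on must align with subject_ids")
        ev = rng.permutation(np.flatnonzero(flags == 1))
        nev = rng.permutation(np.flatnonzero(flags != 1))
        fold_order = rng.permutation(k)
        for pos, i in enumerate(ev):
            fold_of[ids[i]] = int(fold_order[pos % k])
        sizes = np.zeros(k, dtype=int)
        for f in fold_of.values():
            sizes[f] += 1
        tiebreak = rng.permutation(k)
        for i in nev:
            f = int(min(range(k), key=lambda g: (sizes[g], tiebreak[g])))
            fold_of[ids[i]] = f
            sizes[f] += 1
    return FoldAssignment(fold_of=fold_of, k=k)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings.

    ``ensemble_size`` extractor + risk-head pairs are trained per fold
    (differing only in their derived seeds) and their anchored linear
    predictors averaged; member errors are weakly correlated, so a small
    ensemble stabilises the out-of-fold score considerably.
    """

    k_folds: int = 6
    outcomes: tuple[str, ...] = ("VA",)
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    seed: int = 0
    stratify: bool = True
    ensemble_size: int = 3
    n_bootstrap: int = 100
    quantile_cutoff: float = 0.25

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    predictions: dict[str, list[RiskResult]]
    folds: FoldAssignment
    reports: dict[str, dict]
    config: RunConfig

    def predictions_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": r.subject_id,
                "outcome": r.outcome_label,
                "eta": r.linear_predictor,
                "score": r.cine_risk_score,
                "fold": r.fold_id,
            }
            for results in self.predictions.values()
            for r in results
        ]
        return pd.DataFrame(rows).sort_values(["outcome", "subject_id"]).reset_index(drop=True)


def run_pipeline(
    sequences: list[CineSequence],
    cohort: CohortTable,
    config: RunConfig,
    out_dir: str | Path | None = None,
    evaluate: bool = True,
) -> RunResult:
    """Train both networks under the no-leak k-fold protocol and evaluate.

    ``cohort`` carries event codes {0, 1, 2}; each requested outcome is
    retrained separately with the fold assignment shared across outcomes.
    """
    seq_ids = {s.subject_id for s in sequences}
    cohort_ids = set(cohort.subject_ids)
    if seq_ids != cohort_ids:
        raise ValueError(
            f"id mismatch: {len(seq_ids - cohort_ids)} sequences without outcomes, "
            f"{len(cohort_ids - seq_ids)} outcomes without sequences"
        )
    primary_flags = cohort.event_flags("VA")
    folds = make_folds(
        cohort.subject_ids,
        k=config.k_folds,
        seed=stage_seed(config.seed, "folds"),
        stratify_on=primary_flags if config.stratify else None,
    )
    by_id = {s.subject_id: s for s in sequences}

    per_outcome: dict[str, list[list[RiskResult]]] = {o: [] for o in config.outcomes}
    for f in range(folds.k):
        train_ids = folds.ids_not_in_fold(f)
        val_ids = folds.ids_in_fold(f)
        fold_etas: dict[str, list[np.ndarray]] = {o: [] for o in config.outcomes}
        for e in range(config.ensemble_size):
            ext_cfg = ExtractorConfig(
                **{
                    **asdict(config.extractor),
                    "seed": stage_seed(config.seed, "extractor", f * 100 + e),
                }
            )
            extractor = train_extractor(sequences, train_ids, ext_cfg)
            fps = {
                sid: extract_fingerprint(extractor, by_id[sid], fold_id=f)
                for sid in train_ids + val_ids
            }
            for j, outcome in enumerate(config.outcomes):
                oc = CohortTable(records=cohort.records, outcome_label=outcome)
                pred_cfg = PredictorConfig(
                    **{
                        **asdict(config.predictor),
                        "seed": stage_seed(config.seed, "risk", (f * 100 + e) * 10 + j),
                    }
                )
                model = train_risk_predictor(list(fps.values()), oc, train_ids, pred_cfg)
                fold_etas[outcome].append(
                    np.array(
                        [predict_risk(model, fps[sid]).linear_predictor for sid in val_ids]
                    )
                )
        for outcome in config.outcomes:
            eta = np.mean(fold_etas[outcome], axis=0)
            score = 1.0 / (1.0 + np.exp(-eta))
            per_outcome[outcome].append(
                [
                    RiskResult(
                        subject_id=sid,
                        outcome_label=outcome,
                        linear_predictor=float(eta[i]),
                        cine_risk_score=float(score[i]),
                        fold_id=f,
                    )
                    for i, sid in enumerate(val_ids)
                ]
            )

    predictions = {
        o: combine_fold_predictions(res, expected_ids=cohort_ids)
        for o, res in per_outcome.items()
    }
    reports: dict[str, dict] = {}
    if evaluate:
        for outcome in config.outcomes:
            oc = CohortTable(records=cohort.records, outcome_label=outcome)
            reports[outcome] = evaluate_outcome(
                predictions[outcome],
                oc,
                seed=stage_seed(config.seed, "evaluate"),
                n_bootstrap=config.n_bootstrap,
                quantile_cutoff=config.quantile_cutoff,
            )
    result = RunResult(predictions=predictions, folds=folds, reports=reports, config=config)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def evaluate_outcome(
    predictions: list[RiskResult],
    cohort: CohortTable,
    seed: int = 0,
    n_bootstrap: int = 100,
    quantile_cutoff: float = 0.25,
    comparator_covariate: str | None = None,
    adjust_covariates: Sequence[str] = (),
) -> dict:
    """Full survival report for one outcome from pooled out-of-fold scores.

    Pure function of (predictions, cohort, seed): C-index with a seeded
    bootstrap CI, univariate Cox HR of the score, median-split
    Kaplan-Meier + log-rank, low-quantile subgroup incidence rates,
    Fine-Gray when competing events exist, continuous NRI against an
    optional comparator covariate, and a multivariable Cox fit with any
    supplied adjustment covariates.
    """
    if not predictions:
        raise ValueError("empty predictions")
    by_id = {r.subject_id: r for r in predictions}
    missing = set(cohort.subject_ids) - set(by_id)
    if missing:
        raise ValueError(f"predictions missing for {sorted(missing)[:5]}")
    scores = np.array([by_id[s].cine_risk_score for s in cohort.subject_ids])
    times = cohort.times()
    flags = cohort.event_flags()
    codes = cohort.event_codes()

    def c_stat(idx: np.ndarray) -> float:
        return ss.concordance_index(scores[idx], times[idx], flags[idx])[0]

    c, c_lo, c_hi = ss.bootstrap_ci(c_stat, len(scores), n_resamples=n_bootstrap, seed=seed)
    cox = ss.fit_cox(scores[:, None], times, flags, names=["cine_risk_score"])

    labels = ss.dichotomize_at_quantile(scores, 0.5)
    low, high = labels == "low", labels == "high"
    km_low = ss.kaplan_meier(times[low], flags[low])
    km_high = ss.kaplan_meier(times[high], flags[high])
    chi2, logrank_p = ss.log_rank_test(
        [(times[low], flags[low]), (times[high], flags[high])]
    )

    q_labels = ss.dichotomize_at_quantile(scores, quantile_cutoff)
    q_low = q_labels == "low"
    rate_all, ci_all = ss.incidence_rate(int(flags.sum()), float(times.sum()))
    rate_low, ci_low = ss.incidence_rate(int(flags[q_low].sum()), float(times[q_low].sum()))

    report: dict = {
        "outcome": cohort.outcome_label,
        "n": len(scores),
        "n_events": int(flags.sum()),
        "c_index": c,
        "c_index_ci95": (c_lo, c_hi),
        "cox_hr": cox.hazard_ratios["cine_risk_score"],
        "cox_hr_ci95": cox.ci_95["cine_risk_score"],
        "cox_p": cox.p_values["cine_risk_score"],
        "log_rank_chi2": chi2,
        "log_rank_p": logrank_p,
        "median_split_sizes": (int(low.sum()), int(high.sum())),
        "incidence_rate_overall_per_100py": rate_all,
        "incidence_rate_overall_ci95": ci_all,
        f"incidence_rate_low_q{quantile_cutoff:g}_per_100py": rate_low,
        f"incidence_rate_low_q{quantile_cutoff:g}_ci95": ci_low,
        "km": {
            "low": {"times": km_low.event_times.tolist(), "survival": km_low.survival.tolist()},
            "high": {"times": km_high.event_times.tolist(), "survival": km_high.survival.tolist()},
        },
    }
    if (codes == 2).any() and cohort.outcome_label.lower() not in ("all_cause", "all_cause_death"):
        fg = ss.fine_gray(scores[:, None], times, codes, names=["cine_risk_score"])
        report["fine_gray_subhr"] = fg.hazard_ratios["cine_risk_score"]
        report["fine_gray_subhr_ci95"] = fg.ci_95["cine_risk_score"]
        report["fine_gray_p"] = fg.p_values["cine_risk_score"]
    if comparator_covariate is not None:
        old = cohort.covariate(comparator_covariate)
        report[f"nri_vs_{comparator_covariate}"] = ss.nri_continuous(old, scores, flags)
    if adjust_covariates:
        X = np.column_stack([scores] + [cohort.covariate(c) for c in adjust_covariates])
        multi = ss.fit_cox(
            X, times, flags, names=["cine_risk_score", *adjust_covariates]
        )
        report["multivariable_hr"] = multi.hazard_ratios
        report["multivariable_p"] = multi.p_values
    return report


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.predictions_frame().to_csv(out_dir / "predictions.csv", index=False)
    manifest = {
        "config": asdict(result.config),
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "fold_sizes": result.folds.sizes(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if result.reports:
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(result.reports, fh, indent=2, default=str)
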