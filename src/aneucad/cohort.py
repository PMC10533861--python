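"""Synthetic screening cohorts with the statistical structure of a reader study.

The generator emulates a feedback database from a large brain-screening
program: each examination gets a physician category drawn from configured
prevalences (definite aneurysm ~2%, suspicion ~8% of cases), positive
cases are detected by the simulated algorithm with a per-lesion detection
probability, and every case receives a Poisson-distributed number of
false-positive candidates.  Candidate scores are drawn uniformly from
configurable ranges so that top-k truncation (FROC analysis) is exercised.

The Poisson false-positive model is an assumption of this module: real
per-case FP count distributions of deployed detectors are not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

from .records import CaseCandidate, CaseRecord

__all__ = ["CohortConfig", "generate_case_database"]

Rate = Union[float, Mapping[float, float]]


def _resolve(value: Rate, threshold: float | None, name: str) -> float:
    if isinstance(value, Mapping):
        if threshold is None:
            raise ValueError(f"{name} is per-threshold; pass threshold=")
        if threshold not in value:
            raise KeyError(f"{name} has no entry for threshold {threshold}")
        return float(value[threshold])
    return float(value)


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``per_lesion_detection_prob`` and ``fp_rate_per_case`` may each be a
    scalar or a mapping from score-cutoff threshold to value, so the same
    config can describe a detector at several operating points.

    Default prevalences (2% definite, 8.4% suspicion) and detector rates
    (96.5% detection, 2.06 FPs/case) correspond to a screening population
    read at a permissive 0.5 score cutoff.
    """

    n_cases: int = 5000
    prevalence_definite: float = 0.02
    prevalence_suspicion: float = 0.084
    per_lesion_detection_prob: Rate = 0.965
    fp_rate_per_case: Rate = 2.06
    seed: int = 0
    tp_score_range: tuple[float, float] = (0.5, 1.0)
    fp_score_range: tuple[float, float] = (0.5, 1.0)
    # optional demographics for baseline-table style summaries
    include_demographics: bool = False
    age_mean: float = 48.5
    age_sd: float = 11.6
    female_prob: float = 0.435

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        for name in ("prevalence_definite", "prevalence_suspicion", "female_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.prevalence_definite + self.prevalence_suspicion > 1.0:
            raise ValueError("prevalence_definite + prevalence_suspicion must be <= 1")
        for name in ("per_lesion_detection_prob",):
            vals = getattr(self, name)
            vals = vals.values() if isinstance(vals, Mapping) else [vals]
            if any(not 0.0 <= float(v) <= 1.0 for v in vals):
                raise ValueError(f"{name} values must be in [0, 1]")
        fps = self.fp_rate_per_case
        fps = fps.values() if isinstance(fps, Mapping) else [fps]
        if any(float(v) < 0 for v in fps):
            raise ValueError("fp_rate_per_case must be >= 0")


def generate_case_database(
    config: CohortConfig, threshold: float | None = None
) -> list[CaseRecord]:
    """Draw a seeded cohort of :class:`CaseRecord`.

    Each positive (suspicion or definite) case carries exactly one true
    lesion, detected with the configured probability (detected -> one TP
    candidate, missed -> one FN); the per-case FP candidate count is
    Poisson.  Identical config and threshold reproduce the cohort exactly.
    """
    p_det = _resolve(config.per_lesion_detection_prob, threshold, "per_lesion_detection_prob")
    fp_rate = _resolve(config.fp_rate_per_case, threshold, "fp_rate_per_case")
    entropy = (config.seed, 0 if threshold is None else int(round(threshold * 1000)))
    rng = np.random.default_rng(np.random.SeedSequence(entropy))

    probs = [
        1.0 - config.prevalence_definite - config.prevalence_suspicion,
        config.prevalence_suspicion,
        config.prevalence_definite,
    ]
    categories = rng.choice(["none", "suspicion", "definite"], size=config.n_cases, p=probs)
    records: list[CaseRecord] = []
    for i, category in enumerate(categories):
        candidates: list[CaseCandidate] = []
        n_fn = 0
        if category != "none":
            if rng.uniform() < p_det:
                candidates.append(
                    CaseCandidate(float(rng.uniform(*config.tp_score_range)), "TP")
                )
            else:
                n_fn = 1
        n_fp = int(rng.poisson(fp_rate))
        candidates.extend(
            CaseCandidate(float(s), "FP")
            for s in rng.uniform(*config.fp_score_range, size=n_fp)
        )
        records.append(CaseRecord(f"case{i:05d}", str(category), candidates, n_fn))
        if config.include_demographics:
            # attributes used only by baseline-table summaries
            records[-1].age = float(rng.normal(config.age_mean, config.age_sd))
            records[-1].female = bool(rng.uniform() < config.female_prob)
    return records
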