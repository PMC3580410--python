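"""Rescaling module scores across array platforms and pooling cohorts.

Different platforms put the same module score on different scales, so a
median cutpoint learned on one cohort is meaningless on another. The default
rescaling is the minimal affine map matching each cohort's score mean and SD
to a reference cohort's; a quantile-matching mode is provided for
sensitivity analysis. After rescaling, cohorts can be concatenated into one
pooled series (source labels retained) for a pooled median-split
Kaplan-Meier analysis. Cohorts whose endpoint is not overall survival (e.g.
disease-free survival) are excluded from pooling by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScoredCohort", "rescale_to_reference", "rescale_quantile",
           "merge_datasets"]


@dataclass
class ScoredCohort:
    """Per-sample module scores with survival annotations for one cohort."""

    name: str
    scores: np.ndarray
    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] | None = None
    endpoint: str = "os"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.scores)
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("scores, time and event must have equal length")
        if self.sample_ids is None:
            self.sample_ids = [f"{self.name}_{i}" for i in range(n)]


def rescale_to_reference(target_scores, reference_scores) -> np.ndarray:
    """Affine-map target scores onto the reference mean/SD.

    x -> (x - mean_t)/sd_t * sd_r + mean_r. Output mean and SD equal the
    reference's exactly (up to rounding). Constant inputs are rejected.
    """
    t = np.asarray(target_scores, dtype=float)
    r = np.asarray(reference_scores, dtype=float)
    sd_t = t.std(ddof=1)
    sd_r = r.std(ddof=1)
    if sd_t == 0 or sd_r == 0:
        raise ValueError("constant scores cannot be rescaled")
    return (t - t.mean()) / sd_t * sd_r + r.mean()


def rescale_quantile(target_scores, reference_scores) -> np.ndarray:
    """Quantile-match target scores to the reference distribution."""
    t = np.asarray(target_scores, dtype=float)
    r = np.asarray(reference_scores, dtype=float)
    if np.all(t == t[0]) or np.all(r == r[0]):
        raise ValueError("constant scores cannot be rescaled")
    from scipy.stats import rankdata
    q = (rankdata(t) - 0.5) / len(t)
    return np.quantile(r, q)


def merge_datasets(datasets: list[ScoredCohort],
                   include_other_endpoints: bool = False) -> pd.DataFrame:
    """Concatenate rescaled cohorts into one pooled series.

    Returns a DataFrame (sample, score, time, event, source, endpoint).
    Duplicate sample ids across sources are suffixed with the source name.
    Non-overall-survival cohorts are dropped unless
    ``include_other_endpoints`` is set.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    kept = [d for d in datasets
            if include_other_endpoints or d.endpoint == "os"]
    if not kept:
        raise ValueError("all datasets excluded by endpoint filter")
    seen: set[str] = set()
    frames = []
    for d in kept:
        ids = []
        for s in d.sample_ids:
            sid = s if s not in seen else f"{s}__{d.name}"
            seen.add(sid)
            ids.append(sid)
        frames.append(pd.DataFrame({
            "sample": ids,
            "score": d.scores,
            "time": d.time,
            "event": d.event,
            "source": d.name,
            "endpoint": d.endpoint,
        }))
    return pd.concat(frames, ignore_index=True)
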