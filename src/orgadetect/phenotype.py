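"""Organoid-vitality parameters and their correlation with senescence phenotype.

From one image's calibrated detections the module derives the three vitality
parameters — organoid number, average diameter (um) and their product
No. x Dia. — plus, for the two-class (active/aging) model, the aging
fraction and the quality-control decision: a culture whose aging-organoid
rate exceeds 80% is flagged poor quality.

The diameter of one detected organoid is taken as the mean of its box width
and height converted to microns: for the near-circular bodies seen in
brightfield this is the least-assumption estimate from an axis-aligned box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectionSet
from .synthgen import PhenotypeRecord

__all__ = [
    "PhenotypeSummary",
    "CorrelationResult",
    "QC_AGING_THRESHOLD",
    "summarize",
    "correlate",
    "score_batch",
]

#: A sample whose aging fraction strictly exceeds this is considered poor
#: quality for downstream experiments.
QC_AGING_THRESHOLD = 0.80


@dataclass(frozen=True)
class PhenotypeSummary:
    """Per-image vitality parameters."""

    image_id: str
    organoid_number: int
    average_diameter_um: float
    number_times_diameter_um: float
    aging_fraction: float | None = None
    poor_quality_flag: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    method: Literal["pearson", "spearman"]
    r: float
    p_value: float
    n: int


def summarize(
    detections: DetectionSet, qc_threshold: float = QC_AGING_THRESHOLD
) -> PhenotypeSummary:
    """Reduce one image's detections to its vitality parameters.

    ``aging_fraction`` is populated only when at least one box carries an
    "aging"/"active" label; an empty detection set yields all-zero parameters
    and no aging fraction.
    """
    n = len(detections.boxes)
    if n == 0:
        return PhenotypeSummary(detections.image_id, 0, 0.0, 0.0, None, False)
    diameters = [
        0.5 * (b.width + b.height) * detections.um_per_pixel for b in detections.boxes
    ]
    avg = float(np.mean(diameters))
    labels = {b.label for b in detections.boxes}
    aging_fraction = None
    poor = False
    if labels & {"active", "aging"}:
        aging_fraction = sum(1 for b in detections.boxes if b.label == "aging") / n
        poor = aging_fraction > qc_threshold
    return PhenotypeSummary(
        image_id=detections.image_id,
        organoid_number=n,
        average_diameter_um=avg,
        number_times_diameter_um=n * avg,
        aging_fraction=aging_fraction,
        poor_quality_flag=poor,
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: Literal["pearson", "spearman"]
) -> CorrelationResult:
    """Pearson product-moment or Spearman rank correlation with two-sided p.

    Spearman uses mid-ranks for ties. Series of unequal length, fewer than 3
    points, non-finite values or zero variance are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input series")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(res.statistic), float(res.pvalue), len(x))


def score_batch(
    detection_sets: Sequence[DetectionSet],
    phenotype_table: Sequence[PhenotypeRecord],
    join_key: Literal["sample_id", "passage"] = "sample_id",
    qc_threshold: float = QC_AGING_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, CorrelationResult]]:
    """Join per-image summaries with phenotype records and correlate.

    ``detection_sets`` image ids are matched against the phenotype table's
    ``join_key`` column. Returns the joined table and the correlation panel:
    each vitality parameter against passage and against SA-beta-Gal
    positivity, Pearson and Spearman both. Pairs whose correlation is
    undefined (zero variance) are reported as absent, not as a number.
    """
    summaries = [summarize(d, qc_threshold) for d in detection_sets]
    sdf = pd.DataFrame(
        {
            "image_id": [s.image_id for s in summaries],
            "organoid_number": [s.organoid_number for s in summaries],
            "average_diameter_um": [s.average_diameter_um for s in summaries],
            "number_times_diameter_um": [s.number_times_diameter_um for s in summaries],
            "aging_fraction": [s.aging_fraction for s in summaries],
            "poor_quality_flag": [s.poor_quality_flag for s in summaries],
        }
    )
    pdf = pd.DataFrame([vars(r) for r in phenotype_table])
    sdf["join_key"] = sdf["image_id"].astype(str)
    pdf["join_key"] = pdf[join_key].astype(str)
    joined = sdf.merge(pdf.drop(columns=["join_key"]).assign(join_key=pdf["join_key"]), on="join_key")
    if len(joined) < 3:
        unmatched = sorted(set(sdf["join_key"]) - set(pdf["join_key"]))
        raise ValueError(
            f"join on {join_key!r} matched only {len(joined)} records; "
            f"unmatched image ids: {unmatched[:10]}"
        )

    panel: dict[str, CorrelationResult] = {}
    params = ["organoid_number", "average_diameter_um", "number_times_diameter_um", "aging_fraction"]
    targets = ["passage", "sabgal_positivity"]
    for param in params:
        col = joined[param].astype(float)
        if col.isna().any():
            continue
        for target in targets:
            for method in ("pearson", "spearman"):
                try:
                    panel[f"{param}_vs_{target}_{method}"] = correlate(
                        col.to_numpy(), joined[target].to_numpy(dtype=float), method
                    )
                except ValueError:
                    continue  # degenerate pair: reported by absence
    return joined.drop(columns=["join_key"]), panel
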