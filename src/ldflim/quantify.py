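"""Quantification metrics for gated organelle intensities.

Three dimensionless statistics summarise what gating does to the image:

* **fluorescence loss rate** — the percent intensity an ROI loses to the
  gate, ``(1 - <I_f>/<I_uf>) * 100`` where ``<I_f>`` and ``<I_uf>`` are the
  filtered and unfiltered mean ROI intensities;
* **RLL** — the ratio of mean LD intensity to mean LRO intensity,
  ``<I_LDs> / <I_LROs>``; a higher RLL means less LRO interference in fat
  quantification;
* **normalized intensity** — each group's per-worm means divided by the
  control group's average, so the control mean is exactly 1.

"Mean fluorescence intensity" of an ROI is the arithmetic mean over the
ROI's pixels of the (gated or ungated) intensity image; background pixels
are excluded by the label mask.  Group comparisons use Welch's unpaired
two-sample t test, which is standard plumbing here rather than part of the
method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

QUANT_COLUMNS = ["worm_id", "roi_id", "class", "mean_unfiltered",
                 "mean_filtered", "loss_rate_pct"]


def loss_rate(mean_filtered: float, mean_unfiltered: float) -> float:
    """Fluorescence loss rate in percent: ``(1 - <I_f>/<I_uf>) * 100``."""
    if mean_unfiltered <= 0:
        raise ValueError("mean_unfiltered must be > 0")
    if mean_filtered < 0:
        raise ValueError("mean_filtered must be >= 0")
    if mean_filtered > mean_unfiltered * (1 + 1e-12):
        raise ValueError(
            f"mean_filtered ({mean_filtered}) exceeds mean_unfiltered "
            f"({mean_unfiltered}); gating can only remove photons — this "
            "signals a gating bug")
    return (1.0 - mean_filtered / mean_unfiltered) * 100.0


def rll(mean_ld: float, mean_lro: float) -> float:
    """Ratio of mean LD to mean LRO intensity, ``<I_LDs> / <I_LROs>``."""
    if mean_lro <= 0:
        raise ValueError(
            "mean_lro must be > 0; for worms without LROs (glo-1) the RLL "
            "is undefined and should be reported as such, not as infinity")
    return float(mean_ld) / float(mean_lro)


def normalize(values: Sequence[float],
              control_values: Sequence[float]) -> np.ndarray:
    """Divide every value by the control group's average.

    Applied to both the experimental and the control group, so the control
    group's normalized mean is exactly 1.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    mean = control.mean()
    if mean <= 0:
        raise ValueError(f"control mean must be > 0, got {mean}")
    return np.asarray(values, dtype=float) / mean


@dataclass(frozen=True)
class QuantRecord:
    """Per-ROI intensity record under the unfiltered and filtered gates."""

    worm_id: str
    roi_id: int
    organelle_class: str           # "LD" or "LRO"
    mean_unfiltered: float
    mean_filtered: float

    def __post_init__(self) -> None:
        if not 0 <= self.mean_filtered <= self.mean_unfiltered:
            raise ValueError(
                f"need 0 <= mean_filtered <= mean_unfiltered, got "
                f"{self.mean_filtered} vs {self.mean_unfiltered}")

    @property
    def loss_rate_pct(self) -> float:
        return loss_rate(self.mean_filtered, self.mean_unfiltered)


def records_to_frame(records: Iterable[QuantRecord]) -> pd.DataFrame:
    rows = [{"worm_id": r.worm_id, "roi_id": r.roi_id,
             "class": r.organelle_class,
             "mean_unfiltered": r.mean_unfiltered,
             "mean_filtered": r.mean_filtered,
             "loss_rate_pct": r.loss_rate_pct} for r in records]
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


@dataclass
class GroupSummary:
    """Group-level mean intensities and derived statistics."""

    group_id: str
    mean_ld: float
    mean_lro: float | None            # None when the group has no LROs
    normalized_values: np.ndarray
    unnormalized_values: np.ndarray
    control_average: float

    @property
    def rll(self) -> float | None:
        if self.mean_lro is None or self.mean_lro == 0:
            return None
        return rll(self.mean_ld, self.mean_lro)


def select_brightest(records: Sequence[QuantRecord], per_worm: int = 10,
                     by_filtered: bool = False) -> list[QuantRecord]:
    """Per worm and class, keep the ``per_worm`` brightest ROIs.

    Brightness ranks by unfiltered mean intensity by default (set
    ``by_filtered`` to rank by the filtered intensity instead); ties break
    toward the lower roi_id.  A worm contributing fewer than ``per_worm``
    ROIs of a class it has at all is an error, so five worms at the default
    yield exactly 50 records per class.
    """
    key = "mean_filtered" if by_filtered else "mean_unfiltered"
    out: list[QuantRecord] = []
    groups: dict[tuple[str, str], list[QuantRecord]] = {}
    for r in records:
        groups.setdefault((r.worm_id, r.organelle_class), []).append(r)
    for (worm, cls), rs in sorted(groups.items()):
        if len(rs) < per_worm:
            raise ValueError(
                f"worm {worm!r} has only {len(rs)} {cls} ROIs; "
                f"{per_worm} required")
        rs.sort(key=lambda r: (-getattr(r, key), r.roi_id))
        out.extend(rs[:per_worm])
    return out


def fat_storage_compare(group_a: Sequence[tuple[np.ndarray, np.ndarray]],
                        group_b: Sequence[tuple[np.ndarray, np.ndarray]],
                        ) -> dict:
    """Compare per-worm mean intensities between two groups.

    Each group is a sequence of ``(intensity_image, roi_mask)`` pairs, one
    per worm; fat storage is quantified as the mean intensity over the ROI
    mask (the synthetic worm-body mask stands in for the intestinal region).
    Both groups are normalized to group A's average, then compared with
    Welch's unpaired two-sample t test.

    Returns a dict with per-group normalized means, the raw per-worm means,
    Cohen's d on the normalized values, and the t statistic and p value.
    """
    def worm_means(group) -> np.ndarray:
        means = []
        for img, mask in group:
            values = np.asarray(getattr(img, "values", img), dtype=float)
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise ValueError("empty ROI mask in group")
            means.append(values[mask].mean())
        return np.asarray(means)

    a, b = worm_means(group_a), worm_means(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 worms")
    a_n = normalize(a, a)
    b_n = normalize(b, a)
    t, p = stats.ttest_ind(a_n, b_n, equal_var=False)
    pooled_sd = np.sqrt((a_n.var(ddof=1) + b_n.var(ddof=1)) / 2)
    d = (a_n.mean() - b_n.mean()) / pooled_sd if pooled_sd > 0 else np.inf
    return {
        "mean_a_normalized": float(a_n.mean()),
        "mean_b_normalized": float(b_n.mean()),
        "worm_means_a": a.tolist(),
        "worm_means_b": b.tolist(),
        "cohens_d": float(d),
        "t_statistic": float(t),
        "p_value": float(p),
    }
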