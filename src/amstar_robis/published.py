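"""Reference agreement coefficients from the motivating survey.

These are the per-comparison Gwet coefficients (point estimate, 95% CI and
qualitative band) reported by the published survey of 101 systematic
reviews of nutrition for cancer prevention whose comparison scheme this
package implements.  The underlying 101 paired assessments are not publicly
deposited, so the coefficients serve as reference values for band
classification and reporting-format checks — not as quantities this package
can recompute.
"""

from __future__ import annotations

from dataclasses import dataclass

from .agreement import Band

__all__ = ["PublishedCoefficient", "PUBLISHED_AGREEMENT", "PUBLISHED_N_REVIEWS"]

#: Number of reviews in the reference survey sample.
PUBLISHED_N_REVIEWS = 101


@dataclass(frozen=True)
class PublishedCoefficient:
    comparison_id: int
    estimate: float
    ci_low: float
    ci_high: float
    band: Band


PUBLISHED_AGREEMENT: dict[int, PublishedCoefficient] = {
    c.comparison_id: c
    for c in (
        PublishedCoefficient(1, 0.87, 0.78, 0.96, Band.ALMOST_PERFECT),
        PublishedCoefficient(2, 0.99, 0.97, 1.00, Band.ALMOST_PERFECT),
        PublishedCoefficient(3, 0.79, 0.74, 0.85, Band.SUBSTANTIAL),
        PublishedCoefficient(4, 0.87, 0.77, 0.96, Band.ALMOST_PERFECT),
        PublishedCoefficient(5, 0.88, 0.79, 0.98, Band.ALMOST_PERFECT),
        PublishedCoefficient(6, 0.60, 0.44, 0.76, Band.MODERATE),
        PublishedCoefficient(7, 0.88, 0.79, 0.98, Band.ALMOST_PERFECT),
        PublishedCoefficient(8, 0.81, 0.69, 0.92, Band.ALMOST_PERFECT),
        PublishedCoefficient(9, 0.77, 0.64, 0.89, Band.SUBSTANTIAL),
        PublishedCoefficient(10, 0.73, 0.59, 0.86, Band.SUBSTANTIAL),
        PublishedCoefficient(11, 0.18, -0.03, 0.38, Band.SLIGHT),
    )
}
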