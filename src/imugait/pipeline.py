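"""End-to-end convenience layer: trials -> filtered -> events -> features.

``make_gait_pipeline`` composes the three stateless transformers into an
sklearn :class:`~sklearn.pipeline.Pipeline`; ``cohort_features`` is the
function form used by the CLI and the experiment scripts.
"""

from __future__ import annotations

from sklearn.pipeline import Pipeline

from .core import Trial
from .events import GaitEventDetector, PeakCriteria
from .features import CycleFeatureExtractor, FeatureMatrix
from .preprocess import ACC_BAND, GYR_BAND, TrialFilter

__all__ = ["make_gait_pipeline", "cohort_features"]


def make_gait_pipeline(
    mode: str = "time_domain",
    criteria: PeakCriteria | None = None,
    acc_band: tuple[float, float] = ACC_BAND,
    gyr_band: tuple[float, float] = GYR_BAND,
    order: int = 4,
    start_side: str = "R",
) -> Pipeline:
    """Filter -> detect -> extract as one sklearn pipeline over raw trials."""
    return Pipeline(
        [
            ("filter", TrialFilter(acc_band=acc_band, gyr_band=gyr_band, order=order)),
            ("events", GaitEventDetector(criteria=criteria, start_side=start_side)),
            ("features", CycleFeatureExtractor(mode=mode)),
        ]
    )


def cohort_features(
    trials: list[Trial],
    mode: str = "time_domain",
    criteria: PeakCriteria | None = None,
    start_side: str = "R",
) -> FeatureMatrix:
    """Run the full pipeline on raw trials and return the labeled matrix.

    Trials without a valid assembled gait cycle are excluded (recorded on
    ``FeatureMatrix.excluded``), never imputed.
    """
    filt = TrialFilter()
    detector = GaitEventDetector(criteria=criteria, start_side=start_side)
    extractor = CycleFeatureExtractor(mode=mode)
    pairs = detector.fit_transform(filt.fit_transform(trials))
    extractor.fit_transform(pairs)
    fm = extractor.feature_matrix_
    fm.excluded = list(detector.excluded_)
    return fm
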