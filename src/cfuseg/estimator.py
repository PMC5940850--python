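"""The end-to-end segmenter as a scikit-learn-style estimator.

``CFUSegmenter`` learns the fuzzy a priori model from example colonies
(seed clicks or known areas) in :meth:`fit` and runs the full detection
pipeline — preprocess, multi-threshold accumulation, plausibility
filtering, big-blob classification, feedback watershed de-clumping —
in :meth:`predict`.  Parameters follow sklearn conventions
(``get_params``/``set_params``, fitted attributes with a trailing
underscore), so the segmenter drops into sklearn model-selection tooling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator

from .apriori import AprioriModel, apriori_from_areas, blob_from_seed, build_apriori
from .core_model import Segment, SegmentationResult
from .declump import DeclumpConfig, declump_all
from .image_prep import DishConfig, NormalizedImage, prepare_image
from .segment import (
    ThresholdSchedule,
    classify_big_blobs,
    multithreshold_accumulate,
    plausibility_filter,
)

__all__ = ["CFUSegmenter"]

_EIGHT = np.ones((3, 3), dtype=int)


class CFUSegmenter(BaseEstimator):
    """Supervised colony segmenter with feedback-tuned watershed de-clumping.

    Parameters
    ----------
    channel_policy : str
        How multi-channel input collapses to one channel (``luminance``,
        ``max-contrast``, a channel name, or ``channel:i``).
    invert_mode : str
        ``auto`` flips dark-on-bright plates so objects are bright.
    find_dish : bool
        Detect the circular dish and restrict the search to its interior.
    smooth_sigma : float
        Gaussian denoising scale in pixels applied before normalization
        (0 disables).
    t_min, t_max, delta : float
        Intensity-threshold sweep (defaults 0.01, 0.99, 0.1).
    use_intensity : bool
        Enable the a priori intensity band [b_min, b_max] during filtering.
    max_area_frac : float
        Per-threshold oversize cut as a fraction of the search area.
    big_blob_rule : str
        Clump cutoff: ``median_x1.3`` (1.3x the median area) or ``p70``.
    h_min, h_max, h_step : float
        H-maxima depth sweep for the feedback watershed.
    exclude_border : bool
        Drop segments touching the dish-mask boundary.
    max_eccentricity : float or None
        Optional shape filter; segments more eccentric are dropped.
    """

    def __init__(
        self,
        channel_policy: str = "luminance",
        invert_mode: str = "auto",
        find_dish: bool = True,
        smooth_sigma: float = 1.0,
        t_min: float = 0.01,
        t_max: float = 0.99,
        delta: float = 0.1,
        use_intensity: bool = False,
        max_area_frac: float = 0.10,
        big_blob_rule: str = "median_x1.3",
        h_min: float = 0.10,
        h_max: float = 0.30,
        h_step: float = 0.01,
        exclude_border: bool = False,
        max_eccentricity: float | None = None,
    ):
        self.channel_policy = channel_policy
        self.invert_mode = invert_mode
        self.find_dish = find_dish
        self.smooth_sigma = smooth_sigma
        self.t_min = t_min
        self.t_max = t_max
        self.delta = delta
        self.use_intensity = use_intensity
        self.max_area_frac = max_area_frac
        self.big_blob_rule = big_blob_rule
        self.h_min = h_min
        self.h_max = h_max
        self.h_step = h_step
        self.exclude_border = exclude_border
        self.max_eccentricity = max_eccentricity

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None, *, seeds=None, areas=None, model: AprioriModel | None = None):
        """Learn the a priori model.

        Exactly one source: ``seeds`` (pixel positions of example colonies
        in image ``X``, grown by fast marching), ``areas`` (known example
        areas, no image needed), or a ready ``model``.
        """
        given = sum(s is not None for s in (seeds, areas, model))
        if given != 1:
            raise ValueError("provide exactly one of seeds=, areas= or model=")
        if model is not None:
            self.apriori_model_ = model
        elif areas is not None:
            areas = [float(a) for a in areas]
            self.apriori_model_ = apriori_from_areas(min(areas), max(areas))
        else:
            img = self._prepare(X)
            blobs = [blob_from_seed(img, s) for s in seeds]
            self.apriori_model_ = build_apriori(blobs, use_intensity=self.use_intensity)
        self.a_min_ = self.apriori_model_.a_min
        self.a_max_ = self.apriori_model_.a_max
        self.size_mf_ = self.apriori_model_.size_mf
        return self

    # -- prediction ------------------------------------------------------

    def predict(self, X) -> SegmentationResult:
        """Segment one image; returns the full :class:`SegmentationResult`."""
        self._check_fitted()
        img = self._prepare(X)
        return self.segment_normalized(img)

    def fit_predict(self, X, **fit_kw) -> SegmentationResult:
        return self.fit(X, **fit_kw).predict(X)

    def count(self, X) -> int:
        """Colony count of one image (the headline CFU number)."""
        return self.predict(X).n_segments

    def segment_normalized(self, img: NormalizedImage) -> SegmentationResult:
        """Run the detection pipeline on an already-prepared image."""
        self._check_fitted()
        model = self.apriori_model_
        schedule = ThresholdSchedule(t_min=self.t_min, t_max=self.t_max, delta=self.delta)
        mask = multithreshold_accumulate(img, model, schedule, self.max_area_frac)
        kept, _ = plausibility_filter(mask, model, img)
        meta = {
            "thresholds": schedule.thresholds(),
            "a_min": model.a_min,
            "a_max": model.a_max,
            "params": self.get_params(),
        }
        if not kept:
            return SegmentationResult(
                label_mask=np.zeros(img.pixels.shape, dtype=np.int32), segments=[], meta=meta
            )
        singles, clumps = classify_big_blobs(kept, model, rule=self.big_blob_rule)
        ordered = singles + clumps
        label_mask = np.zeros(img.pixels.shape, dtype=np.int32)
        for k, seg in enumerate(ordered, start=1):
            label_mask[seg.rows, seg.cols] = k
        result = SegmentationResult(label_mask=label_mask, segments=ordered, meta=meta)
        clump_ids = list(range(len(singles) + 1, len(ordered) + 1))
        if clump_ids:
            cfg = DeclumpConfig(h_min=self.h_min, h_max=self.h_max, step=self.h_step)
            result = declump_all(result, img, model, cfg, clump_ids=clump_ids)
        result = self._postfilter(result, img)
        return result

    # -- helpers ---------------------------------------------------------

    def _prepare(self, X) -> NormalizedImage:
        if isinstance(X, NormalizedImage):
            return X
        return prepare_image(
            np.asarray(X),
            channel_policy=self.channel_policy,
            invert_mode=self.invert_mode,
            find_dish=self.find_dish,
            smooth_sigma=self.smooth_sigma,
        )

    def _postfilter(self, result: SegmentationResult, img: NormalizedImage) -> SegmentationResult:
        drop: set[int] = set()
        if self.exclude_border and img.dish_mask is not None:
            outside = ndi.binary_dilation(~img.dish_mask, structure=_EIGHT)
            for k, seg in enumerate(result.segments, start=1):
                if outside[seg.rows, seg.cols].any():
                    drop.add(k)
        if self.max_eccentricity is not None:
            for k, seg in enumerate(result.segments, start=1):
                if seg.eccentricity > self.max_eccentricity:
                    drop.add(k)
        if not drop:
            return result
        label_mask = np.zeros_like(result.label_mask)
        segments: list[Segment] = []
        for k, seg in enumerate(result.segments, start=1):
            if k in drop:
                continue
            segments.append(seg)
            label_mask[seg.rows, seg.cols] = len(segments)
        return SegmentationResult(label_mask=label_mask, segments=segments, meta=dict(result.meta))

    def _check_fitted(self) -> None:
        if not hasattr(self, "apriori_model_"):
            raise RuntimeError("CFUSegmenter is not fitted; call fit() first")
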