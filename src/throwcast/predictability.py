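"""Predictability maps: MI_BK over spatial units x time deciles.

For every cell (joint marker or body segment x time interval) the pipeline
builds the stacked position+velocity features, compresses them with
spatiotemporal PCA at a fixed VAF, scores a leave-one-out LDA of the landing
side and records the misclassification index MI_BK. A participant is called
"predictable" at a decile when some spatial unit reaches better than 80%
accuracy there, i.e. MI_BK < 0.20 (the ball-corrected error is the mapped
quantity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ball_baseline_me, loocv_me, misclassification_index
from .dataset import ParticipantData
from .features import PredictorSpec, SpatiotemporalPCA, build_features
from .trialdata import CANONICAL_MARKERS, SEGMENT_NAMES, body_segment_of

FAMILIES = ("marker_decile", "marker_through", "segment_decile",
            "segment_through")

N_DECILES = 10


def _family_parts(family: str):
    if family not in FAMILIES:
        raise ValueError(f"unknown predictor family {family!r}")
    spatial, mode = family.split("_")
    units = CANONICAL_MARKERS if spatial == "marker" else SEGMENT_NAMES
    return spatial, mode, units


@dataclass
class PredictabilityMap:
    """MI_BK values over a spatial-unit x decile grid for one participant.

    Unavailable cells (degenerate LOOCV folds) are NaN. ``me`` holds the raw
    body-kinematics misclassification fractions and ``n_pc`` the number of
    retained spatiotemporal components per cell.
    """

    participant_id: str
    family: str
    units: tuple[str, ...]
    mi: np.ndarray
    me: np.ndarray
    n_pc: np.ndarray
    me_ball: float

    def __post_init__(self):
        expected = (len(self.units), N_DECILES)
        if self.mi.shape != expected:
            raise ValueError(f"map grid must be {expected}")


def compute_map(data: ParticipantData, family: str = "marker_decile",
                vaf: float = 0.98, ridge: float = 1e-8,
                nested_pca: bool = False) -> PredictabilityMap:
    """Sweep every spatial unit x decile cell of one predictor family."""
    spatial, mode, units = _family_parts(family)
    if data.n_used < 4:
        raise ValueError("not enough labeled trials for LOOCV")
    me_ball = ball_baseline_me(data.release_states, data.labels, ridge).me

    shape = (len(units), N_DECILES)
    mi = np.full(shape, np.nan)
    me = np.full(shape, np.nan)
    n_pc = np.zeros(shape, dtype=int)
    for ui, unit in enumerate(units):
        for d in range(1, N_DECILES + 1):
            if spatial == "marker":
                spec = PredictorSpec.for_marker(unit, mode, d)
            else:
                spec = PredictorSpec.for_segment(unit, mode, d)
            fm = build_features(data.aligned, spec)
            try:
                model = SpatiotemporalPCA(vaf=vaf).fit(fm.X.T)
                out = loocv_me(model.scores_, data.labels, ridge=ridge,
                               nested_pca=nested_pca,
                               feature_matrix=fm.X if nested_pca else None,
                               vaf=vaf)
            except ValueError:
                continue   # cell marked unavailable
            me[ui, d - 1] = out.me
            mi[ui, d - 1] = misclassification_index(out.me, me_ball)
            n_pc[ui, d - 1] = model.n_components_
    return PredictabilityMap(data.participant_id, family, tuple(units),
                             mi, me, n_pc, me_ball)


def min_mi(pmap: PredictabilityMap):
    """Global minimum of a map: ``(mi_min, unit, decile)``.

    Exact ties are broken toward the later decile, then canonical unit
    order.
    """
    if np.all(np.isnan(pmap.mi)):
        raise ValueError("all map cells are unavailable")
    best = np.nanmin(pmap.mi)
    ties = np.argwhere(pmap.mi == best)
    ties = ties[np.lexsort((ties[:, 0], -ties[:, 1]))]
    ui, di = ties[0]
    return float(best), pmap.units[ui], int(di + 1)


@dataclass
class PredictabilitySummary:
    """Cohort counts of predictable participants per decile.

    ``counts[d-1]`` is the number of participants whose best spatial unit at
    decile d beats the accuracy threshold; ``segment_counts[d-1]`` tallies
    the body segment containing each counted participant's most informative
    unit at that decile.
    """

    family: str
    n_participants: int
    accuracy_threshold: float
    counts: np.ndarray = field(default_factory=lambda: np.zeros(N_DECILES, int))
    segment_counts: list[dict[str, int]] = field(
        default_factory=lambda: [dict() for _ in range(N_DECILES)])


def predictable_summary(maps: list[PredictabilityMap],
                        accuracy_threshold: float = 0.80
                        ) -> PredictabilitySummary:
    """Count, per decile, participants predictable above the threshold.

    A participant counts at decile d when the minimum MI over spatial units
    there is below 1 - accuracy_threshold; the body segment of the argmin
    unit is tallied.
    """
    if not maps:
        raise ValueError("need at least one map")
    family = maps[0].family
    if any(m.family != family for m in maps):
        raise ValueError("maps must share the predictor family")
    summary = PredictabilitySummary(family, len(maps), accuracy_threshold)
    mi_cut = 1.0 - accuracy_threshold
    for pmap in maps:
        for d in range(N_DECILES):
            col = pmap.mi[:, d]
            if np.all(np.isnan(col)):
                continue
            best = np.nanmin(col)
            if best < mi_cut:
                summary.counts[d] += 1
                ui = int(np.argmax(col == best))   # canonical-order tie-break
                unit = pmap.units[ui]
                seg = unit if unit in SEGMENT_NAMES else body_segment_of(unit)
                tally = summary.segment_counts[d]
                tally[seg] = tally.get(seg, 0) + 1
    return summary


def compare_predictor_spaces(cohort: list[ParticipantData], vaf: float = 0.98,
                             accuracy_threshold: float = 0.80,
                             ridge: float = 1e-8):
    """Compute all four family maps and summaries with a common threshold.

    Returns ``{family: (maps, summary)}`` over the cohort.
    """
    out = {}
    for family in FAMILIES:
        maps = [compute_map(p, family, vaf=vaf, ridge=ridge) for p in cohort]
        out[family] = (maps, predictable_summary(maps, accuracy_threshold))
    return out
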