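"""Assembly of one participant's analysis-ready dataset.

Chains preprocessing, key-event detection, trial exclusion, gray-band side
labeling and release-aligned resampling, producing the containers the
classification and predictability stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import events as ev
from .features import AlignedTrial, align_and_resample, mean_throw_duration
from .labeling import DEFAULT_BAND_WIDTH_M, SideLabel, label_trials
from .preprocess import ProcessedTrial, process_trial
from .trialdata import BoardGeometry, TrialRecord


@dataclass
class TrialResult:
    """Per-trial bookkeeping across the pipeline stages."""

    trial_id: str
    processed: ProcessedTrial
    events: ev.KeyEvents | None
    exclusion: ev.ExclusionReport
    label: SideLabel | None = None
    aligned: AlignedTrial | None = None


@dataclass
class ParticipantData:
    """Labeled, aligned trials of one participant, ready for LDA.

    ``labels`` holds only Right/Left (band and excluded trials are dropped
    from classification); ``release_states`` are the matching six ball
    release-state predictors per trial.
    """

    participant_id: str
    trials: list[TrialResult]
    window_s: float
    aligned: list[AlignedTrial] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.array([]))
    release_states: np.ndarray = field(default_factory=lambda: np.empty((0, 6)))
    band_center: float = float("nan")
    band_width: float = DEFAULT_BAND_WIDTH_M

    @property
    def n_good(self) -> int:
        return sum(not t.exclusion.excluded for t in self.trials)

    @property
    def n_used(self) -> int:
        return len(self.aligned)

    def exclusion_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for t in self.trials:
            tally[t.exclusion.reason] = tally.get(t.exclusion.reason, 0) + 1
        return tally


def assemble_participant(records: list[TrialRecord],
                         board: BoardGeometry | None = None,
                         band_width: float = DEFAULT_BAND_WIDTH_M,
                         filter_order: int = 5, cutoff_hz: float = 15.0,
                         ball_radius: float = 0.045,
                         n_resample: int = 100,
                         **event_params) -> ParticipantData:
    """Run preprocess -> events -> exclusion -> labels -> alignment."""
    if not records:
        raise ValueError("no trials to assemble")
    board = board or BoardGeometry()
    pid = records[0].participant_id

    results: list[TrialResult] = []
    for rec in records:
        processed = process_trial(rec, order=filter_order,
                                  cutoff_hz=cutoff_hz, ball_radius=ball_radius)
        keyev, failure = None, None
        try:
            keyev = ev.detect_events(processed, board, **event_params)
        except ev.EventDetectionError as err:
            failure = err
        report = ev.apply_exclusion_rules(rec, processed, keyev, failure)
        results.append(TrialResult(rec.trial_id, processed, keyev, report))

    good = [t for t in results if not t.exclusion.excluded and t.events]
    if not good:
        raise ValueError("every trial was excluded")

    landings = np.array([t.events.landing[0] for t in good])
    labels_all = label_trials(landings, band_width)
    for t, lab in zip(good, labels_all):
        t.label = lab

    window = mean_throw_duration([t.events for t in good])

    aligned, labels, states = [], [], []
    for t in good:
        if t.label.value == "Band":
            continue
        t.aligned = align_and_resample(t.processed, t.events.t_release,
                                       window, n_resample)
        aligned.append(t.aligned)
        labels.append(t.label.value)
        states.append(t.events.flight_fit.release_state())

    return ParticipantData(
        participant_id=pid,
        trials=results,
        window_s=window,
        aligned=aligned,
        labels=np.array(labels),
        release_states=np.array(states) if states else np.empty((0, 6)),
        band_center=labels_all[0].band_center if labels_all else float("nan"),
        band_width=band_width,
    )
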