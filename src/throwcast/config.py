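"""Pipeline configuration: one structured mapping, validated strictly.

The YAML layout groups parameters by stage (``filter``, ``ball``, ``band``,
``stpca``, ``resample``, ``onset``, ``release``, ``impact``, ``board``,
``sim`` plus top-level ``sample_rate``, ``accuracy_threshold``, ``families``
and ``seed``). Unknown keys are rejected so typos cannot silently fall back
to defaults. All randomness downstream derives from the single ``seed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .synthetic import InformativeMarker, ThrowSimConfig
from .trialdata import BoardGeometry


def _check_range(name, value, lo, hi):
    if not lo <= value <= hi:
        raise ValueError(f"{name}={value} outside valid range [{lo}, {hi}]")


@dataclass(frozen=True)
class PipelineConfig:
    sample_rate: float = 120.0
    filter_order: int = 5
    filter_cutoff_hz: float = 15.0
    ball_radius_m: float = 0.045
    band_width_m: float = 0.225
    stpca_vaf: float = 0.98
    resample_n: int = 100
    onset_rise_m: float = 0.05
    onset_window_s: float = 0.5
    onset_fraction: float = 0.2
    release_window_s: float = 0.5
    release_margin_m: float = 0.03
    impact_fit_window_s: tuple[float, float] = (0.150, 0.450)
    impact_horizon_s: float = 0.300
    board_distance_m: float = 6.0
    accuracy_threshold: float = 0.80
    lda_ridge: float = 1e-8
    nested_pca: bool = False
    families: tuple[str, ...] = ("marker_decile",)
    seed: int = 0
    sim: ThrowSimConfig = field(default_factory=ThrowSimConfig)

    def __post_init__(self):
        _check_range("filter.order", self.filter_order, 1, 10)
        if self.sample_rate <= 2 * self.filter_cutoff_hz:
            raise ValueError("sample_rate must exceed twice the filter cutoff")
        _check_range("stpca.vaf", self.stpca_vaf, 0.0, 1.0)
        _check_range("accuracy_threshold", self.accuracy_threshold, 0.0, 1.0)
        if self.resample_n % 10 != 0 or self.resample_n <= 0:
            raise ValueError("resample.n must be a positive multiple of 10")
        if self.band_width_m < 0 or self.ball_radius_m <= 0:
            raise ValueError("band width must be >= 0 and ball radius > 0")
        lo, hi = self.impact_fit_window_s
        if not 0 < lo < hi:
            raise ValueError("impact fit window must satisfy 0 < start < end")

    @property
    def board(self) -> BoardGeometry:
        return BoardGeometry(distance_m=self.board_distance_m)

    def sim_config(self, seed: int | None = None) -> ThrowSimConfig:
        return replace(
            self.sim,
            sample_rate=self.sample_rate,
            board=self.board,
            seed=self.seed if seed is None else seed,
        )

    def event_params(self) -> dict:
        return dict(
            onset_rise_m=self.onset_rise_m,
            onset_window_s=self.onset_window_s,
            onset_fraction=self.onset_fraction,
            release_window_s=self.release_window_s,
            release_margin_m=self.release_margin_m,
            fit_window_s=tuple(self.impact_fit_window_s),
            horizon_s=self.impact_horizon_s,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["informative_markers"] = [
            [m.marker, m.onset_decile, m.amplitude_m]
            for m in self.sim.informative_markers
        ]
        d["sim"].pop("board", None)
        return d

    def hash(self) -> str:
        blob = yaml.safe_dump(_plainify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        sections = {
            "sample_rate": self.sample_rate,
            "accuracy_threshold": self.accuracy_threshold,
            "seed": self.seed,
            "families": list(self.families),
            "lda_ridge": self.lda_ridge,
            "nested_pca": self.nested_pca,
            "filter": {"order": self.filter_order,
                       "cutoff_hz": self.filter_cutoff_hz},
            "ball": {"radius_m": self.ball_radius_m},
            "band": {"width_m": self.band_width_m},
            "stpca": {"vaf": self.stpca_vaf},
            "resample": {"n": self.resample_n},
            "onset": {"rise_m": self.onset_rise_m,
                      "window_s": self.onset_window_s,
                      "fraction": self.onset_fraction},
            "release": {"window_s": self.release_window_s,
                        "margin_m": self.release_margin_m},
            "impact": {"fit_window_s": list(self.impact_fit_window_s),
                       "horizon_s": self.impact_horizon_s},
            "board": {"distance_m": self.board_distance_m},
            "sim": {k: v for k, v in self.to_dict()["sim"].items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_plainify(sections), fh, sort_keys=False)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


_SECTION_KEYS = {
    "filter": ("order", "cutoff_hz"),
    "ball": ("radius_m",),
    "band": ("width_m",),
    "stpca": ("vaf",),
    "resample": ("n",),
    "onset": ("rise_m", "window_s", "fraction"),
    "release": ("window_s", "margin_m"),
    "impact": ("fit_window_s", "horizon_s"),
    "board": ("distance_m",),
}
_TOP_KEYS = ("sample_rate", "accuracy_threshold", "seed", "families",
             "lda_ridge", "nested_pca", "sim")
_SIM_FIELDS = {f.name for f in fields(ThrowSimConfig)} - {"board"}


def load_config(path_or_dict, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or mapping.

    Unknown sections or keys raise ``ValueError``.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    elif path_or_dict is None:
        raw = {}
    else:
        with open(path_or_dict, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}

    kwargs = {}
    for key, val in raw.items():
        if key in _SECTION_KEYS:
            for sub, subval in (val or {}).items():
                if sub not in _SECTION_KEYS[key]:
                    raise ValueError(f"unknown config key {key}.{sub}")
                name = f"{key}_{sub}" if not sub.startswith(key) else sub
                kwargs[name] = _maybe_tuple(subval)
        elif key == "sim":
            sim_kwargs = {}
            for sub, subval in (val or {}).items():
                if sub not in _SIM_FIELDS:
                    raise ValueError(f"unknown config key sim.{sub}")
                if sub == "informative_markers":
                    subval = tuple(
                        InformativeMarker(m, int(d), float(a))
                        for m, d, a in subval
                    )
                sim_kwargs[sub] = _maybe_tuple(subval)
            kwargs["sim"] = ThrowSimConfig(**sim_kwargs)
        elif key in _TOP_KEYS:
            kwargs[key] = _maybe_tuple(val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def _maybe_tuple(val):
    return tuple(val) if isinstance(val, list) else val
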