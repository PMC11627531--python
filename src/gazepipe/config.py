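"""Run configuration: validated thresholds, windows, and channel parameters.

Configs are flat YAML key-value files.  All times are integer milliseconds,
all positions screen proportions (origin top-left, y increases downward),
and analysis windows must sit on the 100 ms bin grid.  Defaults follow the
analysis conventions used throughout the package: |z| threshold 2.0, ROI
binarization 30%, side binarization 50%, off-screen trial exclusion 50%,
cluster significance 0.05, 1000 permutations, and per-task analysis
windows of 0-1500 ms (fixation, lexical fixation, phonemic cohort) or
-700-1000 ms (anticipatory looking) around the alignment zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]

DEFAULT_WINDOWS = {
    "fixation": (0, 1500),
    "lexical_fixation": (0, 1500),
    "phonemic_cohort": (0, 1500),
    "anticipatory": (-700, 1000),
}


class ConfigError(ValueError):
    """Invalid configuration; message lists every violation found."""


@dataclass
class RunConfig:
    task: str = "phonemic_cohort"
    n_subjects: int = 20
    n_items: int = 18
    seed: int = 1
    methods: tuple[str, ...] = ("infrared", "manual", "webgazer")
    window_start_ms: int | None = None
    window_end_ms: int | None = None
    bin_ms: int = 100
    z_threshold: float = 2.0
    roi_threshold: float = 0.30
    side_threshold: float = 0.50
    exclusion_threshold: float = 0.50
    alpha: float = 0.05
    n_perm: int = 1000
    center_fraction: float = 0.15
    aspect_ratio: float = 16 / 9
    cohort_excess: float = 0.15
    cohort_base_prob: float = 0.08
    effect_window_ms: tuple[int, int] = (400, 900)
    out_dir: str = "results"

    def __post_init__(self):
        if self.window_start_ms is None or self.window_end_ms is None:
            lo, hi = DEFAULT_WINDOWS.get(self.task, (0, 1500))
            self.window_start_ms = lo if self.window_start_ms is None else self.window_start_ms
            self.window_end_ms = hi if self.window_end_ms is None else self.window_end_ms
        self.validate()

    @property
    def window(self) -> tuple[int, int]:
        return (self.window_start_ms, self.window_end_ms)

    def validate(self) -> None:
        errors = []
        for name in ("roi_threshold", "side_threshold", "exclusion_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                errors.append(f"{name} must lie in (0, 1), got {v}")
        if self.z_threshold <= 0:
            errors.append(f"z_threshold must be positive, got {self.z_threshold}")
        if self.n_perm < 1:
            errors.append(f"n_perm must be >= 1, got {self.n_perm}")
        if self.bin_ms <= 0:
            errors.append(f"bin_ms must be positive, got {self.bin_ms}")
        else:
            for name in ("window_start_ms", "window_end_ms"):
                if getattr(self, name) % self.bin_ms:
                    errors.append(f"{name} must sit on the {self.bin_ms} ms bin grid")
        if self.window_end_ms <= self.window_start_ms:
            errors.append("window_end_ms must exceed window_start_ms")
        if self.n_subjects < 1 or self.n_items < 1:
            errors.append("n_subjects and n_items must be >= 1")
        if not 0 < self.center_fraction < 1:
            errors.append(f"center_fraction must lie in (0, 1), got {self.center_fraction}")
        if errors:
            raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["effect_window_ms"] = list(self.effect_window_ms)
        return d

    def digest(self) -> str:
        """Stable content hash of the configuration (for run manifests)."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError("unknown config keys: " + ", ".join(unknown))
    for key in ("methods", "effect_window_ms"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
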