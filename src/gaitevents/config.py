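"""Pipeline configuration: every tunable constant, with range-checked overrides."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields, asdict
from pathlib import Path

__all__ = ["PipelineConfig", "load_config"]

# (lo, hi, lo_inclusive, hi_inclusive) valid ranges per field
_RANGES = {
    "fs": (0.0, 10000.0, False, True),
    "hp_cutoff": (0.0, 50.0, False, True),
    "hp_order": (1, 8, True, True),
    "smooth_m": (1, 1000, True, True),
    "th1": (0.0, 100.0, False, True),
    "window_len": (10, 100000, True, True),
    "fc": (0.0, 100.0, False, True),
    "s_max": (2, 10000, True, True),
    "prior_mu_e": (1, 10000, True, True),
    "prior_mu_c": (1, 10000, True, True),
    "prior_sigma1": (0.0, 10000.0, False, True),
    "prior_sigma2": (0.0, 10000.0, False, True),
    "band_filter_cutoff": (0.0, 1000.0, False, True),
    "wait_len": (0, 1000, True, True),
    "r_b": (0.0, 1.0, False, True),
    "r1": (0.0, 1.0, False, True),
    "r2": (0.0, 1.0, False, True),
    "match_tolerance": (0.0, 10.0, False, True),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults are the method's published operating point at 148.15 Hz sampling."""

    fs: float = 148.15
    hp_cutoff: float = 0.5
    hp_order: int = 2
    smooth_m: int = 30
    th1: float = 1.0
    window_len: int = 300
    fc: float = 0.8125
    s_max: int = 241
    prior_mu_e: int = 75
    prior_mu_c: int = 150
    prior_sigma1: float = 15.0
    prior_sigma2: float = 25.0
    band_filter_cutoff: float = 10.0
    band_filter_kind: str = "lowpass"
    wait_len: int = 15
    r_b: float = 0.8
    r1: float = 0.5
    r2: float = 0.5
    match_tolerance: float = 0.4
    toe_fraction: float = 0.95

    def __post_init__(self):
        for f in fields(self):
            if f.name not in _RANGES:
                continue
            lo, hi, lo_inc, hi_inc = _RANGES[f.name]
            v = getattr(self, f.name)
            ok = (v >= lo if lo_inc else v > lo) and (v <= hi if hi_inc else v < hi)
            if not ok:
                lo_b = "[" if lo_inc else "("
                hi_b = "]" if hi_inc else ")"
                raise ValueError(
                    f"config key {f.name} = {v!r} outside valid range "
                    f"{lo_b}{lo}, {hi}{hi_b}"
                )
        if self.band_filter_kind not in ("lowpass", "highpass"):
            raise ValueError("band_filter_kind must be 'lowpass' or 'highpass'")
        if not self.prior_mu_e < self.prior_mu_c <= self.s_max:
            raise ValueError("prior scales must satisfy prior_mu_e < prior_mu_c <= s_max")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Defaults merged with TOML overrides; unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
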