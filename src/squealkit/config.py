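"""Declarative run configuration for the CLI pipeline.

A single YAML file specifies windowing, flux/quantile options, the
hypothesis directions, the FDR level, screening thresholds and the
synthetic cohort models.  Every section is optional; omitted keys fall
back to the package defaults.  Validation happens eagerly: building a
:class:`RunConfig` constructs the underlying domain objects, which
reject invalid values before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from squealkit.stats import DEFAULT_HYPOTHESES
from squealkit.synth import SquealModel
from squealkit.windows import WindowPlan

__all__ = ["RunConfig", "load_config"]

DEFAULT_COUNTS = {"pig1": (21, 39), "pig2": (26, 28), "pig3": (20, 12)}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    plan: WindowPlan = field(default_factory=WindowPlan)
    flux_reduce: str = "mean"
    q50n_mode: str = "max"
    include_cpp: bool = False
    hnr_floor_pitch: float = 75.0
    alpha: float = 0.05
    hypotheses: dict = field(default_factory=lambda: dict(DEFAULT_HYPOTHESES))
    min_dur_s: float = 0.3
    max_mean_rating: float = 1.0
    sample_rate: int = 44100
    seed: int = 0
    pre_model: SquealModel = field(default_factory=lambda: SquealModel(rolloff_cutoff=8000.0))
    post_model: SquealModel = field(default_factory=lambda: SquealModel(rolloff_cutoff=2000.0))
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for param, direction in self.hypotheses.items():
            if direction not in ("decrease", "increase"):
                raise ValueError(f"bad direction for {param!r}: {direction!r}")


def load_config(path: str | Path | None) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file (or defaults)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    win = raw.get("windows", {})
    plan = WindowPlan(
        n_partial=int(win.get("n_partial", 11)),
        frame_len=int(win.get("frame_len", 1024)),
        overlap_frac=float(win.get("overlap", 0.5)),
        taper=str(win.get("taper", "hamming")),
    )
    hypotheses = dict(DEFAULT_HYPOTHESES)
    hypotheses.update(raw.get("hypotheses", {}))
    synth = raw.get("synth", {})

    def model(block: dict, default_cutoff: float) -> SquealModel:
        kwargs = {"rolloff_cutoff": default_cutoff}
        kwargs.update(block)
        return SquealModel(**kwargs)

    counts = {
        str(k): (int(v[0]), int(v[1]))
        for k, v in synth.get("counts", DEFAULT_COUNTS).items()
    }
    screening = raw.get("screening", {})
    return RunConfig(
        plan=plan,
        flux_reduce=str(raw.get("flux", {}).get("reduce", "mean")),
        q50n_mode=str(raw.get("q50n", {}).get("mode", "max")),
        include_cpp=bool(raw.get("include_cpp", False)),
        hnr_floor_pitch=float(raw.get("hnr", {}).get("floor_pitch", 75.0)),
        alpha=float(raw.get("alpha", 0.05)),
        hypotheses=hypotheses,
        min_dur_s=float(screening.get("min_dur_s", 0.3)),
        max_mean_rating=float(screening.get("max_mean_rating", 1.0)),
        sample_rate=int(raw.get("sample_rate", 44100)),
        seed=int(raw.get("seed", 0)),
        pre_model=model(synth.get("pre", {}), 8000.0),
        post_model=model(synth.get("post", {}), 2000.0),
        counts=counts,
    )
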