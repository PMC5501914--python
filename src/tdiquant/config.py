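"""Analysis configuration: every envelope/beats tunable in one place,
loadable from a plain-text ``key=value`` file. Unknown keys are rejected."""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .envelope import FilterParams
from .errors import TdiError

CONVENTIONS = ("middle", "outer", "both")


@dataclass(frozen=True)
class AnalysisConfig:
    butterworth_order: int = 2
    butterworth_cutoff: float = 0.1
    sg_window_px: int = 15
    sg_poly_order: int = 3
    axis_halfwidth_px: int = 2
    min_distance_frac: float = 0.6
    min_height_frac: float = 0.1
    convention: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        self.filter_params()                    # validates the envelope tunables
        if self.convention not in CONVENTIONS:
            raise TdiError(f"convention must be one of {CONVENTIONS}")
        if not 0 < self.min_distance_frac <= 1:
            raise TdiError("min_distance_frac must lie in (0, 1]")
        if not 0 <= self.min_height_frac < 1:
            raise TdiError("min_height_frac must lie in [0, 1)")

    def filter_params(self) -> FilterParams:
        return FilterParams(
            butterworth_order=self.butterworth_order,
            butterworth_cutoff=self.butterworth_cutoff,
            sg_window_px=self.sg_window_px,
            sg_poly_order=self.sg_poly_order,
            axis_halfwidth_px=self.axis_halfwidth_px)

    @property
    def conventions(self) -> tuple[str, ...]:
        return ("middle", "outer") if self.convention == "both" else (self.convention,)


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse a plain-text config file (``key=value`` lines, ``#`` comments)."""
    types = {f.name: f.type for f in fields(AnalysisConfig)}
    casts = {"int": int, "float": float, "str": str}
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if not sep or key not in types:
            raise TdiError(f"unknown config key: {key!r}")
        try:
            kwargs[key] = casts[types[key]](val)
        except ValueError:
            raise TdiError(f"bad value for {key!r}: {val!r}") from None
    return AnalysisConfig(**kwargs)
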