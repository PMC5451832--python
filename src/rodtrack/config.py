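"""Parameter dataclasses shared across the pipeline.

All defaults follow the published parameter selection for the method:
Gaussian smoothing sigma = 1; level-set weights dt = 1, mu = 0.2, lambda = 5,
alpha = -3, stopping tolerance K = 0.005; size filter r_s = 3 um; septum
threshold multiplier tau = 1.2; width threshold r_w = 1.2 um; sub-window side
w = 0.6 um; trajectory-energy weights (beta, gamma, eta) = (0.02, 0.5, 0.5).
Lengths are in micrometres and converted to pixels via the stack calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its validity constraints."""


@dataclass
class DrlseParams:
    """Weights and numerics of the level-set evolution.

    The product ``mu * dt`` must stay below 0.25 for the forward-Euler update
    of the distance-regularization term to be stable.
    """

    mu: float = 0.2
    lam: float = 5.0
    alpha: float = -3.0
    dt: float = 1.0
    K: float = 0.005
    sigma: float = 1.0
    eps: float = 1.5
    c0: float = 2.0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.lam <= 0:
            raise ConfigurationError("mu and lam must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.K < 0:
            raise ConfigurationError("K must be non-negative")
        if self.eps <= 0:
            raise ConfigurationError("eps must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.mu * self.dt >= 0.25:
            raise ConfigurationError(
                f"stability constraint violated: mu*dt = {self.mu * self.dt:g} >= 0.25"
            )


@dataclass
class SegConfig:
    """First-frame and new-cell segmentation settings."""

    r_s: float = 3.0          # minimum cell length, um
    calibration: float = 0.15  # um per pixel
    thresh_block: int = 25     # adaptive-threshold window, px (odd)
    thresh_offset: float = 5.0   # gray levels below local mean
    min_seed_area: int = 9     # px^2, specks below this never seed

    def __post_init__(self) -> None:
        if self.r_s <= 0:
            raise ConfigurationError("r_s must be positive")
        if self.calibration <= 0:
            raise ConfigurationError("calibration must be positive")
        if self.thresh_block < 3 or self.thresh_block % 2 == 0:
            raise ConfigurationError("thresh_block must be an odd integer >= 3")


@dataclass
class TrackConfig:
    """Frame-to-frame propagation, division detection and identity assignment."""

    w: float = 0.6             # sub-window side, um
    tau: float = 1.2           # septum threshold multiplier
    r_w: float = 1.2           # width threshold / minimum average width, um
    beta: float = 0.02         # velocity-energy weight
    gamma: float = 0.5         # exclusion-energy weight
    eta: float = 0.5           # regularization-energy weight
    window_lookahead: int = 3  # frames enumerated for ambiguous assignments
    max_assignments: int = 64  # enumeration cap before greedy fallback
    min_split_length_um: float | None = None  # default 2*r_s, set by pipeline
    rod_min_eccentricity: float = 0.8
    propagate_margin: int = 12  # px of context around a region when evolving

    def __post_init__(self) -> None:
        if self.w <= 0 or self.r_w <= 0:
            raise ConfigurationError("w and r_w must be positive")
        if min(self.beta, self.gamma, self.eta) < 0:
            raise ConfigurationError("energy weights must be non-negative")


@dataclass
class PipelineConfig:
    """Complete effective configuration of a run, serializable for the log."""

    drlse: DrlseParams = field(default_factory=DrlseParams)
    seg: SegConfig = field(default_factory=SegConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    calibration: float = 0.15
    frame_interval: float = 69.0
    seed: int = 0

    def __post_init__(self) -> None:
        # one calibration governs the run; mirror it into the seg config
        self.seg.calibration = self.calibration

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
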