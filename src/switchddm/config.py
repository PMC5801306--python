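"""Study-design configuration: session structure constants, feedback
conditions and the generative parameter grid used by the simulator.

Defaults encode the training design this package emulates: 14 blocks of
60 trials (2 pre, 10 training, 2 post), a task switch every fourth trial,
a 2-s response deadline, 0.5-0.9 s inter-trial intervals, a 1-s switch
cue and a 600-ms speed criterion for feedback bonuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ddm import DDMParams

CONDITIONS = ("NFB", "AFB", "DFB", "PFB", "MFB", "BFB")
TRIAL_TYPES = ("switch", "nonswitch")

#: Group-level (v, a) endpoints of the ten training blocks, per trial type.
STUDY_BLOCK1 = {"switch": (2.87, 3.22), "nonswitch": (2.58, 2.00)}
STUDY_BLOCK10 = {"switch": (2.15, 2.45), "nonswitch": (2.49, 1.75)}

#: Study group sizes per feedback condition (total 316).
STUDY_GROUP_SIZES = {"NFB": 51, "AFB": 53, "DFB": 57, "PFB": 55,
                     "MFB": 52, "BFB": 48}

#: Between-subject spread used for hierarchical cohort generation.
DEFAULT_DISPERSION = {"v": 0.3, "a": 0.3, "t0": 0.05}


class ConfigError(ValueError):
    """Invalid configuration; ``violations`` lists every failed invariant."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration: " + "; ".join(self.violations))


@dataclass(frozen=True)
class SessionConfig:
    """Structure and feedback scheme of one training session."""

    n_pre_blocks: int = 2
    n_training_blocks: int = 10
    n_post_blocks: int = 2
    trials_per_block: int = 60
    switch_period: int = 4
    deadline: float = 2.0
    iti_range: tuple = (0.5, 0.9)
    cue_duration: float = 1.0
    speed_criterion: float = 0.600
    condition: str = "NFB"
    coin_value_cents: float | None = None
    #: speed-bonus band test: one-sided (rt <= criterion * (1 + pct)) by
    #: default; set True to also require rt >= criterion * (1 - pct)
    two_sided_bands: bool = False
    #: when True the 5%-band bonus stacks on the 20%-band bonus (3 + 1
    #: coins); default is tiered (3 coins only)
    stacked_bonus: bool = False

    def __post_init__(self):
        if self.coin_value_cents is None:
            object.__setattr__(self, "coin_value_cents",
                               0.2 if self.condition == "MFB" else 0.0)

    def violations(self) -> list[str]:
        out = []
        for name in ("n_pre_blocks", "n_training_blocks", "n_post_blocks",
                     "trials_per_block", "switch_period"):
            val = getattr(self, name)
            if not (isinstance(val, (int, np.integer)) and val >= 1):
                out.append(f"{name} must be a count >= 1 (got {val!r})")
        if not self.deadline > 0:
            out.append(f"deadline must be > 0 (got {self.deadline!r})")
        lo, hi = self.iti_range
        if not lo <= hi:
            out.append(f"iti_range low must be <= high (got {self.iti_range!r})")
        if isinstance(self.trials_per_block, (int, np.integer)) and \
                isinstance(self.switch_period, (int, np.integer)) and \
                self.switch_period >= 1 and \
                self.trials_per_block % self.switch_period != 0:
            out.append(
                f"trials_per_block ({self.trials_per_block}) must be divisible "
                f"by switch_period ({self.switch_period})")
        if self.condition not in CONDITIONS:
            out.append(f"condition must be one of {CONDITIONS} (got {self.condition!r})")
        return out

    def validate(self) -> "SessionConfig":
        bad = self.violations()
        if bad:
            raise ConfigError(bad)
        return self

    @property
    def n_blocks(self) -> int:
        return self.n_pre_blocks + self.n_training_blocks + self.n_post_blocks

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def block_phase(self, block_index: int) -> str:
        if block_index <= self.n_pre_blocks:
            return "pre"
        if block_index <= self.n_pre_blocks + self.n_training_blocks:
            return "training"
        return "post"


@dataclass(frozen=True)
class GenerativeGrid:
    """Generative DDM parameters per (trial_type, block_index) cell, plus
    optional between-subject dispersion (per-parameter SD on the natural
    scale) for cohort generation."""

    params: dict
    dispersion: dict = field(default_factory=lambda: {"v": 0.0, "a": 0.0, "t0": 0.0})

    def violations(self, structure=None) -> list[str]:
        out = []
        for key, sd in self.dispersion.items():
            if key not in ("v", "a", "t0"):
                out.append(f"unknown dispersion parameter {key!r}")
            elif sd < 0:
                out.append(f"dispersion for {key!r} must be >= 0 (got {sd})")
        for key, p in self.params.items():
            tt, blk = key
            if tt not in TRIAL_TYPES:
                out.append(f"grid cell {key!r}: unknown trial type")
            if not isinstance(p, DDMParams):
                out.append(f"grid cell {key!r}: value must be DDMParams")
        if structure is not None:
            needed = {(tt, int(b)) for tt, b in
                      zip(structure["trial_type"], structure["block_index"])}
            missing = sorted(needed - set(self.params))
            for cell in missing:
                out.append(f"missing grid cell {cell!r}")
        return out

    def validate(self, structure=None) -> "GenerativeGrid":
        bad = self.violations(structure)
        if bad:
            raise ConfigError(bad)
        return self

    def cell(self, trial_type: str, block_index: int) -> DDMParams:
        try:
            return self.params[(trial_type, int(block_index))]
        except KeyError:
            raise ConfigError(
                [f"missing grid cell ({trial_type!r}, {int(block_index)})"]) from None

    def draw_subject(self, rng) -> "GenerativeGrid":
        """Perturb the grid for one subject: v and a get an independent
        Gaussian offset per cell, t0 one shared offset (it is a single
        subject-level latency).  Values are clipped to stay admissible."""
        rng = np.random.default_rng(rng)
        sv = self.dispersion.get("v", 0.0)
        sa = self.dispersion.get("a", 0.0)
        st = self.dispersion.get("t0", 0.0)
        dt0 = rng.normal(0.0, st) if st > 0 else 0.0
        new = {}
        for key, p in self.params.items():
            dv = rng.normal(0.0, sv) if sv > 0 else 0.0
            da = rng.normal(0.0, sa) if sa > 0 else 0.0
            new[key] = DDMParams(
                v=p.v + dv,
                a=max(p.a + da, 0.2),
                t0=max(p.t0 + dt0, 0.05),
                lapse=p.lapse,
            )
        return GenerativeGrid(new, dict(self.dispersion))

    @classmethod
    def constant(cls, params: DDMParams, config: SessionConfig | None = None,
                 blocks=None, dispersion=None) -> "GenerativeGrid":
        """Same parameters in every (trial_type, block) cell."""
        if blocks is None:
            config = config or SessionConfig()
            blocks = range(1, config.n_blocks + 1)
        cells = {(tt, int(b)): params for tt in TRIAL_TYPES for b in blocks}
        return cls(cells, dict(dispersion or {"v": 0.0, "a": 0.0, "t0": 0.0}))

    @classmethod
    def from_endpoints(cls, block1=None, block10=None,
                       config: SessionConfig | None = None,
                       t0: float = 0.3, lapse: float = 0.10,
                       dispersion=None) -> "GenerativeGrid":
        """Grid shaped like the study's group-level trajectories: (v, a)
        interpolate linearly from the first to the last training block;
        pre blocks reuse the first-block values and post blocks the
        last-block values.  Defaults are the study endpoints."""
        block1 = block1 or STUDY_BLOCK1
        block10 = block10 or STUDY_BLOCK10
        config = config or SessionConfig()
        nt = config.n_training_blocks
        cells = {}
        for tt in TRIAL_TYPES:
            v1, a1 = block1[tt]
            v10, a10 = block10[tt]
            for b in range(1, config.n_blocks + 1):
                phase = config.block_phase(b)
                if phase == "pre":
                    frac = 0.0
                elif phase == "post":
                    frac = 1.0
                else:
                    ti = b - config.n_pre_blocks  # 1..nt
                    frac = 0.0 if nt == 1 else (ti - 1) / (nt - 1)
                cells[(tt, b)] = DDMParams(
                    v=v1 + frac * (v10 - v1),
                    a=a1 + frac * (a10 - a1),
                    t0=t0, lapse=lapse)
        return cls(cells, dict(dispersion if dispersion is not None
                               else {"v": 0.0, "a": 0.0, "t0": 0.0}))


def study_grid(config: SessionConfig | None = None,
               dispersion=None) -> GenerativeGrid:
    """The default study-shaped generative grid (printed group endpoints,
    t0 = 0.3 s, lapse = 0.10, between-subject dispersion on)."""
    return GenerativeGrid.from_endpoints(
        config=config,
        dispersion=dict(DEFAULT_DISPERSION) if dispersion is None else dispersion)

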