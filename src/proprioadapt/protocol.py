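"""Task protocol geometry and trial sequencing.

Three robotic tasks share one workspace convention (see ``kinematics``):

* APM (arm position matching): the robot parks the passive arm at one of
  nine positions on a 3x3 grid with 10 cm spacing, six blocks, 54 trials.
* AMM (arm movement matching): 20 cm passive reaches between three targets
  arranged in a triangle, all six ordered target pairs per block, six
  blocks, 36 trials.
* VMR (visuomotor rotation): 175 reaches to a single target 10 cm ahead,
  25 baseline / 125 rotated (30 deg counter-clockwise) / 25 washout.

Block orders are pseudorandomized so the same position (APM) or reach
target (AMM) never occurs on two consecutive trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["ProtocolSpec", "DEFAULT_PROTOCOL"]

# Planar stand-in for the 30 deg shoulder / 90 deg elbow grid centre of the
# passive (more-affected, here right-side) arm; mirrored across x=0 for the
# active arm.
_WORKSPACE_CENTRE = (0.17, 0.30)


@dataclass(frozen=True)
class ProtocolSpec:
    """Geometry, counts, and passive-movement speeds for the three tasks."""

    apm_grid_spacing: float = 0.10          # m between adjacent grid positions
    apm_blocks: int = 6
    amm_movement_length: float = 0.20       # m, triangle side
    amm_blocks: int = 6
    vmr_baseline_trials: int = 25
    vmr_adaptation_trials: int = 125
    vmr_washout_trials: int = 25
    rotation_deg: float = 30.0              # counter-clockwise cursor rotation
    target_distance: float = 0.10           # m, VMR start->target
    passive_peak_speed_apm: float = 0.283   # m/s, group-mean robot peak speed
    passive_peak_speed_apm_range: tuple[float, float] = (0.167, 0.406)
    passive_peak_speed_amm: float = 0.20    # m/s
    sample_rate: float = 200.0              # Hz
    workspace_centre: tuple[float, float] = _WORKSPACE_CENTRE

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if self.apm_blocks < 1 or self.amm_blocks < 1:
            raise InvalidArgumentError("block counts must be >= 1")
        if min(self.apm_grid_spacing, self.amm_movement_length, self.target_distance) <= 0:
            raise InvalidArgumentError("distances must be positive")

    # ---- geometry -------------------------------------------------------

    def apm_positions(self) -> np.ndarray:
        """The nine grid positions (9, 2) in the passive arm's workspace."""
        cx, cy = self.workspace_centre
        offs = np.array([-1.0, 0.0, 1.0]) * self.apm_grid_spacing
        xx, yy = np.meshgrid(cx + offs, cy + offs)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def amm_positions(self) -> np.ndarray:
        """Three targets (3, 2) in an equilateral triangle with 20 cm sides."""
        cx, cy = self.workspace_centre
        r = self.amm_movement_length / np.sqrt(3.0)
        ang = np.radians([90.0, 210.0, 330.0])
        return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])

    def vmr_start(self) -> np.ndarray:
        cx, _ = self.workspace_centre
        return np.array([cx, 0.20])

    def vmr_target(self) -> np.ndarray:
        return self.vmr_start() + np.array([0.0, self.target_distance])

    # ---- counts ---------------------------------------------------------

    @property
    def n_apm_trials(self) -> int:
        return 9 * self.apm_blocks

    @property
    def n_amm_trials(self) -> int:
        return 6 * self.amm_blocks

    @property
    def n_vmr_trials(self) -> int:
        return self.vmr_baseline_trials + self.vmr_adaptation_trials + self.vmr_washout_trials

    # ---- sequencing -----------------------------------------------------

    def apm_sequence(self, rng: np.random.Generator) -> np.ndarray:
        """Pseudorandom position indices (n_apm_trials,): a permutation of 0..8
        per block, with no repeat across block boundaries."""
        seq: list[int] = []
        for _ in range(self.apm_blocks):
            while True:
                perm = rng.permutation(9)
                if not seq or perm[0] != seq[-1]:
                    break
            seq.extend(int(i) for i in perm)
        return np.array(seq)

    def amm_sequence(self, rng: np.random.Generator) -> np.ndarray:
        """Pseudorandom movement sequence (n_amm_trials, 2) of (from, to) target
        indices: each block covers all six ordered pairs, and the reach target
        (``to``) never repeats on consecutive trials, including across blocks."""
        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        seq: list[tuple[int, int]] = []
        for _ in range(self.amm_blocks):
            while True:
                order = rng.permutation(6)
                block = [pairs[i] for i in order]
                tos = [seq[-1][1]] + [p[1] for p in block] if seq else [p[1] for p in block]
                if all(tos[i] != tos[i + 1] for i in range(len(tos) - 1)):
                    break
            seq.extend(block)
        return np.array(seq)

    def vmr_phases(self) -> np.ndarray:
        """Per-trial phase labels over the 175-trial session."""
        return np.array(
            ["baseline"] * self.vmr_baseline_trials
            + ["adaptation"] * self.vmr_adaptation_trials
            + ["washout"] * self.vmr_washout_trials
        )

    def vmr_rotation_series(self) -> np.ndarray:
        """Imposed rotation per trial, in compensatory degrees (+30 during adaptation)."""
        r = np.zeros(self.n_vmr_trials)
        b = self.vmr_baseline_trials
        r[b : b + self.vmr_adaptation_trials] = self.rotation_deg
        return r


DEFAULT_PROTOCOL = ProtocolSpec()
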