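"""Polysome-profile quantification.

A sucrose-gradient polysome profile is a vector of RNA signal (OD260 or
equivalent) over ordered, equal-volume fractions.  Low fraction indices sit
at the top of the gradient (free subunits and monosomes), high indices at the
bottom (heavy polysomes).  The polysome content (PC) of a sample is the
percentage of total gradient rRNA signal found in the designated polysomal
fractions, computed after baseline subtraction:

    PC = 100 * sum(signal over P fractions) / sum(signal over all fractions)

PC serves both as a readout of global translational state and as a
per-replicate normalization factor for polysome-bound RNA measurements
(stress-to-control PC ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_NP_FRACTIONS = frozenset(range(1, 9))
DEFAULT_P_FRACTIONS = frozenset(range(11, 17))

BASELINE_MODES = ("constant-min", "linear-endpoints")


@dataclass(frozen=True)
class PolysomeProfile:
    """Per-fraction RNA signal with non-polysomal / polysomal designations.

    Fraction indices are 1-based; ``signal[i-1]`` is the signal of fraction
    ``i``.  NP and P index sets must be disjoint and within range; fractions
    in neither set (the monosome/disome shoulder, typically 9-10 of 16) still
    count in the total-signal denominator.
    """

    signal: np.ndarray
    np_fractions: frozenset = DEFAULT_NP_FRACTIONS
    p_fractions: frozenset = DEFAULT_P_FRACTIONS
    sample_id: str = ""
    condition: str = ""
    baseline_subtracted: bool = False
    baseline_mode: str | None = None

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        if sig.ndim != 1 or sig.size == 0:
            raise ValueError("profile signal must be a nonempty 1-D vector")
        if not np.all(np.isfinite(sig)):
            raise ValueError("profile signal must be finite")
        if np.any(sig < 0):
            raise ValueError("profile signal must be non-negative")
        npf = frozenset(int(i) for i in self.np_fractions)
        pf = frozenset(int(i) for i in self.p_fractions)
        object.__setattr__(self, "np_fractions", npf)
        object.__setattr__(self, "p_fractions", pf)
        if npf & pf:
            raise ValueError("NP and P fraction sets must be disjoint")
        for idx_set, name in ((npf, "np"), (pf, "p")):
            if idx_set and (min(idx_set) < 1 or max(idx_set) > sig.size):
                raise ValueError(
                    f"{name}_fractions indices out of range 1..{sig.size}"
                )

    @property
    def n_fractions(self) -> int:
        return int(self.signal.size)

    def p_mask(self) -> np.ndarray:
        mask = np.zeros(self.signal.size, dtype=bool)
        for i in self.p_fractions:
            mask[i - 1] = True
        return mask


@dataclass(frozen=True)
class PolysomeContent:
    """PC of one sample: percent of total gradient signal that is polysomal."""

    pc: float
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self):
        if not (0.0 <= self.pc <= 100.0):
            raise ValueError(f"PC must lie in [0, 100], got {self.pc}")


def subtract_baseline(
    profile: PolysomeProfile, mode: str = "constant-min"
) -> PolysomeProfile:
    """Remove the gradient baseline from a profile.

    ``constant-min`` subtracts the minimum fraction signal (conservative,
    parameter-free).  ``linear-endpoints`` subtracts the straight line through
    the first and last fraction signals.  Net signals are clamped at zero and
    the mode is recorded on the returned profile.
    """
    if mode not in BASELINE_MODES:
        raise ValueError(f"unknown baseline mode {mode!r}; use one of {BASELINE_MODES}")
    sig = profile.signal
    if mode == "constant-min":
        baseline = np.full_like(sig, sig.min())
    else:
        baseline = np.linspace(sig[0], sig[-1], sig.size)
    net = np.clip(sig - baseline, 0.0, None)
    return replace(profile, signal=net, baseline_subtracted=True, baseline_mode=mode)


def compute_polysome_content(
    profile: PolysomeProfile, baseline_mode: str = "constant-min"
) -> PolysomeContent:
    """PC = 100 x polysomal signal / total signal, after baseline subtraction.

    Fraction sums are plain sums (equal-volume aliquots).  If the profile is
    already baseline-subtracted it is used as is.
    """
    if not profile.baseline_subtracted:
        profile = subtract_baseline(profile, mode=baseline_mode)
    total = float(profile.signal.sum())
    if total <= 0:
        raise ValueError("total net signal is zero; PC undefined")
    poly = float(profile.signal[profile.p_mask()].sum())
    return PolysomeContent(
        pc=100.0 * poly / total,
        sample_id=profile.sample_id,
        condition=profile.condition,
    )


def pc_normalization_factor(
    pc_stress: "PolysomeContent | float", pc_control: "PolysomeContent | float"
) -> float:
    """Stress-to-control PC ratio used to rescale polysome-bound stress samples.

    With control PC 20.0 and stress PC 11.16 this returns 0.558: under stress
    only 55.8% as much RNA is polysome-bound, so equal-loading measurements of
    the stress PB population must be scaled down by this factor.
    """
    ps = pc_stress.pc if isinstance(pc_stress, PolysomeContent) else float(pc_stress)
    pcn = pc_control.pc if isinstance(pc_control, PolysomeContent) else float(pc_control)
    if pcn <= 0:
        raise ValueError("control PC must be positive")
    if ps < 0:
        raise ValueError("stress PC must be non-negative")
    return ps / pcn


def correct_qpcr_pb(quantities, factor: float) -> np.ndarray:
    """Multiply qPCR relative quantities of stress PB samples by the PC factor."""
    q = np.asarray(quantities, dtype=float)
    if np.any(q < 0):
        raise ValueError("relative quantities must be non-negative")
    if not factor > 0:
        raise ValueError("PC factor must be positive")
    return q * factor


def gradient_distribution_from_ct(ct, efficiency: float = 2.0) -> np.ndarray:
    """Per-fraction percent of a transcript's total gradient signal from Ct values.

    The relative amount in fraction f is efficiency**(-Ct_f); percentages are
    normalized to sum to 100 across the gradient.  Adding a constant to all Ct
    values (a global loading shift) leaves the distribution unchanged.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.size == 0:
        raise ValueError("empty Ct vector")
    if not np.all(np.isfinite(ct)):
        raise ValueError("all Ct values must be finite")
    if not efficiency > 1:
        raise ValueError("amplification efficiency must exceed 1")
    # subtract the min Ct before exponentiating for numerical stability;
    # the normalization cancels the shift exactly
    w = efficiency ** (-(ct - ct.min()))
    return 100.0 * w / w.sum()
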