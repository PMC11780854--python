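"""Reactivity computation from event-count profiles.

The per-position reactivity of a chemical probing experiment is the raw
event rate: mutation rate = mutations / reads covering the position
(mutational profiling, MaP), stop rate = recorded reverse-transcription
stops / reads informative at the position (RT-stop profiling).  When a
probe-free background channel is available, background-adjusted
reactivity is rate(probe+) − rate(probe−).

Filtering follows the transcriptome-scale evaluation conventions:

* positions are retained only when coverage is strictly over a depth
  threshold (default 500 reads);
* DMS reactivity is meaningful only at adenine and cytosine, so a DMS
  base filter invalidates G/U positions; SHAPE keeps all four bases;
* an mRNA enters the analysis only if at least 50 positions pass the
  coverage threshold.

No normalization (2–8% winsorizing etc.) is applied anywhere: the
evaluation operates on raw rates, whose ranks are what ROC analysis
consumes.

Note on the stop-rate denominator: the denominator used here is the
number of reads informative at the position, i.e. reads whose cDNA
covers or terminates at it — the standard RT-stop convention.  Dividing
stops by stops would be identically 1 and carries no information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ProfilePairingError, ValidationError
from .io_formats import CountProfile

DMS_REACTIVE_BASES = frozenset("AC")


@dataclass
class ReactivityProfile:
    """Per-position reactivity with base identity and validity mask.

    ``reactivity[i]`` is NaN wherever ``valid[i]`` is False (depth 0,
    failed coverage filter, or base excluded by the probe chemistry).
    Without background subtraction every defined value lies in [0, 1];
    after unclamped subtraction values may be negative (≥ −1).
    """

    rna_id: str
    bases: str
    reactivity: np.ndarray
    valid: np.ndarray
    mode: str                    # "stop" | "mutation"
    probe: str | None = None     # "DMS" | "SHAPE" | None (not yet assigned)
    background: str = "none"     # "none" | "subtracted"

    def __post_init__(self) -> None:
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        L = len(self.bases)
        if self.reactivity.shape != (L,) or self.valid.shape != (L,):
            raise ValidationError(
                f"profile {self.rna_id!r}: bases/reactivity/valid lengths differ"
            )
        if self.mode not in ("stop", "mutation"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.probe not in (None, "DMS", "SHAPE"):
            raise ValidationError(f"unknown probe {self.probe!r}")
        # never expose a defined value on an invalid position
        self.reactivity = np.where(self.valid, self.reactivity, np.nan)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def _rate(profile: CountProfile, expected_mode: str) -> ReactivityProfile:
    if profile.mode != expected_mode:
        raise ValidationError(
            f"profile {profile.rna_id!r} has mode {profile.mode!r}, "
            f"expected {expected_mode!r}"
        )
    valid = profile.depth > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(valid, profile.events / np.maximum(profile.depth, 1),
                        np.nan)
    return ReactivityProfile(
        rna_id=profile.rna_id,
        bases=profile.bases,
        reactivity=rate,
        valid=valid,
        mode=profile.mode,
    )


def mutation_rate(profile: CountProfile) -> ReactivityProfile:
    """Mutation rate = mutations / reads covering the position (MaP)."""
    return _rate(profile, "mutation")


def stop_rate(profile: CountProfile) -> ReactivityProfile:
    """Stop rate = recorded RT stops / reads informative at the position."""
    return _rate(profile, "stop")


def background_adjust(
    plus: ReactivityProfile,
    minus: ReactivityProfile,
    clamp: bool = False,
) -> ReactivityProfile:
    """Background-adjusted reactivity: rate(probe+) − rate(probe−).

    A position is valid only where both channels are valid.  With
    ``clamp`` negative differences are set to 0; the default keeps them,
    preserving the rank order that ROC analysis uses.
    """
    if plus.rna_id != minus.rna_id:
        raise ProfilePairingError(
            f"rna_id mismatch: {plus.rna_id!r} vs {minus.rna_id!r}"
        )
    if plus.mode != minus.mode:
        raise ProfilePairingError(
            f"mode mismatch: {plus.mode!r} vs {minus.mode!r}"
        )
    if len(plus) != len(minus):
        raise ProfilePairingError(
            f"length mismatch: {len(plus)} vs {len(minus)}"
        )
    valid = plus.valid & minus.valid
    diff = plus.reactivity - minus.reactivity
    if clamp:
        diff = np.maximum(diff, 0.0)
    return ReactivityProfile(
        rna_id=plus.rna_id,
        bases=plus.bases,
        reactivity=np.where(valid, diff, np.nan),
        valid=valid,
        mode=plus.mode,
        probe=plus.probe,
        background="subtracted",
    )


def apply_coverage_filter(
    profile: ReactivityProfile,
    counts: CountProfile,
    min_depth: int = 500,
) -> ReactivityProfile:
    """Invalidate positions whose coverage is not strictly over min_depth.

    "Over 500" is a strict inequality: depth 500 is dropped, 501 kept.
    """
    if len(profile) != len(counts):
        raise ProfilePairingError(
            f"length mismatch: profile {len(profile)} vs counts {len(counts)}"
        )
    valid = profile.valid & (counts.depth > min_depth)
    return replace(profile, valid=valid,
                   reactivity=np.where(valid, profile.reactivity, np.nan))


def apply_base_filter(profile: ReactivityProfile, probe: str) -> ReactivityProfile:
    """Restrict validity to the bases the probe chemistry reports on.

    DMS methylates unpaired A and C, so only A/C positions stay valid;
    SHAPE acylates the 2'-OH of every nucleotide, so all bases stay.
    """
    if probe not in ("DMS", "SHAPE"):
        raise ValidationError(f"unknown probe {probe!r}")
    if probe == "DMS":
        base_ok = np.array([b in DMS_REACTIVE_BASES for b in profile.bases])
        valid = profile.valid & base_ok
    else:
        valid = profile.valid.copy()
    return replace(profile, probe=probe, valid=valid,
                   reactivity=np.where(valid, profile.reactivity, np.nan))


def mrna_inclusion_rule(
    counts: CountProfile,
    min_positions: int = 50,
    min_depth: int = 500,
) -> bool:
    """Whether an mRNA has enough well-covered positions to be analysed.

    True iff at least ``min_positions`` positions have depth strictly
    over ``min_depth`` (same strict inequality as the coverage filter).
    """
    return int((counts.depth > min_depth).sum()) >= min_positions
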