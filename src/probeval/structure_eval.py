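"""Concordance between reactivity profiles and reference secondary structure.

The central convention, stated prominently because many toolkits use the
opposite one: the POSITIVE class is the UNPAIRED base (a dot in the
dot-bracket reference), and reactivity is the score.  A perfect probing
experiment ranks every dot above every bracket and scores AUC 1.0.

The ROC/AUC here is implemented from first principles (threshold sweep
with tie grouping, trapezoidal area), which makes the trapezoidal AUC
identical to the Mann–Whitney statistic

    AUC = [#(pos > neg) + 0.5 · #(pos = neg)] / (n_pos · n_neg),

i.e. ties across classes receive half credit.  Only valid positions
enter any statistic; invalid positions (low coverage, excluded bases,
missing data) never contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateDataError, ProfilePairingError, ValidationError
from .io_formats import RnaRecord, parse_dotbracket_pairs, read_dotbracket
from .reactivity_core import ReactivityProfile


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructure:
    """Sequence plus pairing table derived from dot-bracket notation.

    Any non-dot symbol (including pseudoknot layers ``[]``, ``{}``,
    ``<>``) counts as paired.  ``partner`` is 0-based with −1 for
    unpaired positions and is an involution where defined.
    """

    rna_id: str
    sequence: str
    structure: str
    partner: np.ndarray
    paired: np.ndarray

    @classmethod
    def from_dotbracket(cls, rna: RnaRecord, structure: str) -> "SecondaryStructure":
        if len(structure) != len(rna):
            raise ValidationError(
                f"structure length {len(structure)} != sequence length {len(rna)}"
            )
        partner = parse_dotbracket_pairs(structure)
        return cls(
            rna_id=rna.id,
            sequence=rna.sequence,
            structure=structure,
            partner=partner,
            paired=partner >= 0,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SecondaryStructure":
        rna, structure = read_dotbracket(path)
        return cls.from_dotbracket(rna, structure)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def unpaired_fraction(self) -> float:
        return float((~self.paired).mean())


@dataclass
class RocResult:
    """ROC curve and area, positive class = unpaired."""

    thresholds: np.ndarray   # descending distinct scores
    fpr: np.ndarray          # includes leading 0 and trailing 1
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class RateHistogram:
    """Half-open-binned histogram of reactivity values.

    ``counts[k]`` covers [edges[k], edges[k+1]); values ≥ range_max pool
    into ``overflow``; negative values (possible after unclamped
    background subtraction) pool into ``underflow``.
    """

    edges: np.ndarray
    counts: np.ndarray
    overflow: int
    underflow: int


@dataclass
class ClassStats:
    n: int
    mean: float
    median: float
    q25: float
    q75: float


@dataclass
class ClassConditionalSummary:
    unpaired: ClassStats
    paired: ClassStats
    overlap: float  # histogram overlap coefficient in [0, 1]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _aligned_scores_labels(
    reactivity: ReactivityProfile, structure: SecondaryStructure
) -> tuple[np.ndarray, np.ndarray]:
    if len(reactivity) != len(structure):
        raise ProfilePairingError(
            f"profile length {len(reactivity)} != structure length "
            f"{len(structure)}"
        )
    mask = reactivity.valid
    scores = reactivity.reactivity[mask]
    labels = ~structure.paired[mask]  # True = unpaired = positive
    return scores, labels


def _top_k_indices(scores: np.ndarray, positions: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest scores; ties broken by ascending position."""
    order = np.lexsort((positions, -scores))
    return order[:k]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def roc_auc(
    reactivity: ReactivityProfile, structure: SecondaryStructure
) -> RocResult:
    """ROC curve and trapezoidal AUC of unpaired-base discrimination.

    Scores are reactivities at valid positions; the positive label is
    "unpaired in the reference".  Equal scores across classes receive
    half credit (trapezoid over tie-grouped thresholds), so the AUC is
    exactly the Mann–Whitney U statistic normalised by n_pos · n_neg.
    """
    scores, labels = _aligned_scores_labels(reactivity, structure)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError(
            f"ROC undefined: n_unpaired={n_pos}, n_paired={n_neg}"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group tied scores: curve points only at the end of each tie block
    distinct = np.nonzero(np.diff(s))[0]
    block_ends = np.append(distinct, len(s) - 1)
    tp = np.cumsum(y)[block_ends]
    fp = np.cumsum(~y)[block_ends]
    tpr = np.concatenate(([0.0], tp / n_pos))
    fpr = np.concatenate(([0.0], fp / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        thresholds=s[block_ends],
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def top_fraction_unpaired(
    reactivity: ReactivityProfile,
    structure: SecondaryStructure,
    x_percent: float,
) -> float:
    """Fraction of the top-x% most reactive valid bases that are unpaired.

    Selects the ceil(x/100 · n_valid) highest-reactivity valid positions
    (score ties broken by ascending position index, so the selection is
    deterministic) and returns the fraction that are dots in the
    reference.  At x = 100 this is exactly the unpaired fraction of the
    valid set.
    """
    if not (0.0 < x_percent <= 100.0):
        raise ValidationError(f"x_percent must be in (0, 100], got {x_percent}")
    scores, labels = _aligned_scores_labels(reactivity, structure)
    n = len(scores)
    if n == 0:
        raise DegenerateDataError("no valid positions")
    k = math.ceil(x_percent / 100.0 * n)
    positions = np.nonzero(reactivity.valid)[0]
    top = _top_k_indices(scores, positions, k)
    return float(labels[top].mean())


def top_fraction_unpaired_pooled(
    profiles: list[ReactivityProfile],
    structures: list[SecondaryStructure],
    x_percent: float,
) -> float:
    """Pooled-ranking variant across molecules (non-default mode).

    Valid positions of all molecules are ranked in one pool; ties are
    broken by (molecule order, position).  The per-molecule function is
    the default because reactivity scales are not comparable across
    molecules without normalization.
    """
    if not (0.0 < x_percent <= 100.0):
        raise ValidationError(f"x_percent must be in (0, 100], got {x_percent}")
    if len(profiles) != len(structures):
        raise ProfilePairingError("profiles/structures count mismatch")
    all_scores, all_labels, all_keys = [], [], []
    for m, (prof, struct) in enumerate(zip(profiles, structures)):
        scores, labels = _aligned_scores_labels(prof, struct)
        positions = np.nonzero(prof.valid)[0]
        all_scores.append(scores)
        all_labels.append(labels)
        all_keys.append(m * 10**9 + positions)
    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    keys = np.concatenate(all_keys)
    if len(scores) == 0:
        raise DegenerateDataError("no valid positions")
    k = math.ceil(x_percent / 100.0 * len(scores))
    top = _top_k_indices(scores, keys, k)
    return float(labels[top].mean())


def rate_histogram(
    reactivity: ReactivityProfile,
    bin_width: float,
    range_max: float = 1.0,
) -> RateHistogram:
    """Histogram of valid reactivities with half-open bins [k·w, (k+1)·w).

    A value exactly on a bin edge belongs to the bin starting there.
    Both the full [0, 1] view and a zoomed view (e.g. range_max = 0.1)
    are obtained by calling with different range_max.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if range_max <= 0:
        raise ValidationError("range_max must be positive")
    values = reactivity.reactivity[reactivity.valid]
    n_bins = int(math.ceil(range_max / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = range_max
    underflow = int((values < 0).sum())
    overflow = int((values >= range_max).sum())
    in_range = values[(values >= 0) & (values < range_max)]
    idx = np.minimum((in_range / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return RateHistogram(edges=edges, counts=counts, overflow=overflow,
                         underflow=underflow)


def fraction_at_least(reactivity: ReactivityProfile, threshold: float) -> float:
    """Fraction of valid positions with reactivity ≥ threshold."""
    values = reactivity.reactivity[reactivity.valid]
    if len(values) == 0:
        raise DegenerateDataError("no valid positions")
    return float((values >= threshold).mean())


def class_conditional_summary(
    reactivity: ReactivityProfile,
    structure: SecondaryStructure,
    bin_width: float = 0.01,
) -> ClassConditionalSummary:
    """Per-class location statistics and a histogram overlap coefficient.

    The overlap coefficient is Σ_bins min(mass_unpaired, mass_paired)
    over a shared half-open bin grid, where each class's bin masses sum
    to 1; identical distributions give 1.0, disjoint supports give 0.0.
    """
    scores, labels = _aligned_scores_labels(reactivity, structure)
    up = scores[labels]
    pp = scores[~labels]
    if len(up) == 0 or len(pp) == 0:
        raise DegenerateDataError(
            f"need both classes: n_unpaired={len(up)}, n_paired={len(pp)}"
        )

    def stats(v: np.ndarray) -> ClassStats:
        return ClassStats(
            n=len(v),
            mean=float(np.mean(v)),
            median=float(np.median(v)),
            q25=float(np.quantile(v, 0.25)),
            q75=float(np.quantile(v, 0.75)),
        )

    lo = math.floor(min(up.min(), pp.min()) / bin_width)
    hi = math.floor(max(up.max(), pp.max()) / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    mass_u = np.histogram(up, bins=edges)[0] / len(up)
    mass_p = np.histogram(pp, bins=edges)[0] / len(pp)
    # np.histogram closes the last bin; consistent for both classes, and
    # the grid extends one full bin past the max so the effect is nil.
    overlap = float(np.minimum(mass_u, mass_p).sum())
    return ClassConditionalSummary(
        unpaired=stats(up), paired=stats(pp), overlap=overlap
    )
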