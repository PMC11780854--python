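"""Base-pair probability marginals, a toy exhaustive ensemble, and
discordance flagging.

The pipeline consumes externally computed base-pair probability matrices
(e.g. from a partition-function folder, imported as plain ``i j p`` TSV)
and reduces them to the marginal probability that base i pairs with
anything: m[i] = Σ_j p[i][j].

For testing the marginalization and the flagging rule without any
external folder, a small exhaustive ensemble is provided: every nested
(pseudoknot-free) structure over a short sequence with hairpin loops of
at least ``min_loop`` unpaired bases and canonical + wobble pairs, each
structure weighted w^(#pairs).  This is the minimal model sufficient to
exercise the marginal invariants exactly; it does not emulate any
thermodynamic parameter set.

Discordance flagging reproduces the cross-check between ensemble
confidence and probing signal: a position is flagged when the ensemble
says it pairs almost certainly (marginal ≥ 0.995 by default) while the
experiment puts it in the top 10% of reactivity — a contradiction worth
inspecting against a 3D structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ValidationError
from .io_formats import RnaRecord
from .reactivity_core import ReactivityProfile
from .structure_eval import _top_k_indices

#: Canonical Watson–Crick plus wobble pairs.
DEFAULT_ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Length guard for exhaustive enumeration.
MAX_ENUM_LENGTH = 30


@dataclass
class PairProbabilityMatrix:
    """Symmetric matrix of pairing probabilities over one RNA.

    ``p[i, j]`` (0-based) is the probability that bases i+1 and j+1 pair.
    Zero diagonal; each row sum (the pairing marginal) must not exceed 1
    beyond a small import tolerance.
    """

    rna_id: str
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValidationError("probability matrix must be square")
        if not np.allclose(self.p, self.p.T, atol=1e-12):
            raise ValidationError("probability matrix must be symmetric")
        if np.any(np.diag(self.p) != 0):
            raise ValidationError("probability matrix must have zero diagonal")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValidationError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.p.shape[0]


def marginal_pairing_probability(
    matrix: PairProbabilityMatrix, tol: float = 1e-6
) -> np.ndarray:
    """m[i] = Σ_{j≠i} p[i][j], the probability that base i+1 pairs at all.

    Marginals may exceed 1 by at most ``tol`` (quadrature/rounding noise
    in imported matrices) and are clipped back; anything larger is an
    inconsistent matrix.
    """
    m = matrix.p.sum(axis=1)
    over = np.nonzero(m > 1.0 + tol)[0]
    if over.size:
        raise ValidationError(
            f"inconsistent matrix: marginal {m[over[0]]:.6g} > 1 at "
            f"position {over[0] + 1}"
        )
    return np.clip(m, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Exhaustive toy ensemble
# ---------------------------------------------------------------------------

def _as_sequence(seq: RnaRecord | str) -> str:
    return seq.sequence if isinstance(seq, RnaRecord) else seq


def enumerate_structures(
    seq: RnaRecord | str,
    min_loop: int = 3,
    allowed_pairs: frozenset = DEFAULT_ALLOWED_PAIRS,
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield every nested structure over ``seq`` exactly once.

    Structures are tuples of 1-based (i, j) pairs, i < j, sorted by i;
    the empty tuple is the unpaired structure.  Hairpin loops must
    enclose at least ``min_loop`` unpaired bases (j − i − 1 ≥ min_loop)
    and only ``allowed_pairs`` may form.  Uniqueness follows from the
    standard decomposition on whether the leftmost base of a region is
    paired and, if so, with which partner.
    """
    s = _as_sequence(seq)
    if len(s) > MAX_ENUM_LENGTH:
        raise ValidationError(
            f"sequence length {len(s)} exceeds enumeration guard "
            f"{MAX_ENUM_LENGTH}"
        )

    def gen(i: int, j: int):
        # all structures over the 0-based closed region [i, j]
        if i > j:
            yield ()
            return
        # case 1: position i unpaired
        yield from gen(i + 1, j)
        # case 2: i pairs with k
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in allowed_pairs:
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        yield ((i + 1, k + 1),) + inner + outer

    for pairs in gen(0, len(s) - 1):
        yield tuple(sorted(pairs))


def n_structures(
    seq: RnaRecord | str,
    min_loop: int = 3,
    allowed_pairs: frozenset = DEFAULT_ALLOWED_PAIRS,
) -> int:
    """Number of nested structures (by exhausting the enumerator)."""
    return sum(1 for _ in enumerate_structures(seq, min_loop, allowed_pairs))


def ensemble_bpp(
    seq: RnaRecord | str,
    pair_weight: float = 1.0,
    min_loop: int = 3,
    allowed_pairs: frozenset = DEFAULT_ALLOWED_PAIRS,
) -> PairProbabilityMatrix:
    """Pair probabilities of the toy ensemble with weight w^(#pairs).

    p[i][j] = Σ_{structures containing (i,j)} w^pairs / Σ_all w^pairs.
    ``pair_weight`` = 1 weights all structures equally; larger values
    concentrate mass on maximally paired structures.
    """
    if pair_weight <= 0:
        raise ValidationError("pair_weight must be positive")
    s = _as_sequence(seq)
    L = len(s)
    acc = np.zeros((L, L), dtype=float)
    z = 0.0
    for pairs in enumerate_structures(seq, min_loop, allowed_pairs):
        w = pair_weight ** len(pairs)
        z += w
        for (i, j) in pairs:
            acc[i - 1, j - 1] += w
            acc[j - 1, i - 1] += w
    rna_id = seq.id if isinstance(seq, RnaRecord) else "toy"
    return PairProbabilityMatrix(rna_id=rna_id, p=acc / z)


# ---------------------------------------------------------------------------
# Discordance flagging
# ---------------------------------------------------------------------------

def flag_discordant(
    marginals: np.ndarray,
    reactivity: ReactivityProfile,
    bpp_min: float = 0.995,
    top_percent: float = 10.0,
) -> list[int]:
    """1-based positions with marginal ≥ bpp_min AND top-x% reactivity.

    The top-x% set is the ceil(x/100 · n_valid) highest-reactivity valid
    positions (ties broken by ascending position), matching the top-x%
    concordance statistic.  The bpp threshold is inclusive (≥).
    """
    marginals = np.asarray(marginals, dtype=float)
    if len(marginals) != len(reactivity):
        raise ValidationError(
            f"marginals length {len(marginals)} != profile length "
            f"{len(reactivity)}"
        )
    if not (0.0 < top_percent <= 100.0):
        raise ValidationError("top_percent must be in (0, 100]")
    valid_idx = np.nonzero(reactivity.valid)[0]
    if valid_idx.size == 0:
        return []
    scores = reactivity.reactivity[valid_idx]
    k = math.ceil(top_percent / 100.0 * valid_idx.size)
    top = valid_idx[_top_k_indices(scores, valid_idx, k)]
    flagged = [int(i) + 1 for i in top if marginals[i] >= bpp_min]
    return sorted(flagged)
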