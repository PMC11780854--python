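"""Generative simulator of chemical-probing experiments.

Given a reference secondary structure with known pairing states, the
simulator produces per-position count profiles for a probe-treated
(plus) and a probe-free background (minus) channel, in either readout:

RT-stop (SEQ) mode
    Each molecule is modified independently at position i with
    probability m_i (higher for unpaired bases).  Reverse transcription
    initiates at the 3' end and walks 5'-ward; it terminates at the
    3'-most modified position, so of several modifications on one
    molecule only that one is detectable.  This censoring is exactly the
    5' positional bias of stop-based detection: signal 5' of a stop is
    invisible.  Natural (modification-independent) stops occur with a
    per-position probability during the walk.  The stop is recorded at
    (modified position + stop_offset) with stop_offset ∈ {0, +1},
    because real protocols differ on whether the count is assigned to
    the modified base or one nucleotide 3' of it.  depth[i] is the
    number of molecules whose cDNA covers or terminates at i.

Mutational (MaP) mode
    Reads are full length.  Every modification independently yields a
    recorded mutation with probability mutation_detect_prob; sequencing
    errors add mutations at seq_error_rate.  depth[i] = n_molecules.

The minus channel runs the identical machinery with all m_i = 0, so it
contains only natural stops / sequencing errors — background noise
statistically independent of the plus channel.

Single-hit kinetics (about one modification per ~200 nucleotides per
molecule) is implemented as a rescaling of the per-position
probabilities to a target expected modification count per molecule, not
as hard truncation: in SEQ mode the censoring already guarantees at most
one observed stop per molecule regardless.

All randomness flows from ``rng_seed`` through fixed-size molecule
chunks, so outputs are identical across runs and platforms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import CountProfile
from .structure_eval import SecondaryStructure

_CHUNK = 20_000  # molecules per vectorised chunk; fixed for determinism

#: Modification-probability levels of the "overlap" benchmark scenario,
#: cycled deterministically over each pairing class.  The classes share
#:  low levels (partial overlap) while only unpaired bases reach the
#: high ones; roughly 90% of positions end up with rates near zero and
#: well under 10% of bases exceed rate 0.1.
OVERLAP_LEVELS_UNPAIRED = (0.0, 0.02, 0.05, 0.10)
OVERLAP_LEVELS_PAIRED = (0.0, 0.0, 0.01, 0.02)

SCENARIO_NAMES = ("separable", "overlap", "background-heavy")


@dataclass
class ProbingSimConfig:
    """Parameters of one simulated probing experiment.

    ``p_mod_unpaired`` / ``p_mod_paired`` are per-base per-molecule
    modification probabilities by pairing class; ``p_mod_by_position``
    (optional, length L) overrides them with explicit per-position
    probabilities, e.g. to model within-class heterogeneity.
    ``target_mods_per_molecule`` rescales the probabilities so their sum
    matches a single-hit budget.  ``mutation_detect_prob`` and
    ``seq_error_rate`` apply in MaP mode; ``natural_stop_rate`` and
    ``stop_offset`` in SEQ mode.
    """

    structure: SecondaryStructure
    mode: str                                # "stop" | "mutation"
    p_mod_unpaired: float
    p_mod_paired: float
    n_molecules: int
    target_mods_per_molecule: float | None = None
    mutation_detect_prob: float = 1.0
    natural_stop_rate: float = 0.0
    seq_error_rate: float = 0.0
    stop_offset: int = 0
    rng_seed: int = 0
    p_mod_by_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("stop", "mutation"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        if self.stop_offset not in (0, 1):
            raise ValidationError("stop_offset must be 0 or +1")
        for name in ("p_mod_unpaired", "p_mod_paired", "mutation_detect_prob",
                     "natural_stop_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.p_mod_by_position is not None:
            arr = np.asarray(self.p_mod_by_position, dtype=float)
            if arr.shape != (len(self.structure),):
                raise ValidationError(
                    "p_mod_by_position length does not match structure"
                )
            if (arr < 0).any() or (arr > 1).any():
                raise ValidationError("p_mod_by_position must lie in [0, 1]")
            self.p_mod_by_position = arr
        if self.p_mod_unpaired < self.p_mod_paired:
            warnings.warn(
                "p_mod_unpaired < p_mod_paired: probes normally react "
                "preferentially with unpaired bases",
                stacklevel=2,
            )

    def modification_probabilities(self) -> np.ndarray:
        """Per-position modification probability vector m (length L)."""
        if self.p_mod_by_position is not None:
            m = self.p_mod_by_position.copy()
        else:
            m = np.where(self.structure.paired, self.p_mod_paired,
                         self.p_mod_unpaired).astype(float)
        if self.target_mods_per_molecule is not None:
            total = m.sum()
            if total > 0:
                m = np.clip(m * (self.target_mods_per_molecule / total), 0.0, 1.0)
        return m


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _simulate_channel(
    config: ProbingSimConfig, m: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (depth, events, modification_counts) for one channel."""
    L = len(m)
    n = config.n_molecules
    depth = np.zeros(L, dtype=np.int64)
    events = np.zeros(L, dtype=np.int64)
    truth = np.zeros(L, dtype=np.int64)
    done = 0
    while done < n:
        c = min(_CHUNK, n - done)
        mod = rng.random((c, L)) < m
        truth += mod.sum(axis=0)
        if config.mode == "mutation":
            detected = mod & (rng.random((c, L)) < config.mutation_detect_prob)
            errs = rng.random((c, L)) < config.seq_error_rate
            events += (detected | errs).sum(axis=0)
            depth += c
        else:
            nat = rng.random((c, L)) < config.natural_stop_rate
            stop = mod | nat
            has_stop = stop.any(axis=1)
            # 3'-most stop position per molecule (0-based)
            j = L - 1 - np.argmax(stop[:, ::-1], axis=1)
            rows = np.nonzero(has_stop)[0]
            j = j[rows]
            is_mod_stop = mod[rows, j]
            recorded = j + np.where(is_mod_stop, config.stop_offset, 0)
            # a +1 offset on a stop at the 3'-terminal base falls off the
            # molecule: no event is observable and the read looks full
            # length
            on_mol = recorded < L
            rec = recorded[on_mol]
            # the cDNA spans [stop, L]: position p is informative iff the
            # recorded stop is <= p (the walk reached p); molecules
            # without an on-molecule stop cover everything
            cnt = np.bincount(rec, minlength=L)
            events += cnt
            n_full = c - len(rec)
            depth += n_full + np.cumsum(cnt)
        done += c
    return depth, events, truth


def simulate_experiment(
    config: ProbingSimConfig,
) -> tuple[CountProfile, CountProfile, np.ndarray]:
    """Simulate plus and minus channels of one probing experiment.

    Returns (plus profile, minus profile, truth), where ``truth`` is the
    per-position count of probe modifications actually placed in the
    plus channel (detected or not).  Deterministic under a fixed
    ``rng_seed``; the two channels use independent seeded streams.
    """
    m = config.modification_probabilities()
    zero = np.zeros_like(m)
    rng_plus = np.random.default_rng([config.rng_seed, 0])
    rng_minus = np.random.default_rng([config.rng_seed, 1])
    depth_p, events_p, truth = _simulate_channel(config, m, rng_plus)
    depth_m, events_m, _ = _simulate_channel(config, zero, rng_minus)
    bases = config.structure.sequence
    plus = CountProfile(
        rna_id=config.structure.rna_id, channel="plus", mode=config.mode,
        bases=bases, depth=depth_p, events=events_p,
    )
    minus = CountProfile(
        rna_id=config.structure.rna_id, channel="minus", mode=config.mode,
        bases=bases, depth=depth_m, events=events_m,
    )
    return plus, minus, truth


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------

def expected_rate_profile(config: ProbingSimConfig) -> np.ndarray:
    """Expected per-position event rate (large-sample limit).

    MaP: rate_i = d_i + (1 − d_i)·e with d_i = m_i · detect and e the
    sequencing-error rate (a mutation is recorded unless both detection
    and error fail).

    SEQ: from the censoring model.  With per-position stop probability
    s_j = m_j + (1 − m_j)·q (modification first, else natural stop at
    rate q) and survival S_j = Π_{k>j} (1 − s_k) of the 3'→5' walk:

        P(mod stop at j)     = m_j · S_j
        P(natural stop at j) = (1 − m_j) · q · S_j

    events recorded at p combine the mod stop at p − offset with the
    natural stop at p; the expected depth at p sums read-through mass
    and all stops recorded at positions ≤ p.  The returned value is the
    ratio of these expectations, which empirical rates approach as
    n_molecules → ∞.
    """
    m = config.modification_probabilities()
    L = len(m)
    if config.mode == "mutation":
        d = m * config.mutation_detect_prob
        return d + (1.0 - d) * config.seq_error_rate

    q = config.natural_stop_rate
    s = m + (1.0 - m) * q
    # survival[j] = P(walk from the 3' end reaches position j)
    surv = np.ones(L)
    surv[:-1] = np.cumprod((1.0 - s)[::-1])[::-1][1:]
    p_mod = m * surv
    p_nat = (1.0 - m) * q * surv
    p_readthrough = float(np.prod(1.0 - s))

    offset = config.stop_offset
    expected_events = np.zeros(L)
    recorded = np.zeros(L)          # stops recorded at each position
    off_molecule = 0.0              # offset pushed a stop past the 3' end
    for j in range(L):
        rec = j + offset
        if rec < L:
            recorded[rec] += p_mod[j]
        else:
            off_molecule += p_mod[j]
        recorded[j] += p_nat[j]
    expected_events = recorded
    # the cDNA spans [stop, L], so depth[p] counts read-through mass,
    # off-molecule stops (full-length-looking reads) and stops recorded
    # at positions <= p
    expected_depth = p_readthrough + off_molecule + np.cumsum(recorded)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(expected_depth > 0, expected_events / expected_depth, 0.0)
    return rate


# ---------------------------------------------------------------------------
# Benchmark scenarios
# ---------------------------------------------------------------------------

def _benchmark_structure(rna_id: str) -> SecondaryStructure:
    """Deterministic 200-nt structure with 45% unpaired bases.

    Eleven 18-nt hairpin units (5-bp GC stem, 5-nt A loop, 3-nt linker)
    plus a 2-nt tail: 90 unpaired / 110 paired positions.
    """
    unit_db = "(((((.....)))))..."
    unit_seq = "GCGCG" + "AAAAA" + "CGCGC" + "AAA"
    db = unit_db * 11 + ".."
    seq = unit_seq * 11 + "AA"
    from .io_formats import RnaRecord

    return SecondaryStructure.from_dotbracket(
        RnaRecord(id=rna_id, sequence=seq), db
    )


def _cycle_levels(paired: np.ndarray, levels_unpaired, levels_paired) -> np.ndarray:
    m = np.zeros(len(paired))
    for cls, levels in ((False, levels_unpaired), (True, levels_paired)):
        idx = np.nonzero(paired == cls)[0]
        for rank, i in enumerate(idx):
            m[i] = levels[rank % len(levels)]
    return m


def make_benchmark_scenario(
    name: str, seed: int, n_molecules: int | None = None
) -> tuple[ProbingSimConfig, SecondaryStructure]:
    """Named scenarios emulating the qualitative shape of real probing data.

    "separable"        MaP, paired bases completely unreactive: empirical
                       rate distributions are disjoint, so downstream
                       ROC AUC and top-10% unpaired fraction are 1.
    "overlap"          MaP with stratified per-position modification
                       levels (see OVERLAP_LEVELS_*): class rate
                       distributions partially overlap, ~90% of bases
                       sit near zero and well under 10% exceed rate 0.1.
    "background-heavy" SEQ with a natural stop rate well above the
                       modification signal, for plus-only versus
                       plus−background comparisons: the background is
                       positionally uniform, so subtracting its noisy
                       estimate only injects variance.
    """
    structure = _benchmark_structure(f"bench-{name}")
    if name == "separable":
        config = ProbingSimConfig(
            structure=structure, mode="mutation",
            p_mod_unpaired=0.08, p_mod_paired=0.0,
            n_molecules=n_molecules or 100_000,
            mutation_detect_prob=1.0, seq_error_rate=0.0,
            rng_seed=seed,
        )
    elif name == "overlap":
        m = _cycle_levels(structure.paired,
                          OVERLAP_LEVELS_UNPAIRED, OVERLAP_LEVELS_PAIRED)
        config = ProbingSimConfig(
            structure=structure, mode="mutation",
            p_mod_unpaired=float(np.mean(OVERLAP_LEVELS_UNPAIRED)),
            p_mod_paired=float(np.mean(OVERLAP_LEVELS_PAIRED)),
            n_molecules=n_molecules or 100_000,
            mutation_detect_prob=1.0, seq_error_rate=0.0,
            rng_seed=seed, p_mod_by_position=m,
        )
    elif name == "background-heavy":
        config = ProbingSimConfig(
            structure=structure, mode="stop",
            p_mod_unpaired=0.008, p_mod_paired=0.001,
            natural_stop_rate=0.02,
            n_molecules=n_molecules or 20_000,
            rng_seed=seed,
        )
    else:
        raise ValidationError(
            f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
        )
    return config, structure


def overlap_level_proportions() -> tuple[dict[float, float], dict[float, float]]:
    """Exact level proportions of the "overlap" scenario's two classes.

    Returns ({level: fraction} for unpaired, same for paired), computed
    from the deterministic level assignment on the benchmark structure.
    Used by distribution-level AUC oracles.
    """
    structure = _benchmark_structure("bench-overlap")
    m = _cycle_levels(structure.paired,
                      OVERLAP_LEVELS_UNPAIRED, OVERLAP_LEVELS_PAIRED)
    out = []
    for cls in (False, True):
        vals = m[structure.paired == cls]
        levels, counts = np.unique(vals, return_counts=True)
        out.append({float(l): float(c) / len(vals)
                    for l, c in zip(levels, counts)})
    return out[0], out[1]
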