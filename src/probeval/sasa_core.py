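"""Shrake–Rupley solvent-accessible surface area and reactivity–SASA
correlation.

The Shrake–Rupley method distributes test points on the expanded sphere
(van der Waals radius + probe radius) of every atom and counts the
fraction not buried inside any neighbouring atom's expanded sphere:

    area = 4π (r + r_probe)² · exposed / total.

A probe radius of 3 Å (roughly a probing reagent rather than water) is
the default throughout.  Test points come from a deterministic
golden-spiral lattice, so results are bit-stable across runs — no RNG is
involved anywhere in this module.

Burial is a strict "inside" test: a point exactly on another atom's
expanded sphere (e.g. from two coincident atoms of equal radius) is NOT
buried.  A small epsilon (1e-9 Å² on squared distances) keeps this
convention stable against floating-point rounding.

Per-residue relative accessibility is the residue's area in the full
structure divided by the same residue's area computed in isolation (all
other residues deleted).  This normalization is stated in the output
metadata so users can substitute fixed per-nucleotide maxima if they
prefer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .errors import DegenerateDataError, ValidationError
from .io_formats import AtomRecord
from .reactivity_core import ReactivityProfile
from .structure_eval import SecondaryStructure, _top_k_indices

#: Van der Waals radii in Å.  "other" elements require an explicit
#: override via the ``radii`` parameter.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}

#: Strict-inside tolerance on squared distances (Å²).
_INSIDE_EPS = 1e-9

CORRELATION_SUBSETS = ("all", "top10", "bottom90", "paired", "unpaired")


@dataclass
class ResidueAccessibility:
    """Absolute and relative solvent accessibility of one nucleotide."""

    chain: str
    residue_index: int
    residue_name: str
    absolute_sasa: float    # Å²
    relative_sasa: float    # absolute / isolated-residue reference


@dataclass
class CorrelationResult:
    subset: str
    r: float
    n: int


def golden_spiral_points(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (deterministic)."""
    if n < 1:
        raise ValidationError("need at least one sphere point")
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _molecular_frame(centers: np.ndarray) -> np.ndarray:
    """Deterministic molecule-fixed orthonormal frame (3×3, columns = axes).

    Principal axes of the centered coordinates, ordered by descending
    spread, with signs fixed by the third moment along each axis (first
    non-negligible odd moment, falling back to the largest-magnitude
    component).  Because the frame transforms covariantly with rigid
    motions, anchoring the test-point lattice to it makes SASA invariant
    under rotation/translation to numerical precision.  For exactly
    symmetric configurations with degenerate principal spreads the frame
    is arbitrary but still deterministic.
    """
    if len(centers) < 2:
        return np.eye(3)
    x = centers - centers.mean(axis=0)
    _, vecs = np.linalg.eigh(x.T @ x)
    vecs = vecs[:, ::-1]  # descending spread
    for k in range(3):
        proj = x @ vecs[:, k]
        skew = (proj**3).sum()
        if abs(skew) > 1e-9:
            sign = math.copysign(1.0, skew)
        else:
            sign = math.copysign(1.0, vecs[np.argmax(np.abs(vecs[:, k])), k])
        vecs[:, k] *= sign
    return vecs


def _atom_radii(atoms: list[AtomRecord], radii: dict[str, float] | None) -> np.ndarray:
    table = dict(DEFAULT_RADII)
    if radii:
        table.update(radii)
    out = np.empty(len(atoms))
    for k, atom in enumerate(atoms):
        if atom.element not in table:
            raise ValidationError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.atom_name!r}, residue {atom.residue_index}); "
                "pass an override via radii={...}"
            )
        out[k] = table[atom.element]
    return out


def shrake_rupley(
    atoms: list[AtomRecord],
    probe_radius: float = 3.0,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å²."""
    if not atoms:
        raise ValidationError("need at least one atom")
    if probe_radius < 0:
        raise ValidationError("probe_radius must be non-negative")
    centers = np.array([a.coord for a in atoms])
    r = _atom_radii(atoms, radii)
    expanded = r + probe_radius
    # lattice oriented in the molecule-fixed frame: rigid-motion invariant
    unit = golden_spiral_points(n_sphere_points) @ _molecular_frame(centers).T
    tree = cKDTree(centers)
    max_expanded = expanded.max()
    areas = np.empty(len(atoms))
    for k in range(len(atoms)):
        pts = centers[k] + expanded[k] * unit
        # neighbours whose expanded sphere could contain any test point
        cutoff = expanded[k] + max_expanded
        neigh = [m for m in tree.query_ball_point(centers[k], cutoff) if m != k]
        if neigh:
            d2 = ((pts[:, None, :] - centers[neigh][None, :, :]) ** 2).sum(-1)
            buried = (d2 < expanded[neigh][None, :] ** 2 - _INSIDE_EPS).any(1)
            exposed = int((~buried).sum())
        else:
            exposed = n_sphere_points
        areas[k] = 4.0 * math.pi * expanded[k] ** 2 * exposed / n_sphere_points
    return areas


def residue_accessibility(
    atoms: list[AtomRecord],
    probe_radius: float = 3.0,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
) -> list[ResidueAccessibility]:
    """Per-residue absolute and relative SASA.

    Absolute values are sums of member-atom areas in the full structural
    context; the relative value divides by the same residue's area with
    every other residue deleted (0 when that reference is 0).
    """
    areas = shrake_rupley(atoms, probe_radius, n_sphere_points, radii)
    groups: dict[tuple[str, int], list[int]] = {}
    for k, atom in enumerate(atoms):
        groups.setdefault((atom.chain, atom.residue_index), []).append(k)
    out = []
    for (chain, resi), members in groups.items():
        absolute = float(areas[members].sum())
        isolated = shrake_rupley(
            [atoms[m] for m in members], probe_radius, n_sphere_points, radii
        )
        reference = float(isolated.sum())
        relative = absolute / reference if reference > 0 else 0.0
        out.append(
            ResidueAccessibility(
                chain=chain,
                residue_index=resi,
                residue_name=atoms[members[0]].residue_name,
                absolute_sasa=absolute,
                relative_sasa=relative,
            )
        )
    return out


def reactivity_accessibility_correlation(
    reactivity: ReactivityProfile,
    access: list[ResidueAccessibility],
    subset: str = "all",
    structure: SecondaryStructure | None = None,
    offset: int = 0,
) -> CorrelationResult:
    """Pearson correlation between reactivity and relative SASA.

    Residue ``resi`` maps to profile position ``resi + offset`` (1-based);
    the offset absorbs numbering shifts between a 3D model and the
    reference sequence.  Positions without a resolved residue, or
    invalid in the profile, are excluded.  Subsets: "all", "top10" /
    "bottom90" (by reactivity rank, ceil(10% · n) split), "paired" /
    "unpaired" (reference structure required).
    """
    if subset not in CORRELATION_SUBSETS:
        raise ValidationError(
            f"unknown subset {subset!r}; choose from {CORRELATION_SUBSETS}"
        )
    if subset in ("paired", "unpaired") and structure is None:
        raise ValidationError(f"subset {subset!r} requires a structure")
    by_position: dict[int, float] = {}
    for acc in access:
        pos = acc.residue_index + offset  # 1-based profile position
        if 1 <= pos <= len(reactivity):
            by_position[pos] = acc.relative_sasa
    positions = np.array(
        sorted(p for p in by_position if reactivity.valid[p - 1]), dtype=int
    )
    if positions.size == 0:
        raise DegenerateDataError("no resolved, valid positions to correlate")
    scores = reactivity.reactivity[positions - 1]
    sasa = np.array([by_position[p] for p in positions])

    if subset in ("top10", "bottom90"):
        k = math.ceil(0.10 * len(positions))
        top = _top_k_indices(scores, positions, k)
        mask = np.zeros(len(positions), dtype=bool)
        mask[top] = True
        keep = mask if subset == "top10" else ~mask
    elif subset in ("paired", "unpaired"):
        paired = structure.paired[positions - 1]
        keep = paired if subset == "paired" else ~paired
    else:
        keep = np.ones(len(positions), dtype=bool)

    x = scores[keep]
    y = sasa[keep]
    if len(x) < 3:
        raise DegenerateDataError(
            f"subset {subset!r} has only {len(x)} points (need ≥ 3)"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError(
            f"zero variance in subset {subset!r}; correlation undefined"
        )
    r = float(pearsonr(x, y).statistic)
    return CorrelationResult(subset=subset, r=r, n=len(x))
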