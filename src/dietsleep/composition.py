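"""Aitchison-simplex primitives for macronutrient energy compositions.

A macronutrient composition is the ordered 5-part vector of energy shares
(protein, carbohydrate, saturated fat, monounsaturated fat, polyunsaturated
fat): strictly positive fractions of total macronutrient energy that sum to
one.  Protein and carbohydrate contribute 4 kcal/g, every fat class 9 kcal/g,
so the composition of a gram-intake vector is the closure of the per-class
kilocalories.

Because compositions carry only relative information, all statistics are done
in log-ratio coordinates.  This module provides:

* ``closure`` and ``energy_shares`` — projection onto the unit simplex;
* ``alr``/``alr_inv`` — additive log-ratio against the last part;
* ``make_basis``/``ilr``/``ilr_inv`` — isometric log-ratio coordinates under
  sequential-binary-partition (pivot) bases, including per-nutrient pivot
  bases whose first balance isolates a focal nutrient against the geometric
  mean of the rest;
* ``variation_matrix`` and ``compositional_mean`` — descriptive statistics in
  Aitchison geometry;
* ``reallocate`` and ``substitute_pairwise`` — the two reallocation
  geometries used to form isocaloric substitution estimands: proportional
  displacement of a fixed energy share between one nutrient and the rest,
  and a one-to-one swap between two nutrients.

All transforms accept a single composition ``(D,)`` or a stack ``(n, D)`` and
operate along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NUTRIENTS",
    "KCAL_PER_GRAM",
    "ReallocationSpec",
    "InfeasibleReallocationError",
    "nutrient_index",
    "closure",
    "energy_shares",
    "perturb",
    "alr",
    "alr_inv",
    "make_basis",
    "ilr",
    "ilr_inv",
    "variation_matrix",
    "compositional_mean",
    "reallocate",
    "substitute_pairwise",
]

#: Canonical part order used throughout the package.
NUTRIENTS = (
    "protein",
    "carbohydrate",
    "saturated_fat",
    "monounsaturated_fat",
    "polyunsaturated_fat",
)

#: Energy density of each part, kcal per gram (Atwater-style factors).
KCAL_PER_GRAM = np.array([4.0, 4.0, 9.0, 9.0, 9.0])

_ALIASES = {
    "protein": 0,
    "carb": 1,
    "carbohydrate": 1,
    "satfat": 2,
    "saturated_fat": 2,
    "monofat": 3,
    "monounsaturated_fat": 3,
    "polyfat": 4,
    "polyunsaturated_fat": 4,
}

# Safety margin subtracted from the smallest share when checking whether a
# displacement is feasible.
_FEASIBILITY_EPS = 1e-6


class InfeasibleReallocationError(ValueError):
    """Raised when a displacement exceeds the cap set by the smallest share."""


def nutrient_index(nutrient: int | str, d: int = 5) -> int:
    """Resolve a nutrient name or index to a 0-based part index."""
    if isinstance(nutrient, str):
        try:
            idx = _ALIASES[nutrient]
        except KeyError:
            raise ValueError(f"unknown nutrient {nutrient!r}; expected one of {NUTRIENTS}") from None
    else:
        idx = int(nutrient)
    if not 0 <= idx < d:
        raise ValueError(f"nutrient index {idx} out of range for a {d}-part composition")
    return idx


@dataclass(frozen=True)
class ReallocationSpec:
    """A displacement of a fixed energy share within the composition.

    Parameters
    ----------
    nutrient:
        Focal part, by name or index.
    delta:
        Magnitude of the displaced energy share (fraction of total energy,
        default 0.06 — i.e. six percentage points).
    mode:
        ``"add"``: the focal part gains ``delta``, the remaining parts shrink
        proportionally to their current shares.  ``"take"``: the focal part
        loses ``delta``, the remainder grows proportionally.  ``"pairwise"``:
        one-to-one swap from the focal part to ``to`` with every other part
        untouched.
    to:
        Receiving part, required for (and only valid in) pairwise mode.
    """

    nutrient: int | str
    delta: float = 0.06
    mode: str = "add"
    to: int | str | None = None

    def __post_init__(self):
        if self.mode not in ("add", "take", "pairwise"):
            raise ValueError(f"unknown reallocation mode {self.mode!r}")
        if (self.to is None) == (self.mode == "pairwise"):
            raise ValueError("'to' must be given exactly when mode='pairwise'")
        if self.delta < 0:
            raise ValueError("delta must be non-negative; use mode='take' to remove share")


def _validated(x, name="composition"):
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError(f"{name} needs at least 2 parts")
    if not np.all(x > 0):
        raise ValueError(f"{name} must be strictly positive")
    return x


def closure(v):
    """Rescale a positive vector (or stack of vectors) to unit sum."""
    v = _validated(v, "vector")
    return v / v.sum(axis=-1, keepdims=True)


def energy_shares(grams):
    """Energy-weighted closure of a 5-part gram-intake vector.

    Grams of protein and carbohydrate are weighted by 4 kcal/g, each fat
    class by 9 kcal/g, and the resulting kilocalories are closed to sum to 1.
    """
    grams = np.asarray(grams, dtype=float)
    if grams.shape[-1] != len(NUTRIENTS):
        raise ValueError(f"expected {len(NUTRIENTS)} gram entries, got {grams.shape[-1]}")
    if not np.all(grams > 0):
        raise ValueError("all gram intakes must be strictly positive")
    return closure(grams * KCAL_PER_GRAM)


def perturb(x, p):
    """Aitchison perturbation: closure of the componentwise product."""
    return closure(_validated(x) * _validated(p))


def alr(x):
    """Additive log-ratio transform with the last part as reference."""
    x = _validated(x)
    return np.log(x[..., :-1] / x[..., -1:])


def alr_inv(z):
    """Inverse additive log-ratio: append the reference and close."""
    z = np.asarray(z, dtype=float)
    ones = np.ones(z.shape[:-1] + (1,))
    return closure(np.concatenate([np.exp(z), ones], axis=-1))


def make_basis(d: int = 5, focal: int | str = "default") -> np.ndarray:
    """Orthonormal sequential-binary-partition (pivot) balance basis.

    Returns a ``(d-1, d)`` matrix ``B`` with orthonormal rows each summing to
    zero.  ``focal="default"`` gives the standard pivot basis in canonical
    part order.  Naming a focal nutrient reorders the partition so that the
    first balance isolates that part against the geometric mean of the rest:

        z1 = sqrt((d-1)/d) * ln( x_focal / g(others) )

    with positive z1 meaning the focal part sits above the geometric mean of
    the others.
    """
    if d < 2:
        raise ValueError("need at least 2 parts")
    if isinstance(focal, str) and focal == "default":
        order = list(range(d))
    else:
        f = nutrient_index(focal, d)
        order = [f] + [j for j in range(d) if j != f]
    basis = np.zeros((d - 1, d))
    for k in range(d - 1):
        r = d - k - 1  # parts remaining below the pivot
        a = np.sqrt(r / (r + 1))
        basis[k, order[k]] = a
        for j in order[k + 1 :]:
            basis[k, j] = -a / r
    return basis


def ilr(x, basis: np.ndarray | None = None):
    """Isometric log-ratio coordinates ``z = B ln(x)`` under ``basis``.

    Distances between compositions in ilr coordinates do not depend on the
    (orthonormal) basis chosen.
    """
    x = _validated(x)
    d = x.shape[-1]
    basis = make_basis(d) if basis is None else np.asarray(basis, dtype=float)
    if basis.shape != (d - 1, d):
        raise ValueError(f"basis shape {basis.shape} does not match {d}-part composition")
    return np.log(x) @ basis.T


def ilr_inv(z, basis: np.ndarray | None = None):
    """Inverse ilr: ``closure(exp(B^T z))``."""
    z = np.asarray(z, dtype=float)
    d = z.shape[-1] + 1
    basis = make_basis(d) if basis is None else np.asarray(basis, dtype=float)
    return closure(np.exp(z @ basis))


def variation_matrix(data) -> np.ndarray:
    """Pairwise log-ratio variances ``T[i, j] = var( ln(x_i / x_j) )``.

    Computed with the sample (n-1) variance across rows.  An entry close to
    zero means the two parts are nearly proportional across samples.
    """
    data = _validated(np.atleast_2d(data))
    if data.shape[0] < 2:
        raise ValueError("variation matrix needs at least 2 samples")
    logs = np.log(data)
    diff = logs[:, :, None] - logs[:, None, :]
    return diff.var(axis=0, ddof=1)


def compositional_mean(data):
    """Closed vector of componentwise geometric means.

    Equals ``ilr_inv`` of the arithmetic mean of ilr coordinates under any
    orthonormal basis; it is the centre of the sample in Aitchison geometry.
    """
    data = _validated(np.atleast_2d(data))
    if data.shape[0] < 1:
        raise ValueError("compositional mean of an empty table")
    return closure(np.exp(np.log(data).mean(axis=0)))


def _check_cap(delta, donor_share, what):
    # Only a share that is being drained can reach zero; proportional
    # scaling keeps every other part positive.
    cap = float(donor_share) - _FEASIBILITY_EPS
    if abs(delta) > cap:
        raise InfeasibleReallocationError(
            f"displacement {abs(delta):g} exceeds the feasible cap {cap:.4g} set by the "
            f"{what} share; larger values cannot be displaced without driving a part to zero"
        )


def reallocate(x, spec: ReallocationSpec):
    """Displace ``spec.delta`` of total energy between one part and the rest.

    Add mode moves share into the focal part and shrinks every other part
    proportionally to its current share; take mode is the mirror image, and
    the two are exact inverses of one another.  The result is closed and
    strictly positive, or an :class:`InfeasibleReallocationError` is raised
    when the displacement would drain a share to zero — in practice the
    binding cap is the smallest share of the composition, which is why
    displacements are limited to about 6 % of energy here.
    """
    x = closure(x)
    if x.ndim != 1:
        raise ValueError("reallocate expects a single composition")
    if spec.mode == "pairwise":
        return substitute_pairwise(x, spec.nutrient, spec.to, spec.delta)
    f = nutrient_index(spec.nutrient, x.shape[-1])
    delta = spec.delta if spec.mode == "add" else -spec.delta
    if delta == 0:
        return x.copy()
    xf = x[f]
    if spec.mode == "take":
        _check_cap(delta, xf, "focal")  # the focal part is drained
    else:
        _check_cap(delta, 1.0 - xf, "remaining")  # the rest shrinks to 1 - x_f - delta
    new_f = xf + delta
    scale = (1.0 - new_f) / (1.0 - xf)
    out = x * scale
    out[f] = new_f
    return closure(out)


def substitute_pairwise(x, frm: int | str, to: int | str, delta: float):
    """One-to-one isocaloric swap: ``frm`` loses ``delta``, ``to`` gains it.

    Every other part is returned bit-identical, so the unit sum is preserved
    exactly.  ``frm == to`` is the identity for any feasible ``delta``.
    """
    x = closure(x)
    if x.ndim != 1:
        raise ValueError("substitute_pairwise expects a single composition")
    i = nutrient_index(frm, x.shape[-1])
    j = nutrient_index(to, x.shape[-1])
    if delta == 0 or i == j:
        return x.copy()
    if delta < 0:
        raise ValueError("delta must be non-negative; swap 'frm' and 'to' instead")
    _check_cap(delta, x[i], "donor")
    out = x.copy()
    out[i] -= delta
    out[j] += delta
    return out
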