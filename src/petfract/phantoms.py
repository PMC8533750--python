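"""Synthetic 3D volumes with known fractal and multifractal structure.

Because clinical PET volumes cannot be redistributed, every measure in this
package is validated on phantoms whose scaling behaviour is known exactly:

``uniform``
    a filled cube (D_q = 3 for all q);
``point``
    a single occupied voxel (D_q = 0);
``cantor_product``
    the product of three 1D Cantor sets — at subdivision ``base`` with k
    kept segments per axis the dimension is 3 log(k)/log(base);
``menger``
    the Menger sponge, 20 of 27 subcubes kept per triadic level,
    D = log 20 / log 3 ~ 2.7268 (coincidentally close to the dimension of
    the human vascular tree, the natural carrier of metastatic spread);
``cascade``
    a dyadic multiplicative cascade distributing mass over the 8 octants
    with fixed fractions w_i, the textbook multifractal measure with the
    closed-form spectrum implemented in :func:`closed_form_dq`;
``body``
    a body-like study: an ellipsoidal torso with diffuse background
    uptake, a few fixed tracer-avid "organs", and a configurable number of
    bright spherical lesions seeded along a random branching path.  A
    fixed budget of tracer quanta is distributed multinomially over the
    uptake-rate field, so adding lesions drains signal from the diffuse
    background exactly as metastatic load concentrates tracer in patients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import GenerationError
from .volume import MAX_VALUE, TracerVolume

__all__ = [
    "PhantomSpec",
    "TheoreticalSpectrum",
    "generate",
    "body_phantom",
    "closed_form_dq",
    "theoretical_spectrum",
]

_KINDS = ("uniform", "point", "cantor_product", "menger", "cascade", "body")

# fixed "organ" blobs of the body phantom: (center, radius), in fractions of
# the grid extent; roughly a liver, a heart and a bladder inside the torso
_ORGANS = (
    ((0.40, 0.42, 0.40), 0.100),
    ((0.58, 0.45, 0.30), 0.070),
    ((0.50, 0.52, 0.66), 0.055),
)
_BODY_SEMI_AXES = (0.42, 0.34, 0.48)  # ellipsoid semi-axes, fractions of extent


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom volume.

    ``level`` is the recursion depth; the grid extent is ``base**level``
    per axis.  ``weights`` (cascade only) are the 8 octant mass fractions,
    summing to 1.  ``keep`` (cantor_product only) lists the kept segment
    indices per axis.  Body-phantom intensities are relative uptake rates:
    the defaults put lesions at 40x the diffuse background, in the range
    of tumor-to-background ratios seen in FDG studies.
    """

    kind: str
    level: int = 1
    base: int = 2
    keep: tuple[int, ...] | None = None
    weights: tuple[float, ...] | None = None
    lesion_count: int = 0
    lesion_radius_voxels: float = 3.0
    lesion_intensity: float = 40.0
    organ_intensity: float = 12.0
    background_intensity: float = 1.0
    tracer_quanta: int | None = None
    quantize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")
        if self.base < 2:
            raise ValueError(f"base must be >= 2, got {self.base}")
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
            object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def extent(self) -> int:
        return self.base**self.level


def _subject(spec: PhantomSpec) -> str:
    return f"{spec.kind}-b{spec.base}-L{spec.level}"


def _as_volume(spec: PhantomSpec, values: np.ndarray) -> TracerVolume:
    return TracerVolume(
        values, subject_id=_subject(spec), provenance="phantom"
    )


def _kron_iterate(pattern: np.ndarray, level: int) -> np.ndarray:
    out = np.ones((1, 1, 1), dtype=pattern.dtype)
    for _ in range(level):
        out = np.kron(out, pattern)
    return out


def _menger_pattern() -> np.ndarray:
    idx = np.indices((3, 3, 3))
    center_axes = (idx == 1).sum(axis=0)
    return (center_axes <= 1).astype(float)  # 20 kept of 27


def _cantor_pattern(base: int, keep: tuple[int, ...]) -> np.ndarray:
    if not keep or any(k < 0 or k >= base for k in keep):
        raise ValueError(f"keep indices must lie in [0, {base - 1}], got {keep}")
    line = np.zeros(base)
    line[list(keep)] = 1.0
    return line[:, None, None] * line[None, :, None] * line[None, None, :]


def _cascade_pattern(weights: tuple[float, ...]) -> np.ndarray:
    return np.asarray(weights, dtype=float).reshape(2, 2, 2)


def generate(spec: PhantomSpec) -> TracerVolume:
    """Build the phantom volume described by ``spec``.

    Deterministic kinds reproduce their analytic construction exactly
    (occupied-voxel sets and, for cascades, the exact mass fractions up to
    one overall scale factor).  Cascade values stay unrounded float64 by
    default — 255-level quantization would destroy the deep tail of the
    measure — and are only rounded when ``quantize`` is set.
    """
    n = spec.extent
    if spec.kind == "uniform":
        return _as_volume(spec, np.full((n, n, n), MAX_VALUE))
    if spec.kind == "point":
        arr = np.zeros((n, n, n))
        arr[n // 2, n // 2, n // 2] = MAX_VALUE
        return _as_volume(spec, arr)
    if spec.kind == "menger":
        if spec.base != 3:
            raise ValueError("the Menger sponge requires base 3")
        return _as_volume(spec, _kron_iterate(_menger_pattern(), spec.level) * MAX_VALUE)
    if spec.kind == "cantor_product":
        keep = spec.keep
        if keep is None:
            keep = (0, spec.base - 1) if spec.base > 2 else (0,)
        return _as_volume(
            spec, _kron_iterate(_cantor_pattern(spec.base, tuple(keep)), spec.level) * MAX_VALUE
        )
    if spec.kind == "cascade":
        if spec.base != 2:
            raise ValueError("the multiplicative cascade is dyadic (base 2)")
        if spec.weights is None or len(spec.weights) != 8:
            got = 0 if spec.weights is None else len(spec.weights)
            raise ValueError(f"cascade needs base^3 = 8 octant weights, got {got}")
        mass = _kron_iterate(_cascade_pattern(spec.weights), spec.level)
        # scaling by the max can overshoot 255 by one ulp
        values = np.minimum(mass * (MAX_VALUE / mass.max()), MAX_VALUE)
        if spec.quantize:
            values = np.rint(values)
        return _as_volume(spec, values)
    if spec.kind == "body":
        return body_phantom(spec)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Body phantom
# ---------------------------------------------------------------------------

def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _body_mask(n: int) -> np.ndarray:
    grids = np.ogrid[0:n, 0:n, 0:n]
    c = (n - 1) / 2
    r2 = sum(
        ((g - c) / (a * n)) ** 2 for g, a in zip(grids, _BODY_SEMI_AXES)
    )
    return r2 <= 1.0


def _rate_field(spec: PhantomSpec, lesion_centers) -> np.ndarray:
    n = spec.extent
    body = _body_mask(n)
    rate = np.where(body, spec.background_intensity, 0.0)
    for center_frac, radius_frac in _ORGANS:
        mask = _sphere_mask(rate.shape, [f * n for f in center_frac], radius_frac * n)
        rate = np.where(mask & body, np.maximum(rate, spec.organ_intensity), rate)
    for center in lesion_centers:
        mask = _sphere_mask(rate.shape, center, spec.lesion_radius_voxels)
        rate = np.where(mask & body, np.maximum(rate, spec.lesion_intensity), rate)
    return rate


def _place_lesions(spec: PhantomSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded branching random walk inside the body ellipsoid.

    Each new lesion sprouts from a uniformly chosen existing one and steps
    a fixed kernel length away, mimicking contiguous vessel-borne spread
    rather than uniform scatter.
    """
    if spec.lesion_count == 0:
        return []
    n = spec.extent
    body = _body_mask(n)
    step = max(2.0 * spec.lesion_radius_voxels, 3.0)

    def inside(p) -> bool:
        ip = np.clip(np.rint(p).astype(int), 0, n - 1)
        return bool(body[tuple(ip)])

    centers: list[np.ndarray] = []
    for _ in range(2000):
        p = rng.uniform(0, n, size=3)
        if inside(p):
            centers.append(p)
            break
    if not centers:
        raise GenerationError("could not seed a lesion inside the body")
    while len(centers) < spec.lesion_count:
        placed = False
        for _ in range(500):
            parent = centers[rng.integers(len(centers))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            p = parent + direction * step * rng.uniform(0.5, 1.5)
            if inside(p):
                centers.append(p)
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place lesion {len(centers) + 1}/{spec.lesion_count} "
                "inside the body after bounded retries"
            )
    return centers


def body_phantom(spec: PhantomSpec) -> TracerVolume:
    """Generate a body-like study with a fixed tracer budget.

    The budget (``tracer_quanta``; default 1.1 quanta per unit of the
    lesion-free uptake rate) is shared multinomially across the whole
    rate field, so it does not grow with lesion burden: bright lesions
    capture quanta at the expense of the diffuse background, thinning its
    occupancy — the mechanism by which metastatic progression lowers both
    the fractal dimension and the multifractal spectrum.
    """
    if spec.kind != "body":
        raise ValueError(f"body_phantom requires kind='body', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    centers = _place_lesions(spec, rng)
    rate = _rate_field(spec, centers)
    if spec.tracer_quanta is not None:
        quanta = int(spec.tracer_quanta)
    else:
        quanta = int(round(1.1 * _rate_field(replace(spec, lesion_count=0), []).sum()))
    p = (rate / rate.sum()).ravel()
    counts = rng.multinomial(quanta, p).reshape(rate.shape)
    values = np.minimum(counts, MAX_VALUE).astype(float)
    return TracerVolume(
        values,
        subject_id=f"body-L{spec.level}-k{spec.lesion_count}-s{spec.seed}",
        provenance="phantom",
    )


# ---------------------------------------------------------------------------
# Closed-form cascade spectrum (oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Exact q -> D_q table of a dyadic multiplicative cascade."""

    q: tuple[int, ...]
    dq: tuple[float, ...]


def closed_form_dq(weights, q: float) -> float:
    """Exact generalized dimension of the dyadic cascade with octant
    fractions ``weights``.

    D_q = log2(sum_i w_i^q) / (1 - q) for q != 1 (sum over positive
    weights only) and D_1 = -sum_i w_i log2 w_i.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    w = w[w > 0]
    if q == 1:
        return float(-np.sum(w * np.log2(w)))
    return float(np.log2(np.sum(w**q)) / (1.0 - q))


def theoretical_spectrum(weights, q_list=range(-10, 11)) -> TheoreticalSpectrum:
    """Closed-form spectrum over a list of integer moment orders."""
    q = tuple(int(v) for v in q_list)
    return TheoreticalSpectrum(q, tuple(closed_form_dq(weights, v) for v in q))
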