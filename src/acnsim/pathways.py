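"""Potential-field growth of capillary pathway networks.

Capillary pathways are modelled like a river basin: a *root point* on the
boundary of a 2D working domain acts as the sink, and pathways grow from
interior *end points* toward it along the steepest descent of a scalar
potential.  The root contributes an attracting potential

    U_root(x, y) = alpha * [(x - x0)^2 + (y - y0)^2]^(1/4)

(i.e. ``alpha * sqrt(r)``, minimised at the root), and every pathway formed
so far contributes a shallow attracting valley

    U_i(x, y) = beta * sum_j [(x - x_ij)^2 + (y - y_ij)^2]^(gamma/2)

with ``beta < 0`` and ``gamma < 0``.  A pathway growing near an earlier one
may therefore be captured by its valley and attach to it as a branch instead
of running all the way to the root.  Grown polylines are finally smoothed
with third-order parametric polynomials to bend the straight steepest-descent
segments into realistic capillary curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "WorkingDomain",
    "PotentialParams",
    "PotentialField",
    "Pathway",
    "CapillaryNetwork",
    "CubicFit",
    "TrappedPathwayError",
    "GrowthError",
    "NetworkGrowthError",
    "SplitRequired",
    "root_potential",
    "pathway_potential",
    "total_potential",
    "steepest_descent_step",
    "grow_pathway",
    "build_network",
    "fit_cubic",
    "choose_parametrization",
    "smooth_pathway",
    "network_to_json",
    "network_from_json",
]

# Fixed 8-connected neighbor ordering used for steepest descent and for
# deterministic tie-breaking: E, NE, N, NW, W, SW, S, SE (y grows downward,
# so "N" is y - 1).
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1),
)

# Regularisation added inside the squared-distance bracket of the pathway
# potential when evaluating within 1 px of a pathway point (gamma < 0 makes
# the bare expression singular on the pathway itself).
SINGULARITY_EPS = 0.5


class TrappedPathwayError(RuntimeError):
    """Raised when every admissible neighbor has higher potential."""


class GrowthError(RuntimeError):
    """Raised when a single pathway cannot be grown (trapped or over budget)."""


class NetworkGrowthError(RuntimeError):
    """Raised when repeated end-point resampling still fails to grow a network."""


class SplitRequired(ValueError):
    """Raised when neither coordinate is monotone along a branch, so the
    branch must be split before cubic parametrisation."""


@dataclass(frozen=True)
class WorkingDomain:
    """2D working domain of ``lx`` x ``ly`` pixels (width x height)."""

    lx: int = 128
    ly: int = 128

    def __post_init__(self) -> None:
        if self.lx < 8 or self.ly < 8:
            raise ValueError(f"domain must be at least 8x8, got {self.lx}x{self.ly}")

    def contains(self, p: tuple[int, int]) -> bool:
        return 0 <= p[0] < self.lx and 0 <= p[1] < self.ly

    def is_interior(self, p: tuple[int, int]) -> bool:
        return 0 < p[0] < self.lx - 1 and 0 < p[1] < self.ly - 1

    def on_boundary(self, p: tuple[int, int]) -> bool:
        return self.contains(p) and not self.is_interior(p)


@dataclass(frozen=True)
class PotentialParams:
    """Strength parameters of the root and pathway potentials.

    alpha : strength of the root attraction (> 0).
    beta  : strength of the pathway attraction (< 0; more negative = stronger).
    gamma : range exponent of the pathway attraction (< 0; more negative =
            shorter range).
    """

    alpha: float = 100.0
    beta: float = -20.0
    gamma: float = -1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta >= 0:
            raise ValueError(f"beta must be negative, got {self.beta}")
        if self.gamma >= 0:
            raise ValueError(f"gamma must be negative, got {self.gamma}")


@dataclass
class PotentialField:
    """Total scalar potential sampled on the grid; ``values[y, x]``."""

    domain: WorkingDomain
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = (self.domain.ly, self.domain.lx)
        if self.values.shape != expected:
            raise ValueError(
                f"field shape {self.values.shape} does not match domain {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential field contains non-finite values")


Terminus = tuple[Literal["root", "attached"], Optional[tuple[int, tuple[int, int]]]]


@dataclass
class Pathway:
    """An ordered grid polyline from an end point toward its terminus.

    ``terminus`` is ``("root", None)`` when the pathway reached the root, or
    ``("attached", (label, point))`` when it attached to an earlier pathway.
    """

    label: int
    points: list[tuple[int, int]]
    terminus: Terminus

    def validate(self) -> None:
        if not self.points:
            raise ValueError("pathway has no points")
        for a, b in zip(self.points, self.points[1:]):
            if a == b:
                raise ValueError(f"pathway {self.label} repeats point {a}")
            if max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1:
                raise ValueError(
                    f"pathway {self.label}: {a} -> {b} are not grid neighbors"
                )


@dataclass
class CapillaryNetwork:
    domain: WorkingDomain
    root: tuple[int, int]
    end_points: list[tuple[int, int]]
    pathways: list[Pathway]
    smoothed: list[np.ndarray] = field(default_factory=list)
    seed: Optional[int] = None
    params: PotentialParams = field(default_factory=PotentialParams)


@dataclass(frozen=True)
class CubicFit:
    """Cubic polynomial through four control points.

    ``axis == "x_of_y"``: x = a3 y^3 + a2 y^2 + a1 y + a0 (coeffs low->high).
    ``axis == "y_of_x"``: y = b3 x^3 + b2 x^2 + b1 x + b0.
    """

    axis: Literal["x_of_y", "y_of_x"]
    coeffs: tuple[float, float, float, float]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        c0, c1, c2, c3 = self.coeffs
        return ((c3 * t + c2) * t + c1) * t + c0


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

def root_potential(p, root: tuple[float, float], alpha: float):
    """Root attraction ``alpha * [(x-x0)^2 + (y-y0)^2]^(1/4)``.

    ``p`` may be a single ``(x, y)`` pair or an ``(..., 2)`` array; the value
    is zero exactly at the root and grows with the square root of distance.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    p = np.asarray(p, dtype=float)
    d2 = (p[..., 0] - root[0]) ** 2 + (p[..., 1] - root[1]) ** 2
    return alpha * d2 ** 0.25


def _pathway_points_array(pathway) -> np.ndarray:
    pts = pathway.points if isinstance(pathway, Pathway) else pathway
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def pathway_potential(p, pathway, beta: float, gamma: float):
    """Attraction of an existing pathway: ``beta * sum_j d_j^gamma`` with
    ``d_j`` the Euclidean distance to pathway point j.

    Negative everywhere (beta < 0) and decaying to zero with distance.
    Squared distances below 1 px^2 are regularised by adding
    ``SINGULARITY_EPS`` inside the bracket so the value stays finite on and
    next to the pathway itself.
    """
    if beta >= 0 or gamma >= 0:
        raise ValueError("beta and gamma must both be negative")
    p = np.asarray(p, dtype=float)
    pts = _pathway_points_array(pathway)
    d2 = (
        (p[..., 0, None] - pts[:, 0]) ** 2
        + (p[..., 1, None] - pts[:, 1]) ** 2
    )
    d2 = np.where(d2 < 1.0, d2 + SINGULARITY_EPS, d2)
    return beta * np.sum(d2 ** (gamma / 2.0), axis=-1)


def _grid_points(domain: WorkingDomain) -> np.ndarray:
    ys, xs = np.mgrid[0 : domain.ly, 0 : domain.lx]
    return np.stack([xs, ys], axis=-1).astype(float)


def _pathway_contribution_grid(
    domain: WorkingDomain, pathway, beta: float, gamma: float
) -> np.ndarray:
    """Pathway potential evaluated over the whole grid, chunked over points
    to bound memory."""
    pts = _pathway_points_array(pathway)
    ys, xs = np.mgrid[0 : domain.ly, 0 : domain.lx]
    out = np.zeros((domain.ly, domain.lx), dtype=float)
    for start in range(0, len(pts), 128):
        chunk = pts[start : start + 128]
        d2 = (
            (xs[..., None] - chunk[:, 0]) ** 2
            + (ys[..., None] - chunk[:, 1]) ** 2
        ).astype(float)
        d2 = np.where(d2 < 1.0, d2 + SINGULARITY_EPS, d2)
        out += np.sum(d2 ** (gamma / 2.0), axis=-1)
    return beta * out


def total_potential(
    domain: WorkingDomain,
    root: tuple[int, int],
    pathways: Sequence[Pathway],
    params: PotentialParams,
) -> PotentialField:
    """Sum of the root potential and all existing pathway potentials on the
    grid.  With no pathways this is the pure root potential."""
    values = root_potential(_grid_points(domain), root, params.alpha)
    for pw in pathways:
        values = values + _pathway_contribution_grid(
            domain, pw, params.beta, params.gamma
        )
    return PotentialField(domain=domain, values=values)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def steepest_descent_step(
    field: PotentialField,
    current: tuple[int, int],
    previous: Optional[tuple[int, int]] = None,
) -> tuple[int, int]:
    """Pick the 8-connected neighbor with the lowest potential.

    The previous point is excluded (no immediate backtracking).  Ties are
    broken by the fixed E, NE, N, NW, W, SW, S, SE ordering, which makes the
    walk deterministic.  Raises :class:`TrappedPathwayError` when every
    admissible neighbor lies strictly above the current potential.
    """
    cx, cy = current
    dom = field.domain
    best: Optional[tuple[int, int]] = None
    best_v = np.inf
    for dx, dy in NEIGHBOR_OFFSETS:
        n = (cx + dx, cy + dy)
        if n == previous or not dom.contains(n):
            continue
        v = field.values[n[1], n[0]]
        if v < best_v:
            best, best_v = n, v
    if best is None or best_v > field.values[cy, cx]:
        raise TrappedPathwayError(
            f"pathway trapped at {current}: no neighbor at or below "
            f"potential {field.values[cy, cx]:.4g}"
        )
    return best


def grow_pathway(
    field: PotentialField,
    start: tuple[int, int],
    root: tuple[int, int],
    existing: Sequence[Pathway],
    label: int = 1,
    max_steps: Optional[int] = None,
) -> Pathway:
    """Grow one pathway from ``start`` by steepest descent of ``field``.

    Growth terminates at the root, or by attachment when the next point
    coincides with or is 8-adjacent to a point of an existing pathway.
    Raises :class:`GrowthError` when the walk gets trapped in a spurious
    local minimum or exceeds the step budget (default ``4 * (lx + ly)``),
    so the caller can resample the end point.
    """
    dom = field.domain
    start = (int(start[0]), int(start[1]))
    root = (int(root[0]), int(root[1]))
    if start == root:
        raise ValueError("end point coincides with the root point")
    if not dom.is_interior(start):
        raise ValueError(f"end point {start} is not strictly inside the domain")
    occupied: dict[tuple[int, int], int] = {}
    for pw in existing:
        for pt in pw.points:
            occupied.setdefault(pt, pw.label)
    if start in occupied:
        raise GrowthError(f"end point {start} lies on pathway {occupied[start]}")
    if max_steps is None:
        max_steps = 4 * (dom.lx + dom.ly)

    def _attachment(pt: tuple[int, int]):
        # coincident or 8-adjacent to any earlier pathway point
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                q = (pt[0] + dx, pt[1] + dy)
                if q in occupied:
                    return occupied[q], q
        return None

    points = [start]
    prev: Optional[tuple[int, int]] = None
    cur = start
    for _ in range(max_steps):
        try:
            nxt = steepest_descent_step(field, cur, prev)
        except TrappedPathwayError as exc:
            raise GrowthError(str(exc)) from exc
        points.append(nxt)
        if nxt == root:
            return Pathway(label=label, points=points, terminus=("root", None))
        hit = _attachment(nxt)
        if hit is not None:
            return Pathway(label=label, points=points, terminus=("attached", hit))
        prev, cur = cur, nxt
    raise GrowthError(
        f"pathway from {start} exceeded the step budget of {max_steps}"
    )


def _sample_boundary_point(domain: WorkingDomain, rng: np.random.Generator):
    edge = int(rng.integers(4))
    if edge == 0:  # top
        return (int(rng.integers(domain.lx)), 0)
    if edge == 1:  # bottom
        return (int(rng.integers(domain.lx)), domain.ly - 1)
    if edge == 2:  # left
        return (0, int(rng.integers(domain.ly)))
    return (domain.lx - 1, int(rng.integers(domain.ly)))


def _sample_interior_point(
    domain: WorkingDomain, rng: np.random.Generator, margin: int
):
    m = max(1, min(margin, (domain.lx - 3) // 2, (domain.ly - 3) // 2))
    return (
        int(rng.integers(m, domain.lx - m)),
        int(rng.integers(m, domain.ly - m)),
    )


def build_network(
    domain: WorkingDomain,
    n_endpoints: int,
    params: PotentialParams = PotentialParams(),
    seed: int = 0,
    margin: int = 10,
    retry_budget: int = 10,
    smooth: bool = True,
    shift_frac: float = 0.06,
) -> CapillaryNetwork:
    """Grow a full capillary network for one working domain.

    One root point is sampled uniformly on the four domain edges and
    ``n_endpoints`` end points uniformly over the interior (excluding a
    ``margin``-px border).  Pathways are grown one after another, each under
    the total potential of the root plus all previously grown pathways, so
    later pathways can branch off earlier ones.  Fully reproducible for a
    fixed seed.
    """
    if n_endpoints < 1:
        raise ValueError("n_endpoints must be >= 1")
    rng = np.random.default_rng(seed)
    root = _sample_boundary_point(domain, rng)
    field = total_potential(domain, root, [], params)
    pathways: list[Pathway] = []
    end_points: list[tuple[int, int]] = []
    for i in range(n_endpoints):
        grown = None
        for _ in range(retry_budget):
            start = _sample_interior_point(domain, rng, margin)
            if start == root or start in end_points:
                continue
            try:
                grown = grow_pathway(field, start, root, pathways, label=i + 1)
                break
            except GrowthError:
                continue
        if grown is None:
            raise NetworkGrowthError(
                f"could not grow pathway {i + 1} after {retry_budget} "
                f"end-point resamples (root={root})"
            )
        grown.validate()
        pathways.append(grown)
        end_points.append(grown.points[0])
        field = PotentialField(
            domain=domain,
            values=field.values
            + _pathway_contribution_grid(domain, grown, params.beta, params.gamma),
        )
    net = CapillaryNetwork(
        domain=domain,
        root=root,
        end_points=end_points,
        pathways=pathways,
        seed=seed,
        params=params,
    )
    if smooth:
        net.smoothed = [
            smooth_pathway(pw, rng=rng, shift_frac=shift_frac)
            if len(pw.points) >= 4
            else np.asarray(pw.points, dtype=float)
            for pw in pathways
        ]
    return net


def random_network(
    seed: int,
    domain: WorkingDomain = WorkingDomain(),
    params: PotentialParams = PotentialParams(),
    **kwargs,
) -> CapillaryNetwork:
    """Network with the default 3-6 end points, the count drawn from the seed."""
    n = 3 + int(np.random.default_rng([seed, 0x5EED]).integers(4))
    return build_network(domain, n, params=params, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# cubic smoothing
# ---------------------------------------------------------------------------

def fit_cubic(points4, axis: Literal["x_of_y", "y_of_x"]) -> CubicFit:
    """Exact cubic through four control points.

    For ``"x_of_y"`` the independent coordinate is y (x = cubic(y)); for
    ``"y_of_x"`` it is x.  The four independent-coordinate values must be
    distinct, otherwise the Vandermonde system is singular.
    """
    pts = np.asarray(points4, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError(f"expected four (x, y) control points, got {pts.shape}")
    if axis == "x_of_y":
        t, v = pts[:, 1], pts[:, 0]
    elif axis == "y_of_x":
        t, v = pts[:, 0], pts[:, 1]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if len(np.unique(t)) < 4:
        raise ValueError(
            f"duplicate independent-coordinate values {t.tolist()} for axis {axis}"
        )
    vand = np.vander(t, 4, increasing=True)
    coeffs = np.linalg.solve(vand, v)
    return CubicFit(axis=axis, coeffs=tuple(float(c) for c in coeffs))


def _monotone(v: np.ndarray) -> bool:
    d = np.diff(v)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def choose_parametrization(branch) -> Literal["x_of_y", "y_of_x"]:
    """Choose which coordinate serves as the cubic's independent variable.

    y must be monotone along the branch for the x=f(y) form and x monotone
    for y=f(x); when both qualify the axis with the larger span wins (better
    conditioning).  Raises :class:`SplitRequired` when neither coordinate is
    monotone.
    """
    pts = np.asarray(branch, dtype=float).reshape(-1, 2)
    if len(pts) < 4:
        raise ValueError(f"branch needs at least 4 points, got {len(pts)}")
    x_mono = _monotone(pts[:, 0])
    y_mono = _monotone(pts[:, 1])
    if x_mono and y_mono:
        span_x = abs(pts[-1, 0] - pts[0, 0])
        span_y = abs(pts[-1, 1] - pts[0, 1])
        return "x_of_y" if span_y > span_x else "y_of_x"
    if y_mono:
        return "x_of_y"
    if x_mono:
        return "y_of_x"
    raise SplitRequired("neither coordinate is monotone along the branch")


def _control_points(pts: np.ndarray) -> np.ndarray:
    n = len(pts)
    idx = [0, round((n - 1) / 3), round(2 * (n - 1) / 3), n - 1]
    return pts[idx]


def _chord_deviation(pts: np.ndarray) -> float:
    """Maximum perpendicular distance of the polyline from its chord."""
    p0, p3 = pts[0], pts[-1]
    chord = p3 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return float(np.max(np.hypot(*(pts - p0).T)))
    cross = np.abs(
        chord[0] * (pts[:, 1] - p0[1]) - chord[1] * (pts[:, 0] - p0[0])
    )
    return float(np.max(cross) / norm)


def _sample_fit(fit: CubicFit, t0: float, t1: float) -> np.ndarray:
    n = max(2, int(abs(t1 - t0) * 4) + 1)
    t = np.linspace(t0, t1, n)
    v = fit(t)
    if fit.axis == "x_of_y":
        return np.stack([v, t], axis=-1)
    return np.stack([t, v], axis=-1)


STRAIGHTNESS_TOL = 1.5  # px; below this the branch counts as straight


def smooth_pathway(
    pathway,
    shift: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    shift_frac: float = 0.06,
) -> np.ndarray:
    """Replace a grown polyline by a densely sampled cubic curve.

    Control points are the first point, the points at the one-third and
    two-thirds positions, and the last point.  Near-straight branches
    (chord deviation < 1.5 px) get their two middle control points shifted
    laterally to bend the segment: by ``shift`` pixels when given (signed;
    0 disables bending), otherwise by ``shift_frac`` of the chord length
    with a random sign drawn from ``rng``.  The first and last points of
    the branch are preserved exactly.  Branches along which neither
    coordinate is monotone are split in half and smoothed recursively.
    """
    pts = np.asarray(
        pathway.points if isinstance(pathway, Pathway) else pathway, dtype=float
    ).reshape(-1, 2)
    if len(pts) < 4:
        raise ValueError(f"pathway needs at least 4 points, got {len(pts)}")

    def _smooth(seg: np.ndarray) -> np.ndarray:
        if len(seg) < 4:
            return seg.copy()
        try:
            axis = choose_parametrization(seg)
        except SplitRequired:
            mid = len(seg) // 2
            left = _smooth(seg[: mid + 1])
            right = _smooth(seg[mid:])
            return np.concatenate([left, right[1:]], axis=0)
        ctrl = _control_points(seg).copy()
        chord = seg[-1] - seg[0]
        chord_len = float(np.hypot(*chord))
        if chord_len > 0 and _chord_deviation(seg) < STRAIGHTNESS_TOL:
            if shift is not None:
                delta = float(shift)
            else:
                magnitude = shift_frac * chord_len
                sign = 1.0 if rng is None else float(rng.choice([-1.0, 1.0]))
                delta = sign * magnitude
            normal = np.array([-chord[1], chord[0]]) / chord_len
            ctrl[1] = ctrl[1] + delta * normal
            ctrl[2] = ctrl[2] + delta * normal
        try:
            fit = fit_cubic(ctrl, axis)
        except ValueError:
            # duplicate independent values among the controls: fall back to
            # splitting, or to the raw polyline when too short to split
            if len(seg) >= 8:
                mid = len(seg) // 2
                left = _smooth(seg[: mid + 1])
                right = _smooth(seg[mid:])
                return np.concatenate([left, right[1:]], axis=0)
            return seg.copy()
        t0, t1 = (ctrl[0, 1], ctrl[3, 1]) if axis == "x_of_y" else (
            ctrl[0, 0], ctrl[3, 0]
        )
        curve = _sample_fit(fit, t0, t1)
        curve[0], curve[-1] = seg[0], seg[-1]
        return curve

    return _smooth(pts)


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def network_to_json(net: CapillaryNetwork) -> str:
    payload = {
        "domain": {"lx": net.domain.lx, "ly": net.domain.ly},
        "root": list(net.root),
        "end_points": [list(p) for p in net.end_points],
        "params": {
            "alpha": net.params.alpha,
            "beta": net.params.beta,
            "gamma": net.params.gamma,
        },
        "seed": net.seed,
        "pathways": [
            {
                "label": pw.label,
                "points": [list(p) for p in pw.points],
                "terminus": [
                    pw.terminus[0],
                    None
                    if pw.terminus[1] is None
                    else [pw.terminus[1][0], list(pw.terminus[1][1])],
                ],
            }
            for pw in net.pathways
        ],
        "smoothed": [c.tolist() for c in net.smoothed],
    }
    return json.dumps(payload)


def network_from_json(text: str) -> CapillaryNetwork:
    d = json.loads(text)
    pathways = []
    for p in d["pathways"]:
        kind, info = p["terminus"]
        terminus: Terminus = (
            ("root", None)
            if kind == "root"
            else ("attached", (info[0], tuple(info[1])))
        )
        pathways.append(
            Pathway(
                label=p["label"],
                points=[tuple(pt) for pt in p["points"]],
                terminus=terminus,
            )
        )
    return CapillaryNetwork(
        domain=WorkingDomain(**d["domain"]),
        root=tuple(d["root"]),
        end_points=[tuple(p) for p in d["end_points"]],
        pathways=pathways,
        smoothed=[np.asarray(c, dtype=float) for c in d["smoothed"]],
        seed=d["seed"],
        params=PotentialParams(**d["params"]),
    )
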