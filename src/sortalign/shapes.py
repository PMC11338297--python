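"""Family-resemblance shape categories and trial-list construction.

Two categories (A and B) are each seeded by a prototype: an ordered, closed
list of 39 vertices in unit-bounding-box canvas coordinates, joined by a
periodic cubic spline.  Exemplars are graded distortions of a prototype,
produced by adding isotropic Gaussian noise to every fifth vertex (indices
0, 5, 10, ...) and re-interpolating the contour.  The module also assembles
the 20-item free-sort set (per category: 3 previously seen exemplars, 6
unseen exemplars, and the prototype) and the xAB match-to-sample trial list
in which every cross-category exemplar pair appears once per block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

Category = Literal["A", "B"]
Role = Literal["prototype", "exemplar"]
Distortion = Literal["none", "low", "medium", "high", "fixed"]

#: Distortion SDs, in units of the prototype's (unit) bounding box.
DISTORTION_SD = {"low": 0.25, "medium": 0.55, "high": 0.75, "fixed": 0.35}

#: Default number of prototype vertices.
N_VERTICES = 39

#: Phase of the perturbed-vertex lattice: indices 0, 5, 10, ... are displaced.
PERTURB_STRIDE = 5


class InvalidShapeError(ValueError):
    """Raised for geometrically invalid shape input."""


class CompositionError(ValueError):
    """Raised when a stimulus set cannot be assembled as requested."""


class DesignError(ValueError):
    """Raised for invalid trial-design input."""


@dataclass(frozen=True)
class ShapeSpec:
    """A prototype or exemplar shape.

    ``vertices`` is the ordered closed vertex list (first vertex not
    repeated); ``contour`` is the optional interpolated closed polyline
    through the vertices (first point == last point), absent for the
    contour-free point stimuli.
    """

    shape_id: str
    category: Category
    role: Role
    distortion: Distortion
    vertices: tuple[tuple[float, float], ...]
    contour: tuple[tuple[float, float], ...] | None = None
    seen_in_preexposure: bool = False

    def __post_init__(self) -> None:
        if self.category not in ("A", "B"):
            raise InvalidShapeError(f"category must be 'A' or 'B', got {self.category!r}")
        if self.contour is not None and self.contour[0] != self.contour[-1]:
            raise InvalidShapeError("contour must be closed (first point == last point)")

    @property
    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def to_dict(self) -> dict:
        return {
            "shape_id": self.shape_id,
            "category": self.category,
            "role": self.role,
            "distortion": self.distortion,
            "vertices": [list(v) for v in self.vertices],
            "contour": None if self.contour is None else [list(p) for p in self.contour],
            "seen_in_preexposure": self.seen_in_preexposure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeSpec":
        return cls(
            shape_id=d["shape_id"],
            category=d["category"],
            role=d["role"],
            distortion=d["distortion"],
            vertices=tuple(tuple(v) for v in d["vertices"]),
            contour=None if d.get("contour") is None else tuple(tuple(p) for p in d["contour"]),
            seen_in_preexposure=bool(d.get("seen_in_preexposure", False)),
        )


@dataclass(frozen=True)
class TrialRow:
    """One xAB match-to-sample trial."""

    block: int
    sample_id: str
    left_id: str
    right_id: str
    correct_side: Literal["left", "right"]
    audio: Literal["label", "noise", "none"]


@dataclass(frozen=True)
class StimulusSet:
    """The 20-item free-sort set, canonically ordered (A before B, by id)."""

    items: tuple[ShapeSpec, ...]

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(s.shape_id for s in self.items)

    def category_of(self) -> dict[str, str]:
        return {s.shape_id: s.category for s in self.items}


def interpolate_contour(
    vertices: Sequence[tuple[float, float]] | np.ndarray, points_per_segment: int = 10
) -> np.ndarray:
    """Closed periodic cubic spline through ``vertices``.

    Returns an ``(n * points_per_segment + 1, 2)`` polyline whose last point
    repeats the first and whose points at indices ``i * points_per_segment``
    equal the input vertices.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 4:
        raise InvalidShapeError("need at least 4 (x, y) vertices for a closed contour")
    if points_per_segment < 1:
        raise InvalidShapeError("points_per_segment must be >= 1")
    n = verts.shape[0]
    # periodic spline needs first == last knot
    knots_t = np.arange(n + 1, dtype=float)
    knots = np.vstack([verts, verts[:1]])
    spline = CubicSpline(knots_t, knots, bc_type="periodic")
    t = np.linspace(0.0, float(n), n * points_per_segment + 1)
    curve = spline(t)
    curve[::points_per_segment] = knots  # exact at knots
    curve[-1] = curve[0]
    return curve


def perturb_shape(proto: ShapeSpec, sd: float, rng_seed: int, *, with_contour: bool = True,
                  distortion: Distortion = "none", shape_id: str | None = None) -> ShapeSpec:
    """Displace every fifth vertex of a prototype by Gaussian noise.

    Noise is i.i.d. N(0, sd) in x and y at vertex indices 0, 5, 10, ...;
    the remaining vertices are untouched and the contour is re-interpolated
    (or dropped when ``with_contour`` is false, for point stimuli).
    Deterministic given ``rng_seed``.
    """
    if proto.role != "prototype":
        raise InvalidShapeError("perturb_shape requires a prototype")
    if sd < 0:
        raise InvalidShapeError("sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    verts = proto.vertex_array.copy()
    idx = np.arange(0, verts.shape[0], PERTURB_STRIDE)
    verts[idx] += rng.normal(0.0, sd, size=(idx.size, 2))
    contour = interpolate_contour(verts) if with_contour else None
    return ShapeSpec(
        shape_id=shape_id or f"{proto.shape_id}-ex{rng_seed}",
        category=proto.category,
        role="exemplar",
        distortion=distortion,
        vertices=tuple(map(tuple, verts)),
        contour=None if contour is None else tuple(map(tuple, contour)),
    )


def generate_category(
    proto: ShapeSpec,
    level_counts: dict[str, int],
    rng_seed: int,
    *,
    with_contour: bool = True,
) -> list[ShapeSpec]:
    """Generate exemplars per distortion level from a prototype.

    ``level_counts`` maps distortion level (a key of ``DISTORTION_SD``) to
    the number of exemplars requested at that level; e.g. the Exp-1 recipe
    is ``{"low": 6, "medium": 6, "high": 6}`` (18 per category) and the
    Exp-2 recipe is ``{"fixed": 10}`` with ``with_contour=False``.
    """
    out: list[ShapeSpec] = []
    seq = 0
    for level in ("low", "medium", "high", "fixed"):
        count = level_counts.get(level, 0)
        if count < 0:
            raise InvalidShapeError("exemplar counts must be >= 0")
        sd = DISTORTION_SD.get(level)
        for _ in range(count):
            out.append(
                perturb_shape(
                    proto,
                    sd,
                    rng_seed=_derive_seed(rng_seed, proto.category, seq),
                    with_contour=with_contour,
                    distortion=level,
                    shape_id=f"{proto.category}{seq + 1:02d}-{level}",
                )
            )
            seq += 1
    return out


def _derive_seed(master: int, tag: str, index: int) -> int:
    h = np.uint64(np.uint64(master) * np.uint64(1000003) + np.uint64(index))
    h ^= np.uint64(sum(map(ord, tag)) * 2654435761)
    return int(h % np.uint64(2**31 - 1))


def assemble_sort_set(
    cat_a: Sequence[ShapeSpec],
    cat_b: Sequence[ShapeSpec],
    seen_ids: Iterable[str],
    n_seen: int = 3,
    n_unseen: int = 6,
) -> StimulusSet:
    """Assemble the 20-item free-sort set: per category ``n_seen``
    previously seen exemplars, ``n_unseen`` unseen exemplars, and the
    prototype (default 3 + 6 + 1).

    ``seen_ids`` are the exemplars presented during pre-exposure; the seen
    slots are filled from them (stable by shape_id), the unseen slots from
    the remainder, plus the category prototype (itself never pre-exposed).
    """
    seen = set(seen_ids)
    known = {s.shape_id for s in list(cat_a) + list(cat_b)}
    unknown = seen - known
    if unknown:
        raise CompositionError(f"seen_ids not found in either category: {sorted(unknown)}")

    def pick(shapes: Sequence[ShapeSpec], category: str) -> list[ShapeSpec]:
        protos = sorted(
            (s for s in shapes if s.role == "prototype"), key=lambda s: s.shape_id
        )
        exemplars = sorted(
            (s for s in shapes if s.role == "exemplar"), key=lambda s: s.shape_id
        )
        seen_ex = [s for s in exemplars if s.shape_id in seen]
        unseen_ex = [s for s in exemplars if s.shape_id not in seen]
        if len(protos) < 1 or len(seen_ex) < n_seen or len(unseen_ex) < n_unseen:
            raise CompositionError(
                f"category {category}: need >=1 prototype, >={n_seen} seen and "
                f">={n_unseen} unseen exemplars; got "
                f"{len(protos)}/{len(seen_ex)}/{len(unseen_ex)}"
            )
        chosen = (
            [replace(s, seen_in_preexposure=True) for s in seen_ex[:n_seen]]
            + unseen_ex[:n_unseen]
            + [protos[0]]
        )
        return sorted(chosen, key=lambda s: s.shape_id)

    return StimulusSet(tuple(pick(cat_a, "A") + pick(cat_b, "B")))


def build_xab_trials(
    a_ids: Sequence[str],
    b_ids: Sequence[str],
    n_blocks: int = 3,
    audio_mode: Literal["label", "noise", "none"] = "none",
    seed: int = 0,
    prototype_ids: Iterable[str] = (),
) -> list[TrialRow]:
    """Build the xAB trial list: per block every A exemplar is paired with
    every B exemplar (81 pairs for 9 + 9 shapes), foils always cross-category.

    The sample alternates deterministically between the A and the B member
    of each pair; the correct side is counterbalanced so that left/right
    counts differ by at most 1 within each block.  Prototypes never appear.
    """
    a_ids, b_ids = list(a_ids), list(b_ids)
    protos = set(prototype_ids)
    if protos & (set(a_ids) | set(b_ids)):
        raise DesignError("prototypes must not appear in the pre-exposure trial list")
    if len(a_ids) != 9 or len(b_ids) != 9:
        raise DesignError(f"need exactly 9 ids per category, got {len(a_ids)}/{len(b_ids)}")
    if n_blocks < 1:
        raise DesignError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[TrialRow] = []
    for block in range(1, n_blocks + 1):
        pairs = [(a, b) for a in a_ids for b in b_ids]
        order = rng.permutation(len(pairs))
        for t, pi in enumerate(order):
            a, b = pairs[pi]
            sample = a if (t + block) % 2 == 0 else b
            target_left = t % 2 == 0
            left, right = (sample, b if sample == a else a) if target_left else (
                b if sample == a else a, sample)
            trials.append(
                TrialRow(
                    block=block,
                    sample_id=sample,
                    left_id=left,
                    right_id=right,
                    correct_side="left" if target_left else "right",
                    audio=audio_mode,
                )
            )
    return trials


# ---------------------------------------------------------------------------
# Prototype fixtures
# ---------------------------------------------------------------------------

def _blob_vertices(seed: int, n: int = N_VERTICES, n_harmonics: int = 5) -> np.ndarray:
    """Synthetic irregular closed blob: smooth random radial perturbation of a
    circle, normalized to the unit bounding box.  Stands in for the paper
    domain's hand-drawn nameless shapes; fixed seeds make it reproducible."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = np.ones(n)
    for h in range(1, n_harmonics + 1):
        amp = rng.uniform(0.05, 0.25) / h
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(h * theta + phase)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return _normalize_unit_box(pts)


def _circle_vertices(n: int = N_VERTICES) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return _normalize_unit_box(np.column_stack([np.cos(theta), np.sin(theta)]))


def _square_vertices(n: int = N_VERTICES) -> np.ndarray:
    """n points evenly spaced along the perimeter of the unit square."""
    s = np.linspace(0.0, 4.0, n, endpoint=False)
    pts = np.empty((n, 2))
    for i, u in enumerate(s):
        side, frac = int(u), u - int(u)
        if side == 0:
            pts[i] = (frac, 0.0)
        elif side == 1:
            pts[i] = (1.0, frac)
        elif side == 2:
            pts[i] = (1.0 - frac, 1.0)
        else:
            pts[i] = (0.0, 1.0 - frac)
    return _normalize_unit_box(pts)


def _normalize_unit_box(pts: np.ndarray) -> np.ndarray:
    pts = pts - pts.min(axis=0)
    return pts / pts.max()


def load_prototypes(experiment: int = 1) -> tuple[ShapeSpec, ShapeSpec]:
    """Load the versioned category-prototype fixtures (A, B).

    Experiment 1: two irregular 39-vertex blobs with contours.  Experiment
    2: a 39-point circle and square, contour-free (point stimuli).  The
    fixtures are synthetic stand-ins generated by this package.
    """
    fname = f"prototypes_exp{experiment}.json"
    try:
        text = resources.files("sortalign.data").joinpath(fname).read_text()
    except FileNotFoundError:
        raise ValueError(f"experiment must be 1 or 2, got {experiment}") from None
    payload = json.loads(text)
    a, b = (ShapeSpec.from_dict(d) for d in payload["prototypes"])
    return a, b


def generate_stimuli(experiment: int = 1, seed: int = 0) -> dict:
    """End-to-end stimulus build: prototypes, exemplars, free-sort set, and
    the pre-exposure exemplar ids.  Returns a dict of all pieces."""
    proto_a, proto_b = load_prototypes(experiment)
    if experiment == 1:
        level_counts, with_contour = {"low": 6, "medium": 6, "high": 6}, True
    elif experiment == 2:
        level_counts, with_contour = {"fixed": 10}, False
    else:
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    cat_a = generate_category(proto_a, level_counts, seed, with_contour=with_contour)
    cat_b = generate_category(proto_b, level_counts, seed + 1, with_contour=with_contour)
    # Pre-exposure uses 9 exemplars per category (never the prototypes);
    # 3 of those 9 later reappear in the free-sort set.
    rng = np.random.default_rng(seed)
    pre_a = sorted(rng.choice([s.shape_id for s in cat_a], size=9, replace=False))
    pre_b = sorted(rng.choice([s.shape_id for s in cat_b], size=9, replace=False))
    seen = set(pre_a) | set(pre_b)
    # Exp 1: 3 seen + 6 unseen + prototype per category; Exp 2 has only 10
    # exemplars per category, so its sort set is the 9 pre-exposed exemplars
    # plus the (never pre-exposed) prototype.
    n_seen, n_unseen = (3, 6) if experiment == 1 else (9, 0)
    sort_set = assemble_sort_set(
        list(cat_a) + [proto_a], list(cat_b) + [proto_b], seen,
        n_seen=n_seen, n_unseen=n_unseen,
    )
    return {
        "prototypes": (proto_a, proto_b),
        "category_a": cat_a,
        "category_b": cat_b,
        "preexposure_ids": (pre_a, pre_b),
        "sort_set": sort_set,
    }
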