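"""Arterial tree geometry, wall stiffness law, and the pressure-area (tube) law.

The systemic arterial network is represented as a bifurcating binary tree of
axisymmetric elastic vessels that taper linearly along their length.  The
packaged nominal tree has 55 vessels (28 terminals); its radii are defined at
the reference pressure of 97 mmHg.  Wall stiffness follows

    F(r0) = (4/3) * (k1 * exp(-k2 * r0) + k3)        [g s^-2 cm^-1]

so that large arteries (r0 >> 1 cm) are governed by ``k3`` alone while small
arteries feel ``k1 + k3``.  The transmural pressure closing the 1D flow
equations is

    p(A) = p_ref + F * (1 - sqrt(A0 / A))

anchored so that ``p(A0) = p_ref`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .units import MMHG_TO_CGS

__all__ = [
    "Vessel",
    "WallModel",
    "WindkesselElements",
    "ArterialTree",
    "load_tree",
    "nominal_tree",
    "scale_tree_to_height",
    "wall_stiffness",
    "tube_law",
    "inverse_tube_law",
    "wave_speed",
    "path_between",
    "path_length",
    "TreeValidationError",
    "TreeParseError",
]

K2_DEFAULT = 22.53  # 1/cm
P_REF_MMHG = 97.0


class TreeParseError(ValueError):
    """Raised when a tree-definition file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


@dataclass(frozen=True)
class WindkesselElements:
    """Nominal three-element Windkessel data attached to a terminal vessel.

    Resistances in dyn s cm^-5, compliance in cm^5/dyn.  At run time these are
    scaled uniformly by the patient parameters S_R (both resistances) and S_C.
    """

    R1: float
    R2: float
    C: float

    def __post_init__(self) -> None:
        if not (self.R1 > 0 and self.R2 > 0 and self.C > 0):
            raise TreeValidationError("Windkessel elements must be positive")


@dataclass(frozen=True)
class Vessel:
    id: int
    name: str
    length: float  # cm
    r_in: float  # cm, inlet radius at reference pressure
    r_out: float  # cm, outlet radius at reference pressure
    daughters: tuple[int, ...] = ()
    parent: int | None = None
    windkessel: WindkesselElements | None = None
    wk_fixed: bool = False  # exempt this terminal from S_R/S_C scaling

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise TreeValidationError(f"vessel {self.id}: length must be > 0")
        if not (self.r_in >= self.r_out > 0):
            raise TreeValidationError(
                f"vessel {self.id}: requires r_in >= r_out > 0 (tapering)"
            )
        if len(self.daughters) not in (0, 2):
            raise TreeValidationError(
                f"vessel {self.id}: must have 0 or 2 daughters, "
                f"got {len(self.daughters)}"
            )

    @property
    def terminal(self) -> bool:
        return len(self.daughters) == 0

    def r0(self, x: float | np.ndarray) -> float | np.ndarray:
        """Reference radius at distance ``x`` (cm) from the inlet (linear taper)."""
        s = np.clip(np.asarray(x, dtype=float) / self.length, 0.0, 1.0)
        out = self.r_in + (self.r_out - self.r_in) * s
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WallModel:
    """Parameters of the arterial wall stiffness law."""

    k1: float  # g s^-2 cm^-1, small-artery stiffness scale
    k3: float  # g s^-2 cm^-1, large-artery stiffness
    k2: float = K2_DEFAULT  # 1/cm, fixed exponential rate
    p_ref: float = P_REF_MMHG  # mmHg, pressure at which r0 is defined

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k3 <= 0 or self.k2 <= 0 or self.p_ref <= 0:
            raise ValueError("require k1 >= 0, k3 > 0, k2 > 0, p_ref > 0")


@dataclass(frozen=True)
class ArterialTree:
    """A validated bifurcating tree of :class:`Vessel` objects."""

    vessels: Mapping[int, Vessel]
    root: int
    named_sites: Mapping[str, tuple[int, float]] = field(default_factory=dict)
    nominal_height: float = 176.0  # cm
    p_out: float = 5.0  # mmHg, venous pressure behind every Windkessel
    height: float | None = None  # cm, set once scaled to a subject

    def __post_init__(self) -> None:
        _validate_topology(self.vessels, self.root)
        for label, (vid, frac) in self.named_sites.items():
            if vid not in self.vessels:
                raise TreeValidationError(
                    f"named site {label!r} refers to unknown vessel {vid}"
                )
            if not 0.0 <= frac <= 1.0:
                raise TreeValidationError(
                    f"named site {label!r}: position {frac} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.vessels)

    @property
    def terminal_ids(self) -> list[int]:
        return [v.id for v in self.vessels.values() if v.terminal]

    def site(self, label_or_site: str | tuple[int, float]) -> tuple[int, float]:
        if isinstance(label_or_site, str):
            try:
                return self.named_sites[label_or_site]
            except KeyError:
                raise KeyError(
                    f"unknown site {label_or_site!r}; "
                    f"known: {sorted(self.named_sites)}"
                ) from None
        vid, frac = label_or_site
        return int(vid), float(frac)

    def path_to_root(self, vid: int) -> list[int]:
        path = [vid]
        while self.vessels[path[-1]].parent is not None:
            path.append(self.vessels[path[-1]].parent)
        return path


def _validate_topology(vessels: Mapping[int, Vessel], root: int) -> None:
    if root not in vessels:
        raise TreeValidationError(f"root id {root} not among vessels")
    seen: set[int] = set()
    stack = [root]
    while stack:
        vid = stack.pop()
        if vid in seen:
            raise TreeValidationError(f"cycle detected at vessel {vid}")
        seen.add(vid)
        v = vessels[vid]
        for d in v.daughters:
            if d not in vessels:
                raise TreeValidationError(f"vessel {vid}: unknown daughter {d}")
            if vessels[d].parent != vid:
                raise TreeValidationError(
                    f"vessel {d}: parent link inconsistent with daughter list"
                )
            stack.append(d)
    if seen != set(vessels):
        orphans = sorted(set(vessels) - seen)
        raise TreeValidationError(f"vessels unreachable from root: {orphans}")


def _build_tree(payload: dict) -> ArterialTree:
    try:
        records = payload["vessels"]
    except KeyError:
        raise TreeParseError("tree file lacks a 'vessels' list") from None
    parent: dict[int, int] = {}
    for rec in records:
        for d in rec.get("daughters", ()):
            if d in parent:
                raise TreeParseError(
                    f"vessel {d} listed as daughter of both {parent[d]} "
                    f"and {rec.get('id')}"
                )
            parent[d] = rec["id"]
    vessels: dict[int, Vessel] = {}
    for rec in records:
        try:
            vid = int(rec["id"])
            wk = rec.get("windkessel")
            vessels[vid] = Vessel(
                id=vid,
                name=str(rec["name"]),
                length=float(rec["length_cm"]),
                r_in=float(rec["r_in_cm"]),
                r_out=float(rec["r_out_cm"]),
                daughters=tuple(int(d) for d in rec.get("daughters", ())),
                parent=parent.get(vid),
                windkessel=WindkesselElements(**wk) if wk else None,
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, TreeValidationError):
                raise
            raise TreeParseError(f"malformed vessel record {rec!r}: {exc}") from exc
        if vid in vessels and len(vessels) != len({v for v in vessels}):
            raise TreeParseError(f"duplicate vessel id {vid}")
    if len(vessels) != len(records):
        raise TreeParseError("duplicate vessel ids in tree file")
    roots = [vid for vid in vessels if vid not in parent]
    if len(roots) != 1:
        raise TreeValidationError(f"expected exactly one root, found {roots}")
    sites = {
        str(k): (int(v[0]), float(v[1]))
        for k, v in payload.get("named_sites", {}).items()
    }
    return ArterialTree(
        vessels=vessels,
        root=roots[0],
        named_sites=sites,
        nominal_height=float(payload.get("nominal_height_cm", 176.0)),
        p_out=float(payload.get("p_out_mmhg", 5.0)),
    )


def load_tree(path: str | Path) -> ArterialTree:
    """Load and validate a tree-definition JSON file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise TreeParseError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise TreeParseError(f"{path}: top level must be an object")
    return _build_tree(payload)


def nominal_tree() -> ArterialTree:
    """The packaged nominal 55-vessel tree."""
    ref = resources.files("pulsewave.data") / "arterial_tree_55.json"
    return _build_tree(json.loads(ref.read_text()))


def scale_tree_to_height(
    tree: ArterialTree,
    height: float,
    bounds: tuple[float, float] = (120.0, 220.0),
) -> ArterialTree:
    """Scale all vessel lengths by ``height / nominal_height``.

    Radii are left unchanged: subject height mainly stretches path lengths and
    hence wave transit times.  Topology and named sites are preserved.
    """
    lo, hi = bounds
    if not lo <= height <= hi:
        raise ValueError(f"height {height} cm outside plausible range [{lo}, {hi}]")
    factor = height / tree.nominal_height
    vessels = {
        vid: replace(v, length=v.length * factor) for vid, v in tree.vessels.items()
    }
    return replace(tree, vessels=vessels, height=height)


def wall_stiffness(r0, wall: WallModel):
    """Stiffness F(r0) in g s^-2 cm^-1; vectorised over ``r0``."""
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("r0 must be positive")
    out = (4.0 / 3.0) * (wall.k1 * np.exp(-wall.k2 * r0) + wall.k3)
    return float(out) if out.ndim == 0 else out


def tube_law(A, A0, F, p_ref: float = P_REF_MMHG):
    """Transmural pressure (mmHg) at cross-sectional area ``A`` (cm^2)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or np.any(np.asarray(A0) <= 0) or np.any(np.asarray(F) <= 0):
        raise ValueError("A, A0 and F must be positive")
    p = p_ref + F * (1.0 - np.sqrt(A0 / A)) / MMHG_TO_CGS
    return float(p) if p.ndim == 0 else p


def inverse_tube_law(p, A0, F, p_ref: float = P_REF_MMHG):
    """Area (cm^2) at transmural pressure ``p`` (mmHg); inverse of :func:`tube_law`."""
    p = np.asarray(p, dtype=float)
    z = 1.0 - (p - p_ref) * MMHG_TO_CGS / np.asarray(F, dtype=float)
    if np.any(z <= 0):
        raise ValueError(
            "pressure at or beyond the tube-law asymptote p_ref + F is unreachable"
        )
    A = np.asarray(A0, dtype=float) / z**2
    return float(A) if A.ndim == 0 else A


def wave_speed(r0, wall: WallModel, rho: float = 1.055):
    """Linearised pulse wave speed c0 = sqrt(F/(2 rho)) in cm/s at area A0."""
    F = wall_stiffness(r0, wall)
    return np.sqrt(F / (2.0 * rho))


def path_between(
    tree: ArterialTree, site_a, site_b
) -> tuple[list[int], float]:
    """Vessel path and arc length (cm) between two sites on a common root-leaf line.

    Raises ``ValueError`` if neither site is an ancestor of the other or the
    sites coincide.
    """
    a_vid, a_frac = tree.site(site_a)
    b_vid, b_frac = tree.site(site_b)
    anc_a = tree.path_to_root(a_vid)
    anc_b = tree.path_to_root(b_vid)
    if b_vid in anc_a:
        upper, u_frac, lower, l_frac = (b_vid, b_frac), b_frac, (a_vid, a_frac), a_frac
        chain = anc_a[: anc_a.index(b_vid) + 1][::-1]
    elif a_vid in anc_b:
        upper, u_frac, lower, l_frac = (a_vid, a_frac), a_frac, (b_vid, b_frac), b_frac
        chain = anc_b[: anc_b.index(a_vid) + 1][::-1]
    else:
        raise ValueError(
            "sites must lie on a common root-to-leaf path "
            f"(vessels {a_vid} and {b_vid} are in different subtrees)"
        )
    # chain runs from the upper (rootward) vessel down to the lower vessel
    length = (1.0 - u_frac) * tree.vessels[chain[0]].length
    for vid in chain[1:-1]:
        length += tree.vessels[vid].length
    if len(chain) > 1:
        length += l_frac * tree.vessels[chain[-1]].length
    else:
        length = abs(l_frac - u_frac) * tree.vessels[chain[0]].length
    if length <= 0:
        raise ValueError("sites coincide: zero path length")
    return chain, length


def path_length(tree: ArterialTree, site_a, site_b) -> float:
    """Arc length (cm) between two sites along the tree."""
    return path_between(tree, site_a, site_b)[1]
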