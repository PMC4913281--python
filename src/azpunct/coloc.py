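"""Cross-channel punctum association and categorical colocalization.

Pairs of puncta across two channels are associated when their centroids
fall within a distance criterion or their thresholded regions share at
least one pixel — distance matters because at active zones the two
scaffold proteins sit side-by-side ~100 nm apart rather than on top of
each other, so an overlap-only criterion would miss genuine partners.
Each punctum of the reference (Bassoon) channel is then scored into the
exhaustive category schemes used for Bassoon-VGCC and Piccolo-Bassoon
pairings, and flanking-pair ("sandwich", Piccolo-Bassoon-Piccolo)
geometry is detected explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import AzpunctError, PunctaSet

DEFAULT_ASSOCIATION_RADIUS_NM = 150.0
DEFAULT_SANDWICH_MIN_SEP_NM = 60.0
DEFAULT_SANDWICH_MAX_SEP_NM = 200.0
DEFAULT_SANDWICH_MIN_ANGLE_DEG = 120.0

BASSOON_VGCC_CATEGORIES = ("1V:1B", "2V:1B", ">=3V:1B", "B_only", "V_only")
PICCOLO_BASSOON_CATEGORIES = ("1P:1B", "2P:1B", ">=3P:1B", "1P:2B",
                              "B_only", "P_only")

# Known protein labels and the association-graph side each scheme expects
# (side A is the reference/Bassoon side).
_SCHEME_SIDES = {
    "bassoon_vgcc": ("bassoon", "vgcc"),
    "piccolo_bassoon": ("bassoon", "piccolo"),
}


class SchemeError(AzpunctError):
    """Association graph channels do not match the requested scheme."""


@dataclass
class AssociationGraph:
    """Bipartite association between puncta of two channels.

    Edges are (id_A, id_B, centroid_distance_nm, overlap_px) tuples; node
    id sets include unpaired puncta.
    """

    edges: list[tuple[int, int, float, int]]
    nodes_a: set[int]
    nodes_b: set[int]
    channel_a: str
    channel_b: str

    def __post_init__(self) -> None:
        for a, b, dist, _ in self.edges:
            if a not in self.nodes_a or b not in self.nodes_b:
                raise ValueError("edge references a punctum not in the node sets")
            if dist < 0:
                raise ValueError("distances must be nonnegative")

    def neighbors_of_a(self, a: int) -> list[int]:
        return [e[1] for e in self.edges if e[0] == a]

    def neighbors_of_b(self, b: int) -> list[int]:
        return [e[0] for e in self.edges if e[1] == b]


@dataclass
class ColocCategoryTable:
    scheme: str
    counts: dict[str, int]
    normalized: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (BASSOON_VGCC_CATEGORIES if self.scheme == "bassoon_vgcc"
                    else PICCOLO_BASSOON_CATEGORIES if self.scheme == "piccolo_bassoon"
                    else None)
        if expected is None:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if set(self.counts) != set(expected):
            raise ValueError(f"counts must cover exactly the categories {expected}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class SandwichMotifHit:
    bassoon_id: int
    piccolo_ids: tuple[int, int]
    flank_separation_nm: float
    flank_angle_deg: float


def _centroids(puncta: PunctaSet) -> dict[int, tuple[float, float]]:
    return {p.label: (p.centroid_x_nm, p.centroid_y_nm) for p in puncta.puncta}


def associate_puncta(set_a: PunctaSet, set_b: PunctaSet,
                     radius_nm: float = DEFAULT_ASSOCIATION_RADIUS_NM
                     ) -> AssociationGraph:
    """Associate puncta across channels by centroid distance OR pixel overlap.

    An edge (a, b) exists iff the centroid distance is <= ``radius_nm`` or
    the two labeled regions overlap in at least one pixel.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive")
    if set_a.pixel_size_nm != set_b.pixel_size_nm:
        raise ValueError("puncta sets have different pixel sizes")
    ca, cb = _centroids(set_a), _centroids(set_b)

    overlap: dict[tuple[int, int], int] = {}
    if set_a.label_image is not None and set_b.label_image is not None:
        if set_a.label_image.shape != set_b.label_image.shape:
            raise ValueError("puncta sets live on different pixel grids")
        both = (set_a.label_image > 0) & (set_b.label_image > 0)
        if both.any():
            pairs = np.stack([set_a.label_image[both], set_b.label_image[both]],
                             axis=1)
            uniq, n = np.unique(pairs, axis=0, return_counts=True)
            overlap = {(int(a), int(b)): int(k) for (a, b), k in zip(uniq, n)}

    edges: list[tuple[int, int, float, int]] = []
    for a, (ax, ay) in ca.items():
        for b, (bx, by) in cb.items():
            dist = math.hypot(ax - bx, ay - by)
            ov = overlap.get((a, b), 0)
            if dist <= radius_nm or ov >= 1:
                edges.append((a, b, dist, ov))
    return AssociationGraph(edges=edges, nodes_a=set(ca), nodes_b=set(cb),
                            channel_a=set_a.channel, channel_b=set_b.channel)


def _check_scheme(graph: AssociationGraph, scheme: str) -> None:
    want_a, want_b = _SCHEME_SIDES[scheme]
    known = {"bassoon", "piccolo", "vgcc"}
    a, b = graph.channel_a.lower(), graph.channel_b.lower()
    if a in known and a != want_a:
        raise SchemeError(f"scheme {scheme!r} expects channel A {want_a!r}, got {a!r}")
    if b in known and b != want_b:
        raise SchemeError(f"scheme {scheme!r} expects channel B {want_b!r}, got {b!r}")


def _degree_maps(graph: AssociationGraph) -> tuple[dict[int, list[int]],
                                                   dict[int, list[int]]]:
    adj_a: dict[int, list[int]] = {a: [] for a in graph.nodes_a}
    adj_b: dict[int, list[int]] = {b: [] for b in graph.nodes_b}
    for a, b, _, _ in graph.edges:
        adj_a[a].append(b)
        adj_b[b].append(a)
    return adj_a, adj_b


def assign_bassoon_vgcc(graph: AssociationGraph
                        ) -> tuple[dict[int, str], dict[int, str]]:
    """Per-punctum category assignment for the Bassoon-VGCC scheme.

    Returns (bassoon assignments, vgcc assignments); a VGCC punctum appears
    in the second map only when it is unpaired ("V_only").
    """
    _check_scheme(graph, "bassoon_vgcc")
    adj_a, adj_b = _degree_maps(graph)
    assign_a: dict[int, str] = {}
    for a in graph.nodes_a:
        d = len(adj_a[a])
        assign_a[a] = ("B_only" if d == 0 else "1V:1B" if d == 1
                       else "2V:1B" if d == 2 else ">=3V:1B")
    assign_b = {b: "V_only" for b in graph.nodes_b if len(adj_b[b]) == 0}
    return assign_a, assign_b


def categorize_bassoon_vgcc(graph: AssociationGraph) -> ColocCategoryTable:
    """Score each Bassoon punctum by its number of associated VGCC puncta.

    Categories: one, two, or three-plus VGCC per Bassoon; Bassoon with no
    VGCC partner; VGCC with no Bassoon partner.
    """
    assign_a, assign_b = assign_bassoon_vgcc(graph)
    counts = {c: 0 for c in BASSOON_VGCC_CATEGORIES}
    for cat in list(assign_a.values()) + list(assign_b.values()):
        counts[cat] += 1
    return ColocCategoryTable(scheme="bassoon_vgcc", counts=counts)


def assign_piccolo_bassoon(graph: AssociationGraph
                           ) -> tuple[dict[int, str], dict[int, str]]:
    """Per-punctum category assignment for the Piccolo-Bassoon scheme.

    A Piccolo punctum associated with exactly two Bassoon puncta is scored
    once as "1P:2B" (a flank shared between two sandwiches) and removed
    from those Bassoon puncta's degree counts before the Bassoon puncta
    are binned.  Returns (bassoon assignments, piccolo assignments); a
    Piccolo punctum appears in the second map when it is unpaired
    ("P_only") or shared ("1P:2B").
    """
    _check_scheme(graph, "piccolo_bassoon")
    adj_a, adj_b = _degree_maps(graph)
    shared = {b for b in graph.nodes_b if len(adj_b[b]) == 2}
    assign_b: dict[int, str] = {b: "1P:2B" for b in shared}
    assign_b.update({b: "P_only" for b in graph.nodes_b if len(adj_b[b]) == 0})
    assign_a: dict[int, str] = {}
    for a in graph.nodes_a:
        d = sum(1 for b in adj_a[a] if b not in shared)
        assign_a[a] = ("B_only" if d == 0 else "1P:1B" if d == 1
                       else "2P:1B" if d == 2 else ">=3P:1B")
    return assign_a, assign_b


def categorize_piccolo_bassoon(graph: AssociationGraph) -> ColocCategoryTable:
    """Score Bassoon puncta by associated Piccolo count, with a shared-flank
    category ("one Piccolo for two Bassoon"); isolated Piccolo are
    Piccolo-only."""
    assign_a, assign_b = assign_piccolo_bassoon(graph)
    counts = {c: 0 for c in PICCOLO_BASSOON_CATEGORIES}
    for cat in list(assign_a.values()) + list(assign_b.values()):
        counts[cat] += 1
    return ColocCategoryTable(scheme="piccolo_bassoon", counts=counts)


def normalize_category_counts(table: ColocCategoryTable) -> ColocCategoryTable:
    """Fill the normalized ratios (counts divided by the grand total)."""
    total = table.total
    if total == 0:
        raise ValueError("cannot normalize a table with zero total count")
    normalized = {c: n / total for c, n in table.counts.items()}
    return ColocCategoryTable(scheme=table.scheme, counts=dict(table.counts),
                              normalized=normalized)


def _angle_deg(bx: float, by: float, p1: tuple[float, float],
               p2: tuple[float, float]) -> float:
    v1 = (p1[0] - bx, p1[1] - by)
    v2 = (p2[0] - bx, p2[1] - by)
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def detect_sandwich(piccolo: PunctaSet, bassoon: PunctaSet,
                    graph: AssociationGraph,
                    min_sep_nm: float = DEFAULT_SANDWICH_MIN_SEP_NM,
                    max_sep_nm: float = DEFAULT_SANDWICH_MAX_SEP_NM,
                    min_angle_deg: float = DEFAULT_SANDWICH_MIN_ANGLE_DEG
                    ) -> list[SandwichMotifHit]:
    """Detect Piccolo-Bassoon-Piccolo flanking geometry.

    For every Bassoon punctum with at least two associated Piccolo puncta,
    all Piccolo pairs whose separation lies in [min_sep_nm, max_sep_nm] and
    whose Piccolo-Bassoon-Piccolo angle is at least ``min_angle_deg`` are
    candidates.  Candidates are accepted greedily by descending angle, each
    Bassoon yielding at most one hit and each Piccolo joining at most one
    hit, so the most collinear motifs win shared flanks.
    """
    _check_scheme(graph, "piccolo_bassoon")
    cp = _centroids(piccolo)
    cb = _centroids(bassoon)
    adj_a, _ = _degree_maps(graph)
    candidates: list[SandwichMotifHit] = []
    for a, partners in adj_a.items():
        if len(partners) < 2:
            continue
        bx, by = cb[a]
        for i in range(len(partners)):
            for j in range(i + 1, len(partners)):
                p1, p2 = partners[i], partners[j]
                sep = math.hypot(cp[p1][0] - cp[p2][0], cp[p1][1] - cp[p2][1])
                if not (min_sep_nm <= sep <= max_sep_nm):
                    continue
                angle = _angle_deg(bx, by, cp[p1], cp[p2])
                if angle < min_angle_deg:
                    continue
                candidates.append(SandwichMotifHit(
                    bassoon_id=a,
                    piccolo_ids=(min(p1, p2), max(p1, p2)),
                    flank_separation_nm=sep,
                    flank_angle_deg=angle,
                ))
    candidates.sort(key=lambda h: (-h.flank_angle_deg, h.bassoon_id, h.piccolo_ids))
    hits: list[SandwichMotifHit] = []
    used_b: set[int] = set()
    used_p: set[int] = set()
    for h in candidates:
        if h.bassoon_id in used_b or used_p.intersection(h.piccolo_ids):
            continue
        hits.append(h)
        used_b.add(h.bassoon_id)
        used_p.update(h.piccolo_ids)
    return hits
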