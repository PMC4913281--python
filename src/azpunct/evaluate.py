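"""Scoring pipeline output against simulator ground truth.

These helpers close the loop between the scene generator and the analysis
stages: they match segmented puncta to ground-truth puncta by centroid
proximity, derive the colocalization category each ground-truth punctum
ought to receive from its motif membership, and score category fidelity
and flanking-motif ("sandwich") detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .coloc import (
    AssociationGraph,
    SandwichMotifHit,
    assign_piccolo_bassoon,
)
from .core import PunctaSet
from .simgen import GroundTruthPunctum, SceneSpec

DEFAULT_MATCH_RADIUS_NM = 100.0


def match_to_truth(puncta: PunctaSet, truth: list[GroundTruthPunctum],
                   radius_nm: float = DEFAULT_MATCH_RADIUS_NM
                   ) -> dict[int, int]:
    """Greedy one-to-one matching of segmented puncta to ground truth.

    Pairs are accepted in order of increasing centroid distance up to
    ``radius_nm``.  Returns {segmented label -> ground-truth punctum_id}.
    """
    pairs = []
    for rec in puncta.puncta:
        for t in truth:
            d = math.hypot(rec.centroid_x_nm - t.x_nm, rec.centroid_y_nm - t.y_nm)
            if d <= radius_nm:
                pairs.append((d, rec.label, t.punctum_id))
    pairs.sort()
    used_seg: set[int] = set()
    used_truth: set[int] = set()
    out: dict[int, int] = {}
    for _, lab, tid in pairs:
        if lab in used_seg or tid in used_truth:
            continue
        out[lab] = tid
        used_seg.add(lab)
        used_truth.add(tid)
    return out


def expected_piccolo_bassoon_categories(scene: SceneSpec,
                                        bassoon_channel: str = "bassoon",
                                        piccolo_channel: str = "piccolo"
                                        ) -> dict[int, str]:
    """Category each ground-truth punctum should receive, from its motif.

    Covers scenes built from sandwich, coloc_pair and solitary motifs:
    a sandwich's center punctum should score "2P:1B", a colocalized pair's
    reference punctum "1P:1B", a solitary reference punctum "B_only" and a
    solitary partner punctum "P_only".  Flank and paired partner puncta
    carry no category of their own and are omitted.
    """
    out: dict[int, str] = {}
    for p in scene.puncta:
        if p.motif_role == "center":
            out[p.punctum_id] = "2P:1B"
        elif p.motif_role == "pair_member" and p.channel == bassoon_channel:
            out[p.punctum_id] = "1P:1B"
        elif p.motif_role == "solo":
            out[p.punctum_id] = ("B_only" if p.channel == bassoon_channel
                                 else "P_only")
    return out


@dataclass
class CategoryFidelity:
    n_scored: int
    n_matched: int

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_scored if self.n_scored else float("nan")


def score_category_fidelity(scene: SceneSpec, bassoon: PunctaSet,
                            piccolo: PunctaSet, graph: AssociationGraph
                            ) -> CategoryFidelity:
    """Fraction of category-carrying ground-truth puncta assigned their
    expected Piccolo-Bassoon category by the pipeline.

    A ground-truth punctum with no segmented match counts as a mismatch.
    """
    expected = expected_piccolo_bassoon_categories(scene)
    assign_a, assign_b = assign_piccolo_bassoon(graph)
    match_b = match_to_truth(bassoon, scene.puncta_in_channel(bassoon.channel))
    match_p = match_to_truth(piccolo, scene.puncta_in_channel(piccolo.channel))
    truth_to_seg_b = {tid: lab for lab, tid in match_b.items()}
    truth_to_seg_p = {tid: lab for lab, tid in match_p.items()}
    n_scored = n_matched = 0
    for tid, want in expected.items():
        n_scored += 1
        if want == "P_only":
            lab = truth_to_seg_p.get(tid)
            got = assign_b.get(lab) if lab is not None else None
        else:
            lab = truth_to_seg_b.get(tid)
            got = assign_a.get(lab) if lab is not None else None
        if got == want:
            n_matched += 1
    return CategoryFidelity(n_scored=n_scored, n_matched=n_matched)


@dataclass
class SandwichScore:
    n_true: int
    n_hits: int
    n_recovered: int
    n_false: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_true if self.n_true else float("nan")

    @property
    def false_discovery_rate(self) -> float:
        return self.n_false / self.n_hits if self.n_hits else 0.0


def score_sandwich_detection(scene: SceneSpec, bassoon: PunctaSet,
                             hits: list[SandwichMotifHit],
                             radius_nm: float = DEFAULT_MATCH_RADIUS_NM
                             ) -> SandwichScore:
    """Recall and false-discovery rate of sandwich detection.

    A hit is a true positive when its Bassoon punctum lies within
    ``radius_nm`` of a distinct ground-truth sandwich center.
    """
    centers = [(p.x_nm, p.y_nm) for p in scene.puncta
               if p.motif_role == "center" and p.channel == bassoon.channel]
    cb = {p.label: (p.centroid_x_nm, p.centroid_y_nm) for p in bassoon.puncta}
    recovered: set[int] = set()
    n_false = 0
    for h in hits:
        bx, by = cb[h.bassoon_id]
        dists = [math.hypot(bx - x, by - y) for x, y in centers]
        if dists and min(dists) <= radius_nm:
            idx = dists.index(min(dists))
            if idx in recovered:
                n_false += 1
            else:
                recovered.add(idx)
        else:
            n_false += 1
    return SandwichScore(n_true=len(centers), n_hits=len(hits),
                         n_recovered=len(recovered), n_false=n_false)
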