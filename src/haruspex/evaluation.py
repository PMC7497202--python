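"""Per-residue comparison of predicted class volumes against a reference model.

A residue's predicted class is the majority argmax class over the map voxels
within 3 A of its backbone atoms (mirroring the annotation radius). The
evaluation set consists of residues with mean backbone density >= 1 sigma
for which either the truth or the prediction is a structural class; true
negatives (unassigned on both sides) are not counted. Within that set:

* tp — truth is structural and the prediction matches it;
* fn — truth is structural but nothing was predicted (unassigned);
* fp — everything else: a wrong structural class, or a structural
  prediction where the truth is unassigned.

tp/fp/fn are reported as percentages of the evaluation set and converted to
recall = 100*tp/(tp+fn), precision = 100*tp/(tp+fp) and their harmonic mean
F1. A residue predicted with the wrong structural class counts as fp only
(not also fn), which keeps tp+fp+fn at 100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .map_io import DensityMap
from .model_annotation import CLASSES, Residue, ResidueLabels, StructuralModel
from .inference import PredictionVolume
from .voxel_labeling import residue_backbone_density

__all__ = [
    "EvaluationCounts",
    "residue_predicted_class",
    "evaluate",
    "evaluate_residue_classes",
    "per_map_report",
    "EVAL_RADIUS",
    "EVAL_DENSITY_GATE",
]

EVAL_RADIUS = 3.0        # A, around backbone atoms
EVAL_DENSITY_GATE = 1.0  # sigma, minimum mean backbone density


@dataclass
class EvaluationCounts:
    """tp/fp/fn percentages of the evaluation set plus derived metrics."""

    tp: float
    fp: float
    fn: float
    recall: float
    precision: float
    f1: float
    n_residues: int = 0

    @classmethod
    def from_counts(cls, tp: float, fp: float, fn: float,
                    n_residues: int = 0) -> "EvaluationCounts":
        """Derive recall/precision/F1 from tp/fp/fn (counts or percentages)."""
        recall = min(100.0, 100.0 * tp / (tp + fn)) if tp + fn > 0 else 0.0
        precision = min(100.0, 100.0 * tp / (tp + fp)) if tp + fp > 0 else 0.0
        f1 = (min(100.0, 2.0 * recall * precision / (recall + precision))
              if recall + precision > 0 else 0.0)
        return cls(tp=tp, fp=fp, fn=fn, recall=recall, precision=precision,
                   f1=f1, n_residues=n_residues)

    def as_dict(self) -> Dict[str, float]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "recall": self.recall, "precision": self.precision,
                "f1": self.f1, "n_residues": self.n_residues}


def residue_predicted_class(pv: PredictionVolume, residue: Residue,
                            dmap: DensityMap, radius: float = EVAL_RADIUS) -> str:
    """Majority argmax class over voxels within ``radius`` of the backbone.

    Ties resolve to the lowest channel index; a residue with no voxels in
    range (outside the map) reads as unassigned.
    """
    atoms = residue.backbone_atoms()
    if not atoms:
        return "unassigned"
    shape = pv.shape
    votes = np.zeros(len(CLASSES), dtype=np.int64)
    seen = set()
    r2 = radius ** 2
    for atom in atoms:
        los, his, dxs = [], [], []
        ok = True
        for ax in range(3):
            lo = int(np.ceil((atom[ax] - radius - pv.origin[ax]) / pv.voxel_size))
            hi = int(np.floor((atom[ax] + radius - pv.origin[ax]) / pv.voxel_size)) + 1
            lo, hi = max(lo, 0), min(hi, shape[ax])
            if lo >= hi:
                ok = False
                break
            los.append(lo)
            his.append(hi)
            dxs.append(pv.origin[ax] + np.arange(lo, hi) * pv.voxel_size - atom[ax])
        if not ok:
            continue
        d2 = (dxs[0] ** 2)[:, None, None] + (dxs[1] ** 2)[None, :, None] \
            + (dxs[2] ** 2)[None, None, :]
        sel = np.argwhere(d2 <= r2)
        for ix, iy, iz in sel:
            key = (ix + los[0], iy + los[1], iz + los[2])
            if key in seen:
                continue
            seen.add(key)
            votes[int(pv.probs[key].argmax())] += 1
    if votes.sum() == 0:
        return "unassigned"
    return CLASSES[int(votes.argmax())]


def evaluate_residue_classes(pairs: Sequence) -> EvaluationCounts:
    """tp/fp/fn percentages from (truth_class, predicted_class) pairs.

    Pairs where both sides are unassigned (true negatives) are dropped from
    the evaluation set. Feeding the truth as its own prediction therefore
    yields recall = precision = 100 by construction.
    """
    tp = fp = fn = 0
    n_eval = 0
    for t, p in pairs:
        if t == "unassigned" and p == "unassigned":
            continue
        n_eval += 1
        if t != "unassigned" and p == t:
            tp += 1
        elif t != "unassigned" and p == "unassigned":
            fn += 1
        else:
            fp += 1
    if n_eval == 0:
        raise ValueError("evaluation set is empty (no residues pass the gates)")
    scale = 100.0 / n_eval
    return EvaluationCounts.from_counts(tp * scale, fp * scale, fn * scale,
                                        n_residues=n_eval)


def evaluate(pv: PredictionVolume, model: StructuralModel, truth: ResidueLabels,
             dmap: DensityMap) -> EvaluationCounts:
    """Per-residue tp/fp/fn percentages for one map (sigma-normalized)."""
    pairs = []
    for res in model.polymer_residues():
        dens = residue_backbone_density(dmap, res)
        if dens is None or dens < EVAL_DENSITY_GATE:
            continue
        pairs.append((truth.get(res), residue_predicted_class(pv, res, dmap)))
    return evaluate_residue_classes(pairs)


def per_map_report(counts: Sequence[EvaluationCounts],
                   map_ids: Optional[Sequence[str]] = None) -> Dict:
    """Per-map table plus median recall/precision/F1 across maps."""
    if not counts:
        raise ValueError("need at least one map's counts")
    ids = list(map_ids) if map_ids is not None else [str(i) for i in range(len(counts))]
    report = {
        "per_map": {i: c.as_dict() for i, c in zip(ids, counts)},
        "median_recall": float(np.median([c.recall for c in counts])),
        "median_precision": float(np.median([c.precision for c in counts])),
        "median_f1": float(np.median([c.f1 for c in counts])),
    }
    return report


def report_to_json(report: Dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_tsv(report: Dict) -> str:
    lines = ["map\ttp\tfp\tfn\trecall\tprecision\tf1\tn_residues"]
    for map_id, c in report["per_map"].items():
        lines.append("\t".join([map_id] + [f"{c[k]:.2f}" for k in
                                           ("tp", "fp", "fn", "recall", "precision", "f1")]
                               + [str(c["n_residues"])]))
    return "\n".join(lines) + "\n"
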