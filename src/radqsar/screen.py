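"""Screening of newly designed compounds against activity thresholds.

Candidate compounds arrive as a descriptor table; each is scored by the
three GA-MLR equations (and optionally by the three trained networks), and
flagged when its predicted activities clear the design thresholds: more than
80% scavenging for the hydroxyl radical and superoxide anion (8.0 on the
percent/10 scale) and above 70% for DPPH (7.0). "More than" is strict:
a prediction exactly at the threshold fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ann import TrainedAnn, forward
from .data import DescriptorTable
from .errors import RadqsarError
from .stats import MlrModel, predict_linear

__all__ = ["ActivityThresholds", "ScreenResult", "ScreenReport",
           "published_equations", "screen_candidates", "screen_report"]

#: Coefficients of the three published GA-MLR equations for pyrrole
#: antioxidants (responses on the percent/10 scale):
#:   Y1 (hydroxyl radical) = -90.879 X17 - 47.988 X19 + 0.016 X20 + 207.384
#:   Y2 (superoxide anion) = -43.836 X19 + 0.005 X20 - 75.277 X21 + 47.527
#:   Y3 (DPPH)             =  61.220 X16 -  1.240 X26 + 0.052 X30 - 102.072
_PUBLISHED = {
    "Y1": (("X17", "X19", "X20"), (-90.879, -47.988, 0.016), 207.384),
    "Y2": (("X19", "X20", "X21"), (-43.836, 0.005, -75.277), 47.527),
    "Y3": (("X16", "X26", "X30"), (61.220, -1.240, 0.052), -102.072),
}


def published_equations() -> dict[str, MlrModel]:
    """The three published regression equations as :class:`MlrModel` records."""
    return {rid: MlrModel(ids, coefs, intercept, rid)
            for rid, (ids, coefs, intercept) in _PUBLISHED.items()}


@dataclass(frozen=True)
class ActivityThresholds:
    """Pass thresholds on the percent/10 scale (defaults: 80%/80%/70%)."""

    oh_min: float = 8.0
    o2_min: float = 8.0
    dpph_min: float = 7.0

    def __post_init__(self) -> None:
        for name in ("oh_min", "o2_min", "dpph_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise RadqsarError(f"{name} must be on the percent/10 scale "
                                   f"[0, 10], got {v}")

    @classmethod
    def from_percent(cls, oh: float, o2: float, dpph: float
                     ) -> "ActivityThresholds":
        return cls(oh / 10.0, o2 / 10.0, dpph / 10.0)

    def flags(self, y1: float, y2: float, y3: float) -> dict[str, bool]:
        """Strictly-greater pass flags per activity, plus the combined
        radical-pair rule (both hydroxyl and superoxide above threshold)."""
        oh, o2, dpph = y1 > self.oh_min, y2 > self.o2_min, y3 > self.dpph_min
        return {"oh": oh, "o2": o2, "dpph": dpph, "radical_pair": oh and o2}


@dataclass(frozen=True)
class ScreenResult:
    """Predictions and pass flags for one candidate compound."""

    compound_id: str
    mlr_predictions: tuple[float, float, float]
    ann_predictions: tuple[float, float, float] | None
    passes_mlr: dict[str, bool]
    passes_ann: dict[str, bool] | None
    passes_both: dict[str, bool] | None


@dataclass
class ScreenReport:
    """Ranked screening table with per-activity pass counts."""

    results: list[ScreenResult]
    counts_mlr: dict[str, int] = field(default_factory=dict)
    counts_ann: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"compound": r.compound_id,
                   "mlr_y1": r.mlr_predictions[0],
                   "mlr_y2": r.mlr_predictions[1],
                   "mlr_y3": r.mlr_predictions[2]}
            if r.ann_predictions is not None:
                row.update(ann_y1=r.ann_predictions[0],
                           ann_y2=r.ann_predictions[1],
                           ann_y3=r.ann_predictions[2])
            row.update({f"mlr_pass_{k}": v for k, v in r.passes_mlr.items()})
            if r.passes_ann is not None:
                row.update({f"ann_pass_{k}": v for k, v in r.passes_ann.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def screen_candidates(candidates: DescriptorTable,
                      mlr_models: dict[str, MlrModel] | None = None,
                      ann_models: dict[str, TrainedAnn] | None = None,
                      thresholds: ActivityThresholds | None = None
                      ) -> list[ScreenResult]:
    """Predict the three activities for every candidate and evaluate the
    pass rules for each model family. ``passes_both`` requires agreement
    (both MLR and network predictions clear the threshold) and is None when
    no networks are supplied."""
    mlr_models = mlr_models or published_equations()
    thresholds = thresholds or ActivityThresholds()
    for rid in ("Y1", "Y2", "Y3"):
        if rid not in mlr_models:
            raise RadqsarError(f"missing regression model for {rid}")

    mlr_pred = {rid: predict_linear(mlr_models[rid], candidates)
                for rid in ("Y1", "Y2", "Y3")}
    ann_pred = None
    if ann_models is not None:
        for rid in ("Y1", "Y2", "Y3"):
            if rid not in ann_models:
                raise RadqsarError(f"missing network model for {rid}")
        ann_pred = {rid: forward(ann_models[rid], candidates)
                    for rid in ("Y1", "Y2", "Y3")}

    results = []
    for i, cid in enumerate(candidates.compound_ids):
        m = tuple(float(mlr_pred[rid][i]) for rid in ("Y1", "Y2", "Y3"))
        pm = thresholds.flags(*m)
        a = pa = pb = None
        if ann_pred is not None:
            a = tuple(float(ann_pred[rid][i]) for rid in ("Y1", "Y2", "Y3"))
            pa = thresholds.flags(*a)
            pb = {k: pm[k] and pa[k] for k in pm}
        results.append(ScreenResult(cid, m, a, pm, pa, pb))
    return results


def screen_report(results: list[ScreenResult]) -> ScreenReport:
    """Rank results by predicted hydroxyl-radical activity (descending, ties
    by compound id) and count candidates clearing each threshold."""
    ordered = sorted(results,
                     key=lambda r: (-r.mlr_predictions[0], r.compound_id))
    keys = ("oh", "o2", "dpph", "radical_pair")
    counts_mlr = {k: sum(r.passes_mlr[k] for r in ordered) for k in keys}
    counts_ann = {}
    if ordered and ordered[0].passes_ann is not None:
        counts_ann = {k: sum(r.passes_ann[k] for r in ordered) for k in keys}
    return ScreenReport(results=ordered, counts_mlr=counts_mlr,
                        counts_ann=counts_ann)
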