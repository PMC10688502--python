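"""Confusion-matrix statistics and jackknife curves for ranked predictions."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "Measures",
    "JackknifeCurve",
    "confusion",
    "measures",
    "jackknife",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Measures:
    """SN, SP, PPV, NPV, F (harmonic mean of SN and PPV) and ACC."""

    sn: float
    sp: float
    ppv: float
    npv: float
    f: float
    acc: float

    def as_dict(self) -> dict[str, float]:
        return {"SN": self.sn, "SP": self.sp, "PPV": self.ppv,
                "NPV": self.npv, "F": self.f, "ACC": self.acc}


@dataclass
class JackknifeCurve:
    """Cumulative true-positive count over ranks 1..n."""

    cumulative_tp: list[int]


def _ranking_of(prediction) -> Sequence[str]:
    return getattr(prediction, "ranking", prediction)


def confusion(prediction, essentials: set[str],
              universe: set[str]) -> ConfusionCounts:
    """Confusion counts of a prediction against the gold standard.

    The universe is the cleaned PPI node set; gold-standard proteins
    outside it are ignored (with a logged count).
    """
    pred = set(_ranking_of(prediction))
    if not pred <= universe:
        raise ValueError("prediction contains proteins outside the universe")
    outside = len(essentials - universe)
    if outside:
        logger.info("confusion: %d gold-standard proteins outside the network",
                    outside)
    ess = essentials & universe
    if not ess:
        logger.warning("confusion: no gold-standard protein in the universe; "
                       "measures are degenerate")
    tp = len(pred & ess)
    fp = len(pred) - tp
    fn = len(ess - pred)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def measures(c: ConfusionCounts) -> Measures:
    """Six standard measures; any 0/0 is defined as 0."""
    sn = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    f = 2 * sn * ppv / (sn + ppv) if (sn + ppv) > 0 else 0.0
    acc = _ratio(c.tp + c.tn, c.total)
    return Measures(sn=sn, sp=sp, ppv=ppv, npv=npv, f=f, acc=acc)


def jackknife(prediction, essentials: Iterable[str]) -> JackknifeCurve:
    """Cumulative essentials among the top-r predictions, r = 1..n."""
    ess = set(essentials)
    out: list[int] = []
    count = 0
    for v in _ranking_of(prediction):
        count += v in ess
        out.append(count)
    return JackknifeCurve(cumulative_tp=out)
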