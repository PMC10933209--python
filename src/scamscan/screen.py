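"""Descriptor-threshold baseline screens for colloidal aggregation.

Fast single-descriptor classifiers — the baselines an MD-based
aggregation call competes against.  The flagship rule is "aggregation
occurs when logD > 3": the octanol/water distribution coefficient at
assay pH captures effective hydrophobicity after ionisation, and
discriminates aggregators better than logP (which over-calls ionisable
compounds) or the amphiphilic-moment descriptor vsurf_A.

Input is a labelled CSV with header ``id,logp,logd,vsurf_a,tpsa,label``
(``tpsa`` optional, label ``aggregator``/``non-aggregator``).  Screens
report per-compound predictions, the success rate against experimental
labels, and the misclassified ids; `compare_methods` lines several
screens (including MD-derived calls) up side by side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .metrics import AGGREGATOR, NON_AGGREGATOR, AggregationReport

__all__ = [
    "CompoundRecord",
    "ScreenResult",
    "read_compound_table",
    "threshold_classify",
    "success_rate",
    "md_calls_from_table",
    "compare_methods",
]

_LABELS = (AGGREGATOR, NON_AGGREGATOR)
_DESCRIPTORS = ("logp", "logd", "vsurf_a", "tpsa")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's descriptors plus its experimental call."""

    id: str
    logp: float | None = None
    logd: float | None = None
    vsurf_a: float | None = None
    tpsa: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        for name in _DESCRIPTORS:
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{self.id}: descriptor {name} is not finite")
        if self.label is not None and self.label not in _LABELS:
            raise ValueError(f"{self.id}: unknown label {self.label!r}")

    def descriptor(self, name: str) -> float | None:
        if name not in _DESCRIPTORS:
            raise KeyError(
                f"unknown descriptor {name!r}; available: {list(_DESCRIPTORS)}"
            )
        return getattr(self, name)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one threshold screen over a compound table."""

    method: str
    predictions: dict[str, str]  # id -> predicted label
    success_rate_percent: float | None
    misclassified: tuple[str, ...]
    skipped: tuple[str, ...] = ()  # ids lacking the descriptor
    confusion: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "success_rate_percent": self.success_rate_percent,
            "misclassified": list(self.misclassified),
            "skipped": list(self.skipped),
            "confusion": self.confusion,
            "predictions": self.predictions,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Load a labelled descriptor CSV (columns id,logp,logd,vsurf_a,tpsa,label)."""
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'id'")
    records = []
    for row in df.to_dict("records"):
        def _num(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        label = row.get("label")
        if isinstance(label, str):
            label = label.strip().lower()
        elif label is not None and not isinstance(label, str):
            label = None
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                logp=_num("logp"),
                logd=_num("logd"),
                vsurf_a=_num("vsurf_a"),
                tpsa=_num("tpsa"),
                label=label,
            )
        )
    if not records:
        raise ValueError(f"{path}: empty compound table")
    return records


def threshold_classify(
    records: Sequence[CompoundRecord],
    descriptor: str = "logd",
    threshold: float = 3.0,
    direction: str = "greater_means_aggregator",
    inclusive: bool = False,
) -> ScreenResult:
    """Single-descriptor threshold screen.

    With the default strict ``greater_means_aggregator`` rule a
    compound is called an aggregator iff ``descriptor > threshold`` —
    a value exactly at the threshold (e.g. logD = 3.0 under the
    "logD > 3" rule) is a non-aggregator.  Records lacking the
    descriptor are excluded and reported in ``skipped``.
    """
    if direction not in ("greater_means_aggregator", "less_means_aggregator"):
        raise ValueError(f"unknown direction {direction!r}")
    if records and descriptor not in _DESCRIPTORS:
        raise KeyError(
            f"unknown descriptor {descriptor!r}; available: {list(_DESCRIPTORS)}"
        )
    predictions: dict[str, str] = {}
    skipped: list[str] = []
    for rec in records:
        value = rec.descriptor(descriptor)
        if value is None:
            skipped.append(rec.id)
            continue
        if direction == "greater_means_aggregator":
            hit = value >= threshold if inclusive else value > threshold
        else:
            hit = value <= threshold if inclusive else value < threshold
        predictions[rec.id] = AGGREGATOR if hit else NON_AGGREGATOR

    labelled = [r for r in records if r.label is not None and r.id in predictions]
    if labelled:
        rate, missed = success_rate(
            [predictions[r.id] for r in labelled],
            [r.label for r in labelled],
            ids=[r.id for r in labelled],
        )
        confusion = _confusion(
            [predictions[r.id] for r in labelled], [r.label for r in labelled]
        )
    else:
        rate, missed, confusion = None, (), {}
    op = ">" if direction == "greater_means_aggregator" else "<"
    if inclusive:
        op += "="
    return ScreenResult(
        method=f"{descriptor} {op} {threshold:g}",
        predictions=predictions,
        success_rate_percent=rate,
        misclassified=tuple(missed),
        skipped=tuple(skipped),
        confusion=confusion,
    )


def _confusion(predicted: Sequence[str], truth: Sequence[str]) -> dict[str, int]:
    keys = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for p, t in zip(predicted, truth):
        if t == AGGREGATOR:
            keys["tp" if p == AGGREGATOR else "fn"] += 1
        else:
            keys["fp" if p == AGGREGATOR else "tn"] += 1
    return keys


def success_rate(
    predicted: Sequence[str],
    truth: Sequence[str],
    ids: Sequence[str] | None = None,
) -> tuple[float, tuple[str, ...]]:
    """Percentage of matching calls, to one decimal, plus misclassified ids.

    31 correct of 32 reports 96.9 (the figure usually quoted rounded
    to 97).
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} labels"
        )
    if not predicted:
        raise ValueError("need at least one prediction/label pair")
    if ids is None:
        ids = [str(i) for i in range(len(predicted))]
    missed = tuple(i for i, p, t in zip(ids, predicted, truth) if p != t)
    rate = round(100.0 * (len(predicted) - len(missed)) / len(predicted), 1)
    return rate, missed


def md_calls_from_table(
    path: str | Path, threshold: float = 20.0
) -> dict[str, str]:
    """MD aggregation calls from an ``md_fc5`` column in a compound CSV.

    Convenience for comparison tables when precomputed fC_5 values are
    stored alongside descriptors; a compound is called an aggregator
    when its fC_5 meets the threshold (percent).
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "md_fc5" not in df.columns:
        raise ValueError(f"{path}: no md_fc5 column")
    return {
        str(r["id"]): (AGGREGATOR if float(r["md_fc5"]) >= threshold else NON_AGGREGATOR)
        for _, r in df.iterrows()
        if not math.isnan(float(r["md_fc5"]))
    }


def compare_methods(
    methods: Mapping[str, Mapping[str, str] | Sequence[AggregationReport] | ScreenResult],
    truth: Mapping[str, str],
) -> pd.DataFrame:
    """Per-compound agreement table across prediction methods.

    ``methods`` maps a method name to its predictions: a ``{id: label}``
    mapping, a :class:`ScreenResult`, or a sequence of MD
    :class:`AggregationReport` objects (keyed by ``compound_id``).
    Returns a DataFrame with one row per compound (union of ids present
    in the truth labels), one column per method plus the experimental
    label; unscored compounds are marked ``not-scored``.  A summary row
    ``__success_rate__`` holds each method's success percentage over
    the compounds it scored.
    """
    norm: dict[str, dict[str, str]] = {}
    for name, preds in methods.items():
        if isinstance(preds, ScreenResult):
            norm[name] = dict(preds.predictions)
        elif isinstance(preds, Mapping):
            norm[name] = dict(preds)
        else:
            norm[name] = {
                r.compound_id: r.label for r in preds if r.compound_id is not None
            }
    shared = set(truth) & set().union(*(set(p) for p in norm.values()))
    if not shared:
        raise ValueError("no compound ids shared between methods and truth labels")

    rows = {}
    for cid in sorted(truth):
        rows[cid] = {"experimental": truth[cid]}
        for name, preds in norm.items():
            rows[cid][name] = preds.get(cid, "not-scored")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"

    summary = {"experimental": ""}
    for name, preds in norm.items():
        scored = [cid for cid in truth if cid in preds]
        if scored:
            rate, _ = success_rate(
                [preds[c] for c in scored], [truth[c] for c in scored], ids=scored
            )
            summary[name] = f"{rate:.1f}"
        else:
            summary[name] = "not-scored"
    df.loc["__success_rate__"] = summary
    return df
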