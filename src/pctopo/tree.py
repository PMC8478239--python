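"""The published decision-rule cascade for chaperone responsiveness.

The tree was originally trained on a Fabry-disease responsiveness dataset
and is encoded here verbatim as a fixed rule cascade — it is not refit.
Reading order of the nodes:

1. ΔΔG ≥ 1.7 kcal/mol            → non-responsive  (leaf ``root_destab``)
2. residue contacts the ligand    → non-responsive  (leaf ``ligand``)
3. few contacts (< 4)             → responsive      (leaf ``small_contacts``)
4. ΔΔG ≤ −1.4 kcal/mol            → non-responsive  (leaf ``over_stabilized``)
5. ΔΔG < 0.94 kcal/mol            → responsive      (leaf ``mid_ddg``)
6. many inverse-parallel
   relations (≥ 100)              → non-responsive  (leaf ``pinv_high``)
   otherwise                      → responsive      (leaf ``pinv_low``)

Published leaf probabilities of responsiveness (p1) exist for three leaves:
small_contacts 0.60, root_destab 0.28, pinv_high 0.34. The remaining four
leaves have no published p1; they default to the class-typical published
values (0.60 responsive / 0.28 non-responsive) and are configurable —
treat those four numbers as placeholders, not published results.

The contacts threshold (4) and inverse-parallel threshold (100) are
likewise not published; the worked examples only pin them to (3, 5] and
[1, 219] respectively. Both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from pctopo.metrics import ConfusionTable, mcc


@dataclass(frozen=True)
class TreeThresholds:
    ddg_high: float = 1.7  # kcal/mol; ≥ → non-responsive at the root
    ddg_mid: float = 0.94  # kcal/mol; < → responsive at node 5
    ddg_low: float = -1.4  # kcal/mol; ≤ → non-responsive (over-stabilised)
    contacts_small: int = 4  # strict less-than → responsive
    pinv_high: int = 100  # ≥ → non-responsive

    def __post_init__(self):
        if not self.ddg_low < self.ddg_mid < self.ddg_high:
            raise ValueError("need ddg_low < ddg_mid < ddg_high")
        if self.contacts_small < 1 or self.pinv_high < 1:
            raise ValueError("count thresholds must be >= 1")


#: leaves and their class; p1 = probability of the responsive class
LEAF_CLASSES = {
    "root_destab": False,
    "ligand": False,
    "small_contacts": True,
    "over_stabilized": False,
    "mid_ddg": True,
    "pinv_high": False,
    "pinv_low": True,
}


@dataclass(frozen=True)
class LeafTable:
    """p1 (responsive-class probability) per leaf.

    Published values: small_contacts 0.60, root_destab 0.28, pinv_high
    0.34. The other four default to class-typical values and carry no
    published support.
    """

    p1: Mapping[str, float] = field(default_factory=lambda: {
        "root_destab": 0.28,
        "ligand": 0.28,
        "small_contacts": 0.60,
        "over_stabilized": 0.28,
        "mid_ddg": 0.60,
        "pinv_high": 0.34,
        "pinv_low": 0.60,
    })

    def __post_init__(self):
        missing = set(LEAF_CLASSES) - set(self.p1)
        if missing:
            raise ValueError(f"leaf table missing leaves: {sorted(missing)}")
        for leaf, p in self.p1.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"leaf {leaf}: p1 {p} outside [0, 1]")


@dataclass(frozen=True)
class Prediction:
    label: bool  # True = responsive
    p1: float
    leaf_id: str
    trace: tuple[str, ...]


_REQUIRED = ("ddg", "binds_ligand", "n_contacts", "p_inv")


def predict(features: Mapping, thresholds: TreeThresholds = TreeThresholds(),
            leaves: LeafTable = LeafTable()) -> Prediction:
    """Run one feature vector through the rule cascade.

    ``features`` is any mapping (dict, Series, dataclass asdict) with keys
    ddg, binds_ligand, n_contacts, p_inv.
    """
    for key in _REQUIRED:
        if key not in features or features[key] is None or (
                isinstance(features[key], float) and math.isnan(features[key])):
            raise ValueError(f"missing required feature: {key}")
    ddg = float(features["ddg"])
    lig = bool(features["binds_ligand"])
    n_contacts = int(features["n_contacts"])
    p_inv = int(features["p_inv"])
    t = thresholds
    trace = []

    trace.append(f"ddg {ddg} >= {t.ddg_high}? {'yes' if ddg >= t.ddg_high else 'no'}")
    if ddg >= t.ddg_high:
        leaf = "root_destab"
    else:
        trace.append(f"binds_ligand? {'yes' if lig else 'no'}")
        if lig:
            leaf = "ligand"
        else:
            trace.append(f"n_contacts {n_contacts} < {t.contacts_small}? "
                         f"{'yes' if n_contacts < t.contacts_small else 'no'}")
            if n_contacts < t.contacts_small:
                leaf = "small_contacts"
            else:
                trace.append(f"ddg {ddg} <= {t.ddg_low}? {'yes' if ddg <= t.ddg_low else 'no'}")
                if ddg <= t.ddg_low:
                    leaf = "over_stabilized"
                else:
                    trace.append(f"ddg {ddg} < {t.ddg_mid}? {'yes' if ddg < t.ddg_mid else 'no'}")
                    if ddg < t.ddg_mid:
                        leaf = "mid_ddg"
                    else:
                        trace.append(f"p_inv {p_inv} >= {t.pinv_high}? "
                                     f"{'yes' if p_inv >= t.pinv_high else 'no'}")
                        leaf = "pinv_high" if p_inv >= t.pinv_high else "pinv_low"
    return Prediction(
        label=LEAF_CLASSES[leaf],
        p1=leaves.p1[leaf],
        leaf_id=leaf,
        trace=tuple(trace),
    )


def predict_batch(table: pd.DataFrame, thresholds: TreeThresholds = TreeThresholds(),
                  leaves: LeafTable = LeafTable()) -> pd.DataFrame:
    """Row-wise predict over a feature table; order preserved.

    Per-row failures are collected and reported together.
    """
    rows, errors = [], []
    for idx, row in table.iterrows():
        try:
            p = predict(row, thresholds, leaves)
            rows.append({
                "variant": row.get("variant", idx),
                "responsive": p.label, "p1": p.p1, "leaf_id": p.leaf_id,
                "trace": " | ".join(p.trace),
            })
        except Exception as exc:  # noqa: BLE001 - aggregate per-row errors
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ValueError("prediction failed for some rows:\n" + "\n".join(errors))
    if not rows:
        return pd.DataFrame(columns=["variant", "responsive", "p1", "leaf_id", "trace"])
    return pd.DataFrame(rows, index=table.index)


def evaluate(predictions: Sequence[bool], labels: Sequence[bool]) -> dict:
    """Accuracy summary: n, n_correct, confusion counts, and MCC (NaN when
    only one observed class is present)."""
    if len(predictions) != len(labels):
        raise ValueError(f"length mismatch: {len(predictions)} predictions, {len(labels)} labels")
    preds = [bool(p) for p in predictions]
    obs = [bool(l) for l in labels]
    table = ConfusionTable(
        tp=sum(p and o for p, o in zip(preds, obs)),
        fp=sum(p and not o for p, o in zip(preds, obs)),
        tn=sum(not p and not o for p, o in zip(preds, obs)),
        fn=sum(not p and o for p, o in zip(preds, obs)),
    )
    both_classes = len(set(obs)) == 2
    return {
        "n": len(obs),
        "n_correct": table.tp + table.tn,
        "confusion": table,
        "mcc": mcc(table) if both_classes else float("nan"),
    }
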