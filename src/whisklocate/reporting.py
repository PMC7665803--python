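"""Population classification ledger and proportion tables.

Collects per-neuron analysis flags into a single table, checks the
partitions are consistent (silent/active, touch/non-touch,
location/non-location, whisking-tuning classes), and reports the
proportions used throughout the population summaries, split by training
condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LEDGER_COLUMNS = [
    "neuron_id", "depth", "condition", "active", "putative_excitatory",
    "touch_unit", "location_tuned", "angle_tuned_whisking",
    "phase_tuned_whisking", "co_tuned",
]


@dataclass
class PopulationLedger:
    table: pd.DataFrame
    proportions: dict

    def __len__(self) -> int:
        return len(self.table)


def classify_population(rows: list[dict]) -> PopulationLedger:
    """Build the classification ledger from per-neuron result dicts.

    Each row needs ``neuron_id`` and whichever flags were computed; missing
    flags default to False (``active`` defaults to spikes > 0 if a
    ``total_spikes`` field is present).  Raises if a neuron violates the
    partition invariants (e.g. location tuned but not a touch unit).
    """
    if not rows:
        raise ValueError("no neurons to classify")
    recs = []
    missing = [r.get("neuron_id", "?") for r in rows if "neuron_id" not in r]
    if missing:
        raise ValueError(f"rows without neuron_id: {missing}")
    for r in rows:
        active = bool(r.get("active",
                            r.get("total_spikes", 1) > 0))
        rec = dict(
            neuron_id=r["neuron_id"],
            depth=float(r.get("depth", np.nan)),
            condition=r.get("condition", "naive"),
            active=active,
            putative_excitatory=bool(r.get("putative_excitatory", True)),
            touch_unit=bool(r.get("touch_unit", False)) and active,
            location_tuned=bool(r.get("location_tuned", False)) and active,
            angle_tuned_whisking=bool(r.get("angle_tuned_whisking", False)) and active,
            phase_tuned_whisking=bool(r.get("phase_tuned_whisking", False)) and active,
        )
        rec["co_tuned"] = rec["angle_tuned_whisking"] and rec["phase_tuned_whisking"]
        if rec["location_tuned"] and not rec["touch_unit"]:
            raise ValueError(
                f"{rec['neuron_id']}: location_tuned without touch_unit")
        recs.append(rec)
    table = pd.DataFrame(recs, columns=LEDGER_COLUMNS)

    act = table[table["active"] & table["putative_excitatory"]]
    n_active = len(act)
    props: dict = {
        "n_total": len(table),
        "n_silent": int((~table["active"]).sum()),
        "n_active": n_active,
    }
    if n_active:
        props.update(
            touch_unit_pct=100 * act["touch_unit"].mean(),
            location_tuned_pct=100 * act["location_tuned"].mean(),
            angle_tuned_whisking_pct=100 * act["angle_tuned_whisking"].mean(),
            phase_tuned_whisking_pct=100 * act["phase_tuned_whisking"].mean(),
        )
        n_touch = int(act["touch_unit"].sum())
        props["location_tuned_of_touch_pct"] = (
            100 * act["location_tuned"].sum() / n_touch if n_touch else np.nan)
        for cond, sub in act.groupby("condition"):
            nt = int(sub["touch_unit"].sum())
            props[f"{cond}_n"] = len(sub)
            props[f"{cond}_touch_units"] = nt
            props[f"{cond}_location_tuned_of_touch_pct"] = (
                100 * sub["location_tuned"].sum() / nt if nt else np.nan)
    _check_partitions(table)
    return PopulationLedger(table=table, proportions=props)


def _check_partitions(table: pd.DataFrame) -> None:
    n = len(table)
    assert int(table["active"].sum()) + int((~table["active"]).sum()) == n
    bad = table["location_tuned"] & ~table["touch_unit"]
    if bad.any():
        raise ValueError("partition violation: location_tuned but not touch_unit")
    bad = table["co_tuned"] & ~(table["angle_tuned_whisking"]
                                & table["phase_tuned_whisking"])
    if bad.any():
        raise ValueError("partition violation: co_tuned flags inconsistent")
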