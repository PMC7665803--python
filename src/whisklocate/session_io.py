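"""Session bundle types and the plain-CSV on-disk session format.

A *session* is one neuron recorded across many trials of the pole
localization task.  All downstream analysis consumes :class:`SessionBundle`
objects; nothing else in the package touches raw files.

Conventions (fixed here, documented in docs/methods.md):

* times are milliseconds from trial start, 0-based sample indexing;
* whisker angle in degrees, sampled at 1 kHz (one sample per ms);
* pole locations in mm, with 0 = most posterior presented position;
* on disk, a session is a directory of CSV tables plus ``metadata.txt``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLING_RATE = 1000.0  # Hz; whisker video frame rate

OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection", "none")
CONDITIONS = ("naive", "trained")

_TABLES = ("trials.csv", "touches.csv", "spikes.csv", "whisker.csv")


class SessionFormatError(Exception):
    """A session directory is missing a table or a required column."""


class SessionValidationError(Exception):
    """A bundle violates a structural invariant; names the trial and field."""


@dataclass
class TouchEvent:
    """One pole contact, times in ms from trial start."""

    onset: float
    offset: float
    angle_at_touch: float
    max_curvature_change: float
    direction: str = "protraction"


@dataclass
class Trial:
    """One trial of the localization task.

    ``pole_onset``/``sampling_period``/``answer_period`` are in seconds and
    default to the task structure (0.5 s pre-pole, 0.75 s sampling, 1.25 s
    answer).
    """

    pole_location: float
    touches: list[TouchEvent] = field(default_factory=list)
    licked: bool = False
    outcome: str = "none"
    pole_onset: float = 0.5
    sampling_period: float = 0.75
    answer_period: float = 1.25

    @property
    def duration_ms(self) -> int:
        return int(round((self.pole_onset + self.sampling_period + self.answer_period) * 1000))


@dataclass
class SessionBundle:
    """One neuron's session: trials, spikes, and the whisker trace.

    ``spike_times[i]`` is an array of spike times (ms) for trial ``i``;
    ``whisker_angle[i]`` is the 1-kHz angle series (degrees) of length
    ``trials[i].duration_ms``; ``mask_flags[i]`` marks samples with a valid
    whisker trace (False near the fur mask).
    """

    session_id: str
    neuron_depth: float  # um from pia
    condition: str  # "naive" | "trained"
    trials: list[Trial]
    spike_times: list[np.ndarray]
    whisker_angle: list[np.ndarray]
    mask_flags: list[np.ndarray]
    sampling_rate: float = SAMPLING_RATE

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def all_touches(self) -> list[tuple[int, TouchEvent]]:
        """(trial index, touch) pairs in session order."""
        return [(i, tc) for i, tr in enumerate(self.trials) for tc in tr.touches]

    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_times))

    def validate(self) -> None:
        """Check every structural invariant; raise SessionValidationError."""
        if self.sampling_rate != SAMPLING_RATE:
            raise SessionValidationError(
                f"session {self.session_id}: sampling_rate must be "
                f"{SAMPLING_RATE}, got {self.sampling_rate}")
        if self.condition not in CONDITIONS:
            raise SessionValidationError(
                f"session {self.session_id}: condition {self.condition!r}")
        n = self.n_trials
        for name, seq in (("spike_times", self.spike_times),
                          ("whisker_angle", self.whisker_angle),
                          ("mask_flags", self.mask_flags)):
            if len(seq) != n:
                raise SessionValidationError(
                    f"session {self.session_id}: {name} has {len(seq)} "
                    f"entries for {n} trials")
        for i, tr in enumerate(self.trials):
            dur = tr.duration_ms
            if tr.outcome not in OUTCOMES:
                raise SessionValidationError(f"trial {i}: outcome {tr.outcome!r}")
            if len(self.whisker_angle[i]) != dur:
                raise SessionValidationError(
                    f"trial {i}: whisker_angle length {len(self.whisker_angle[i])}"
                    f" != duration {dur} ms")
            if len(self.mask_flags[i]) != dur:
                raise SessionValidationError(
                    f"trial {i}: mask_flags length {len(self.mask_flags[i])}")
            sp = np.asarray(self.spike_times[i])
            if sp.size and (sp.min() < 0 or sp.max() > dur):
                raise SessionValidationError(
                    f"trial {i}: spike_times outside [0, {dur}] ms")
            prev_off = -np.inf
            for j, tc in enumerate(tr.touches):
                if not tc.offset > tc.onset:
                    raise SessionValidationError(
                        f"trial {i}: touches[{j}] offset <= onset")
                if tc.onset < prev_off:
                    raise SessionValidationError(
                        f"trial {i}: touches[{j}] overlaps or is out of order")
                if tc.onset < 0 or tc.offset > dur:
                    raise SessionValidationError(
                        f"trial {i}: touches[{j}] outside trial")
                if not np.isfinite(tc.angle_at_touch):
                    raise SessionValidationError(
                        f"trial {i}: touches[{j}] angle_at_touch not finite")
                prev_off = tc.offset

    def has_tracked_whisker(self, trial: int) -> bool:
        """Trials with no valid whisker samples stay in the bundle but are
        excluded from kinematic analyses."""
        return bool(np.any(self.mask_flags[trial]))


def write_session(bundle: SessionBundle, path: str | os.PathLike) -> None:
    """Write a validated bundle as a directory of CSV tables.

    Layout: ``metadata.txt`` (key: value), ``trials.csv``, ``touches.csv``,
    ``spikes.csv``, ``whisker.csv``.  Floats are written at full precision so
    write -> read -> write is byte-identical.
    """
    bundle.validate()
    os.makedirs(path, exist_ok=True)
    p = os.fspath(path)

    with open(os.path.join(p, "metadata.txt"), "w") as fh:
        fh.write(f"session_id: {bundle.session_id}\n")
        fh.write(f"neuron_depth: {bundle.neuron_depth!r}\n")
        fh.write(f"condition: {bundle.condition}\n")
        fh.write(f"sampling_rate: {bundle.sampling_rate!r}\n")

    trows, crows, srows, wrows = [], [], [], []
    for i, tr in enumerate(bundle.trials):
        trows.append(dict(trial=i, pole_location=tr.pole_location,
                          pole_onset=tr.pole_onset,
                          sampling_period=tr.sampling_period,
                          answer_period=tr.answer_period,
                          licked=int(tr.licked), outcome=tr.outcome))
        for j, tc in enumerate(tr.touches):
            crows.append(dict(trial=i, touch=j, onset=tc.onset, offset=tc.offset,
                              angle_at_touch=tc.angle_at_touch,
                              max_curvature_change=tc.max_curvature_change,
                              direction=tc.direction))
        for t in np.asarray(bundle.spike_times[i], dtype=float):
            srows.append(dict(trial=i, time_ms=t))
        ang = np.asarray(bundle.whisker_angle[i], dtype=float)
        msk = np.asarray(bundle.mask_flags[i], dtype=bool)
        wrows.append(pd.DataFrame(dict(
            trial=i, t_ms=np.arange(len(ang)), angle=ang, tracked=msk.astype(int))))

    _t_cols = ["trial", "pole_location", "pole_onset", "sampling_period",
               "answer_period", "licked", "outcome"]
    _c_cols = ["trial", "touch", "onset", "offset", "angle_at_touch",
               "max_curvature_change", "direction"]
    pd.DataFrame(trows, columns=_t_cols).to_csv(
        os.path.join(p, "trials.csv"), index=False)
    pd.DataFrame(crows, columns=_c_cols).to_csv(
        os.path.join(p, "touches.csv"), index=False)
    pd.DataFrame(srows, columns=["trial", "time_ms"]).to_csv(
        os.path.join(p, "spikes.csv"), index=False)
    if wrows:
        wdf = pd.concat(wrows, ignore_index=True)
    else:
        wdf = pd.DataFrame(columns=["trial", "t_ms", "angle", "tracked"])
    wdf.to_csv(os.path.join(p, "whisker.csv"), index=False)


def read_session(path: str | os.PathLike) -> SessionBundle:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`SessionFormatError` for missing tables/columns and
    :class:`SessionValidationError` for invariant violations.
    """
    p = os.fspath(path)
    meta_path = os.path.join(p, "metadata.txt")
    if not os.path.exists(meta_path):
        raise SessionFormatError(f"{p}: missing metadata.txt")
    meta = {}
    with open(meta_path) as fh:
        for line in fh:
            if ":" in line:
                k, v = line.split(":", 1)
                meta[k.strip()] = v.strip()
    for t in _TABLES:
        if not os.path.exists(os.path.join(p, t)):
            raise SessionFormatError(f"{p}: missing table {t}")

    def _read(name):  # round_trip: exact float64 round-trip through text
        return pd.read_csv(os.path.join(p, name), float_precision="round_trip")

    trials_df = _read("trials.csv")
    touches_df = _read("touches.csv")
    spikes_df = _read("spikes.csv")
    whisker_df = _read("whisker.csv")
    for df, cols, name in (
            (trials_df, {"trial", "pole_location", "outcome"}, "trials.csv"),
            (touches_df, {"trial", "onset", "offset"}, "touches.csv"),
            (spikes_df, {"trial", "time_ms"}, "spikes.csv"),
            (whisker_df, {"trial", "t_ms", "angle", "tracked"}, "whisker.csv")):
        missing = cols - set(df.columns)
        if missing:
            raise SessionFormatError(f"{p}: {name} missing columns {sorted(missing)}")

    trials: list[Trial] = []
    spike_times: list[np.ndarray] = []
    whisker_angle: list[np.ndarray] = []
    mask_flags: list[np.ndarray] = []
    touch_groups = dict(tuple(touches_df.groupby("trial"))) if len(touches_df) else {}
    spike_groups = dict(tuple(spikes_df.groupby("trial"))) if len(spikes_df) else {}
    whisker_groups = dict(tuple(whisker_df.groupby("trial"))) if len(whisker_df) else {}

    for _, row in trials_df.sort_values("trial").iterrows():
        i = int(row["trial"])
        touches = []
        if i in touch_groups:
            g = touch_groups[i].sort_values("touch") if "touch" in touch_groups[i] \
                else touch_groups[i].sort_values("onset")
            for _, c in g.iterrows():
                touches.append(TouchEvent(
                    onset=float(c["onset"]), offset=float(c["offset"]),
                    angle_at_touch=float(c["angle_at_touch"]),
                    max_curvature_change=float(c["max_curvature_change"]),
                    direction=str(c.get("direction", "protraction"))))
        trials.append(Trial(
            pole_location=float(row["pole_location"]), touches=touches,
            licked=bool(int(row["licked"])), outcome=str(row["outcome"]),
            pole_onset=float(row["pole_onset"]),
            sampling_period=float(row["sampling_period"]),
            answer_period=float(row["answer_period"])))
        spike_times.append(
            np.sort(spike_groups[i]["time_ms"].to_numpy(dtype=float))
            if i in spike_groups else np.empty(0))
        if i in whisker_groups:
            g = whisker_groups[i].sort_values("t_ms")
            whisker_angle.append(g["angle"].to_numpy(dtype=float))
            mask_flags.append(g["tracked"].to_numpy(dtype=int).astype(bool))
        else:
            whisker_angle.append(np.empty(0))
            mask_flags.append(np.empty(0, dtype=bool))

    bundle = SessionBundle(
        session_id=meta.get("session_id", os.path.basename(p)),
        neuron_depth=float(meta.get("neuron_depth", "nan")),
        condition=meta.get("condition", "naive"),
        trials=trials, spike_times=spike_times,
        whisker_angle=whisker_angle, mask_flags=mask_flags,
        sampling_rate=float(meta.get("sampling_rate", SAMPLING_RATE)))
    bundle.validate()
    return bundle
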