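"""Reading and writing cohort containers and analysis tables.

Cohorts are stored in HDF5 with one group per mouse and one dataset per
session (``/mouse_<id>/session_<k>/responses``, neuron x frequency x
repeat), plus behavioral motion traces and a CSV-compatible manifest of
ground truth. Motion traces and window manifests round-trip through plain
CSV for interoperability with scoring done elsewhere.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import MotionTrace
from .cohort import CohortConfig, MouseData, SyntheticCohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_motion_csv",
    "read_motion_csv",
]


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> None:
    cfg = cohort.config
    with h5py.File(path, "w") as h5:
        h5.attrs["seed"] = cfg.seed
        h5.attrs["n_sessions"] = cfg.n_sessions
        h5.attrs["n_pre_sessions"] = cfg.n_pre_sessions
        h5.create_dataset("frequencies_hz", data=np.asarray(cfg.frequencies))
        for mouse in cohort.mice:
            grp = h5.create_group(f"mouse_{mouse.mouse_id}")
            grp.attrs["group"] = mouse.group
            grp.attrs["gradient"] = mouse.gradient
            grp.attrs["ls_true"] = mouse.ls_true
            grp.create_dataset("bf_log2", data=mouse.bf_log2)
            grp.create_dataset("gain", data=mouse.gain)
            grp.create_dataset("width_octaves", data=mouse.width_octaves)
            grp.create_dataset("amplitude", data=mouse.amplitude)
            for s, resp in enumerate(mouse.responses, start=1):
                grp.create_dataset(f"session_{s}/responses", data=resp)
            for s, trace in mouse.motion.items():
                bgrp = grp.create_group(f"behavior/retrieval_{s}")
                bgrp.create_dataset("samples", data=trace.samples)
                bgrp.attrs["frame_rate"] = trace.frame_rate
                if trace.windows:
                    labels = np.array([w[0] for w in trace.windows], dtype="S10")
                    times = np.array([[w[1], w[2]] for w in trace.windows])
                    bgrp.create_dataset("window_labels", data=labels)
                    bgrp.create_dataset("window_times", data=times)


def read_cohort(path: str | Path) -> SyntheticCohort:
    """Load a cohort container written by :func:`write_cohort`.

    The stored config is partial (only what analyses need); generator
    parameters not required downstream are left at defaults.
    """
    with h5py.File(path, "r") as h5:
        freqs = tuple(float(f) for f in h5["frequencies_hz"][()])
        n_sessions = int(h5.attrs["n_sessions"])
        mice = []
        for name in sorted(k for k in h5 if k.startswith("mouse_")):
            grp = h5[name]
            responses = [
                grp[f"session_{s}/responses"][()] for s in range(1, n_sessions + 1)
            ]
            motion = {}
            if "behavior" in grp:
                for bname in grp["behavior"]:
                    bgrp = grp["behavior"][bname]
                    windows = []
                    if "window_labels" in bgrp:
                        labels = [x.decode() for x in bgrp["window_labels"][()]]
                        times = bgrp["window_times"][()]
                        windows = [
                            (lab, float(t0), float(t1))
                            for lab, (t0, t1) in zip(labels, times)
                        ]
                    motion[int(bname.split("_")[1])] = MotionTrace(
                        samples=bgrp["samples"][()],
                        frame_rate=float(bgrp.attrs["frame_rate"]),
                        windows=windows,
                    )
            mice.append(
                MouseData(
                    mouse_id=name.removeprefix("mouse_"),
                    group=grp.attrs["group"],
                    gradient=float(grp.attrs["gradient"]),
                    ls_true=float(grp.attrs["ls_true"]),
                    bf_log2=grp["bf_log2"][()],
                    gain=grp["gain"][()],
                    width_octaves=grp["width_octaves"][()],
                    amplitude=grp["amplitude"][()],
                    responses=responses,
                    motion=motion,
                )
            )
        config = CohortConfig(
            n_conditioned=sum(m.group == "conditioned" for m in mice),
            n_pseudo=sum(m.group == "pseudo" for m in mice),
            frequencies=freqs,
            repeats_per_frequency=mice[0].responses[0].shape[2] if mice else 25,
            n_sessions=n_sessions,
            n_pre_sessions=int(h5.attrs["n_pre_sessions"]),
            seed=int(h5.attrs["seed"]),
            discriminability_gradient=tuple(
                m.gradient for m in mice if m.group == "conditioned"
            )
            or None,
        )
    return SyntheticCohort(config=config, mice=mice)


def write_motion_csv(trace: MotionTrace, trace_path: str | Path, windows_path: str | Path | None = None) -> None:
    t = np.arange(len(trace.samples)) / trace.frame_rate
    pd.DataFrame({"time_s": t, "motion_index": trace.samples}).to_csv(
        trace_path, index=False
    )
    if windows_path is not None:
        pd.DataFrame(
            trace.windows, columns=["label", "start_s", "end_s"]
        ).to_csv(windows_path, index=False)


def read_motion_csv(trace_path: str | Path, windows_path: str | Path | None = None) -> MotionTrace:
    df = pd.read_csv(trace_path)
    if len(df) < 2:
        raise ValueError("motion trace needs at least 2 samples")
    dt = float(np.median(np.diff(df["time_s"])))
    windows = []
    if windows_path is not None:
        wdf = pd.read_csv(windows_path)
        windows = [
            (row.label, float(row.start_s), float(row.end_s))
            for row in wdf.itertuples()
        ]
    return MotionTrace(
        samples=df["motion_index"].to_numpy(),
        frame_rate=1.0 / dt,
        windows=windows,
    )
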