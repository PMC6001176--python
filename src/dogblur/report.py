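"""Batch scoring of slice sequences and the CSV quality report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SliceRecord
from .quality import MultiscaleConfig, SliceAssessment, assess_image

__all__ = ["REPORT_COLUMNS", "ScoreReport", "score_volume", "write_report", "write_trajectories"]

REPORT_COLUMNS = (
    "file",
    "slice_index",
    "d1",
    "d2",
    "L",
    "mu_Id",
    "mu_CA",
    "mu_CB",
    "q1",
    "q2",
    "Q",
    "warnings",
)

FLOAT_COLUMNS = ("mu_Id", "mu_CA", "mu_CB", "q1", "q2", "Q")


@dataclass(frozen=True)
class ScoreReport:
    """One row per scored slice, in input order."""

    frame: pd.DataFrame
    trajectories: tuple = ()

    def __post_init__(self) -> None:
        if tuple(self.frame.columns) != REPORT_COLUMNS:
            raise ValueError(f"report columns must be {REPORT_COLUMNS}")

    def __len__(self) -> int:
        return len(self.frame)


def score_volume(
    records: Sequence[SliceRecord],
    config: MultiscaleConfig | None = None,
) -> ScoreReport:
    """Score each slice independently; failures become warning rows.

    Each row's scores equal a standalone :func:`dogblur.quality.assess_image`
    call on that slice (no cross-slice state).  A slice that cannot be
    scored (e.g. too small) yields a row of NaNs with the error message in
    the warnings column.
    """
    if not records:
        raise ValueError("need at least one slice record")
    config = config or MultiscaleConfig()
    rows = []
    trajectories: list = []
    for rec in records:
        d1, d2 = rec.image.shape if rec.image.ndim == 2 else (0, 0)
        row = {
            "file": rec.source_path,
            "slice_index": rec.slice_index,
            "d1": d1,
            "d2": d2,
            "L": np.nan,
            "mu_Id": np.nan,
            "mu_CA": np.nan,
            "mu_CB": np.nan,
            "q1": np.nan,
            "q2": np.nan,
            "Q": np.nan,
            "warnings": "",
        }
        try:
            res: SliceAssessment = assess_image(rec.image, config)
        except Exception as exc:
            row["warnings"] = f"error: {exc}"
            trajectories.append(None)
        else:
            t = res.trajectory
            row.update(
                L=t.L,
                mu_Id=t.mu_reference,
                mu_CA=t.mu_ca,
                mu_CB=t.mu_cb,
                q1=res.score.q1,
                q2=res.score.q2,
                Q=res.score.Q,
                warnings="; ".join(res.warnings),
            )
            trajectories.append(t)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    return ScoreReport(frame=frame, trajectories=tuple(trajectories))


def _fmt(x: float) -> str:
    return "" if pd.isna(x) else f"{x:.6g}"


def write_report(report: ScoreReport, path: str | Path) -> None:
    """Write the fixed-schema CSV; floats carry 6 significant digits."""
    out = report.frame.copy()
    for col in FLOAT_COLUMNS:
        out[col] = out[col].map(_fmt)
    out["L"] = out["L"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def write_trajectories(report: ScoreReport, path: str | Path) -> None:
    """Optional long-format CSV of per-scale edge-map means."""
    rows = []
    for (_, r), traj in zip(report.frame.iterrows(), report.trajectories):
        if traj is None:
            continue
        for s, (m1, m2) in enumerate(zip(traj.mu_high, traj.mu_low), start=1):
            rows.append(
                {
                    "file": r["file"],
                    "slice_index": r["slice_index"],
                    "scale": s,
                    "mED1": f"{m1:.6g}",
                    "mED2": f"{m2:.6g}",
                }
            )
    pd.DataFrame(rows, columns=["file", "slice_index", "scale", "mED1", "mED2"]).to_csv(
        path, index=False
    )
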