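"""Figure output for ROC and FROC curves."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .events import FROCPoint
from .perframe import ROCCurve

__all__ = ["plot_roc", "plot_froc"]


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_roc(curve: ROCCurve, path: str | Path, title: str = "Per-frame ROC") -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    fprs = [p[0] for p in curve.points]
    tprs = [p[1] for p in curve.points]
    ax.plot(fprs, tprs, marker=".", lw=1.5, label=f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate (per frame)")
    ax.set_ylabel("True positive rate (per frame)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    _save(fig, path)


def plot_froc(
    points: Sequence[FROCPoint],
    path: str | Path,
    swept: str = "delta",
    mark_value: float | None = None,
    title: str = "FROC",
) -> None:
    """Per-polyp recall against average FP events per patient.

    ``mark_value`` x-marks one operating point of the sweep (e.g. the
    working threshold delta = 0.6 or tau = 1 s).
    """
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    xs = [p.avg_fp_events_per_patient for p in points]
    ys = [p.per_polyp_recall for p in points]
    ax.plot(xs, ys, marker="o", ms=3, lw=1.5)
    if mark_value is not None:
        for p in points:
            if abs(p.swept_value - mark_value) < 1e-9:
                ax.plot(
                    [p.avg_fp_events_per_patient],
                    [p.per_polyp_recall],
                    marker="x",
                    ms=10,
                    c="red",
                )
    ax.set_xlabel("Average FP events per patient")
    ax.set_ylabel("Per-polyp recall")
    ax.set_title(f"{title} (sweep: {swept})")
    ax.set_ylim(-0.02, 1.02)
    _save(fig, path)
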