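"""Regression and Bland-Altman agreement figures for SR vs HR velocities."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import EvalReport, regression_bland_altman

__all__ = ["agreement_figure", "write_report_csv"]


def agreement_figure(
    pred: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray,
    path: str | Path,
    max_points: int = 20_000,
    seed: int = 0,
) -> None:
    """2x4 panel figure: SR-vs-HR regression (top) and Bland-Altman
    (bottom) for each velocity component and the speed."""
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    fields = [
        (r"$v_x$", pred[..., 0][mask], target[..., 0][mask]),
        (r"$v_y$", pred[..., 1][mask], target[..., 1][mask]),
        (r"$v_z$", pred[..., 2][mask], target[..., 2][mask]),
        (r"$\|v\|$", np.linalg.norm(pred, axis=-1)[mask],
         np.linalg.norm(target, axis=-1)[mask]),
    ]
    fig, axes = plt.subplots(2, 4, figsize=(16, 7))
    for col, (label, p, t) in enumerate(fields):
        if p.size > max_points:
            sel = rng.choice(p.size, max_points, replace=False)
            p, t = p[sel], t[sel]
        slope, offset, bias, (lo, hi) = regression_bland_altman(p, t)
        ax = axes[0, col]
        ax.plot(t, p, ".", ms=1, alpha=0.3)
        lim = np.array([min(t.min(), p.min()), max(t.max(), p.max())])
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.plot(lim, slope * lim + offset, "r-", lw=0.8)
        ax.set_title(f"{label}: y = {slope:.3f}x + {offset:.3f}")
        ax.set_xlabel("HR (m/s)")
        ax.set_ylabel("SR (m/s)")
        ax = axes[1, col]
        mean, diff = (p + t) / 2, p - t
        ax.plot(mean, diff, ".", ms=1, alpha=0.3)
        for y, style in ((bias, "r-"), (lo, "r--"), (hi, "r--")):
            ax.axhline(y, lw=0.8, ls=style[1:], color="r")
        ax.set_title(f"bias {bias:.3f}, LoA [{lo:.3f}, {hi:.3f}]")
        ax.set_xlabel("mean (m/s)")
        ax.set_ylabel("SR - HR (m/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_report_csv(reports: list[tuple[dict, EvalReport]], path: str | Path) -> None:
    """One row per (metadata, report); metadata keys become lead columns."""
    import csv

    meta_keys = list(reports[0][0].keys())
    rep_keys = list(reports[0][1].as_dict().keys())
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=meta_keys + rep_keys)
        w.writeheader()
        for meta, rep in reports:
            w.writerow({**meta, **rep.as_dict()})
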