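"""Optional figure exports: Kaplan-Meier curves by quartile and the
penalised-spline hazard-ratio curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cox import SplineFit, hr_curve
from .outcomes import km_curve

_QUARTILE_COLORS = {"Q1": "#c0392b", "Q2": "#e67e22", "Q3": "#2980b9", "Q4": "#27ae60"}


def plot_km_by_quartile(records: pd.DataFrame, path, title: str = "") -> None:
    """Step-plot survival by LE8 quartile (Q1 least healthy)."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for q, color in _QUARTILE_COLORS.items():
        sub = records[records["quartile"] == q]
        if len(sub) == 0:
            continue
        km = km_curve(sub)
        ax.step(km["time"], km["survival"], where="post", label=q, color=color)
    ax.set_xlabel("Years of follow-up")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="LE8 quartile")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_hr_curve(fit: SplineFit, path, title: str = "") -> None:
    """Hazard-ratio curve with pointwise 95% CI band."""
    curve = hr_curve(fit)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(curve["exposure"], curve["hr"], color="#2c3e50")
    ax.fill_between(
        curve["exposure"], curve["ci_low"], curve["ci_high"],
        alpha=0.25, color="#2c3e50", linewidth=0,
    )
    ax.axhline(1.0, ls="--", lw=0.8, color="grey")
    ax.set_yscale("log")
    ax.set_xlabel("LE8 composite score")
    ax.set_ylabel("Hazard ratio (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
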