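"""Agreement figures: area scatter and Bland-Altman plot."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import EvalReport

__all__ = ["agreement_plots"]


def agreement_plots(report: EvalReport, path: Union[str, Path],
                    title: str = "") -> None:
    """Two panels: manual-vs-automated area scatter, and Bland-Altman.

    The scatter shows the identity line and the r^2; the Bland-Altman panel
    shows manual - automated differences against pair means with the bias
    and 1.96 SD limits of agreement.
    """
    auto = report.per_scan["area_auto_mm2"].to_numpy(float)
    manual = report.per_scan["area_manual_mm2"].to_numpy(float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))

    ax1.scatter(auto, manual, s=14, alpha=0.7)
    lim = [0, max(auto.max(), manual.max()) * 1.05 + 1e-6]
    ax1.plot(lim, lim, "k--", lw=0.8)
    ax1.set_xlabel("automated area (mm$^2$)")
    ax1.set_ylabel("manual area (mm$^2$)")
    ax1.set_title(f"r$^2$ = {report.r2:.3f}")

    mean_pair = (auto + manual) / 2
    diff = manual - auto
    ax2.scatter(mean_pair, diff, s=14, alpha=0.7)
    ax2.axhline(report.bias_mm2, color="k", lw=1)
    for l in report.loa_mm2:
        ax2.axhline(l, color="r", ls="--", lw=0.8)
    ax2.set_xlabel("mean of methods (mm$^2$)")
    ax2.set_ylabel("manual $-$ automated (mm$^2$)")
    ax2.set_title(
        f"bias {report.bias_mm2:.3f}, LOA [{report.loa_mm2[0]:.3f}, {report.loa_mm2[1]:.3f}]"
    )
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
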