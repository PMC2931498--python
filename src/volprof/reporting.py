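"""Model-comparison tables and volume-effectiveness figures."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .volume_models import FitSummary

__all__ = ["comparison_report", "volume_plot"]

_LINESTYLES = {"mean": "-", "linear": "--", "spline": ":", "cutoff": "-."}


def comparison_report(summaries: Mapping[str, FitSummary]) -> pd.DataFrame:
    """Rank fitted trend families by ascending DIC (ties broken by smaller pD).

    Returns a frame with DIC, pD, Dbar (one decimal, the conventional
    presentation) and the DIC difference to the best family.
    """
    if len(summaries) < 2:
        raise ValueError("comparison needs summaries for at least 2 families")
    provider_sets = {
        fam: None if s.provider_rates is None else tuple(s.provider_rates["provider_id"])
        for fam, s in summaries.items()
    }
    known = {v for v in provider_sets.values() if v is not None}
    if len(known) > 1:
        raise ValueError("fits cover different provider sets; refusing to compare")
    rows = [
        {"family": fam, "DIC": s.dic, "pD": s.p_d, "Dbar": s.d_bar}
        for fam, s in summaries.items()
    ]
    df = pd.DataFrame(rows).sort_values(["DIC", "pD"], kind="mergesort")
    df["delta_DIC"] = df["DIC"] - df["DIC"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    for col in ("DIC", "pD", "Dbar", "delta_DIC"):
        df[col] = df[col].round(1)
    return df.reset_index(drop=True)


def volume_plot(
    aggregates: pd.DataFrame,
    curves: Mapping[str, pd.DataFrame],
    mean_rate: float,
    path,
    provider_rates: pd.DataFrame | None = None,
    dics: Mapping[str, float] | None = None,
    xlabel: str = "pooled patient volume",
    ylabel: str = "risk-adjusted rate",
    title: str | None = None,
) -> None:
    """Scatter of provider risk-adjusted rates vs. volume with trend curves.

    Dots are providers (shrunk posterior rates when supplied, else crude
    O/E x mean rate); one line per trend family, mean/linear/spline drawn
    solid/dashed/dotted, with DIC values in the legend.
    """
    fig, ax = plt.subplots(figsize=(7, 5))
    if provider_rates is not None:
        merged = aggregates.merge(provider_rates, on="provider_id")
        ax.plot(merged["z"], merged["rate_mean"], "o", color="0.4", ms=4, label=None)
    else:
        crude = aggregates["O"] / aggregates["E"] * mean_rate
        ax.plot(aggregates["z"], crude, "o", color="0.4", ms=4)
    for fam, curve in curves.items():
        label = fam
        if dics and fam in dics:
            label = f"{fam} (DIC {dics[fam]:.1f})"
        ax.plot(
            curve["volume"],
            curve["trend_mean"] * mean_rate,
            _LINESTYLES.get(fam, "-"),
            color="k",
            label=label,
        )
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if str(path).endswith(".svg"):
        # strip the creation date and fix element-id hashing so that byte
        # digests of figures are reproducible across reruns
        with matplotlib.rc_context({"svg.hashsalt": "volprof"}):
            fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path)
    plt.close(fig)
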