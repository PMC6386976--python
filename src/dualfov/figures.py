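"""Optional matplotlib figures (predicted-vs-measured scatter)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def predicted_vs_measured(per_sample, path, title: str = "") -> None:
    """Scatter of ensemble mean predictions vs. measured population.

    Error bars show the SD of the hold-out predictions across resampling
    iterations; the 1:1 line is drawn for reference.
    """
    df = per_sample.dropna(subset=["mean_predicted"])
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.errorbar(
        df["measured"], df["mean_predicted"], yerr=df["sd_predicted"],
        fmt="o", ms=3, lw=0.8, alpha=0.7,
    )
    lim = [0, max(df["measured"].max(), df["mean_predicted"].max()) * 1.05]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel(r"measured population (plants $\times 10^4$ ha$^{-1}$)")
    ax.set_ylabel(r"predicted population (plants $\times 10^4$ ha$^{-1}$)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
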