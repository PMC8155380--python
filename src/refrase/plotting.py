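"""Plot helpers for the evaluation sweep (metric-vs-iteration panels)."""

from __future__ import annotations


def plot_sweep_panels(table, out_path=None):
    """Panels of n_rel, sigma_chi(R1), mean chi(R1) and rim RMSE over
    iterations, one line per (instance, threshold).

    ``table`` is the tidy DataFrame from :func:`refrase.evaluate.sweep`
    (iteration 0 = conventional).  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("n_rel", "relative mask difference $n_{rel}$"),
              ("chi_std_R1", r"$\sigma_\chi(R_1)$ [ppm]"),
              ("chi_mean_R1", r"$\bar\chi(R_1)$ [ppm]"),
              ("rmse_rim", "rim RMSE [ppm]")]
    fig, axes = plt.subplots(len(panels), 1, figsize=(6, 11), sharex=True)
    for ax, (col, label) in zip(axes, panels):
        for (inst, q), grp in table.groupby(["instance", "q_lc_min"]):
            grp = grp.sort_values("iteration")
            ax.plot(grp["iteration"], grp[col], marker="o",
                    label=f"inst {inst}, $Q_{{LC,min}}$={q}")
        ax.set_ylabel(label)
        ax.grid(alpha=0.3)
    axes[-1].set_xlabel("iteration (0 = conventional)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
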