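"""Figure helpers mirroring the standard panels of VTE experiments."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiment import ExperimentResult, GridResult


def plot_experiment(result: ExperimentResult, path: str) -> None:
    """Performance/uncertainty, VTE fraction and context-belief heatmap."""
    trials = np.arange(1, result.n_trials + 1)
    fig, axes = plt.subplots(3, 1, figsize=(7, 9), sharex=True)

    ax = axes[0]
    ax.plot(trials, result.performance, "k-o", ms=3, label="performance")
    ax.plot(trials, result.uncertainty, "r-s", ms=3, label="uncertainty")
    ax.set_ylabel("fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="center right", fontsize=8)
    ax.set_title(f"{result.simulation} ({result.n_runs} runs)")

    ax = axes[1]
    if result.vte_fraction_easy is not None:
        ax.plot(trials, result.vte_fraction_easy, "b-o", ms=3, label="VTE (easy)")
        ax.plot(trials, result.vte_fraction_costly, "g-s", ms=3, label="VTE (costly)")
    else:
        ax.plot(trials, result.vte_fraction, "b-o", ms=3, label="VTE fraction")
    ax.set_ylabel("VTE fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="upper right", fontsize=8)

    ax = axes[2]
    ax.imshow(
        result.context_belief.T,
        aspect="auto",
        cmap="gray",
        origin="lower",
        extent=(0.5, result.n_trials + 0.5, -0.5, result.context_belief.shape[1] - 0.5),
        vmin=0.0,
        vmax=1.0,
    )
    ax.set_ylabel("context")
    ax.set_xlabel("trial")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_grid(result: GridResult, path: str) -> None:
    """Mean sweep count at the probe trial over the (c, diff) grid."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(result.mean_sweeps, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(result.diff_values)), [f"{d:g}" for d in result.diff_values])
    ax.set_yticks(range(len(result.c_values)), [f"{c:g}" for c in result.c_values])
    ax.set_xlabel("diff (high − usual reward)")
    ax.set_ylabel("c (usual reward)")
    ax.set_title(f"mean sweeps, trial {result.trial_index}")
    fig.colorbar(im, ax=ax, label="mean executed sweeps")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
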