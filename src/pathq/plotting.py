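"""Basic plots: ROC curves and phase planes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt  # noqa: E402

from .benchmark import BenchmarkResult  # noqa: E402
from .timecourse import TimeCourseSet  # noqa: E402

__all__ = ["plot_roc", "plot_phase_plane"]


def plot_roc(results: dict[float, BenchmarkResult], path=None, title=""):
    """Overlayed ROC curves, one per SNR level."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for snr in sorted(results, reverse=True):
        r = results[snr]
        ax.plot(r.fpr, r.tpr, label=f"SNR {snr:g} dB (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title or "rewiring detection ROC")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_phase_plane(tcs: list[TimeCourseSet], var_x: str, var_y: str,
                     path=None, labels=None):
    """Trajectory of one variable against another for several conditions."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for i, tc in enumerate(tcs):
        lab = labels[i] if labels else tc.condition_label
        ax.plot(tc.series(var_x), tc.series(var_y), lw=0.9, label=lab)
        ax.plot(tc.series(var_x)[0], tc.series(var_y)[0], "+",
                color=ax.lines[-1].get_color(), ms=10)
    ax.set_xlabel(var_x)
    ax.set_ylabel(var_y)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
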