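"""Plot helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import TitrationResult

__all__ = ["plot_titration"]


def plot_titration(results: list[TitrationResult], path) -> None:
    """Cleaved fraction vs mutant percentage, one open marker per enzyme."""
    fig, ax = plt.subplots(figsize=(5, 4))
    markers = ("o", "s", "^")
    for t, m in zip(results, markers):
        x = [100 * p for p in t.grid]
        y = [100 * v for v in t.cleaved_mean]
        err = [100 * s for s in t.cleaved_sd]
        ax.errorbar(
            x, y, yerr=err, marker=m, mfc="none", ls="-", capsize=2, label=t.enzyme_name
        )
    ax.set_xlabel("mutant DNA (%)")
    ax.set_ylabel("cleaved products / total DNA (%)")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
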