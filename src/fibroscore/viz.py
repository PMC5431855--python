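"""Optional rendering of a score matrix as a diverging blue-red heat map.

Numeric TSV export is the tested surface; this layer only maps the signed
integers onto a symmetric diverging palette (blue for negative, red for
positive profile values).
"""

from __future__ import annotations


def plot_score_matrix(matrix, path=None, ax=None):
    """Render one score matrix; returns the matplotlib Axes."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    K = len(matrix.materials)
    bound = max(1, K - 1)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(matrix.readouts) + 2, 0.8 * K + 1.5))
    im = ax.imshow(matrix.entries, cmap="RdBu_r", vmin=-bound, vmax=bound)
    ax.set_xticks(range(len(matrix.readouts)), matrix.readouts, rotation=45, ha="right")
    ax.set_yticks(range(K), matrix.materials)
    ax.set_title(f"Significance profile — {matrix.condition}")
    for i in range(K):
        for j in range(len(matrix.readouts)):
            ax.text(j, i, str(matrix.entries[i, j]), ha="center", va="center", fontsize=9)
    ax.figure.colorbar(im, ax=ax, label="profile score")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
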