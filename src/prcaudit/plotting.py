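"""Thin optional plotting wrapper around the curve export.

Requires matplotlib; everything scientific lives in the curve itself
(:meth:`prcaudit.estimators.PRCurve.to_frame` carries the same data).
"""

from __future__ import annotations

from .estimators import PRCurve

__all__ = ["plot_curve"]


def plot_curve(curve: PRCurve, ax=None, label: str | None = None, **plot_kw):
    """Draw one PR curve; anchors as markers, connectors as lines.

    Returns the matplotlib axes. Step connectors are drawn exactly because
    the emitted vertices already include the step corners.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = curve.to_frame()
    ax.plot(frame["recall"], frame["precision"], label=label, **plot_kw)
    anchors = frame[frame["kind"] == "anchor"]
    ax.plot(anchors["recall"], anchors["precision"], "o", ms=4, color=ax.lines[-1].get_color())
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)
    if label:
        ax.legend()
    return ax
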