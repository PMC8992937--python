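"""Figure helpers regenerating the study's plot layouts from a tidy metrics CSV.

Each function takes the tidy table written by the sweep (columns: seed,
duration_s, n_iterations, n_subsets, postfilter_fwhm_mm, sphere_diameter_mm,
rc_percent, bv_percent, cnr, rose_visible) and draws seed-mean curves.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

KEYS = ["duration_s", "n_iterations", "postfilter_fwhm_mm", "sphere_diameter_mm"]


def _mean(df: pd.DataFrame) -> pd.DataFrame:
    return df.groupby(KEYS)[["rc_percent", "bv_percent", "cnr"]].mean().reset_index()


def plot_rc_bv_vs_iterations(df: pd.DataFrame, fwhm_mm: float = 8.0):
    """RC and BV against iteration number, one panel per acquisition duration."""
    import matplotlib.pyplot as plt

    m = _mean(df[df.postfilter_fwhm_mm == fwhm_mm])
    durations = sorted(m.duration_s.unique())
    fig, axes = plt.subplots(1, len(durations), figsize=(4.2 * len(durations), 3.6),
                             sharey=True)
    for ax, dur in zip(axes if len(durations) > 1 else [axes], durations):
        sub = m[m.duration_s == dur]
        for d, g in sub.groupby("sphere_diameter_mm"):
            ax.plot(g.n_iterations, g.rc_percent, "o-", label=f"{d:g} mm")
            ax.plot(g.n_iterations, g.bv_percent, "s--", alpha=0.5)
        ax.set_title(f"{dur:g} s/view")
        ax.set_xlabel("iterations")
    (axes[0] if len(durations) > 1 else axes).set_ylabel("RC (solid) / BV (dashed), %")
    (axes[-1] if len(durations) > 1 else axes).legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_rc_vs_filter(df: pd.DataFrame, n_iterations: int = 12):
    """RC-BV trade-off against post-filter FWHM at a fixed iteration count."""
    import matplotlib.pyplot as plt

    m = _mean(df[df.n_iterations == n_iterations])
    durations = sorted(m.duration_s.unique())
    fig, axes = plt.subplots(1, len(durations), figsize=(4.2 * len(durations), 3.6),
                             sharey=True)
    for ax, dur in zip(axes if len(durations) > 1 else [axes], durations):
        sub = m[m.duration_s == dur]
        for d, g in sub.groupby("sphere_diameter_mm"):
            g = g.sort_values("postfilter_fwhm_mm")
            ax.plot(g.postfilter_fwhm_mm, g.rc_percent, "o-", label=f"{d:g} mm RC")
            ax.plot(g.postfilter_fwhm_mm, g.bv_percent, "s--", alpha=0.5)
        ax.set_title(f"{dur:g} s/view")
        ax.set_xlabel("post-filter FWHM (mm)")
    fig.tight_layout()
    return fig


def plot_cnr_vs_iterations(df: pd.DataFrame, fwhm_mm: float = 8.0):
    """CNR against iteration number with the Rose threshold marked."""
    import matplotlib.pyplot as plt

    m = _mean(df[df.postfilter_fwhm_mm == fwhm_mm])
    durations = sorted(m.duration_s.unique())
    fig, axes = plt.subplots(1, len(durations), figsize=(4.2 * len(durations), 3.6),
                             sharey=True)
    for ax, dur in zip(axes if len(durations) > 1 else [axes], durations):
        sub = m[m.duration_s == dur]
        for d, g in sub.groupby("sphere_diameter_mm"):
            ax.plot(g.n_iterations, g.cnr, "o-", label=f"{d:g} mm")
        ax.axhline(5.0, ls=":", color="k", label="Rose (CNR = 5)")
        ax.set_title(f"{dur:g} s/view")
        ax.set_xlabel("iterations")
    (axes[0] if len(durations) > 1 else axes).set_ylabel("CNR")
    (axes[-1] if len(durations) > 1 else axes).legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_cnr_vs_duration(df: pd.DataFrame, n_iterations: int = 12, fwhm_mm: float = 8.0):
    """CNR against acquisition duration per sphere size."""
    import matplotlib.pyplot as plt

    m = _mean(df[(df.n_iterations == n_iterations) & (df.postfilter_fwhm_mm == fwhm_mm)])
    fig, ax = plt.subplots(figsize=(5, 3.8))
    for d, g in m.groupby("sphere_diameter_mm"):
        g = g.sort_values("duration_s")
        ax.plot(g.duration_s, g.cnr, "o-", label=f"{d:g} mm")
    ax.axhline(5.0, ls=":", color="k")
    ax.set_xlabel("seconds per view")
    ax.set_ylabel("CNR")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def save_all(csv_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Regenerate every figure layout from a metrics CSV."""
    df = pd.read_csv(csv_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fn in (
        ("rc_bv_vs_iterations", plot_rc_bv_vs_iterations),
        ("rc_vs_filter", plot_rc_vs_filter),
        ("cnr_vs_iterations", plot_cnr_vs_iterations),
        ("cnr_vs_duration", plot_cnr_vs_duration),
    ):
        fig = fn(df)
        p = out / f"{name}.png"
        fig.savefig(p, dpi=130)
        written.append(p)
    return written
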