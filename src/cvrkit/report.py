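"""Self-contained HTML quality-control report for one participant.

One file, openable in any browser: raw capnograph vs extracted etCO2
envelope, global BOLD vs optimally shifted etCO2 (alignment check), axial
mosaics of the CVR and delay maps, the IC reclassification table, and a job
summary.  Images are embedded as base64 PNGs; mosaics use the neurological
display convention (left of image = left of brain).
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


@dataclass
class ReportBundle:
    """Everything the report renders; optional sections may be None."""

    subject: str
    capno_times: np.ndarray | None = None
    capno_samples: np.ndarray | None = None
    etco2_times: np.ndarray | None = None
    etco2_values: np.ndarray | None = None
    frame_times: np.ndarray | None = None
    global_signal: np.ndarray | None = None
    shifted_etco2_on_frames: np.ndarray | None = None
    cvr_map: np.ndarray | None = None
    delay_map: np.ndarray | None = None
    mask: np.ndarray | None = None
    reclassification: pd.DataFrame | None = None
    denoising_skipped: bool = False
    job_summary: dict = field(default_factory=dict)


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight",
                metadata={"Software": None})
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _timecourse_png(bundle: ReportBundle) -> str | None:
    if bundle.capno_times is None or bundle.etco2_times is None:
        return None
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(bundle.capno_times, bundle.capno_samples, lw=0.4, color="0.6",
            label="raw CO2 recording")
    ax.plot(bundle.etco2_times, bundle.etco2_values, lw=1.5, color="crimson",
            label="etCO2 (upper envelope)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("CO2 (mmHg)")
    ax.legend(loc="lower right", fontsize=8)
    return _fig_to_b64(fig)


def _alignment_png(bundle: ReportBundle) -> str | None:
    if bundle.global_signal is None or bundle.shifted_etco2_on_frames is None:
        return None

    def z(x):
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(bundle.frame_times, z(bundle.global_signal), lw=1.0, color="navy",
            label="global BOLD (z)")
    ax.plot(bundle.frame_times, z(bundle.shifted_etco2_on_frames), lw=1.0,
            color="crimson", label="etCO2 at global delay (z)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("z-score")
    ax.legend(loc="lower right", fontsize=8)
    return _fig_to_b64(fig)


def _mosaic_png(volume: np.ndarray, mask: np.ndarray | None, cmap: str,
                symmetric: bool, title: str) -> str:
    data = np.asarray(volume, dtype=float)
    if mask is None:
        mask = np.isfinite(data)
    zs = np.flatnonzero(mask.any(axis=(0, 1)))
    z_sel = np.unique(np.linspace(zs[0], zs[-1], 25).round().astype(int))
    finite = data[np.isfinite(data)]
    if finite.size and symmetric:
        vmax = np.percentile(np.abs(finite), 99) or 1.0
        vmin = -vmax
    elif finite.size:
        vmin, vmax = np.percentile(finite, [1, 99])
    else:
        vmin, vmax = 0, 1
    n = len(z_sel)
    ncol = 5
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2 * ncol, 2 * nrow))
    axes = np.atleast_1d(axes).ravel()
    im = None
    for ax, zi in zip(axes, z_sel):
        # neurological convention: image left = subject left (+x to the right)
        im = ax.imshow(data[:, :, zi].T, origin="lower", cmap=cmap,
                       vmin=vmin, vmax=vmax, interpolation="nearest")
        ax.set_title(f"z={zi}", fontsize=7)
        ax.axis("off")
    for ax in axes[n:]:
        ax.axis("off")
    if im is not None:
        fig.colorbar(im, ax=axes.tolist(), shrink=0.7)
    fig.suptitle(title, fontsize=10)
    return _fig_to_b64(fig)


def _img_section(anchor: str, title: str, png_b64: str | None, note: str = "") -> str:
    body = (
        f'<img src="data:image/png;base64,{png_b64}" alt="{title}"/>'
        if png_b64
        else "<p class='notice'>section skipped (no data)</p>"
    )
    return f'<section id="{anchor}"><h2>{title}</h2>{body}<p>{note}</p></section>'


def _reclass_section(bundle: ReportBundle) -> str:
    if bundle.denoising_skipped:
        body = "<p class='notice'>Denoising was skipped; no IC re-classification performed.</p>"
    elif bundle.reclassification is None or bundle.reclassification.empty:
        body = "<p class='notice'>Zero components re-classified (empty noise set).</p>"
    else:
        df = bundle.reclassification
        n_rescued = int((df["original_label"] != df["final_label"]).sum()) if (
            {"original_label", "final_label"} <= set(df.columns)
        ) else 0
        header = (
            f"<p>{n_rescued} component(s) re-classified from noise to signal.</p>"
            if n_rescued
            else "<p>Zero components were re-classified.</p>"
        )
        body = header + df.to_html(index=False, float_format=lambda v: f"{v:.3f}")
    return f'<section id="reclassification"><h2>IC re-classification</h2>{body}</section>'


def render_report(bundle: ReportBundle, out_path: str | Path) -> Path:
    """Render the QC report to a single self-contained HTML file."""
    summary_rows = "".join(
        f"<tr><th>{k}</th><td>{v}</td></tr>" for k, v in bundle.job_summary.items()
    )
    sections = [
        f'<section id="summary"><h2>Job summary</h2>'
        f"<table>{summary_rows}</table></section>",
        _img_section(
            "physio", "Recorded CO2 vs upper envelope (etCO2)",
            _timecourse_png(bundle),
        ),
        _img_section(
            "alignment", "Global BOLD signal vs etCO2 (alignment check)",
            _alignment_png(bundle),
            "etCO2 shown at the estimated global delay; curves should superimpose.",
        ),
        _img_section(
            "cvr-map", "CVR map (%BOLD/mmHg)",
            _mosaic_png(bundle.cvr_map, bundle.mask, "RdBu_r", True,
                        "CVR, axial mosaic (neurological convention)")
            if bundle.cvr_map is not None else None,
        ),
        _img_section(
            "delay-map", "Delay map (s)",
            _mosaic_png(bundle.delay_map, bundle.mask, "PuOr", True,
                        "Delay, axial mosaic (neurological convention)")
            if bundle.delay_map is not None else None,
        ),
        _reclass_section(bundle),
    ]
    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>CVR report — sub-{bundle.subject}</title>"
        "<style>body{font-family:sans-serif;margin:2em;max-width:1100px}"
        "img{max-width:100%}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 8px;text-align:left}"
        ".notice{color:#a00}</style></head><body>"
        f"<h1>CVR participant report — sub-{bundle.subject}</h1>"
        + "".join(sections)
        + "</body></html>"
    )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(html)
    return out_path
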