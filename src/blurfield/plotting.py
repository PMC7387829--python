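"""Optional matplotlib renderings of wavefronts, PSFs and study curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_wavefront", "plot_psf", "plot_strehl_vs_pupil",
           "plot_spectrum"]


def plot_wavefront(analysis, path=None):
    """Heatmap of the pupil wavefront (um) for one field analysis."""
    fig, ax = plt.subplots(figsize=(4, 3.2))
    c = analysis.pupil_coords_mm
    im = ax.imshow(analysis.wavefront_um, origin="lower",
                   extent=[c[0], c[-1], c[0], c[-1]], cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="wavefront error (um)")
    ax.set_xlabel("pupil x (mm)")
    ax.set_ylabel("pupil y (mm)")
    ax.set_title(f"e={analysis.field.eccentricity_deg:g} deg, "
                 f"S={analysis.strehl:.2f}, RMS={analysis.rms_wavefront_um:.3f} um")
    return _finish(fig, path)


def plot_psf(analysis_or_kernel, path=None, log_floor=1e-6):
    """Log-intensity map of a PSF (field analysis or blur kernel)."""
    psf = getattr(analysis_or_kernel, "psf", None)
    scale = getattr(analysis_or_kernel, "psf_scale_arcmin", None)
    if psf is None:
        psf = analysis_or_kernel.intensity
        scale = analysis_or_kernel.pixel_scale_arcmin
    half = psf.shape[0] / 2.0 * scale
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(np.log10(np.maximum(psf / psf.max(), log_floor)),
                   origin="lower", extent=[-half, half, -half, half],
                   cmap="inferno")
    fig.colorbar(im, ax=ax, label="log10 relative intensity")
    ax.set_xlabel("visual angle (arcmin)")
    ax.set_ylabel("visual angle (arcmin)")
    return _finish(fig, path)


def plot_strehl_vs_pupil(report, path=None):
    """Worst-case Strehl against pupil diameter with the 0.8 criterion."""
    pupils = sorted(report.per_pupil)
    worst = [report.per_pupil[p].strehl for p in pupils]
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    ax.plot(pupils, worst, "o-", label="worst case")
    ax.axhline(report.criterion, ls="--", color="gray",
               label=f"criterion {report.criterion}")
    ax.set_xlabel("pupil diameter (mm)")
    ax.set_ylabel("worst-field Strehl ratio")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"extent {report.field_extent_deg:g} deg")
    return _finish(fig, path)


def plot_spectrum(stimulus, fit, path=None):
    """One-directional spectrum of a stimulus with its log-log fit line."""
    px = stimulus.pixels.astype(float)
    px -= px.mean(axis=1, keepdims=True)
    spec = (np.abs(np.fft.rfft(px, axis=1)) ** 2).mean(axis=0)
    f = np.fft.rfftfreq(px.shape[1], d=stimulus.pixel_scale_arcmin / 60.0)
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    sel = f > 0
    ax.loglog(f[sel], spec[sel], lw=0.8)
    lo, hi = fit.frequency_range_cpd
    xs = np.geomspace(lo, hi, 50)
    ax.loglog(xs, 10 ** (fit.intercept + fit.slope * np.log10(xs)), "r--",
              label=f"slope {fit.slope:.2f}")
    ax.set_xlabel("spatial frequency (cycles/deg)")
    ax.set_ylabel("one-directional power")
    ax.legend(frameon=False)
    return _finish(fig, path)


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
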