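"""Figure export: contact plots and spacing-fit overlays."""
from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.figure import Figure

from .calibration import ContactPlot
from .spacing_analysis import MixtureFit

__all__ = ["plot_contact", "plot_spacing_fit"]


def plot_contact(contacts: ContactPlot, path: str | Path, title: str = "") -> None:
    """Render the boolean proximity matrix as an image."""
    fig = Figure(figsize=(6, 6))
    ax = fig.add_subplot(111)
    ax.imshow(contacts.matrix, origin="lower", cmap="Greys", interpolation="none")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.set_title(title or f"contacts < {contacts.threshold:g} Å ({contacts.atom_rule})")
    fig.savefig(path, dpi=150)


def plot_spacing_fit(
    fit: MixtureFit,
    path: str | Path,
    bin_width: float = 5.0,
    title: str = "",
) -> None:
    """Histogram of the distances with the fitted mixture density overlaid.

    The bin width is a display choice only — the fit itself never bins.
    """
    x = fit.samples
    fig = Figure(figsize=(7, 4.5))
    ax = fig.add_subplot(111)
    bins = np.arange(x.min() - bin_width, x.max() + 2 * bin_width, bin_width)
    ax.hist(x, bins=bins, density=True, alpha=0.4, color="steelblue", label="measured")
    grid = np.linspace(bins[0], bins[-1], 400)
    density = np.zeros_like(grid)
    for mu, w, sd in zip(fit.modes, fit.weights, fit.sds):
        density += w * np.exp(-0.5 * ((grid - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    ax.plot(grid, density, color="firebrick", lw=2, label="mixture fit")
    for mu in fit.modes:
        ax.axvline(mu, color="firebrick", ls=":", lw=1)
    ax.set_xlabel("center-to-center distance (Å)")
    ax.set_ylabel("density")
    ax.set_title(title)
    ax.legend()
    fig.savefig(path, dpi=150)
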