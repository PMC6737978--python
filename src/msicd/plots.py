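"""Illustrative plots: waveform, frequency response, radial profile.

These figures are for inspection only; nothing downstream reads them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_waveform", "plot_frequency_response", "plot_radial_profile"]


def plot_waveform(trace, path):
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.times, trace.u, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("displacement (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_frequency_response(resp, path):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.loglog(resp.freqs, resp.response, marker="o", ms=3, lw=1)
    if resp.plateau_value is not None:
        ax.axhline(resp.plateau_value, ls="--", c="gray", lw=0.8, label="plateau")
        ax.legend()
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(f"{resp.variant} frequency term (Pa Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radial_profile(profile, path):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.bin_mid, profile.rate, marker="s", ms=4, lw=1)
    ax.set_xlabel("radius (mm)")
    ax.set_ylabel("PI-positive rate (%)")
    if profile.computable:
        ax.set_title(f"{profile.method} r = {profile.correlation:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
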