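"""Minimal quick-look plotting (lines and heatmaps).

These helpers exist to eyeball a dataset during pipeline development, not
to produce publication figures.  Everything funnels through
:func:`quickplot`, which writes a PNG/SVG and returns the path.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .datamodel import AnalogData, CrossSpectralData, SpectralData, SpikeData
from .errors import ParameterError

__all__ = ["quickplot"]


def quickplot(data, path: str, kind: str = "auto", trial: int = 0, pair=None) -> str:
    """Render one dataset view to an image file.

    AnalogData -> channel traces of one trial; SpectralData -> spectrum
    lines (one time bin) or a time-frequency heatmap; CrossSpectralData ->
    one channel pair's spectrum (``pair=(i, j)`` required when more than
    one pair exists); SpikeData -> raster.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    try:
        if isinstance(data, AnalogData):
            t = data.time(trial)
            ax.plot(t, data.trial(trial))
            ax.set_xlabel("time (s)")
            ax.set_ylabel("amplitude")
            ax.legend(data.channels, fontsize=7, loc="upper right")
        elif isinstance(data, SpectralData):
            tr = np.asarray(data.trial(trial))
            power = tr if not np.iscomplexobj(tr) else np.abs(tr) ** 2
            power = power.mean(axis=1)  # taper axis
            if power.shape[0] == 1 or kind == "lines":
                ax.plot(data.freqs, power[0])
                ax.set_xlabel("frequency (Hz)")
                ax.set_ylabel("power")
                ax.legend(data.channels, fontsize=7, loc="upper right")
            else:
                mesh = ax.pcolormesh(
                    data.time_vector[: power.shape[0]],
                    data.freqs,
                    power[:, :, 0].T,
                    shading="auto",
                )
                fig.colorbar(mesh, ax=ax, label="power")
                ax.set_xlabel("time (s)")
                ax.set_ylabel("frequency (Hz)")
        elif isinstance(data, CrossSpectralData):
            n_ch = len(data.channels)
            if pair is None:
                if n_ch > 1:
                    raise ParameterError(
                        "CrossSpectralData holds a full channel-by-channel matrix; "
                        "pass pair=(i, j) to select which pair to plot"
                    )
                pair = (0, 0)
            i, j = pair
            x = data.freqs if data.freqs is not None else data.lags
            vals = np.asarray(data.data[:, :, i, j])
            if np.iscomplexobj(vals):
                vals = np.abs(vals)
            ax.plot(x, vals.mean(axis=0))
            ax.set_xlabel("frequency (Hz)" if data.freqs is not None else "lag (s)")
            ax.set_ylabel(data.measure)
            ax.set_title(f"{data.channels[i]} - {data.channels[j]}")
        elif isinstance(data, SpikeData):
            for i in range(data.n_trials):
                t = data.trial_times(i)
                ax.plot(t, np.full_like(t, i), "|", color="k", markersize=3)
            ax.set_xlabel("time (s)")
            ax.set_ylabel("trial")
        else:
            raise ParameterError(f"no quickplot for {type(data).__name__}")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
    finally:
        plt.close(fig)
    return os.path.abspath(path)
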