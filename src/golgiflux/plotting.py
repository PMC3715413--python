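"""Optional matplotlib panels of converged scenario profiles.

Plotting is an optional extra; the core package never imports matplotlib.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .core import SteadyStateResult

SNARE_NAMES = ("er_v", "alpha_t", "alpha_v", "beta_t", "beta_v")
ENZYME_NAMES = ("enz_cis", "enz_med", "enz_trans")


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_profiles(
    result: SteadyStateResult,
    names: Optional[Sequence[str]] = None,
    normalize: bool = False,
    ax=None,
    **kwargs,
):
    """Pre-shift concentration profiles vs cisterna number.

    ``normalize`` scales each profile by its maximum (the convention for
    enzyme panels).
    """
    ax = _axes(ax)
    names = list(names) if names is not None else result.species_names
    x = range(1, result.profiles.shape[1] + 1)
    for name in names:
        prof = result.profile(name)
        if normalize and prof.max() > 0:
            prof = prof / prof.max()
        ax.plot(x, prof, marker="o", label=name, **kwargs)
    ax.set_xlabel("cisterna number (cis → trans)")
    ax.set_ylabel("normalized concentration" if normalize else "concentration / $C_0$")
    ax.legend()
    return ax


def plot_snare_and_enzyme_panels(result: SteadyStateResult, fig=None):
    """Two-panel figure: SNARE profiles (absolute) and enzyme profiles
    (max-normalized), the standard presentation of a full-model run."""
    import matplotlib.pyplot as plt

    if fig is None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    else:
        axes = fig.subplots(1, 2)
    present = set(result.species_names)
    plot_profiles(result, [n for n in SNARE_NAMES if n in present], ax=axes[0])
    plot_profiles(result, [n for n in ENZYME_NAMES if n in present], normalize=True, ax=axes[1])
    axes[0].set_title("SNAREs")
    axes[1].set_title("Golgi enzymes")
    fig.tight_layout()
    return fig
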