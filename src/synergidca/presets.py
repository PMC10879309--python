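"""Genotype presets for the synthetic oscillation generator.

Each preset bundles the parameters of one crossing scheme's calcium
oscillation regime: the female genotype (wild type or the *fer*/*lre*
receptor mutants, which nearly abolish oscillations) crossed with a pollen
donor (same-species wild type, the *myb97,101,120* triple mutant, or an
interspecific donor).  Wild-type same-species crosses oscillate at roughly
one transient per minute for 16-58 min of pollen-tube contact; the other
presets encode the direction and rough magnitude of the published regime
differences, not absolute calibrated values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import UnknownPresetError

__all__ = ["GenotypePreset", "make_preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class GenotypePreset:
    """Parameter bundle describing one crossing scheme's oscillation regime.

    Attributes
    ----------
    name:
        Preset identifier (one of :data:`PRESET_NAMES`).
    baseline_ratio:
        Resting YFP/CFP ratio (dimensionless ratio units).
    mean_interval_s:
        Mean inter-transient interval of the renewal process, seconds.
    interval_shape:
        Gamma shape of the interval law; larger values give more
        quasi-periodic oscillations.
    amplitude_mean:
        Mean transient amplitude in ratio units (lognormal law).
    amplitude_cv:
        Coefficient of variation of transient amplitudes.
    transient_rise_s, transient_decay_s:
        Time constants of the difference-of-exponentials transient kernel.
    burst_probability:
        Probability that the interaction ends in a terminal rupture burst.
    burst_amplitude_multiplier:
        Burst amplitude as a multiple of ``amplitude_mean``.
    """

    name: str
    baseline_ratio: float = 1.0
    mean_interval_s: float = 60.0
    interval_shape: float = 4.0
    amplitude_mean: float = 0.5
    amplitude_cv: float = 0.3
    transient_rise_s: float = 5.0
    transient_decay_s: float = 20.0
    burst_probability: float = 0.0
    burst_amplitude_multiplier: float = 3.0

    def __post_init__(self) -> None:
        for field in ("mean_interval_s", "interval_shape", "transient_rise_s",
                      "transient_decay_s"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if not 0.0 <= self.burst_probability <= 1.0:
            raise ValueError("burst_probability must lie in [0, 1]")
        if self.amplitude_mean < 0:
            raise ValueError("amplitude_mean must be non-negative")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")
        if self.transient_rise_s >= self.transient_decay_s:
            raise ValueError("transient_rise_s must be smaller than "
                             "transient_decay_s")

    def without_burst(self) -> "GenotypePreset":
        """Copy of this preset with the terminal burst disabled."""
        return replace(self, burst_probability=0.0)


_WILDTYPE = GenotypePreset(
    name="wildtype",
    mean_interval_s=60.0,      # roughly one transient per minute
    amplitude_mean=0.5,
    burst_probability=0.7,     # same-species receptions usually end in rupture
)

# fer / lre females: oscillations nearly ablated; the residual transients are
# rare and markedly less intense than wild type.  myb triple-mutant pollen:
# oscillations persist but at a lower frequency and slightly lower intensity.
# Interspecific donors share the wild-type frequency; A. lyrata transients are
# less intense while O. pumila transients are indistinguishable from wild type.
_PRESETS: dict[str, GenotypePreset] = {
    "wildtype": _WILDTYPE,
    "fer_lre_female": replace(
        _WILDTYPE, name="fer_lre_female",
        mean_interval_s=1200.0,
        amplitude_mean=0.25 * _WILDTYPE.amplitude_mean,
        burst_probability=0.0,
    ),
    "myb_pollen": replace(
        _WILDTYPE, name="myb_pollen",
        mean_interval_s=120.0,
        amplitude_mean=0.8 * _WILDTYPE.amplitude_mean,
        burst_probability=0.0,
    ),
    "interspecific_lyrata": replace(
        _WILDTYPE, name="interspecific_lyrata",
        mean_interval_s=60.0,
        amplitude_mean=0.8 * _WILDTYPE.amplitude_mean,
        burst_probability=0.0,
    ),
    "interspecific_pumila": replace(
        _WILDTYPE, name="interspecific_pumila",
        mean_interval_s=60.0,
        amplitude_mean=1.0 * _WILDTYPE.amplitude_mean,
        burst_probability=0.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def make_preset(name: str) -> GenotypePreset:
    """Return the documented parameter bundle for a crossing scheme.

    Parameters
    ----------
    name:
        One of :data:`PRESET_NAMES`.

    Raises
    ------
    UnknownPresetError
        If ``name`` is not a known preset.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        ) from None
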