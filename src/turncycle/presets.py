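"""Named generator presets matching the study conditions.

Each preset bundles the statistical structure of one recording condition:
step-period mean/SD for the four leg-side combinations of tethered curve
walking, slow pilocarpine-rhythm frequencies of the deafferented
mesothoracic ganglion, and side-specific load-response class mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

__all__ = ["GeneratorPreset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class GeneratorPreset:
    """Parameters of the synthetic recording generator.

    Phases of nerve-activity peaks are in degrees of the step cycle
    (touchdown = 0°); gait phases elsewhere are cycle fractions in [0, 1).
    """

    name: str
    mean_period: float = 0.83      # s, step period mean
    sd_period: float = 0.21        # s, step period SD
    duty_fraction: float = 0.6     # stance/(stance+swing)
    pro_peak_deg: float = 270.0    # protractor activity peak, degrees
    ret_peak_deg: float = 90.0     # retractor activity peak, degrees
    kappa: float = 4.0             # von Mises concentration of nerve phases
    base_rate: float = 40.0        # spikes/s mean motoneuron rate
    rhythm_freq_quiet: float = 0.27   # Hz, pilocarpine rhythm, quiescent
    rhythm_freq_step: float = 1.16    # Hz, pilocarpine rhythm, stepping
    p_ret_act: float = 0.662       # P(load stimulus activates retractor)
    p_pro_act: float = 0.15        # P(retractor terminated / protractor activated)
    p_none: float = 0.188          # P(no response)
    none_phase_mu: float = 0.89    # cycle fraction where no-response stimuli cluster
    none_kappa: float = 8.0        # concentration of the no-response phase
    crosstalk_coeff: float = 0.3   # antagonist bleed-through into an EMG channel
    noise_sd: float = 0.05         # additive Gaussian noise, signal units
    fs: float = 2000.0             # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_period > 0:
            raise ValueError("mean_period must be positive")
        if self.sd_period < 0:
            raise ValueError("sd_period must be non-negative")
        if not 0 < self.duty_fraction < 1:
            raise ValueError("duty_fraction must be in (0, 1)")
        if self.kappa < 0 or self.none_kappa < 0:
            raise ValueError("von Mises concentrations must be >= 0")
        total = self.p_ret_act + self.p_pro_act + self.p_none
        if abs(total - 1.0) > 1e-12:
            raise ValueError("class probabilities must sum to 1")
        if not 0 <= self.crosstalk_coeff < 1:
            raise ValueError("crosstalk_coeff must be in [0, 1)")
        if not 0 <= self.none_phase_mu < 1:
            raise ValueError("none_phase_mu must be in [0, 1)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def replace(self, **kwargs) -> "GeneratorPreset":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def _p(name: str, **kw) -> GeneratorPreset:
    return GeneratorPreset(name=name, **kw)


# Step-period means/SDs per leg and turning side; pilocarpine rhythm
# frequencies; load-response class mixtures per side.
PRESETS: dict[str, GeneratorPreset] = {
    "fl-inside": _p("fl-inside", mean_period=0.83, sd_period=0.21),
    "fl-outside": _p("fl-outside", mean_period=1.21, sd_period=0.37),
    "ml-inside": _p("ml-inside", mean_period=0.76, sd_period=0.15),
    "ml-outside": _p("ml-outside", mean_period=1.13, sd_period=0.28),
    "pilo-quiet": _p("pilo-quiet", rhythm_freq_quiet=0.27, rhythm_freq_step=1.16),
    "pilo-stepping": _p("pilo-stepping", rhythm_freq_quiet=0.27, rhythm_freq_step=1.16),
    "load-inside": _p("load-inside", p_ret_act=0.662, p_pro_act=0.15, p_none=0.188,
                      none_phase_mu=0.89, fs=1000.0),
    "load-outside": _p("load-outside", mean_period=1.21, sd_period=0.37,
                       p_ret_act=1.0, p_pro_act=0.0, p_none=0.0, fs=1000.0),
}


def get_preset(name: str, **overrides) -> GeneratorPreset:
    """Look up a named preset, optionally overriding fields."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return preset.replace(**overrides) if overrides else preset
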