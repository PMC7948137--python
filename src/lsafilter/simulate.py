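"""Synthetic multi-trial ERP generator.

Emulates the scalp topography of an evoked response at a single time
point: every electrode records the sum of a widespread Gaussian field
(the large vertex wave) and one or more local Gaussian fields, corrupted
by three noise processes —

* per-source multiplicative amplitude variability, N(1, 1) per source per
  trial (the neural trial-by-trial fluctuation the LSA filter exploits);
* additive global noise, N(0, 1 µV) per trial, identical at every
  electrode (shared electrical/neural background);
* per-electrode conductance gain, N(1, 0.05) per channel, identical
  across trials (electrode-skin interface differences).

Field widths are expressed as fractions of the cap radius (the maximal
geodesic distance from Cz).  The "nonneural" noise processes — global
additive noise and conductance gain — can be scaled jointly by a
multiplier to probe robustness; the neural amplitude variability is the
signal the adaptive filter uses and is never scaled.

With the default N(1, 1) amplitude noise a source can flip sign on a
given trial; this is intentional (the generator follows its reference
conditions literally) and is what makes the cross-trial regression
informative.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import EpochSet, Topography
from .montage import Montage, standard_105_montage

__all__ = [
    "SourceSpec",
    "NoiseSpec",
    "SimulationConfig",
    "gaussian_field",
    "simulate_epochs",
    "shift_montage",
    "single_local_config",
    "three_local_config",
    "midline_local_config",
    "widespread_only_config",
]


@dataclass
class SourceSpec:
    """A Gaussian scalp field.

    Parameters
    ----------
    center : str
        Electrode label at which the field peaks.
    peak : float
        Signed peak amplitude in µV.
    sd : float
        Spatial standard deviation as a fraction of the cap radius.
    kind : str
        ``"widespread"`` or ``"local"``.
    """

    center: str
    peak: float
    sd: float
    kind: str = "local"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"source spatial sd must be > 0, got {self.sd}")
        if self.kind not in ("widespread", "local"):
            raise ValueError(f"source kind must be widespread or local, got {self.kind!r}")


@dataclass
class NoiseSpec:
    """The three trial-to-trial variability processes.

    ``amp_sd`` is the SD of the multiplicative per-source amplitude noise
    (mean 1); ``global_sd`` the SD (µV) of the additive noise shared by
    all electrodes; ``conductance_sd`` the SD of the per-electrode gain
    (mean 1).  ``nonneural_multiplier`` jointly scales the two nonneural
    SDs (global and conductance) only.
    """

    amp_sd: float = 1.0
    global_sd: float = 1.0
    conductance_sd: float = 0.05
    nonneural_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("amp_sd", "global_sd", "conductance_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nonneural_multiplier < 1:
            raise ValueError("nonneural_multiplier must be >= 1")


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic :class:`EpochSet`.

    ``cap_shift`` displaces the *true* electrode positions along the
    mediolateral (x) axis, in mm, while labels stay nominal — emulating a
    misplaced cap whose data are analyzed as if the cap were in place.
    """

    sources: list[SourceSpec]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_trials: int = 40
    seed: int = 0
    cap_shift: float = 0.0
    n_samples: int = 1
    srate: float = 1000.0
    montage: Montage | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not self.sources:
            raise ValueError("at least one source is required")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def resolve_montage(self) -> Montage:
        return self.montage if self.montage is not None else standard_105_montage(120)

    def echo(self) -> dict:
        """JSON-serializable record of the configuration (montage omitted)."""
        d = {
            "sources": [asdict(s) for s in self.sources],
            "noise": asdict(self.noise),
            "n_trials": self.n_trials,
            "seed": self.seed,
            "cap_shift": self.cap_shift,
            "n_samples": self.n_samples,
            "srate": self.srate,
        }
        return d


def gaussian_field(montage: Montage, source: SourceSpec) -> Topography:
    """Evaluate a Gaussian scalp field at every electrode.

    The value at channel c is ``peak * exp(-d(c, center)^2 / (2 s^2))``
    where d is the geodesic scalp distance and ``s = sd * cap_radius``.
    """
    if source.sd <= 0:
        raise ValueError("source spatial sd must be > 0")
    dist = montage.scalp_distances_from(source.center)
    s = source.sd * montage.cap_radius()
    values = source.peak * np.exp(-(dist**2) / (2.0 * s**2))
    return Topography(values, montage.labels, units="uV")


def shift_montage(montage: Montage, cap_shift: float) -> Montage:
    """Displace all electrodes by ``cap_shift`` mm along the mediolateral
    axis (positive = toward the right ear) and re-project onto the head
    sphere.  Labels are unchanged."""
    shift_cm = float(cap_shift) / 10.0
    if abs(shift_cm) > montage.head_radius:
        raise ValueError(
            f"cap shift {cap_shift} mm exceeds the head radius "
            f"({montage.head_radius:.1f} cm)"
        )
    moved = montage.positions - montage.center + np.array([shift_cm, 0.0, 0.0])
    moved *= (montage.head_radius / np.linalg.norm(moved, axis=1))[:, None]
    return Montage(
        list(montage.labels),
        moved + montage.center,
        head_radius=montage.head_radius,
        center=montage.center.copy(),
    )


def simulate_epochs(config: SimulationConfig) -> EpochSet:
    """Generate a synthetic :class:`EpochSet` from ``config``.

    For trial k, channel c, sample t::

        data[k, c, t] = gain_c * ( sum_s (1 + amp_sd * z[s, k, t]) * field_s[c]
                                   + global_sd * M * g[k, t] )

    with z, g standard normal, ``gain_c ~ N(1, conductance_sd * M)`` and
    M the nonneural multiplier.  Draw order (one seeded generator): the
    per-source amplitude deviates in source list order, then the global
    deviates, then the gains — so fixtures are stable across versions.

    When ``cap_shift`` is nonzero the fields are evaluated on the shifted
    (true) electrode positions while the returned labels remain nominal.
    """
    montage = config.resolve_montage()
    field_montage = (
        shift_montage(montage, config.cap_shift) if config.cap_shift else montage
    )
    fields = np.array(
        [gaussian_field(field_montage, s).values for s in config.sources]
    )  # (n_sources, n_channels)

    rng = np.random.default_rng(config.seed)
    n_src = len(config.sources)
    k, c, t = config.n_trials, len(montage.labels), config.n_samples
    m = config.noise.nonneural_multiplier
    z = rng.standard_normal((n_src, k, t))
    g = rng.standard_normal((k, t))
    gains = 1.0 + config.noise.conductance_sd * m * rng.standard_normal(c)

    amps = 1.0 + config.noise.amp_sd * z  # (n_src, k, t)
    neural = np.einsum("skt,sc->kct", amps, fields)
    common = config.noise.global_sd * m * g  # (k, t)
    data = gains[None, :, None] * (neural + common[:, None, :])

    times = np.arange(t) / config.srate
    return EpochSet(
        data,
        list(montage.labels),
        times,
        config.srate,
        units="uV",
        provenance={"seed": config.seed, "config": config.echo()},
    )


# -- canonical study configurations ------------------------------------------

def _widespread() -> SourceSpec:
    return SourceSpec("Cz", -20.0, 0.5, kind="widespread")


def single_local_config(seed: int = 0, nonneural_multiplier: float = 1.0,
                        montage: Montage | None = None) -> SimulationConfig:
    """Widespread −20 µV vertex field plus one −1 µV local field at C3."""
    return SimulationConfig(
        sources=[_widespread(), SourceSpec("C3", -1.0, 0.2)],
        noise=NoiseSpec(nonneural_multiplier=nonneural_multiplier),
        seed=seed,
        montage=montage,
    )


def three_local_config(seed: int = 0, montage: Montage | None = None) -> SimulationConfig:
    """Widespread vertex field plus three local fields.

    Peaks −1, +1 and −0.7 µV with spatial SDs of 20%, 20% and 30% of the
    cap radius.  Centers (C3, C4, P7) are the package's choice: two
    roughly mirror-located sources of opposite polarity plus a posterior
    one, the arrangement in which the contralateral difference merges
    sources with their spurious mirror images.
    """
    return SimulationConfig(
        sources=[
            _widespread(),
            SourceSpec("C3", -1.0, 0.2),
            SourceSpec("C4", 1.0, 0.2),
            SourceSpec("P7", -0.7, 0.3),
        ],
        seed=seed,
        montage=montage,
    )


def midline_local_config(seed: int = 0, montage: Montage | None = None) -> SimulationConfig:
    """Widespread vertex field plus one −1 µV local field on the midline (Fz)."""
    return SimulationConfig(
        sources=[_widespread(), SourceSpec("Fz", -1.0, 0.2)],
        seed=seed,
        montage=montage,
    )


def widespread_only_config(seed: int = 0, cap_shift: float = 0.0,
                           montage: Montage | None = None) -> SimulationConfig:
    """Widespread vertex field only (optionally with a mediolateral cap
    shift in mm); used for false-positive tests."""
    return SimulationConfig(
        sources=[_widespread()],
        seed=seed,
        cap_shift=cap_shift,
        montage=montage,
    )
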