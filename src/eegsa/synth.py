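"""Seeded synthetic EEG cohorts with planted group-level band-ratio differences.

Each channel is a sum of band-limited sinusoids (one tone per canonical EEG
band, placed at an integer frequency near the band center so a 1-s DFT grid
captures it in a single bin), plus 1/f "pink" background noise, a 50 Hz
mains component and sporadic high-amplitude half-sine artifacts exceeding
the 200 µV rejection rule.

The tone amplitudes are calibrated from target band-power ratios via the
analytic power of a sinusoid (A²/2): given targets for α/β and (α+θ)/β the
three θ/α/β powers are fixed up to an overall scale, so the empirical
region-wise ratio metrics converge to the configured targets as the
recording length grows.

Two calibration constructors are provided:

* :func:`amplitudes_from_ratios` — hit arbitrary α/β and (α+θ)/β targets
  (used to reproduce published group means for a single group/region);
* :func:`default_spec` — the default two-group cohort, which plants group
  differences *only* in the frontal and central regions and only in the
  α/β, θ/(α+θ) and (α+θ)/β metrics.  This uses the unique construction
  θ-power = β-power (then θ/β and (α+θ)/(α+β) are identically 1 in both
  groups while the trio moves with the α power), so the correlation
  screening stage has an exactly known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .recording import GROUPS, REGIONS, ArtifactEvent, RawRecording

#: Integer tone frequency per band (Hz), inside the contiguous band intervals.
BAND_TONE_HZ: dict[str, float] = {
    "delta": 3.0,
    "theta": 7.0,
    "alpha": 12.0,
    "beta": 23.0,
    "gamma": 45.0,
}

_BANDS = tuple(BAND_TONE_HZ)


@dataclass
class SynthSpec:
    """Parameters of the synthetic cohort generator.

    ``band_amplitudes[group][region][band]`` is the group-mean oscillation
    amplitude in µV; ``alpha_ratio_sd[group][region]`` the between-subject
    standard deviation of the subject-level α/β power-ratio target (0
    disables subject scatter).
    """

    sampling_rate: float = 256.0
    duration: float = 300.0
    channels_per_region: dict[str, int] = field(
        default_factory=lambda: {"F": 2, "C": 2, "P": 2, "O": 2}
    )
    band_amplitudes: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    alpha_ratio_sd: dict[str, dict[str, float]] = field(default_factory=dict)
    band_freqs: dict[str, float] = field(default_factory=lambda: dict(BAND_TONE_HZ))
    pink_noise_sd: float = 5.0
    line_noise_amp: float = 2.0
    artifact_rate: float = 0.5  # events per minute
    artifact_peak_range: tuple[float, float] = (250.0, 400.0)
    artifact_duration_range: tuple[float, float] = (0.2, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 2 * max(self.band_freqs.values()):
            raise ValueError("sampling_rate must exceed twice the highest band tone")
        if self.duration < 5.0:
            raise ValueError("duration must allow at least one 5 s epoch")
        for region, n in self.channels_per_region.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if n < 1:
                raise ValueError(f"region {region!r} needs >= 1 channel")
        for group, per_region in self.band_amplitudes.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            for region, amps in per_region.items():
                if region not in REGIONS:
                    raise ValueError(f"unknown region {region!r}")
                for band, a in amps.items():
                    if a < 0:
                        raise ValueError(f"negative amplitude for {group}/{region}/{band}")
        if min(self.artifact_peak_range) <= 200.0:
            raise ValueError("artifact peaks must exceed the 200 µV rejection rule")
        if self.pink_noise_sd < 0 or self.line_noise_amp < 0 or self.artifact_rate < 0:
            raise ValueError("noise parameters must be non-negative")


def amplitudes_from_ratios(
    alpha_beta: float,
    alphatheta_beta: float,
    beta_amp: float = 10.0,
    delta_amp: float = 4.0,
    gamma_amp: float = 2.0,
) -> dict[str, float]:
    """Tone amplitudes whose analytic powers (A²/2) hit ratio targets.

    Given target α/β and (α+θ)/β power ratios and a β amplitude, solves
    P_α = (α/β)·P_β and P_θ = ((α+θ)/β − α/β)·P_β.  Requires
    ``alphatheta_beta > alpha_beta`` (θ power must be positive).
    """
    if alphatheta_beta <= alpha_beta:
        raise ValueError("(alpha+theta)/beta target must exceed alpha/beta target")
    if alpha_beta <= 0 or beta_amp <= 0:
        raise ValueError("targets and beta amplitude must be positive")
    p_beta = beta_amp**2 / 2.0
    p_alpha = alpha_beta * p_beta
    p_theta = (alphatheta_beta - alpha_beta) * p_beta
    return {
        "delta": delta_amp,
        "theta": float(np.sqrt(2 * p_theta)),
        "alpha": float(np.sqrt(2 * p_alpha)),
        "beta": beta_amp,
        "gamma": gamma_amp,
    }


#: Group-mean α/β targets per region for the default cohort.  F and C use
#: the published group means; P and O are identical across groups (no
#: planted difference).  Between-subject scatter follows the published α/β
#: standard deviations for F and C.
_DEFAULT_ALPHA_BETA = {
    "high": {"F": 0.457, "C": 0.462, "P": 0.473, "O": 0.457},
    "low": {"F": 0.752, "C": 0.812, "P": 0.473, "O": 0.457},
}
_DEFAULT_ALPHA_SD = {
    "high": {"F": 0.003, "C": 0.034, "P": 0.05, "O": 0.05},
    "low": {"F": 0.102, "C": 0.015, "P": 0.05, "O": 0.05},
}


def default_spec(
    duration: float = 300.0,
    pink_noise_sd: float = 5.0,
    line_noise_amp: float = 2.0,
    artifact_rate: float = 0.5,
    seed: int = 0,
) -> SynthSpec:
    """The default two-group cohort spec (differences in F/C trio only).

    θ power equals β power in every group and region, so θ/β and
    (α+θ)/(α+β) carry no group information; the α/β, θ/(α+θ) and (α+θ)/β
    metrics differ between groups in F and C only.
    """
    amps: dict[str, dict[str, dict[str, float]]] = {}
    for group in GROUPS:
        amps[group] = {}
        for region in ("F", "C", "P", "O"):
            ab = _DEFAULT_ALPHA_BETA[group][region]
            # theta power = beta power  =>  (α+θ)/β target = α/β + 1
            amps[group][region] = amplitudes_from_ratios(ab, ab + 1.0)
    return SynthSpec(
        duration=duration,
        band_amplitudes=amps,
        alpha_ratio_sd={g: dict(_DEFAULT_ALPHA_SD[g]) for g in GROUPS},
        pink_noise_sd=pink_noise_sd,
        line_noise_amp=line_noise_amp,
        artifact_rate=artifact_rate,
        seed=seed,
    )


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, scaled to standard deviation sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    shaped = np.fft.irfft(spec * shaping, n=n)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def generate_recording(
    spec: SynthSpec, group: str, subject_id: str, seed: int
) -> RawRecording:
    """One synthetic multi-channel recording for a subject of ``group``.

    Deterministic: identical (spec, group, subject_id, seed) reproduce the
    sample series bit for bit.
    """
    spec.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if group not in spec.band_amplitudes:
        raise ValueError(f"spec has no band amplitudes for group {group!r}")
    # independent child streams: signal noise/phases vs artifact placement,
    # so the artifact draw is reproducible from the seed alone
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    art_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs

    channels: list[tuple[str, str]] = []
    per_region = spec.band_amplitudes[group]
    for region in per_region:
        count = spec.channels_per_region.get(region, 0)
        if count < 1:
            raise ValueError(f"no channel count configured for region {region!r}")
        for k in range(count):
            channels.append((f"{region}{k + 1}", region))

    data = np.zeros((len(channels), n))
    ch = 0
    for region, amps in per_region.items():
        # per-subject scatter: jitter the alpha amplitude so the subject's
        # α/β power ratio is N(group target, alpha_ratio_sd)
        sd = spec.alpha_ratio_sd.get(group, {}).get(region, 0.0)
        region_amps = dict(amps)
        if sd > 0 and amps.get("beta", 0) > 0:
            p_beta = amps["beta"] ** 2 / 2.0
            target = (amps.get("alpha", 0.0) ** 2 / 2.0) / p_beta
            drawn = max(1e-3, rng.normal(target, sd))
            region_amps["alpha"] = float(np.sqrt(2 * drawn * p_beta))
        for _ in range(spec.channels_per_region[region]):
            sig = np.zeros(n)
            for band in _BANDS:
                a = region_amps.get(band, 0.0)
                phase = rng.uniform(0, 2 * np.pi)
                if a > 0:
                    sig += a * np.sin(2 * np.pi * spec.band_freqs[band] * t + phase)
            sig += _pink_noise(n, spec.pink_noise_sd, rng)
            if spec.line_noise_amp > 0:
                sig += spec.line_noise_amp * np.sin(
                    2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
                )
            data[ch] = sig
            ch += 1

    # amplitude artifacts: Poisson count at the configured events/minute
    artifacts: list[ArtifactEvent] = []
    n_events = art_rng.poisson(spec.artifact_rate * spec.duration / 60.0)
    for _ in range(n_events):
        channel = int(art_rng.integers(0, len(channels)))
        dur = art_rng.uniform(*spec.artifact_duration_range)
        peak = art_rng.uniform(*spec.artifact_peak_range)
        start = art_rng.uniform(0, max(spec.duration - dur, 0))
        sign = 1.0 if art_rng.random() < 0.5 else -1.0
        i0 = int(round(start * fs))
        width = max(2, int(round(dur * fs)))
        i1 = min(i0 + width, n)
        pulse = np.sin(np.linspace(0, np.pi, i1 - i0)) * peak * sign
        data[channel, i0:i1] += pulse
        artifacts.append(ArtifactEvent(channel, start, dur, peak * sign))

    return RawRecording(
        subject_id=subject_id,
        channels=channels,
        sampling_rate=fs,
        data=data,
        group=group,
        artifacts=artifacts,
    )


def subject_seed(master_seed: int, group: str, index: int) -> int:
    """Deterministic per-subject seed, independent of cohort ordering."""
    gcode = GROUPS.index(group)
    ss = np.random.SeedSequence(entropy=(int(master_seed), gcode, int(index)))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    spec: SynthSpec, n_high: int, n_low: int, seed: int | None = None
) -> list[RawRecording]:
    """A labeled cohort: ``n_high`` high-SA and ``n_low`` low-SA subjects.

    Each subject's seed derives deterministically from the master seed and
    the subject's (group, index), so regenerating any subject in isolation
    reproduces its series.
    """
    if n_high < 1 or n_low < 1:
        raise ValueError("both group sizes must be >= 1")
    master = spec.seed if seed is None else seed
    recs: list[RawRecording] = []
    for i in range(n_high):
        recs.append(
            generate_recording(spec, "high", f"H{i + 1:02d}", subject_seed(master, "high", i))
        )
    for i in range(n_low):
        recs.append(
            generate_recording(spec, "low", f"L{i + 1:02d}", subject_seed(master, "low", i))
        )
    return recs


# ---------------------------------------------------------------------------
# Spec (de)serialization


def spec_to_yaml(spec: SynthSpec, path: str | Path) -> None:
    payload = {
        "sampling_rate": spec.sampling_rate,
        "duration": spec.duration,
        "channels_per_region": spec.channels_per_region,
        "band_amplitudes": spec.band_amplitudes,
        "alpha_ratio_sd": spec.alpha_ratio_sd,
        "band_freqs": spec.band_freqs,
        "pink_noise_sd": spec.pink_noise_sd,
        "line_noise_amp": spec.line_noise_amp,
        "artifact_rate": spec.artifact_rate,
        "artifact_peak_range": list(spec.artifact_peak_range),
        "artifact_duration_range": list(spec.artifact_duration_range),
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def spec_from_yaml(path: str | Path) -> SynthSpec:
    payload = yaml.safe_load(Path(path).read_text())
    payload["artifact_peak_range"] = tuple(payload["artifact_peak_range"])
    payload["artifact_duration_range"] = tuple(payload["artifact_duration_range"])
    return SynthSpec(**payload)
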